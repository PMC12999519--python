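"""Reference-based bulk deconvolution and cell-proportion association tests.

The signature is built from per-type mean CPM over reference cells,
restricted to the top-specificity marker genes per type; proportions are
estimated by non-negative least squares on the marker genes followed by
renormalization onto the simplex.  Proportion changes are tested on the
adjusted-logit scale with the same mixed-model machinery used for
differential expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .diffexpr import contrast_form_vs_control, fit_cohort_lmm
from .containers import ExprMatrix
from .enrich import adjust_bh, specificity_from_profiles


def build_signature(
    cell_counts: pd.DataFrame,
    labels: pd.Series,
    n_markers_per_type: int = 50,
):
    """Per-type mean CPM signature restricted to the marker-gene union.

    ``cell_counts`` is cell x gene; markers are the genes with highest
    specificity for each type.  Returns ``(signature, markers, warnings)``
    with signature gene x type.
    """
    if labels.nunique() < 2:
        raise ValueError("need at least 2 cell types")
    depth = cell_counts.sum(axis=1).astype(float)
    cpm = cell_counts.div(depth, axis=0) * 1e6
    profiles = cpm.groupby(labels).mean().T  # gene x type
    profiles = profiles.reindex(sorted(profiles.columns), axis=1)
    spec = specificity_from_profiles(profiles)
    warnings = []
    markers: dict = {}
    for t in profiles.columns:
        ranked = spec[t].sort_values(ascending=False)
        chosen = ranked.head(n_markers_per_type)
        if (chosen <= 1.0 / len(profiles.columns) + 1e-12).all():
            warnings.append(f"type {t!r}: no distinctly specific markers")
        markers[t] = set(chosen.index)
    union = sorted(set().union(*markers.values()))
    return profiles.loc[union], markers, warnings


def estimate_proportions(bulk_cpm: pd.DataFrame, signature: pd.DataFrame) -> pd.DataFrame:
    """Per-sample NNLS decomposition of bulk CPM on the signature.

    ``bulk_cpm`` is gene x sample on the linear CPM scale.  Estimates are
    renormalized to sum to 1; the residual norm is stored in
    ``attrs['residual_norm']``.
    """
    shared = signature.index.intersection(bulk_cpm.index)
    if len(shared) < 10:
        raise ValueError("fewer than 10 shared marker genes")
    S = signature.loc[shared].values
    if np.linalg.matrix_rank(S) < S.shape[1]:
        raise ValueError("singular signature matrix")
    # expression noise is roughly multiplicative, so weight rows by the
    # inverse signature scale to keep high-expression markers from
    # dominating the squared loss
    scale = np.maximum(S.mean(axis=1), 1e-8)
    Sw = S / scale[:, None]
    out = np.empty((bulk_cpm.shape[1], S.shape[1]))
    resid = np.empty(bulk_cpm.shape[1])
    for j, c in enumerate(bulk_cpm.columns):
        w, r = nnls(Sw, bulk_cpm.loc[shared, c].values / scale)
        total = w.sum()
        out[j] = w / total if total > 0 else 1.0 / S.shape[1]
        resid[j] = r
    props = pd.DataFrame(out, index=bulk_cpm.columns, columns=signature.columns)
    props.attrs["residual_norm"] = pd.Series(resid, index=bulk_cpm.columns)
    return props


def adjusted_logit(p, a: float = 0.001) -> np.ndarray:
    """logit of p* = a + (1 - 2a) p; strictly increasing on [0, 1]."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    q = a + (1.0 - 2.0 * a) * p
    return np.log(q / (1.0 - q))


def proportion_association(
    props: pd.DataFrame,
    meta: pd.DataFrame,
    a: float = 0.001,
    random_group: str = "individual_id",
    covariates: tuple = (),
) -> pd.DataFrame:
    """Per-day form-vs-control Wald contrasts of adjusted-logit proportions.

    Each cell type is treated as a response in the mixed model (random
    intercept by individual); BH across all rows.
    """
    meta = meta.loc[props.index]
    logit_vals = pd.DataFrame(
        adjusted_logit(props.values, a=a), index=props.index, columns=props.columns
    )
    # cell types as "genes": build a gene x sample ExprMatrix-shaped frame
    y = logit_vals.T
    expr = ExprMatrix(
        values=y, norm_factors=pd.Series(1.0, index=y.columns), offset=0.0
    )
    fit = fit_cohort_lmm(expr, meta, covariates=covariates, random_group=random_group)
    rows = []
    for day in sorted(meta["day"].unique()):
        for form in sorted(set(meta["form"]) - {"control"}):
            try:
                res = contrast_form_vs_control(fit, form, day)
            except ValueError:
                continue
            res = res.rename(columns={"gene": "celltype"})
            rows.append(res)
    out = pd.concat(rows, ignore_index=True)
    out["fdr"] = adjust_bh(out["p"].values)
    return out
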