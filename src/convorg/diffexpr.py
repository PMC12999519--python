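"""Per-gene mixed-model differential expression and cross-form meta-analysis.

The model follows the cell-means parameterization: one coefficient per
(form, day) cell plus the nuisance covariates, with a single random
intercept (individual by default).  Form-vs-control contrasts at each
day are Wald t-tests; Benjamini-Hochberg correction is applied within
each (form, day) family.  The cross-form meta-analysis is a fixed-effect
inverse-variance model per gene and day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CONTROL, ExprMatrix
from .enrich import adjust_bh
from .lmm import LmmFit, fit_gene_lmm

DEFAULT_COVARIATES = ("sex", "batch", "ancestry_pc1", "ancestry_pc2", "seq_pc1", "seq_pc2")


def _cellmeans_design(meta: pd.DataFrame, covariates) -> pd.DataFrame:
    """Full-rank design: one indicator per (form, day) cell + centered covariates."""
    cells = meta["form"].astype(str) + "@" + meta["day"].astype(str)
    X = pd.get_dummies(cells, dtype=float)
    X.columns = [f"cell[{c}]" for c in X.columns]
    for cov in covariates:
        if cov not in meta.columns:
            continue
        col = meta[cov]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            for c in dummies.columns:
                X[c] = dummies[c] - dummies[c].mean()
        else:
            X[cov] = col.astype(float) - col.astype(float).mean()
    X.index = meta.index
    return X


def fit_cohort_lmm(
    expr: ExprMatrix,
    meta: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    random_group: str = "individual_id",
) -> LmmFit:
    """Fit the per-gene mixed model over the whole cohort.

    The random intercept groups samples from the same individual; pass a
    different nesting column (line_id, differentiation_id) to change the
    grouping.
    """
    meta = meta.loc[expr.values.columns]
    X = _cellmeans_design(meta, covariates)
    return fit_gene_lmm(expr.values, X, meta[random_group])


def contrast_form_vs_control(fit: LmmFit, form: str, day) -> pd.DataFrame:
    """DE rows for one form at one day versus control at the same day."""
    name_f = f"cell[{form}@{day}]"
    name_c = f"cell[{CONTROL}@{day}]"
    for name in (name_f, name_c):
        if name not in fit.coef_names:
            raise ValueError(f"missing design cell {name!r}")
    c = np.zeros(len(fit.coef_names))
    c[fit.coef_names.index(name_f)] = 1.0
    c[fit.coef_names.index(name_c)] = -1.0
    out = fit.contrast(c)
    out.insert(0, "day", day)
    out.insert(0, "form", form)
    out.insert(0, "gene", out.index)
    out["fdr"] = adjust_bh(out["p"].values)
    return out.reset_index(drop=True)


def de_all_contrasts(fit: LmmFit, meta: pd.DataFrame) -> pd.DataFrame:
    """Every (affected form, day) contrast present in the design."""
    rows = []
    days = sorted(meta["day"].unique())
    forms = [f for f in meta["form"].unique() if f != CONTROL]
    for day in days:
        for form in sorted(forms):
            if f"cell[{form}@{day}]" in fit.coef_names:
                rows.append(contrast_form_vs_control(fit, form, day))
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------- meta-analysis

def meta_fixed_effect(results: pd.DataFrame, include_forms=None) -> pd.DataFrame:
    """Fixed-effect inverse-variance meta-analysis per gene and day.

    Weights are 1/se^2; beta = sum(w b)/sum(w), se = 1/sqrt(sum w),
    z = beta/se with a two-sided normal p and BH correction per day.
    Requires >= 2 forms per gene x day.
    """
    df = results if include_forms is None else results[results["form"].isin(include_forms)]
    if (df["se"] <= 0).any():
        raise ValueError("all standard errors must be positive")
    rows = []
    for (gene, day), grp in df.groupby(["gene", "day"], sort=True):
        if len(grp) < 2:
            raise ValueError(f"gene {gene} day {day}: meta-analysis needs >= 2 forms")
        w = 1.0 / grp["se"].values ** 2
        beta = float(np.sum(w * grp["logFC"].values) / np.sum(w))
        se = float(1.0 / np.sqrt(np.sum(w)))
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(dict(gene=gene, day=day, beta=beta, se=se, z=z, p=p))
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    for day, grp in out.groupby("day"):
        out.loc[grp.index, "fdr"] = adjust_bh(grp["p"].values)
    return out


# ------------------------------------------------------------- summaries

def cnv_dosage_summary(
    results: pd.DataFrame, cnv_gene_sets: dict, dosages: dict, fdr_cut: float = 0.005
) -> pd.DataFrame:
    """Per-form CNV dosage check: direction agreement and significance.

    ``dosages`` maps form -> dosage (e.g. 0.5 deletion, 1.5 duplication);
    the expected logFC direction is negative for dosage < 1 and positive
    for dosage > 1.  Fractions are NaN when no CNV gene was tested.
    """
    rows = []
    tested_forms = set(results["form"])
    for form, genes in cnv_gene_sets.items():
        if form not in tested_forms:
            raise ValueError(f"unknown form {form!r} in CNV sets")
        if not genes:
            raise ValueError(f"empty CNV set for form {form!r}")
        sub = results[(results["form"] == form) & results["gene"].isin(genes)]
        n = len(sub["gene"].unique())
        if n == 0:
            rows.append(dict(form=form, n_genes=0, frac_expected_direction=np.nan,
                             frac_significant=np.nan))
            continue
        sign = -1.0 if dosages[form] < 1.0 else 1.0
        rows.append(
            dict(
                form=form,
                n_genes=n,
                frac_expected_direction=float((np.sign(sub["logFC"]) == sign).mean()),
                frac_significant=float((sub["fdr"] < fdr_cut).mean()),
            )
        )
    return pd.DataFrame(rows)


def peak_expression_day(expr: ExprMatrix, meta: pd.DataFrame) -> pd.Series:
    """Day of maximum mean expression per gene; ties go to the earliest day."""
    days = sorted(meta["day"].unique())
    if len(days) < 2:
        raise ValueError("need at least 2 days")
    means = pd.DataFrame(
        {d: expr.values.loc[:, meta.index[meta["day"] == d]].mean(axis=1) for d in days}
    )
    idx = np.argmax(means.values, axis=1)  # argmax takes the first maximum
    return pd.Series([days[i] for i in idx], index=expr.values.index, name="peak_day")
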