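"""CROP-seq style CRISPRi validation: cell QC, gRNA assignment,
knockdown quantification and pseudobulk differential expression."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .enrich import adjust_bh


def cell_qc(
    counts: pd.DataFrame,
    mito_genes,
    min_features: int = 200,
    max_mito_frac: float = 0.10,
):
    """Keep cells with > min_features genes and mito fraction < max_mito_frac.

    Both inequalities are strict.  ``counts`` is cell x gene.  An empty
    mito list skips the mito filter with a warning.
    Returns ``(filtered_counts, warnings)``.
    """
    warnings = []
    n_features = (counts.values > 0).sum(axis=1)
    keep = n_features > min_features
    mito = [g for g in mito_genes if g in counts.columns]
    if not mito:
        warnings.append("empty mitochondrial gene list: mito filter skipped")
    else:
        depth = counts.values.sum(axis=1).astype(float)
        mito_frac = counts.loc[:, mito].values.sum(axis=1) / np.maximum(depth, 1.0)
        keep &= mito_frac < max_mito_frac
    return counts.loc[keep], warnings


def assign_grnas(
    grna_umis: pd.DataFrame,
    guide_map: pd.DataFrame,
    min_umi: int = 10,
    target_level: bool = True,
) -> pd.DataFrame:
    """Assign each cell the unique target whose guide passes the UMI cut.

    ``grna_umis`` is long (cell, guide, umi); ``guide_map`` maps guide ->
    (target, is_ntc).  The UMI threshold applies per guide; guides of the
    same target then collapse to one target (``target_level=True``, the
    default) or are required to be a single guide (``target_level=False``).
    A cell is assigned iff exactly one target (or guide) passes.
    """
    unmapped = set(grna_umis["guide"]) - set(guide_map.index)
    if unmapped:
        raise ValueError(f"unmapped guide: {sorted(unmapped)[0]!r}")
    rows = []
    for cell, grp in grna_umis.groupby("cell"):
        passing = grp[grp["umi"] >= min_umi]
        targets = guide_map.loc[passing["guide"], "target"]
        units = sorted(set(targets)) if target_level else sorted(passing["guide"])
        if len(units) == 1:
            tgt = units[0] if target_level else guide_map.loc[units[0], "target"]
            umi = int(passing.loc[targets.values == tgt, "umi"].sum()) if target_level else int(
                passing.set_index("guide").loc[units[0], "umi"]
            )
            rows.append(dict(cell=cell, assigned=tgt, umi=umi,
                             n_guides=int(grp["guide"].nunique())))
        else:
            rows.append(dict(cell=cell, assigned=None, umi=int(grp["umi"].max()),
                             n_guides=int(grp["guide"].nunique())))
    return pd.DataFrame(rows).set_index("cell")


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    depth = counts.sum(axis=1).astype(float)
    return counts.div(np.maximum(depth, 1.0), axis=0) * 1e6


def knockdown_ratio(
    counts: pd.DataFrame,
    assignments: pd.DataFrame,
    target: str,
    replicates: pd.Series,
    ntc_label: str = "NTC",
) -> pd.Series:
    """Remaining target expression in target cells relative to NTC, per replicate.

    ratio = mean CPM of the target gene in target-assigned cells / mean
    in NTC-assigned cells.  Replicates without target cells, or with zero
    NTC expression, are reported missing.
    """
    cpm = _cpm(counts)[target]
    assigned = assignments["assigned"]
    out = {}
    for rep in sorted(replicates.unique()):
        cells = replicates.index[replicates == rep]
        tgt_cells = [c for c in cells if assigned.get(c) == target]
        ntc_cells = [c for c in cells if assigned.get(c) == ntc_label]
        if not tgt_cells or not ntc_cells:
            out[rep] = np.nan
            continue
        denom = cpm.loc[ntc_cells].mean()
        out[rep] = float(cpm.loc[tgt_cells].mean() / denom) if denom > 0 else np.nan
    return pd.Series(out, name=f"kd_ratio_{target}")


def _squeeze_var(s2: np.ndarray, df: float):
    """Empirical-Bayes variance moderation (scaled inverse-chi-square prior).

    Method-of-moments on log s^2: solve trigamma(d0/2) = var(log s2) -
    trigamma(df/2); returns (prior_df, prior_var, moderated s^2).
    """
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    var_z = max(np.var(z, ddof=1) - special.polygamma(1, df / 2.0), 0.0)
    if var_z <= 1e-10:
        d0 = np.inf
        s0 = float(np.exp(e.mean()))
        return d0, s0, np.full_like(s2, s0)
    # invert trigamma by Newton iteration (limma's approach)
    y = var_z
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        delta = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s0 = float(np.exp(e.mean() + special.digamma(x) - np.log(x)))
    s2_mod = (d0 * s0 + df * s2) / (d0 + df)
    return d0, s0, s2_mod


def pseudobulk_de(
    counts: pd.DataFrame,
    assignments: pd.DataFrame,
    target: str,
    replicates: pd.Series,
    ntc_label: str = "NTC",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Moderated two-sample test of target cells vs NTC on pseudobulk log2-CPM.

    Counts are summed per (arm, replicate), converted to log2 CPM, and a
    per-gene two-sample t-test with an empirical-Bayes shrunken pooled
    variance compares arms; logFC sign is target minus NTC; BH applied.
    """
    assigned = assignments["assigned"]
    arms = {}
    for arm, label in (("target", target), ("ntc", ntc_label)):
        cols = {}
        for rep in sorted(replicates.unique()):
            cells = [
                c for c in replicates.index[replicates == rep]
                if assigned.get(c) == label and c in counts.index
            ]
            if cells:
                cols[f"{arm}_{rep}"] = counts.loc[cells].sum(axis=0)
        if len(cols) < 2:
            raise ValueError(f"arm {arm!r} has fewer than 2 replicates with cells")
        arms[arm] = pd.DataFrame(cols)
    pb = pd.concat([arms["target"], arms["ntc"]], axis=1)
    depth = pb.sum(axis=0).astype(float)
    logcpm = np.log2((pb + pseudocount).div(depth + 2 * pseudocount, axis=1) * 1e6)
    t_cols = list(arms["target"].columns)
    c_cols = list(arms["ntc"].columns)
    n1, n2 = len(t_cols), len(c_cols)
    m1 = logcpm[t_cols].mean(axis=1).values
    m2 = logcpm[c_cols].mean(axis=1).values
    v1 = logcpm[t_cols].var(axis=1, ddof=1).values
    v2 = logcpm[c_cols].var(axis=1, ddof=1).values
    df = float(n1 + n2 - 2)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    d0, _, s2_mod = _squeeze_var(s2, df)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    tstat = (m1 - m2) / np.maximum(se, 1e-12)
    df_total = df + (d0 if np.isfinite(d0) else 1e6)
    p = np.clip(2.0 * stats.t.sf(np.abs(tstat), df_total), 1e-300, 1.0)
    out = pd.DataFrame(
        {"logFC": m1 - m2, "stat": tstat, "p": p}, index=logcpm.index
    )
    out["fdr"] = adjust_bh(out["p"].values)
    return out
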