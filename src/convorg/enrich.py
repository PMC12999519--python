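"""Gene-set enrichment: Fisher/hypergeometric tests, EWCE-style bootstrap
cell-type enrichment, and the shared Benjamini-Hochberg utility."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def adjust_bh(p, grouping=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, optionally within groups."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if grouping is not None:
        grouping = np.asarray(grouping)
        out = np.empty_like(p)
        for g in np.unique(grouping):
            sel = grouping == g
            out[sel] = adjust_bh(p[sel])
        return out
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _contingency(set_a, set_b, universe):
    universe = set(universe)
    a = set(set_a) & universe
    b = set(set_b) & universe
    if not a or not b:
        raise ValueError("empty gene set after harmonization to universe")
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(universe) - n11 - n10 - n01
    return np.array([[n11, n10], [n01, n00]])


def fisher_enrichment(set_a, set_b, universe):
    """Two-sided Fisher exact test of overlap between two gene sets.

    Returns ``(odds_ratio, p, table)``.  The odds ratio is the sample OR
    (n11*n00)/(n10*n01), with Haldane's 0.5 correction added to every
    cell when any cell is zero.  The two-sided p sums hypergeometric
    probabilities of tables at most as probable as the observed one.
    """
    table = _contingency(set_a, set_b, universe)
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    oddsratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(oddsratio), float(p), table


def hypergeometric_overlap(set_a, set_b, universe) -> float:
    """Upper-tail hypergeometric p: P(overlap >= observed)."""
    table = _contingency(set_a, set_b, universe)
    n11 = table[0, 0]
    K = table[0, 0] + table[0, 1]  # |A|
    k = table[0, 0] + table[1, 0]  # |B|
    N = table.sum()
    if n11 > min(K, k):
        raise ValueError("overlap larger than smallest set (impossible input)")
    return float(stats.hypergeom.sf(n11 - 1, N, K, k))


def ewce_bootstrap(
    gene_set,
    specificity: pd.DataFrame,
    n_boot: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-type enrichment of a gene set by specificity bootstrap.

    ``specificity`` is gene x cell-type with rows summing to 1 (each
    gene's mean-expression share across types).  The observed statistic
    is the mean specificity of the set per type; the null resamples
    same-size gene sets from the background.  p uses the add-one rule
    (never exactly 0), fold = observed / mean(null), BH across types.
    """
    genes = [g for g in gene_set if g in specificity.index]
    missing = set(gene_set) - set(genes)
    if missing:
        raise ValueError(f"genes absent from specificity background: {sorted(missing)[:5]}")
    k = len(genes)
    if k == 0:
        raise ValueError("empty gene set")
    if k > specificity.shape[0]:
        raise ValueError("gene set larger than background")
    rng = np.random.default_rng(seed)
    spec = specificity.values
    obs = specificity.loc[genes].mean(axis=0).values
    idx = rng.integers(0, spec.shape[0], size=(n_boot, k))
    null_means = spec[idx].mean(axis=1)  # n_boot x types
    p = (1.0 + (null_means >= obs[None, :]).sum(axis=0)) / (n_boot + 1.0)
    fold = obs / null_means.mean(axis=0)
    out = pd.DataFrame(
        {"fold": fold, "p": p}, index=specificity.columns
    )
    out["fdr"] = adjust_bh(out["p"].values)
    return out


def specificity_from_profiles(mean_profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-gene specificity: share of each gene's mean expression per type.

    ``mean_profiles`` is gene x cell-type (e.g. mean CPM per type); rows
    with all-zero expression are dropped.
    """
    vals = mean_profiles.values.astype(float)
    totals = vals.sum(axis=1)
    keep = totals > 0
    spec = vals[keep] / totals[keep, None]
    return pd.DataFrame(spec, index=mean_profiles.index[keep], columns=mean_profiles.columns)


def enrichment_table(query_sets: dict, target_sets: dict, universe) -> pd.DataFrame:
    """Fisher enrichment of every query set against every target list."""
    rows = []
    for qname, q in query_sets.items():
        for tname, t in target_sets.items():
            try:
                oratio, p, table = fisher_enrichment(q, t, universe)
            except ValueError:
                continue
            rows.append(
                dict(
                    set=qname, list=tname, odds_ratio=oratio, p=p,
                    n11=table[0, 0], n10=table[0, 1], n01=table[1, 0], n00=table[1, 1],
                )
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = adjust_bh(out["p"].values)
    return out
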