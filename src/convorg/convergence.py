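"""Cross-form convergence over differentiation time.

Builds the gene x condition (form x day) logFC matrix, clusters
conditions (Ward on Euclidean distances of the Spearman correlation
rows, i.e. ward.D2 semantics), attaches multiscale-bootstrap support
values (BP and the approximately-unbiased AU from the two-parameter
probit fit), measures clustering concordance across linkage/distance
choices, and runs the per-day correlation trend test (ANOVA + Tukey HSD
over all pairwise form correlations per day).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


# ----------------------------------------------------------- logFC matrix

def condition_logfc_matrix(de: pd.DataFrame) -> pd.DataFrame:
    """Gene x condition matrix of logFC, restricted to shared genes.

    Conditions are labelled ``form@day``.  Genes missing from any
    condition are dropped from all.
    """
    mat = de.pivot_table(
        index="gene",
        columns=de["form"].astype(str) + "@" + de["day"].astype(str),
        values="logFC",
    )
    mat = mat.dropna(axis=0, how="any")
    if mat.empty:
        raise ValueError("no genes shared across all conditions")
    return mat


# ------------------------------------------------------------- clustering

def _ward2_linkage(X: np.ndarray) -> np.ndarray:
    """Ward linkage with squared-increment (ward.D2) semantics on rows of X."""
    return hierarchy.linkage(X, method="ward", metric="euclidean")


def correlation_and_cluster(lfc: pd.DataFrame, cor_method: str = "spearman"):
    """Spearman correlation of conditions + Ward.D2 tree of the correlation rows.

    Returns ``(corr, linkage, labels)``; ties in the input order are
    resolved deterministically by condition label order (columns are
    sorted before clustering).
    """
    if lfc.shape[1] < 3:
        raise ValueError("need at least 3 conditions")
    lfc = lfc.reindex(sorted(lfc.columns), axis=1)
    const = lfc.columns[lfc.std(axis=0) == 0]
    if len(const):
        raise ValueError(f"constant condition column: {const[0]!r}")
    corr = lfc.corr(method=cor_method)
    Z = _ward2_linkage(corr.values)
    return corr, Z, list(corr.columns)


def linkage_to_newick(Z: np.ndarray, labels: list) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


# ------------------------------------------------- multiscale bootstrap

@dataclass
class ClusterSupport:
    """Per-cluster bootstrap probabilities and AU values.

    ``clusters`` maps a frozenset of member labels to a dict with bp
    (at scale 1), au, and the per-scale BP table.
    """

    clusters: dict
    n_boot: int
    scales: tuple

    def table(self) -> pd.DataFrame:
        rows = [
            {"members": "|".join(sorted(k)), "bp": v["bp"], "au": v["au"]}
            for k, v in self.clusters.items()
        ]
        return pd.DataFrame(rows, columns=["members", "bp", "au"])


def _tree_clusters(Z: np.ndarray, labels: list) -> set:
    """All internal-node member sets (excluding the root and leaves)."""
    n = len(labels)
    members = {i: frozenset([labels[i]]) for i in range(n)}
    out = set()
    for k, (a, b, _, _) in enumerate(Z):
        members[n + k] = members[int(a)] | members[int(b)]
        out.add(members[n + k])
    out.discard(frozenset(labels))
    return out


def multiscale_bootstrap(
    lfc: pd.DataFrame,
    n_boot: int = 10_000,
    scales: tuple = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4),
    seed: int = 0,
    cor_method: str = "spearman",
) -> ClusterSupport:
    """Multiscale bootstrap support for the condition clustering.

    At each scale r, ceil(r * n_genes) genes are resampled with
    replacement and the clustering recomputed; BP_r is the frequency of
    each observed cluster.  AU comes from the weighted least-squares fit
    Phi^-1(1 - BP_r) = v sqrt(r) + c / sqrt(r), with AU = 1 - Phi(v - c).
    The bootstrap budget ``n_boot`` is split evenly across scales; BP is
    reported at r = 1.
    """
    n_genes = lfc.shape[0]
    if n_genes < 10:
        raise ValueError("need at least 10 genes for bootstrap resampling")
    rng = np.random.default_rng(seed)
    corr, Z, labels = correlation_and_cluster(lfc, cor_method=cor_method)
    target = _tree_clusters(Z, labels)
    per_scale = max(1, n_boot // len(scales))
    counts = {c: {r: 0 for r in scales} for c in target}
    vals = lfc.values
    for r in scales:
        m = int(np.ceil(r * n_genes))
        for _ in range(per_scale):
            idx = rng.integers(0, n_genes, size=m)
            sub = pd.DataFrame(vals[idx], columns=lfc.columns)
            try:
                _, Zb, labs = correlation_and_cluster(sub, cor_method=cor_method)
            except ValueError:
                continue
            found = _tree_clusters(Zb, labs)
            for c in target:
                if c in found:
                    counts[c][r] += 1

    clusters = {}
    sq = np.sqrt(np.asarray(scales))
    for c in target:
        bp_r = np.array([counts[c][r] / per_scale for r in scales])
        bp1 = bp_r[np.isclose(scales, 1.0)][0] if np.isclose(scales, 1.0).any() else bp_r[-1]
        if np.all(bp_r == 0):
            clusters[c] = {"bp": 0.0, "au": np.nan, "bp_per_scale": dict(zip(scales, bp_r))}
            continue
        if np.all(bp_r == 1):
            clusters[c] = {"bp": 1.0, "au": 1.0, "bp_per_scale": dict(zip(scales, bp_r))}
            continue
        eps = 1.0 / (2.0 * per_scale)
        bp_c = np.clip(bp_r, eps, 1.0 - eps)
        zval = stats.norm.ppf(1.0 - bp_c)
        # delta-method weights: var(z) ~ bp(1-bp) / (B phi(z)^2)
        w = per_scale * stats.norm.pdf(zval) ** 2 / (bp_c * (1.0 - bp_c))
        A = np.column_stack([sq, 1.0 / sq])
        WA = A * w[:, None]
        try:
            v, cc = np.linalg.solve(A.T @ WA, A.T @ (w * zval))
            au = float(1.0 - stats.norm.cdf(v - cc))
        except np.linalg.LinAlgError:
            au = np.nan
        clusters[c] = {"bp": float(bp1), "au": au, "bp_per_scale": dict(zip(scales, bp_r))}
    return ClusterSupport(clusters=clusters, n_boot=per_scale * len(scales), scales=scales)


# -------------------------------------------------- clustering concordance

_LINKAGE_METHODS = ("ward.D", "ward.D2", "complete", "average", "mcquitty")
_DISTANCES = ("euclidean", "maximum", "manhattan", "minkowski")


def _distance(X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "maximum":
        return pdist(X, metric="chebyshev")
    if metric == "manhattan":
        return pdist(X, metric="cityblock")
    if metric == "minkowski":
        return pdist(X, metric="minkowski", p=3)
    return pdist(X, metric="euclidean")


def _linkage(d: np.ndarray, method: str) -> np.ndarray:
    if method == "ward.D2":
        return hierarchy.linkage(d, method="ward")
    if method == "ward.D":
        # ward.D applies the Ward recurrence to the raw dissimilarities:
        # identical merges to ward.D2 on sqrt(d), heights squared back.
        Z = hierarchy.linkage(np.sqrt(d), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
        return Z
    if method == "mcquitty":
        return hierarchy.linkage(d, method="weighted")
    return hierarchy.linkage(d, method=method)


def cophenetic_correlation(Z1: np.ndarray, Z2: np.ndarray) -> float:
    """Pearson correlation of the two trees' cophenetic distance vectors."""
    c1 = hierarchy.cophenet(Z1)
    c2 = hierarchy.cophenet(Z2)
    return float(np.corrcoef(c1, c2)[0, 1])


def rand_index(labels_a, labels_b) -> float:
    """Plain Rand index: agreement fraction over all item pairs."""
    from sklearn.metrics import rand_score

    return float(rand_score(labels_a, labels_b))


def clustering_concordance(
    lfc: pd.DataFrame,
    methods: tuple = _LINKAGE_METHODS,
    distances: tuple = _DISTANCES,
    subsample_sizes: tuple = (10_000, 5_000, 2_000),
    n_rep: int = 100,
    n_clusters: int = 4,
    seed: int = 0,
    cor_method: str = "spearman",
):
    """Concordance of the condition clustering across algorithmic choices.

    For every pair of (method, distance) combinations, the cophenetic
    correlation between trees and the Rand index between k-cut partitions
    are computed on the full data; gene subsampling at the requested
    sizes (auto-capped at the gene count, with a note) repeats the
    default ward.D2/euclidean clustering ``n_rep`` times and reports the
    same measures against the full-data tree.
    Returns ``(pairwise_table, subsample_table, notes)``.
    """
    notes = []
    corr = lfc.corr(method=cor_method)
    X = corr.values
    combos = [(m, d) for m in methods for d in distances]
    trees = {md: _linkage(_distance(X, md[1]), md[0]) for md in combos}
    cuts = {
        md: hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
        for md, Z in trees.items()
    }
    rows = []
    for i, a in enumerate(combos):
        for b in combos[i + 1 :]:
            rows.append(
                dict(
                    method_a="/".join(a), method_b="/".join(b),
                    cophenetic=cophenetic_correlation(trees[a], trees[b]),
                    rand=rand_index(cuts[a], cuts[b]),
                )
            )
    pairwise = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    ref_tree = trees[("ward.D2", "euclidean")]
    ref_cut = cuts[("ward.D2", "euclidean")]
    sub_rows = []
    n_genes = lfc.shape[0]
    for size in subsample_sizes:
        eff = min(size, n_genes)
        if eff < size:
            notes.append(f"subsample size {size} capped at {eff} genes")
        for rep in range(n_rep):
            idx = rng.choice(n_genes, size=eff, replace=False)
            sub_corr = lfc.iloc[idx].corr(method=cor_method)
            Zs = _linkage(_distance(sub_corr.values, "euclidean"), "ward.D2")
            sub_rows.append(
                dict(
                    size=size, rep=rep,
                    cophenetic=cophenetic_correlation(ref_tree, Zs),
                    rand=rand_index(
                        ref_cut, hierarchy.fcluster(Zs, t=n_clusters, criterion="maxclust")
                    ),
                )
            )
    return pairwise, pd.DataFrame(sub_rows), notes


# ------------------------------------------------------ convergence trend

def convergence_trend(lfc: pd.DataFrame):
    """Per-day pairwise form correlations + one-way ANOVA + Tukey HSD.

    For each day, Spearman rho is computed for every unordered pair of
    forms (C(F,2) values per day); the rho values (untransformed) enter a
    one-way ANOVA by day, and day pairs are compared with Tukey's HSD via
    the studentized range distribution.
    Returns ``(rho_table, anova_dict, tukey_table)``.
    """
    cols = pd.DataFrame(
        [c.rsplit("@", 1) for c in lfc.columns], columns=["form", "day"], index=lfc.columns
    )
    days = sorted(cols["day"].unique(), key=lambda d: float(d))
    if len(days) < 2:
        raise ValueError("need at least 2 days")
    rows = []
    for day in days:
        conds = cols.index[cols["day"] == day]
        forms = sorted(cols.loc[conds, "form"])
        if len(forms) < 2:
            raise ValueError(f"day {day} has fewer than 2 forms")
        for fa, fb in combinations(forms, 2):
            rho = stats.spearmanr(lfc[f"{fa}@{day}"], lfc[f"{fb}@{day}"]).statistic
            rows.append(dict(day=day, form_a=fa, form_b=fb, rho=float(rho)))
    rho_table = pd.DataFrame(rows)

    groups = [rho_table.loc[rho_table["day"] == d, "rho"].values for d in days]
    F, p = stats.f_oneway(*groups)
    k = len(days)
    n_total = sum(len(g) for g in groups)
    df_w = n_total - k
    anova = dict(F=float(F), p=float(p), df_between=k - 1, df_within=df_w)

    # Tukey HSD on the day groups
    ms_w = np.sum([np.sum((g - g.mean()) ** 2) for g in groups]) / df_w
    tukey_rows = []
    for (i, da), (j, db) in combinations(enumerate(days), 2):
        ga, gb = groups[i], groups[j]
        diff = gb.mean() - ga.mean()
        se = np.sqrt(ms_w / 2.0 * (1.0 / len(ga) + 1.0 / len(gb)))
        q = abs(diff) / se
        padj = float(stats.studentized_range.sf(q, k, df_w)) if q > 0 else 1.0
        tukey_rows.append(dict(day_a=da, day_b=db, diff=float(diff), p_adj=padj))
    return rho_table, anova, pd.DataFrame(tukey_rows)
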