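"""Robust, form-balanced consensus signed co-expression networks.

The network pipeline: pick a soft-threshold power to approximate
scale-free topology, build the signed adjacency
a_ij = ((1 + cor)/2)^beta, convert it to topological-overlap
dissimilarity, take the element-wise median of the dissimilarity across
form-balanced resampled networks, detect modules on the average-linkage
tree with a simplified hybrid cut (branch decomposition + size floor +
deep-split sensitivity + kME adoption/pruning + eigengene merging),
compute eigengenes/kME, and test module-trait associations, spline
trajectories, and a light-weight preservation statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import CONTROL, ModuleSet
from .enrich import adjust_bh


@dataclass
class NetworkParams:
    """Tunables for consensus network construction and module detection.

    Defaults are the desk-scale profile; the full-scale profile used in
    the study this pipeline emulates (min module size 160, deep split 4,
    detect cut 0.9999, merge cut 0.1, 100 resamples) can be requested via
    ``NetworkParams.paper_scale()``.
    """

    beta: int = 6
    resamples: int = 20
    min_per_form: int = 4
    min_module_size: int = 30
    deep_split: int = 4
    cut_height_detect: float = 0.9999
    cut_height_merge: float = 0.1
    kme_adopt: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not (0.0 < self.cut_height_detect <= 1.0 and 0.0 < self.cut_height_merge <= 1.0):
            raise ValueError("cut heights must lie in (0, 1]")

    @classmethod
    def paper_scale(cls, **kw) -> "NetworkParams":
        base = dict(resamples=100, min_module_size=160, deep_split=4,
                    cut_height_detect=0.9999, cut_height_merge=0.1)
        base.update(kw)
        return cls(**base)


# ------------------------------------------------------------- adjacency

def _ipow(base: np.ndarray, exp: int) -> np.ndarray:
    """Element-wise integer power by squaring (much faster than ** for arrays)."""
    exp = int(exp)
    result = None
    acc = base
    while exp:
        if exp & 1:
            result = acc.copy() if result is None else result * acc
        exp >>= 1
        if exp:
            acc = acc * acc
    return result


def signed_adjacency(expr: pd.DataFrame, beta: int) -> np.ndarray:
    """Signed adjacency ((1 + cor)/2)^beta with unit diagonal.

    ``expr`` is gene x sample; raises on constant genes (undefined
    correlation).
    """
    vals = np.asarray(expr.values, dtype=np.float64)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[np.where(sd == 0)[0][0]]
        raise ValueError(f"constant gene: {bad!r}")
    cor = np.corrcoef(vals)
    a = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def tom_dissimilarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological-overlap dissimilarity 1 - TOM.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i the connectivity excluding the diagonal; the diagonal of the
    dissimilarity is 0.
    """
    A = np.asarray(adjacency, dtype=np.float64)
    if np.max(np.abs(A - A.T)) > 1e-10:
        raise ValueError("adjacency must be symmetric")
    k = A.sum(axis=0) - 1.0
    L = A @ A - A  # (A@A)_ij counts u=i and u=j, each contributing a_ij
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = L / (kmin + 1.0 - A)  # diagonal is 0/0 and overwritten below
    np.fill_diagonal(tom, 1.0)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    return np.clip(diss, 0.0, 1.0)


# ----------------------------------------------------------- soft power

def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_betas=tuple(range(1, 21)),
    target_r2: float = 0.8,
    n_bins: int = 10,
):
    """Smallest power with scale-free fit R^2 >= target.

    The fit index is -sign(slope) * R^2 of log10(freq) vs log10(k) over
    ~10 occupied connectivity bins.  If no power reaches the target, the
    best-fitting one is returned with ``warning=True``.
    Returns ``(beta, fit_table, warning)``.
    """
    if expr.shape[0] < 30:
        raise ValueError("need at least 30 genes")
    vals = np.asarray(expr.values, dtype=np.float32)
    cor = np.corrcoef(vals)
    base = (1.0 + cor) / np.float32(2.0)
    np.fill_diagonal(base, 0.0)
    rows = []
    power = {}
    acc = np.ones_like(base)
    for b in range(1, max(candidate_betas) + 1):
        acc = acc * base
        if b in candidate_betas:
            power[b] = acc.sum(axis=0)
    for b in candidate_betas:
        k = power[b].astype(np.float64)
        edges = np.linspace(k.min(), k.max(), n_bins + 1)
        which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
        freq = np.bincount(which, minlength=n_bins).astype(float)
        kmean = np.array([k[which == i].mean() if freq[i] else np.nan for i in range(n_bins)])
        occ = (freq > 0) & (kmean > 0)
        if occ.sum() < 2:
            raise ValueError("fewer than 2 occupied connectivity bins")
        x = np.log10(kmean[occ])
        y = np.log10(freq[occ])
        slope, _, r, _, _ = stats.linregress(x, y)
        rows.append(dict(beta=b, fit=-np.sign(slope) * r**2, slope=slope,
                         mean_k=float(k.mean())))
    table = pd.DataFrame(rows)
    ok = table[table["fit"] >= target_r2]
    if len(ok):
        return int(ok["beta"].iloc[0]), table, False
    return int(table.loc[table["fit"].idxmax(), "beta"]), table, True


# ------------------------------------------------------------- consensus

def _balanced_resample(meta: pd.DataFrame, min_per_form: int, rng) -> list:
    """Within-form bootstrap keeping >= min_per_form distinct samples per form."""
    ids = []
    for form, grp in meta.groupby("form"):
        pool = list(grp.index)
        if len(pool) < min_per_form:
            raise ValueError(f"form {form!r} has fewer than {min_per_form} samples")
        while True:
            draw = [pool[i] for i in rng.integers(0, len(pool), size=len(pool))]
            if len(set(draw)) >= min_per_form:
                break
        ids.extend(draw)
    return ids


def consensus_from_stack(stack: np.ndarray) -> np.ndarray:
    """Element-wise median across a stack of dissimilarity matrices.

    The consensus is order-invariant and, because the median is
    monotone-equivariant, median(1 - TOM) == 1 - median(TOM).
    """
    return np.median(np.asarray(stack), axis=0)


def consensus_resampled_tom(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    params: NetworkParams,
    resample: bool = True,
) -> np.ndarray:
    """Element-wise median of TOM dissimilarity over form-balanced resamples.

    Each iteration resamples samples with replacement within each form
    (re-drawing until at least ``min_per_form`` distinct samples per form
    survive), builds the signed adjacency and its TOM dissimilarity; the
    consensus is the per-entry median across iterations.  With
    ``resample=False`` and one iteration this is the plain TOM
    dissimilarity.
    """
    rng = np.random.default_rng(params.seed)
    meta = meta.loc[expr.columns]
    per_form = meta.groupby("form").size()
    small = per_form[per_form < params.min_per_form]
    if len(small):
        raise ValueError(
            f"form {small.index[0]!r} has {small.iloc[0]} samples "
            f"(need >= {params.min_per_form})"
        )
    n_iter = params.resamples if resample else 1
    n = expr.shape[0]
    vals32 = np.asarray(expr.values, dtype=np.float32)
    stack = np.empty((n_iter, n, n), dtype=np.float32)
    for it in range(n_iter):
        if resample:
            ids = _balanced_resample(meta, params.min_per_form, rng)
            pos = [expr.columns.get_loc(s) for s in ids]
            sub = vals32[:, pos]
        else:
            sub = vals32
        # single-precision fast path: the consensus median is insensitive
        # to float32 rounding of individual TOM entries
        sd = sub.std(axis=1)
        if (sd == 0).any():
            raise ValueError(f"constant gene: {expr.index[int(np.argmax(sd == 0))]!r}")
        cor = np.corrcoef(sub).astype(np.float32)
        a = _ipow((1.0 + cor) / np.float32(2.0), params.beta)
        np.fill_diagonal(a, 1.0)
        k = a.sum(axis=0) - 1.0
        L = a @ a - a
        tom = L / (np.minimum.outer(k, k) + 1.0 - a)
        np.fill_diagonal(tom, 1.0)
        stack[it] = np.clip(1.0 - tom, 0.0, 1.0)
    return consensus_from_stack(stack).astype(np.float64)


# -------------------------------------------------------- module detection

def _branch_modules(Z, n_leaves, min_size, floor_split, cut_height):
    """Recursive branch decomposition of an scipy linkage tree.

    Returns a list of leaf-index arrays, one per detected branch module.
    Nodes merging at or above ``cut_height`` can never be modules and are
    always descended into; below it, a node splits when both children
    reach the deep-split floor, and a node whose recursion yields nothing
    but that itself meets the module size floor becomes a module.
    """
    children = {}
    height = {i: 0.0 for i in range(n_leaves)}
    for k, (a, b, h, _) in enumerate(Z):
        children[n_leaves + k] = (int(a), int(b))
        height[n_leaves + k] = h

    def leaves(node):
        if node < n_leaves:
            return [node]
        a, b = children[node]
        return leaves(a) + leaves(b)

    sizes = {}

    def size(node):
        if node not in sizes:
            sizes[node] = 1 if node < n_leaves else size(children[node][0]) + size(children[node][1])
        return sizes[node]

    def split(node):
        if size(node) < min_size or node < n_leaves:
            return []
        a, b = children[node]
        if height[node] >= cut_height:
            return split(a) + split(b)
        if size(a) >= floor_split and size(b) >= floor_split:
            got = split(a) + split(b)
            if got:
                return got
        else:
            big = a if size(a) >= size(b) else b
            got = split(big)
            if got:
                return got
        return [np.array(leaves(node))]

    root = n_leaves + len(Z) - 1
    return split(root)


def detect_modules(
    consensus_diss: np.ndarray,
    expr: pd.DataFrame,
    params: NetworkParams,
) -> ModuleSet:
    """Detect modules on the consensus dissimilarity and refine with kME.

    Average-linkage tree, branches below ``cut_height_detect``; the
    deep-split sensitivity (0-4) scales the size floor for recursive
    branch splitting by (1 - deep_split/6).  Candidate modules are then
    pruned by kME (genes below ``kme_adopt`` leave; shrunken modules
    dissolve), unassigned genes with max kME >= ``kme_adopt`` are
    adopted, and modules with eigengene dissimilarity below
    ``cut_height_merge`` are merged iteratively.
    """
    genes = list(expr.index)
    n = len(genes)
    if params.min_module_size > n:
        raise ValueError("min_module_size exceeds gene count")
    d = np.asarray(consensus_diss, dtype=np.float64)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")

    # restrict to branches that formed below the detection cut
    floor_split = max(3, int(round(params.min_module_size * (1.0 - params.deep_split / 6.0))))
    branches = _branch_modules(Z, n, params.min_module_size, floor_split, params.cut_height_detect)

    labels = np.zeros(n, dtype=int)
    next_label = 1
    for idx in branches:
        if idx.size >= params.min_module_size:
            labels[idx] = next_label
            next_label += 1
    if labels.max() == 0:
        return module_eigengenes_kme(expr, pd.Series(labels, index=genes))

    labels_s = pd.Series(labels, index=genes)

    # kME pruning: drop weak members, dissolve shrunken modules
    for _ in range(3):
        ms = module_eigengenes_kme(expr, labels_s)
        changed = False
        for m in ms.modules:
            members = ms.module_genes(m)
            weak = members[ms.kme.loc[members, f"M{m}"] < params.kme_adopt]
            if len(weak):
                labels_s.loc[weak] = 0
                changed = True
            if (labels_s == m).sum() < params.min_module_size:
                labels_s.loc[labels_s == m] = 0
                changed = True
        labels_s = _relabel(labels_s)
        if not changed or labels_s.max() == 0:
            break

    if labels_s.max() == 0:
        return module_eigengenes_kme(expr, labels_s)

    # adoption of unassigned genes by best kME
    ms = module_eigengenes_kme(expr, labels_s)
    free = labels_s.index[labels_s == 0]
    if len(free) and len(ms.modules):
        kme_free = ms.kme.loc[free]
        best = kme_free.values.argmax(axis=1)
        best_val = kme_free.values[np.arange(len(free)), best]
        adopt = best_val >= params.kme_adopt
        labels_s.loc[free[adopt]] = [ms.modules[b] for b in best[adopt]]

    # iterative eigengene merging
    while True:
        ms = module_eigengenes_kme(expr, labels_s)
        if len(ms.modules) < 2:
            break
        me_corr = ms.eigengenes.corr().values
        diss = 1.0 - me_corr
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= params.cut_height_merge:
            break
        keep, drop = sorted((ms.modules[i], ms.modules[j]))
        labels_s.loc[labels_s == drop] = keep
        labels_s = _relabel(labels_s)
    return module_eigengenes_kme(expr, _relabel(labels_s))


def _relabel(labels: pd.Series) -> pd.Series:
    """Renumber modules 1..k by decreasing size, keeping 0 for unassigned."""
    out = pd.Series(0, index=labels.index, dtype=int)
    sizes = labels[labels > 0].value_counts()
    for new, old in enumerate(sizes.index, start=1):
        out[labels == old] = new
    return out


# ---------------------------------------------------------- eigengenes

def module_eigengenes_kme(expr: pd.DataFrame, labels: pd.Series) -> ModuleSet:
    """Eigengenes (first PC of the standardized module) and kME.

    The eigengene sign is oriented so the mean kME of the module's own
    genes is positive.  kME is the Pearson correlation of every gene
    with every eigengene.
    """
    labels = labels.reindex(expr.index).fillna(0).astype(int)
    modules = sorted(set(labels) - {0})
    vals = np.asarray(expr.values, dtype=np.float64)
    sd = vals.std(axis=1)
    mean = vals.mean(axis=1)
    std = np.where(sd > 0, sd, 1.0)
    zs = (vals - mean[:, None]) / std[:, None]
    mes = {}
    for m in modules:
        idx = np.where(labels.values == m)[0]
        if idx.size < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        if (sd[idx] == 0).all():
            raise ValueError(f"module {m} consists of constant genes")
        sub = zs[idx]  # genes x samples
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        me = vt[0]
        if np.mean(sub @ me) < 0:  # orient: own genes correlate positively
            me = -me
        me = (me - me.mean()) / (me.std() if me.std() > 0 else 1.0)
        mes[f"M{m}"] = me
    eigengenes = pd.DataFrame(mes, index=expr.columns)
    if modules:
        me_vals = eigengenes.values  # samples x modules
        mez = (me_vals - me_vals.mean(axis=0)) / np.where(
            me_vals.std(axis=0) > 0, me_vals.std(axis=0), 1.0
        )
        kme_vals = zs @ mez / expr.shape[1]
        # genes with zero variance get kME 0
        kme_vals[sd == 0] = 0.0
        kme = pd.DataFrame(kme_vals, index=expr.index, columns=eigengenes.columns)
    else:
        kme = pd.DataFrame(index=expr.index)
    return ModuleSet(labels=labels, eigengenes=eigengenes, kme=kme)


# ----------------------------------------------------- trait association

def module_trait_association(
    modules: ModuleSet,
    meta: pd.DataFrame,
    signed_sqrt: bool = True,
) -> pd.DataFrame:
    """Regress each eigengene on form (control baseline) and on diagnosis.

    signed_adjusted_R = sign(sum of coefficients) * sqrt(max(adj R^2, 0))
    by default (set ``signed_sqrt=False`` for signed adjusted R^2
    itself).  BH across modules is applied within each term family.
    """
    import statsmodels.api as sm

    meta = meta.loc[modules.eigengenes.index]
    if CONTROL not in set(meta["form"]):
        raise ValueError("control samples required")
    rows = []
    warns = []
    for term, col in (("form", "form"), ("diagnosis", "diagnosis")):
        levels = [l for l in meta[col].unique() if l != CONTROL]
        counts = meta[col].value_counts()
        keep_levels = [l for l in levels if counts.get(l, 0) >= 2]
        for l in set(levels) - set(keep_levels):
            warns.append(f"{col} level {l!r} dropped (<2 samples)")
        sel = meta[col].isin([CONTROL, *keep_levels])
        sub = meta[sel]
        X = pd.get_dummies(
            pd.Categorical(sub[col], categories=[CONTROL, *sorted(keep_levels)]),
            drop_first=True, dtype=float,
        )
        X.index = sub.index
        X = sm.add_constant(X)
        for mcol in modules.eigengenes.columns:
            y = modules.eigengenes.loc[sub.index, mcol]
            fit = sm.OLS(y.values, X.values).fit()
            adj = fit.rsquared_adj
            coefs = fit.params[1:]
            sgn = np.sign(coefs.sum()) if coefs.sum() != 0 else 0.0
            mag = np.sqrt(max(adj, 0.0)) if signed_sqrt else max(adj, 0.0)
            for name, b, p in zip(X.columns[1:], coefs, fit.pvalues[1:]):
                rows.append(
                    dict(
                        module=mcol, family=term, term=str(name), beta=float(b),
                        p=float(p), signed_adjusted_R=float(sgn * mag),
                    )
                )
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    for (fam, term), grp in out.groupby(["family", "term"]):
        out.loc[grp.index, "fdr"] = adjust_bh(grp["p"].values)
    out.attrs["warnings"] = warns
    return out


# ------------------------------------------------------ trajectory test

def _quadratic_spline_basis(x: np.ndarray, df: int = 2) -> np.ndarray:
    """B-spline basis, degree 2, df columns (no interior knots for df=2)."""
    from scipy.interpolate import BSpline

    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    degree = 2
    n_interior = max(df - degree, 0)
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    n_basis = len(t) - degree - 1
    full = BSpline.design_matrix(x, t, degree, extrapolate=True).toarray()
    assert full.shape[1] == n_basis
    return full[:, 1 : df + 1]  # drop one column in lieu of the intercept


def module_trajectory_test(modules: ModuleSet, meta: pd.DataFrame) -> pd.DataFrame:
    """Spline-by-form interaction F-test per module and form vs control.

    Eigengene ~ spline(day, df=2, degree=2) x form on the {form, control}
    subset; the F-test compares the interaction model to the additive
    one.  BH across all rows.
    """
    import statsmodels.api as sm

    meta = meta.loc[modules.eigengenes.index]
    days = np.sort(meta["day"].unique())
    if len(days) < 3:
        raise ValueError("need at least 3 distinct days")
    forms = [f for f in meta["form"].unique() if f != CONTROL]
    rows = []
    for form in sorted(forms):
        sel = meta["form"].isin([CONTROL, form])
        sub = meta[sel]
        basis = _quadratic_spline_basis(sub["day"].values)
        is_f = (sub["form"] == form).values.astype(float)
        X0 = np.column_stack([np.ones(len(sub)), basis, is_f])
        X1 = np.column_stack([X0, basis * is_f[:, None]])
        for mcol in modules.eigengenes.columns:
            y = modules.eigengenes.loc[sub.index, mcol].values
            fit0 = sm.OLS(y, X0).fit()
            fit1 = sm.OLS(y, X1).fit()
            f, p, _ = fit1.compare_f_test(fit0)
            rows.append(dict(module=mcol, form=form, F=float(f), p=float(np.clip(p, 1e-300, 1.0))))
    out = pd.DataFrame(rows)
    out["fdr"] = adjust_bh(out["p"].values)
    return out


# -------------------------------------------------------- preservation

def module_preservation_lite(
    expr_ref: pd.DataFrame,
    labels_ref: pd.Series,
    expr_test: pd.DataFrame,
    beta: int = 6,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation Z-scores for module density and connectivity preservation.

    Z_density compares the mean within-module signed adjacency in the
    test data against a label-permutation null; Z_connectivity does the
    same for the correlation of intramodular connectivity between
    reference and test.  Z_summary is their mean.  Modules with fewer
    than 3 genes in the shared universe are skipped.
    """
    shared = expr_ref.index.intersection(expr_test.index)
    if len(shared) < 50:
        raise ValueError("shared gene universe too small (< 50)")
    rng = np.random.default_rng(seed)
    a_ref = signed_adjacency(expr_ref.loc[shared], beta)
    a_test = signed_adjacency(expr_test.loc[shared], beta)
    labels = labels_ref.reindex(shared).fillna(0).astype(int).values
    rows = []
    for m in sorted(set(labels) - {0}):
        idx = np.where(labels == m)[0]
        if idx.size < 3:
            rows.append(dict(module=m, n_genes=int(idx.size), z_density=np.nan,
                             z_connectivity=np.nan, z_summary=np.nan,
                             note="skipped: <3 shared genes"))
            continue

        def density(a, ii):
            sub = a[np.ix_(ii, ii)]
            return (sub.sum() - ii.size) / (ii.size * (ii.size - 1))

        kr_mod = a_ref[np.ix_(idx, idx)].sum(axis=0) - 1.0

        def conn_cor(ii):
            # ref intramodular connectivity (fixed) vs test connectivity of
            # the candidate set; permuting the set breaks the gene pairing
            kt = a_test[np.ix_(ii, ii)].sum(axis=0) - 1.0
            if kr_mod.std() == 0 or kt.std() == 0:
                return 0.0
            return np.corrcoef(kr_mod, kt)[0, 1]

        obs_d = density(a_test, idx)
        obs_c = conn_cor(idx)
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.choice(len(shared), size=idx.size, replace=False)
            null_d[b] = density(a_test, perm)
            null_c[b] = conn_cor(perm)
        zd = (obs_d - null_d.mean()) / max(null_d.std(ddof=1), 1e-12)
        zc = (obs_c - null_c.mean()) / max(null_c.std(ddof=1), 1e-12)
        rows.append(dict(module=m, n_genes=int(idx.size), z_density=float(zd),
                         z_connectivity=float(zc), z_summary=float((zd + zc) / 2.0),
                         note=""))
    return pd.DataFrame(rows)
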