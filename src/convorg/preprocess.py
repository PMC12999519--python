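"""Expression filtering, TMM normalization, outlier removal and QC metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor as linalg_cho_factor, cho_solve as linalg_cho_solve

from .containers import CohortCounts, ExprMatrix


# ------------------------------------------------------------- filtering

def filter_low_expressed(
    cohort: CohortCounts,
    min_reads: int = 10,
    min_frac: float = 0.3,
    group_by: str | None = "day",
) -> CohortCounts:
    """Remove genes expressed at very low levels.

    A gene is kept for a group when at least ``min_frac`` of that group's
    samples have >= ``min_reads`` reads (inclusive at the boundary).
    With ``group_by`` set, the gene must pass in every group present; with
    ``group_by=None`` the rule applies over all samples at once.
    Per-day pipelines should subset to the day first, making the group
    under analysis the only one.
    """
    if not (0.0 < min_frac <= 1.0):
        raise ValueError("min_frac must lie in (0, 1]")
    if cohort.counts.empty:
        raise ValueError("empty counts")
    if group_by is None:
        groups = {"all": list(cohort.samples.index)}
    else:
        groups = {k: list(v.index) for k, v in cohort.samples.groupby(group_by)}
    keep = np.ones(len(cohort.genes), dtype=bool)
    for _, ids in groups.items():
        sub = cohort.counts.loc[:, ids].values
        frac = (sub >= min_reads).mean(axis=1)
        keep &= frac >= min_frac
    return cohort.subset_genes(cohort.genes[keep])


# ------------------------------------------------------------------- TMM

def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """Weighted trimmed mean of M-values between one sample and the reference."""
    pos = (obs > 0) & (ref > 0)
    o, r = obs[pos], ref[pos]
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    fin = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, w = m[fin], a[fin], w[fin]
    if m.size == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:  # edgeR shortcut: essentially identical samples
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_norm_factors(
    counts: pd.DataFrame, logratio_trim: float = 0.3, sum_trim: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose 75th percentile of
    library-scaled counts is closest to the mean of those percentiles.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    q75 = np.array([np.percentile(counts[c].values / lib[c], 75) for c in counts.columns])
    ref_i = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = counts.iloc[:, ref_i].values.astype(float)
    lib_ref = float(lib.iloc[ref_i])
    factors = np.array(
        [
            _tmm_pair_factor(
                counts[c].values.astype(float), ref, float(lib[c]), lib_ref,
                logratio_trim, sum_trim,
            )
            for c in counts.columns
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def tmm_normalize(cohort: CohortCounts, pseudocount: float = 0.5) -> ExprMatrix:
    """TMM normalization to log2 CPM on effective library sizes."""
    factors = tmm_norm_factors(cohort.counts)
    lib = cohort.counts.sum(axis=0).astype(float)
    eff = lib * factors
    cpm = (cohort.counts + pseudocount) / (eff + pseudocount * 2.0) * 1e6
    values = np.log2(cpm)
    return ExprMatrix(values=values, norm_factors=factors, offset=pseudocount)


# ---------------------------------------------------------------- outliers

@dataclass
class OutlierReport:
    table: pd.DataFrame  # sample_id, group, connectivity, z, removed
    z_cut: float
    warnings: list

    @property
    def removed(self) -> list:
        return list(self.table.index[self.table["removed"]])


def detect_outliers(
    expr: ExprMatrix,
    meta: pd.DataFrame,
    z_cut: float = -2.0,
    group_by: tuple = ("day", "form"),
    method: str = "pearson",
    iterate: bool = False,
) -> OutlierReport:
    """Flag samples with low standardized network connectivity.

    Within each group (day x form by default), the connectivity of
    sample s is k_s = sum over other samples of cor(s, t); z-scores of k
    are taken within the group and samples with z < ``z_cut`` flagged.
    Single pass unless ``iterate`` is set, in which case flagged samples
    are dropped and the pass repeated until no new outlier appears.
    """
    rows = []
    warns = []
    group_by = list(group_by)
    for key, grp in meta.groupby(group_by):
        ids = list(grp.index)
        if len(ids) < 3:
            raise ValueError(f"group {key} has fewer than 3 samples")
        active = list(ids)
        removed: set = set()
        last_stats: dict = {}
        while True:
            sub = expr.values.loc[:, active]
            cor = sub.corr(method=method).values
            k = cor.sum(axis=1) - 1.0
            sd = k.std(ddof=1)
            if sd == 0:
                warns.append(f"group {key}: zero connectivity spread, no outliers")
                z = np.zeros_like(k)
                newly = []
            else:
                z = (k - k.mean()) / sd
                newly = [s for s, zz in zip(active, z) if zz < z_cut]
            last_stats.update({s: (kk, zz) for s, kk, zz in zip(active, k, z)})
            removed |= set(newly)
            if not iterate or not newly or len(active) - len(newly) < 3:
                break
            active = [s for s in active if s not in removed]
        for s in ids:
            kk, zz = last_stats[s]
            rows.append((s, str(key), kk, zz, s in removed))
    table = pd.DataFrame(
        rows, columns=["sample_id", "group", "connectivity", "z", "removed"]
    ).set_index("sample_id")
    return OutlierReport(table=table, z_cut=z_cut, warnings=warns)


# ------------------------------------------------------------- covariates

def _design_matrix(meta: pd.DataFrame, covariates: list) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        col = meta[cov]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c]
        else:
            cols[cov] = col.astype(float)
    X = pd.DataFrame(cols, index=meta.index)
    X.insert(0, "intercept", 1.0)
    return X


def regress_covariates(expr: ExprMatrix, meta: pd.DataFrame, covariates: list) -> ExprMatrix:
    """Residualize expression on covariates; gene means are restored.

    Categorical covariates are dummy-coded (first level dropped).  Raises
    on a rank-deficient design, naming collinear columns.
    """
    X = _design_matrix(meta.loc[expr.values.columns], covariates)
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # identify columns involved in the collinearity by dropping one at a time
        bad = [
            c
            for c in X.columns[1:]
            if np.linalg.matrix_rank(X.drop(columns=c).values) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    Y = expr.values.values.T  # samples x genes
    beta, *_ = np.linalg.lstsq(X.values, Y, rcond=None)
    resid = Y - X.values @ beta
    resid += Y.mean(axis=0, keepdims=True)
    values = pd.DataFrame(resid.T, index=expr.values.index, columns=expr.values.columns)
    return ExprMatrix(values=values, norm_factors=expr.norm_factors, offset=expr.offset)


# -------------------------------------------------------- reproducibility

def reproducibility_correlations(expr: ExprMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation for every within-(day, form) sample pair.

    One row per unordered pair with labels describing whether the two
    samples come from the same line / individual.
    """
    rows = []
    for (day, form), grp in meta.groupby(["day", "form"]):
        ids = list(grp.index)
        if len(ids) < 2:
            continue
        sub = expr.values.loc[:, ids]
        rho = sub.corr(method="spearman")
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                same_ind = grp.loc[a, "individual_id"] == grp.loc[b, "individual_id"]
                same_line = grp.loc[a, "line_id"] == grp.loc[b, "line_id"]
                rows.append(
                    dict(
                        sample_a=a,
                        sample_b=b,
                        day=day,
                        form=form,
                        rho=rho.loc[a, b],
                        line_label="same line" if same_line else "different lines",
                        individual_label=(
                            "same individual" if same_ind else "different individuals"
                        ),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_a", "sample_b", "day", "form", "rho", "line_label", "individual_label",
        ],
    )


# ---------------------------------------------------- variance partition

def reml_variance_components(
    y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray], n_starts: int = 3
) -> tuple[np.ndarray, float]:
    """REML estimates for V = sum_k s2_k Z_k Z_k' + s2_e I.

    Optimizes the restricted log-likelihood over log variances with a few
    starts (handles near-boundary solutions that trip general-purpose
    mixed-model fitters on small crossed designs).  Returns
    ``(component_variances, residual_variance)``.
    """
    from scipy.optimize import minimize

    y = np.asarray(y, float)
    n, p = X.shape
    ZZ = [Z @ Z.T for Z in Zs]
    tot = max(np.var(y, ddof=1), 1e-10)

    def neg_reml(log_s2):
        s2 = np.exp(log_s2)
        V = s2[-1] * np.eye(n)
        for k, M in enumerate(ZZ):
            V += s2[k] * M
        try:
            cho = linalg_cho_factor(V)
        except Exception:
            return 1e10
        Vi_y = linalg_cho_solve(cho, y)
        Vi_X = linalg_cho_solve(cho, X)
        XtViX = X.T @ Vi_X
        try:
            ci = linalg_cho_factor(XtViX)
        except Exception:
            return 1e10
        beta = linalg_cho_solve(ci, X.T @ Vi_y)
        r = y - X @ beta
        quad = r @ linalg_cho_solve(cho, r)
        logdetV = 2.0 * np.sum(np.log(np.diag(cho[0])))
        logdetX = 2.0 * np.sum(np.log(np.diag(ci[0])))
        return 0.5 * (logdetV + logdetX + quad)

    k = len(ZZ)
    starts = [np.full(k + 1, np.log(tot / (k + 1)))]
    starts.append(np.r_[np.full(k, np.log(tot * 0.05)), np.log(tot * 0.95)])
    starts.append(np.r_[np.full(k, np.log(tot * 0.45)), np.log(tot * 0.05)])
    best, best_val = None, np.inf
    for s0 in starts[:n_starts]:
        res = minimize(neg_reml, s0, method="Nelder-Mead",
                       options=dict(maxiter=2000, xatol=1e-8, fatol=1e-10))
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    s2 = np.exp(best)
    return s2[:-1], float(s2[-1])


def linkage_matrix_for(term_values) -> np.ndarray:
    """Indicator matrix (n x levels) for a categorical term."""
    codes, uniq = pd.factorize(np.asarray(term_values))
    Z = np.zeros((len(codes), len(uniq)))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def variance_fractions(expr: ExprMatrix, meta: pd.DataFrame, terms: list) -> pd.DataFrame:
    """Per-gene fraction of variance attributed to each metadata term.

    Categorical terms enter as random intercepts (variance components by
    REML on V = sum_k s2_k Z_k Z_k' + s2_e I), continuous terms as fixed
    effects whose contribution is the variance of the fitted component.
    Fractions are non-negative and sum to 1 (residual column included).
    """
    meta = meta.loc[expr.values.columns]
    cat_terms, num_terms = [], []
    for t in terms:
        col = meta[t]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            if col.nunique() < 2:
                raise ValueError(f"term {t!r} has a single level")
            cat_terms.append(t)
        else:
            num_terms.append(t)
    n = len(meta)
    X = np.column_stack([np.ones(n)] + [meta[t].values.astype(float) for t in num_terms])
    Zs = [linkage_matrix_for(meta[t]) for t in cat_terms]
    out = {}
    for gene in expr.values.index:
        y = expr.values.loc[gene].values.astype(float)
        if cat_terms:
            comp_vars, resid_var = reml_variance_components(y, X, Zs)
            # GLS fixed effects at the REML variances for the numeric terms
            V = resid_var * np.eye(n)
            for s2, Z in zip(comp_vars, Zs):
                V += s2 * Z @ Z.T
            Vi_X = np.linalg.solve(V, X)
            beta = np.linalg.solve(X.T @ Vi_X, Vi_X.T @ y)
        else:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            comp_vars = []
            resid_var = float(np.var(y - X @ beta, ddof=X.shape[1]))
        fracs = {t: float(v) for t, v in zip(cat_terms, comp_vars)}
        for i, t in enumerate(num_terms):
            fracs[t] = float(np.var(beta[i + 1] * X[:, i + 1], ddof=0))
        fracs["residual"] = resid_var
        total = sum(max(v, 0.0) for v in fracs.values())
        out[gene] = {k: max(v, 0.0) / total if total > 0 else 0.0 for k, v in fracs.items()}
    table = pd.DataFrame(out).T
    return table.reindex(columns=[*cat_terms, *num_terms, "residual"]).fillna(0.0)
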