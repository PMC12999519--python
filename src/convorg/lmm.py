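"""Vectorized single-random-intercept linear mixed model.

All genes share one fixed-effect design X (n x p) and one grouping
(random intercept, e.g. individual).  With lambda = sigma_u^2 /
sigma_e^2 the marginal covariance is V = I + lambda * Z Z', which is
block diagonal by group:

    V_j^{-1} = I - lambda / (1 + n_j lambda) * J_{n_j},
    log|V|   = sum_j log(1 + n_j lambda).

Everything needed for REML profiling reduces to group sums, so the
likelihood can be evaluated for all genes simultaneously at each
candidate lambda; lambda is chosen per gene on a log grid (with
lambda = 0 included, collapsing exactly to OLS).  Wald tests use the
residual degrees-of-freedom approximation df = n - p - q + 1 (q groups).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

_DEFAULT_GRID = np.concatenate([[0.0], np.logspace(-5, 3, 97)])


@dataclass
class LmmFit:
    """Per-gene REML fits sharing one design and grouping."""

    genes: list
    coef_names: list
    beta: np.ndarray        # genes x p
    cov_beta: np.ndarray    # genes x p x p (scaled by sigma_e^2 already)
    sigma2: np.ndarray      # genes, residual variance
    lam: np.ndarray         # genes, variance ratio sigma_u^2 / sigma_e^2
    df_resid: float
    n: int
    n_groups: int

    def contrast(self, c: np.ndarray) -> pd.DataFrame:
        """Wald test of c'beta = 0 for every gene (two-sided t)."""
        c = np.asarray(c, dtype=float)
        est = self.beta @ c
        var = np.einsum("i,gij,j->g", c, self.cov_beta, c)
        se = np.sqrt(np.maximum(var, 1e-300))
        t = est / se
        p = 2.0 * stats.t.sf(np.abs(t), self.df_resid)
        return pd.DataFrame(
            {"logFC": est, "se": se, "stat": t, "p": p}, index=self.genes
        )


def _group_codes(groups: pd.Series | np.ndarray) -> tuple[np.ndarray, int]:
    codes, uniq = pd.factorize(np.asarray(groups))
    return codes, len(uniq)


def fit_gene_lmm(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    groups,
    lam_grid: np.ndarray | None = None,
) -> LmmFit:
    """REML fit of y_g = X beta_g + Z u_g + e_g for every gene (row of Y).

    Parameters
    ----------
    Y : gene x sample expression (samples must match X rows).
    X : sample x p fixed-effect design (full rank, intercept included).
    groups : per-sample random-intercept labels.

    When the REML-optimal lambda is 0 the fit equals ordinary least
    squares exactly.
    """
    lam_grid = _DEFAULT_GRID if lam_grid is None else np.asarray(lam_grid, float)
    Xv = np.asarray(X.values, dtype=float)
    Yv = np.asarray(Y.values, dtype=float)  # G x n
    n, p = Xv.shape
    if Yv.shape[1] != n:
        raise ValueError("Y columns must match X rows")
    if np.linalg.matrix_rank(Xv) < p:
        raise ValueError("singular fixed-effect design")
    codes, q = _group_codes(groups)
    sizes = np.bincount(codes, minlength=q).astype(float)

    # group-sum operator S: q x n indicator
    def gsum(A):  # sum rows of A within groups -> q x cols
        out = np.zeros((q, A.shape[1]))
        np.add.at(out, codes, A)
        return out

    XtX = Xv.T @ Xv
    Sx = gsum(Xv)                      # q x p
    Sy = gsum(Yv.T)                    # q x G
    XtY = Xv.T @ Yv.T                  # p x G
    yty = np.einsum("gn,gn->g", Yv, Yv)  # G

    G = Yv.shape[0]
    best = np.full(G, np.inf)
    best_lam = np.zeros(G)
    store = {}
    for lam in lam_grid:
        c = lam / (1.0 + sizes * lam)  # q
        XtVX = XtX - (Sx * c[:, None]).T @ Sx
        XtVY = XtY - Sx.T @ (Sy * c[:, None])
        yVy = yty - np.einsum("qg,qg->g", Sy * c[:, None], Sy)
        try:
            cho = linalg.cho_factor(XtVX)
        except linalg.LinAlgError:
            continue
        betas = linalg.cho_solve(cho, XtVY)  # p x G
        rss = np.maximum(yVy - np.einsum("pg,pg->g", XtVY, betas), 1e-300)
        logdetV = np.sum(np.log1p(sizes * lam))
        logdetXtVX = 2.0 * np.sum(np.log(np.diag(cho[0])))
        crit = (n - p) * np.log(rss) + logdetV + logdetXtVX
        better = crit < best - 1e-10
        best = np.where(better, crit, best)
        best_lam = np.where(better, lam, best_lam)
        store[lam] = (XtVX, betas, rss)

    beta = np.empty((G, p))
    sigma2 = np.empty(G)
    cov = np.empty((G, p, p))
    for lam in np.unique(best_lam):
        sel = best_lam == lam
        XtVX, betas, rss = store[lam]
        beta[sel] = betas.T[sel]
        sigma2[sel] = rss[sel] / (n - p)
        inv = np.linalg.inv(XtVX)
        cov[sel] = sigma2[sel][:, None, None] * inv[None, :, :]
    df = float(n - p - q + 1) if q > 1 else float(n - p)
    if df < 1:
        df = 1.0
    return LmmFit(
        genes=list(Y.index),
        coef_names=list(X.columns),
        beta=beta,
        cov_beta=cov,
        sigma2=sigma2,
        lam=best_lam,
        df_resid=df,
        n=n,
        n_groups=q,
    )
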