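"""Filtering, TMM normalization, outlier detection, residualization, QC."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from convorg.containers import CohortCounts, ExprMatrix
from convorg.preprocess import (
    detect_outliers,
    filter_low_expressed,
    regress_covariates,
    reproducibility_correlations,
    reml_variance_components,
    tmm_norm_factors,
    tmm_normalize,
    variance_fractions,
)


def _cohort_from_counts(counts, day=25, form="control"):
    n = counts.shape[1]
    meta = pd.DataFrame(
        {
            "individual_id": [f"i{i}" for i in range(n)],
            "line_id": [f"l{i}" for i in range(n)],
            "differentiation_id": [f"d{i}" for i in range(n)],
            "day": day,
            "form": form,
            "diagnosis": "control" if form == "control" else "affected",
            "sex": "M",
            "batch": "b0",
        },
        index=counts.columns,
    )
    return CohortCounts(counts=counts, samples=meta)


class TestFilter:
    def test_all_zero_gene_removed(self, toy_counts):
        counts = toy_counts.copy()
        counts.iloc[0] = 0
        cohort = _cohort_from_counts(counts)
        out = filter_low_expressed(cohort, group_by=None)
        assert counts.index[0] not in out.genes

    @pytest.mark.parametrize("n_pass,kept", [(3, True), (2, False)])
    def test_inclusive_boundary_at_30_percent(self, n_pass, kept):
        # 10 samples; gene passes in exactly n_pass of them
        counts = pd.DataFrame(
            np.full((2, 10), 50), index=["ok", "boundary"],
            columns=[f"s{i}" for i in range(10)],
        )
        counts.loc["boundary"] = [20] * n_pass + [0] * (10 - n_pass)
        cohort = _cohort_from_counts(counts)
        out = filter_low_expressed(cohort, min_reads=10, min_frac=0.3, group_by=None)
        assert ("boundary" in out.genes.tolist()) is kept

    def test_idempotent(self, toy_counts):
        cohort = _cohort_from_counts(toy_counts)
        once = filter_low_expressed(cohort, group_by=None)
        twice = filter_low_expressed(once, group_by=None)
        assert list(once.genes) == list(twice.genes)

    def test_min_frac_validated(self, toy_counts):
        with pytest.raises(ValueError, match="min_frac"):
            filter_low_expressed(_cohort_from_counts(toy_counts), min_frac=0.0)


def _tmm_bruteforce(counts, ref_i):
    """Independent re-derivation of the weighted trimmed mean of M-values."""
    lib = counts.sum(axis=0).astype(float)
    out = {}
    for c in counts.columns:
        obs = counts[c].values.astype(float)
        ref = counts.iloc[:, ref_i].values.astype(float)
        lo, lr = lib[c], float(lib.iloc[ref_i])
        keep = (obs > 0) & (ref > 0)
        o, r = obs[keep], ref[keep]
        m = np.log2((o / lo) / (r / lr))
        a = 0.5 * np.log2((o / lo) * (r / lr))
        w = (lo - o) / (lo * o) + (lr - r) / (lr * r)
        if np.max(np.abs(m)) < 1e-6:
            out[c] = 1.0
            continue
        from scipy.stats import rankdata as rank  # average ranks for ties

        n = len(m)
        lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        sel = (
            (rank(m) >= lo_m) & (rank(m) <= hi_m)
            & (rank(a) >= lo_a) & (rank(a) <= hi_a)
        )
        out[c] = 2.0 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))
    f = pd.Series(out)
    return f / np.exp(np.mean(np.log(f)))


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 101)
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        f = tmm_norm_factors(counts)
        assert np.allclose(f, 1.0)

    def test_depth_scaling_leaves_factors_first_order(self, toy_counts):
        # M-values are exactly depth-invariant; the precision weights are
        # only asymptotically so, hence a first-order tolerance.
        counts = toy_counts.copy()
        doubled = counts.copy()
        doubled["s0"] = counts["s0"] * 2
        f1 = tmm_norm_factors(counts)
        f2 = tmm_norm_factors(doubled)
        assert np.allclose(f1.values, f2.values, atol=0.01)

    def test_proportional_columns_share_factor(self, toy_counts):
        counts = toy_counts.copy()
        counts["s1"] = counts["s0"] * 2  # same composition, double depth
        f = tmm_norm_factors(counts)
        assert f["s0"] == pytest.approx(f["s1"], abs=0.01)

    def test_composition_shift_matches_bruteforce_oracle(self, toy_counts):
        counts = toy_counts.copy()
        counts.iloc[:150, 0] *= 4  # composition shift in s0
        f = tmm_norm_factors(counts)
        lib = counts.sum(axis=0).astype(float)
        q75 = np.array([np.percentile(counts[c] / lib[c], 75) for c in counts.columns])
        ref_i = int(np.argmin(np.abs(q75 - q75.mean())))
        oracle = _tmm_bruteforce(counts, ref_i)
        assert np.allclose(f.values, oracle.loc[f.index].values, atol=1e-8)

    def test_matches_edger_calcnormfactors(self, tmp_path, toy_counts):
        counts = toy_counts.copy()
        counts.iloc[:150, 0] *= 3
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t", index=False)
        script = tmp_path / "tmm.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim('{path}'))
            cat(sprintf('%.10f\\n', calcNormFactors(x, method='TMM')))
        """))
        res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        ref = np.array([float(x) for x in res.stdout.split()])
        mine = tmm_norm_factors(counts).values
        assert np.allclose(mine, ref, atol=1e-6)

    def test_zero_library_named(self):
        counts = pd.DataFrame({"good": [1, 2, 3], "empty": [0, 0, 0]})
        with pytest.raises(ValueError, match="empty"):
            tmm_norm_factors(counts)

    def test_log_cpm_shape_and_finiteness(self, toy_counts):
        expr = tmm_normalize(_cohort_from_counts(toy_counts))
        assert expr.values.shape == toy_counts.shape
        assert np.isfinite(expr.values.values).all()


class TestOutliers:
    def _expr(self, vals, ids):
        df = pd.DataFrame(vals, columns=ids)
        return ExprMatrix(values=df, norm_factors=pd.Series(1.0, index=ids), offset=0.5)

    def _meta(self, ids):
        return pd.DataFrame({"day": 25, "form": "control"}, index=ids)

    def test_identical_samples_no_outliers(self):
        ids = [f"s{i}" for i in range(5)]
        vals = np.tile(np.arange(50, dtype=float)[:, None], (1, 5))
        report = detect_outliers(self._expr(vals, ids), self._meta(ids))
        assert report.removed == []
        assert any("zero connectivity" in w for w in report.warnings)

    def test_noise_sample_flagged(self, rng):
        ids = [f"s{i}" for i in range(10)]
        shared = rng.normal(size=200)
        vals = np.column_stack(
            [shared + 0.05 * rng.normal(size=200) for _ in range(9)]
            + [rng.normal(size=200)]
        )
        report = detect_outliers(self._expr(vals, ids), self._meta(ids))
        assert report.removed == ["s9"]

    def test_z_standardized_within_group(self, rng):
        ids = [f"s{i}" for i in range(8)]
        vals = rng.normal(size=(100, 8))
        report = detect_outliers(self._expr(vals, ids), self._meta(ids))
        z = report.table["z"].values
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_group_of_two_rejected(self, rng):
        ids = ["a", "b"]
        vals = rng.normal(size=(50, 2))
        with pytest.raises(ValueError, match="fewer than 3"):
            detect_outliers(self._expr(vals, ids), self._meta(ids))


class TestRegressCovariates:
    def _expr(self, vals, ids):
        df = pd.DataFrame(vals, columns=ids)
        return ExprMatrix(values=df, norm_factors=pd.Series(1.0, index=ids), offset=0.5)

    def test_orthogonal_covariate_leaves_values(self, rng):
        n = 40
        ids = [f"s{i}" for i in range(n)]
        cov = np.r_[np.ones(n // 2), -np.ones(n // 2)]
        gene = np.tile([1.0, -1.0], n // 2)  # exactly orthogonal to cov
        meta = pd.DataFrame({"c": cov}, index=ids)
        out = regress_covariates(self._expr(gene[None, :], ids), meta, ["c"])
        assert np.allclose(out.values.values[0], gene, atol=1e-8)

    def test_exact_linear_dependence_removed(self, rng):
        n = 30
        ids = [f"s{i}" for i in range(n)]
        cov = rng.normal(size=n)
        meta = pd.DataFrame({"c": cov}, index=ids)
        out = regress_covariates(self._expr((2.0 * cov)[None, :], ids), meta, ["c"])
        assert out.values.values[0].var() == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        n, g = 50, 7
        ids = [f"s{i}" for i in range(n)]
        meta = pd.DataFrame(
            {"c1": rng.normal(size=n), "c2": rng.normal(size=n)}, index=ids
        )
        Y = rng.normal(size=(g, n))
        out = regress_covariates(self._expr(Y, ids), meta, ["c1", "c2"])
        X = np.column_stack([np.ones(n), meta["c1"], meta["c2"]])
        beta = np.linalg.solve(X.T @ X, X.T @ Y.T)
        resid = Y.T - X @ beta + Y.mean(axis=1)
        assert np.allclose(out.values.values, resid.T, atol=1e-8)

    def test_collinear_design_named(self, rng):
        n = 20
        ids = [f"s{i}" for i in range(n)]
        c = rng.normal(size=n)
        meta = pd.DataFrame({"c1": c, "c2": 2 * c}, index=ids)
        with pytest.raises(ValueError, match="collinear"):
            regress_covariates(self._expr(rng.normal(size=(3, n)), ids), meta, ["c1", "c2"])


class TestReproducibility:
    def test_duplicated_sample_has_rho_one_and_pair_counts(self, rng):
        n = 6
        ids = [f"s{i}" for i in range(n)]
        vals = rng.normal(size=(100, n))
        vals[:, 1] = vals[:, 0]
        expr = ExprMatrix(
            values=pd.DataFrame(vals, columns=ids),
            norm_factors=pd.Series(1.0, index=ids), offset=0.5,
        )
        meta = pd.DataFrame(
            {
                "day": 25, "form": "F1",
                "individual_id": ["i0", "i0", "i1", "i1", "i2", "i2"],
                "line_id": ["l0", "l0", "l1", "l2", "l3", "l4"],
            },
            index=ids,
        )
        table = reproducibility_correlations(expr, meta)
        assert len(table) == n * (n - 1) // 2
        dup = table[(table.sample_a == "s0") & (table.sample_b == "s1")]
        assert dup["rho"].iloc[0] == pytest.approx(1.0)
        assert dup["line_label"].iloc[0] == "same line"
        assert dup["individual_label"].iloc[0] == "same individual"
        cross = table[(table.sample_a == "s0") & (table.sample_b == "s2")]
        assert cross["individual_label"].iloc[0] == "different individuals"


class TestVarianceFractions:
    def _expr(self, Y, meta):
        return ExprMatrix(
            values=Y, norm_factors=pd.Series(1.0, index=meta.index), offset=0.5
        )

    def _meta(self):
        day = np.repeat(["a", "b", "c", "d"], 6)
        ind = np.tile([f"i{j}" for j in range(6)], 4)
        return pd.DataFrame(
            {"day": day, "individual_id": ind},
            index=[f"s{i}" for i in range(24)],
        )

    def test_day_dominated_and_noise_genes(self, rng):
        meta = self._meta()
        dmap = {"a": 0.0, "b": 1.0, "c": 2.0, "d": 3.0}
        g_day = np.array([dmap[d] for d in meta["day"]]) + rng.normal(0, 0.05, 24)
        g_noise = rng.normal(size=24)
        Y = pd.DataFrame([g_day, g_noise], index=["day_gene", "noise"], columns=meta.index)
        vf = variance_fractions(self._expr(Y, meta), meta, ["day", "individual_id"])
        assert vf.loc["day_gene", "day"] > 0.95
        assert vf.loc["noise", "residual"] > 0.6
        assert np.allclose(vf.sum(axis=1), 1.0, atol=1e-6)

    def test_matches_bruteforce_reml_oracle(self, rng):
        from scipy.optimize import minimize

        meta = self._meta()
        Zs = [pd.get_dummies(meta[t]).values.astype(float) for t in ["day", "individual_id"]]
        X = np.ones((24, 1))
        Y = pd.DataFrame(
            rng.normal(size=(3, 24))
            + 1.0 * Zs[0] @ rng.normal(size=4)
            + 0.5 * Zs[1] @ rng.normal(size=6),
            index=["g1", "g2", "g3"], columns=meta.index,
        )
        vf = variance_fractions(self._expr(Y, meta), meta, ["day", "individual_id"])

        # independent oracle: direct REML by L-BFGS-B on raw variances
        def oracle(y):
            def nll(s2):
                V = s2[2] * np.eye(24) + s2[0] * Zs[0] @ Zs[0].T + s2[1] * Zs[1] @ Zs[1].T
                sign, logdetV = np.linalg.slogdet(V)
                Vi = np.linalg.inv(V)
                XtViX = X.T @ Vi @ X
                beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
                r = y - X @ beta
                return 0.5 * (logdetV + np.log(np.linalg.det(XtViX)) + r @ Vi @ r)

            best = None
            for s0 in ([0.5, 0.5, 0.5], [1.5, 0.1, 0.5], [0.1, 1.5, 0.5]):
                res = minimize(nll, s0, method="L-BFGS-B",
                               bounds=[(1e-10, None)] * 3)
                if best is None or res.fun < best.fun:
                    best = res
            s2 = best.x
            return s2 / s2.sum()

        for g in Y.index:
            frac = oracle(Y.loc[g].values)
            assert abs(vf.loc[g, "day"] - frac[0]) < 0.02
            assert abs(vf.loc[g, "individual_id"] - frac[1]) < 0.02
            assert abs(vf.loc[g, "residual"] - frac[2]) < 0.02

    def test_single_level_term_rejected(self, rng):
        meta = self._meta()
        meta["flat"] = "x"
        Y = pd.DataFrame(rng.normal(size=(1, 24)), index=["g"], columns=meta.index)
        with pytest.raises(ValueError, match="single level"):
            variance_fractions(self._expr(Y, meta), meta, ["flat"])
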