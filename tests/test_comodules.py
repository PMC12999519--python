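"""Signed network construction, TOM, consensus, module detection,
eigengenes, trait association, trajectories and preservation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from convorg.comodules import (
    NetworkParams,
    consensus_from_stack,
    consensus_resampled_tom,
    detect_modules,
    module_eigengenes_kme,
    module_preservation_lite,
    module_trait_association,
    module_trajectory_test,
    pick_soft_threshold,
    signed_adjacency,
    tom_dissimilarity,
    _quadratic_spline_basis,
)


def _blocky_expr(rng, n_blocks=3, block=60, n_noise=0, n_samples=60, noise=0.5):
    """Expression with planted correlated blocks; returns (expr, labels)."""
    cols = []
    labels = []
    for b in range(n_blocks):
        factor = rng.normal(size=n_samples)
        for _ in range(block):
            cols.append(factor + noise * rng.normal(size=n_samples))
            labels.append(b + 1)
    for _ in range(n_noise):
        cols.append(rng.normal(size=n_samples))
        labels.append(0)
    genes = [f"g{i:04d}" for i in range(len(cols))]
    expr = pd.DataFrame(cols, index=genes,
                        columns=[f"s{i}" for i in range(n_samples)])
    return expr, pd.Series(labels, index=genes)


class TestAdjacency:
    def test_correlation_extremes(self):
        x = np.arange(10, dtype=float)
        expr = pd.DataFrame([x, 2 * x + 1, -x], index=["a", "b", "c"])
        a = signed_adjacency(expr, beta=6)
        assert a[0, 1] == pytest.approx(1.0)  # cor = +1
        assert a[0, 2] == pytest.approx(0.0, abs=1e-12)  # cor = -1

    def test_zero_correlation_squared(self):
        expr = pd.DataFrame(
            [[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]], index=["a", "b"]
        )
        a = signed_adjacency(expr, beta=2)
        assert a[0, 1] == pytest.approx(0.25)

    def test_constant_gene_named(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            signed_adjacency(expr, beta=2)


class TestTom:
    def test_two_gene_hand_value(self):
        a = np.array([[1.0, 0.5], [0.5, 1.0]])
        d = tom_dissimilarity(a)
        assert d[0, 1] == pytest.approx(0.5)
        assert d[0, 0] == 0.0

    def test_identity_adjacency_no_overlap(self):
        d = tom_dissimilarity(np.eye(5))
        off = d[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        n = 20
        c = rng.uniform(-1, 1, size=(n, n))
        a = ((1 + (c + c.T) / 2) / 2) ** 3
        np.fill_diagonal(a, 1.0)
        d = tom_dissimilarity(a)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                L = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                k_i = sum(a[i, u] for u in range(n) if u != i)
                k_j = sum(a[j, u] for u in range(n) if u != j)
                tom = (L + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                assert abs((1 - tom) - d[i, j]) < 1e-10

    def test_asymmetry_rejected(self, rng):
        a = rng.uniform(size=(4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            tom_dissimilarity(a)

    def test_range(self, rng):
        expr = pd.DataFrame(rng.normal(size=(30, 40)))
        d = tom_dissimilarity(signed_adjacency(expr, 6))
        assert (d >= 0).all() and (d <= 1).all()


class TestSoftThreshold:
    def test_mean_connectivity_decreases(self, rng):
        expr, _ = _blocky_expr(rng, n_blocks=2, block=40, n_noise=40)
        _, table, _ = pick_soft_threshold(expr, candidate_betas=range(1, 13))
        ks = table["mean_k"].values
        assert (np.diff(ks) < 0).all()

    def test_selection_equals_exhaustive_scan(self, rng):
        expr, _ = _blocky_expr(rng, n_blocks=2, block=50, n_noise=60)
        beta, table, warn = pick_soft_threshold(expr, target_r2=0.8)
        ok = table[table["fit"] >= 0.8]
        if len(ok):
            assert beta == ok["beta"].min() and not warn
        else:
            assert beta == table.loc[table["fit"].idxmax(), "beta"] and warn

    def test_white_noise_sets_warning(self, rng):
        expr = pd.DataFrame(rng.normal(size=(60, 30)))
        _, table, warn = pick_soft_threshold(expr, candidate_betas=range(1, 7),
                                             target_r2=0.95)
        assert warn


class TestConsensus:
    def _meta(self, columns):
        n = len(columns)
        form = ["F1"] * (n // 2) + ["F2"] * (n - n // 2)
        return pd.DataFrame({"form": form}, index=columns)

    def test_no_resampling_equals_plain_tom(self, rng):
        expr, _ = _blocky_expr(rng, n_blocks=2, block=20, n_noise=10, n_samples=20)
        params = NetworkParams(beta=6, resamples=1, seed=0)
        cons = consensus_resampled_tom(expr, self._meta(expr.columns), params,
                                       resample=False)
        plain = tom_dissimilarity(signed_adjacency(expr, 6))
        assert np.max(np.abs(cons - plain)) < 1e-5  # float32 pipeline

    def test_median_of_hand_stack(self):
        stack = np.array([[[0.0, 0.2], [0.2, 0.0]],
                          [[0.0, 0.4], [0.4, 0.0]],
                          [[0.0, 0.9], [0.9, 0.0]]])
        cons = consensus_from_stack(stack)
        assert cons[0, 1] == pytest.approx(0.4)

    def test_small_form_rejected(self, rng):
        expr, _ = _blocky_expr(rng, n_blocks=2, block=15, n_samples=7)
        meta = pd.DataFrame({"form": ["F1"] * 3 + ["F2"] * 4}, index=expr.columns)
        params = NetworkParams(beta=6, resamples=2, min_per_form=4, seed=0)
        with pytest.raises(ValueError, match="F1"):
            consensus_resampled_tom(expr, meta, params)

    def test_deterministic_under_seed(self, rng):
        expr, _ = _blocky_expr(rng, n_blocks=2, block=15, n_noise=10, n_samples=24)
        meta = self._meta(expr.columns)
        params = NetworkParams(beta=6, resamples=5, seed=3)
        c1 = consensus_resampled_tom(expr, meta, params)
        c2 = consensus_resampled_tom(expr, meta, params)
        assert np.array_equal(c1, c2)


class TestDetectModules:
    def test_three_planted_blocks_recovered(self, rng):
        expr, truth = _blocky_expr(rng, n_blocks=3, block=60, n_noise=60)
        params = NetworkParams(beta=6, resamples=1, min_module_size=30, seed=0)
        cons = tom_dissimilarity(signed_adjacency(expr, 6))
        ms = detect_modules(cons, expr, params)
        assert len(ms.modules) == 3
        assert adjusted_rand_score(truth.values, ms.labels.values) >= 0.9

    def test_pure_noise_mostly_unassigned(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(200, 50)),
            index=[f"g{i}" for i in range(200)],
        )
        params = NetworkParams(beta=6, resamples=1, min_module_size=30, seed=0)
        cons = tom_dissimilarity(signed_adjacency(expr, 6))
        ms = detect_modules(cons, expr, params)
        assert (ms.labels == 0).mean() > 0.5

    def test_highly_correlated_modules_merge(self, rng):
        # two blocks driven by almost the same factor: eigengene corr ~ 0.97
        f = rng.normal(size=80)
        cols, labels = [], []
        for b in range(2):
            fb = 0.99 * f + 0.14 * rng.normal(size=80)
            for _ in range(40):
                cols.append(fb + 0.3 * rng.normal(size=80))
                labels.append(b + 1)
        expr = pd.DataFrame(cols, index=[f"g{i}" for i in range(80)])
        params = NetworkParams(beta=6, resamples=1, min_module_size=20,
                               cut_height_merge=0.1, seed=0)
        cons = tom_dissimilarity(signed_adjacency(expr, 6))
        ms = detect_modules(cons, expr, params)
        assert len(ms.modules) == 1

    def test_min_size_larger_than_genes_rejected(self, rng):
        expr, _ = _blocky_expr(rng, n_blocks=1, block=20, n_samples=15)
        params = NetworkParams(beta=6, min_module_size=100, seed=0)
        cons = tom_dissimilarity(signed_adjacency(expr, 6))
        with pytest.raises(ValueError, match="min_module_size"):
            detect_modules(cons, expr, params)


class TestEigengenes:
    def test_identical_genes_give_unit_kme(self):
        x = np.sin(np.linspace(0, 6, 30))
        expr = pd.DataFrame([x, x, x, x], index=list("abcd"))
        labels = pd.Series([1, 1, 1, 1], index=list("abcd"))
        ms = module_eigengenes_kme(expr, labels)
        assert np.allclose(ms.kme["M1"], 1.0)
        zx = (x - x.mean()) / x.std()
        assert np.allclose(np.abs(ms.eigengenes["M1"]), np.abs(zx), atol=1e-8)

    def test_sign_flip_changes_eigengene_not_kme_magnitude(self, rng):
        expr, truth = _blocky_expr(rng, n_blocks=1, block=20, n_samples=25)
        ms1 = module_eigengenes_kme(expr, truth)
        ms2 = module_eigengenes_kme(-expr, truth)
        assert np.allclose(np.abs(ms1.kme.values), np.abs(ms2.kme.values), atol=1e-10)
        # orientation rule: own-module mean kME positive in both
        assert ms1.kme["M1"].mean() > 0 and ms2.kme["M1"].mean() > 0

    def test_eigengene_matches_svd_share(self, rng):
        expr, truth = _blocky_expr(rng, n_blocks=1, block=25, n_samples=30)
        ms = module_eigengenes_kme(expr, truth)
        z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1)).T.values
        s = np.linalg.svd(z, compute_uv=False)
        share = s[0] ** 2 / (s**2).sum()
        # mean squared own-module kME equals the top eigenvalue share
        assert ms.kme["M1"].pow(2).mean() == pytest.approx(share, abs=1e-6)

    def test_tiny_module_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 10)), index=list("abc"))
        labels = pd.Series([1, 0, 0], index=list("abc"))
        with pytest.raises(ValueError, match="fewer than 2"):
            module_eigengenes_kme(expr, labels)


def _assoc_setup(rng, shift_form=None, shift=0.0, dx_shift=0.0):
    n_per = 10
    forms = ["control", "F1", "F2"]
    ids, rows = [], []
    for f in forms:
        for i in range(n_per):
            ids.append(f"{f}_{i}")
            rows.append(dict(form=f, diagnosis="control" if f == "control" else "affected",
                             day=25 + 25 * (i % 2), individual_id=f"{f}_i{i // 2}"))
    meta = pd.DataFrame(rows, index=ids)
    me = rng.normal(size=len(ids))
    if shift_form:
        me[meta["form"] == shift_form] += shift
    me[meta["diagnosis"] == "affected"] += dx_shift
    genes = [f"g{i}" for i in range(4)]
    expr = pd.DataFrame(rng.normal(size=(4, len(ids))), index=genes, columns=ids)
    expr.iloc[0] = me + 0.05 * rng.normal(size=len(ids))
    expr.iloc[1] = me + 0.05 * rng.normal(size=len(ids))
    labels = pd.Series([1, 1, 0, 0], index=genes)
    ms = module_eigengenes_kme(expr, labels)
    return ms, meta, expr, labels


class TestTraitAssociation:
    def test_independent_eigengene_near_zero(self, rng):
        ms, meta, _, _ = _assoc_setup(rng)
        out = module_trait_association(ms, meta)
        f = out[(out["family"] == "form")]
        assert np.abs(f["beta"]).max() < 0.8
        assert np.abs(f["signed_adjusted_R"]).max() < 0.5

    def test_shifted_form_beta_recovered(self, rng):
        ms, meta, _, _ = _assoc_setup(rng, shift_form="F1", shift=-3.0)
        out = module_trait_association(ms, meta)
        form_rows = out[(out["family"] == "form") & (out["module"] == "M1")]
        f1 = form_rows[form_rows["term"].str.contains("F1")].iloc[0]
        f2 = form_rows[form_rows["term"].str.contains("F2")].iloc[0]
        assert f1["beta"] < 0 and f1["fdr"] < 0.01
        assert abs(f1["beta"]) > 3 * abs(f2["beta"])

    def test_diagnosis_shift_signed_R_negative(self, rng):
        ms, meta, _, _ = _assoc_setup(rng, dx_shift=-1.5)
        out = module_trait_association(ms, meta)
        row = out[(out["family"] == "diagnosis") & (out["module"] == "M1")]
        assert row["beta"].iloc[0] < 0
        assert row["signed_adjusted_R"].iloc[0] < 0

    def test_control_required(self, rng):
        from convorg.comodules import module_eigengenes_kme as mek

        _, meta, expr, labels = _assoc_setup(rng)
        keep = meta.index[meta["form"] != "control"]
        ms = mek(expr.loc[:, keep], labels)
        with pytest.raises(ValueError, match="control"):
            module_trait_association(ms, meta.loc[keep])


class TestTrajectory:
    def _setup(self, rng, diverge=False):
        days = [25, 50, 75, 100]
        rows, ids = [], []
        for f in ["control", "F1"]:
            for i in range(6):
                for d in days:
                    ids.append(f"{f}_{i}_{d}")
                    rows.append(dict(form=f, day=d, individual_id=f"{f}_{i}",
                                     diagnosis="control" if f == "control" else "affected"))
        meta = pd.DataFrame(rows, index=ids)
        x = meta["day"].values / 100.0
        me = np.sin(x * 3) + 0.1 * rng.normal(size=len(ids))
        if diverge:
            me = me + np.where(meta["form"] == "F1", 1.5 * x**2, 0.0)
        genes = [f"g{i}" for i in range(4)]
        expr = pd.DataFrame(rng.normal(size=(4, len(ids))), index=genes, columns=ids)
        expr.iloc[0] = me
        expr.iloc[1] = me + 0.05 * rng.normal(size=len(ids))
        labels = pd.Series([1, 1, 0, 0], index=genes)
        return module_eigengenes_kme(expr, labels), meta

    def test_spline_basis_has_df_columns(self):
        basis = _quadratic_spline_basis(np.array([25.0, 50.0, 75.0, 100.0]))
        assert basis.shape == (4, 2)

    def test_identical_trajectories_not_significant(self, rng):
        ms, meta = self._setup(rng, diverge=False)
        out = module_trajectory_test(ms, meta)
        assert (out["p"] > 0.05).all()

    def test_divergent_form_detected(self, rng):
        ms, meta = self._setup(rng, diverge=True)
        out = module_trajectory_test(ms, meta)
        assert out[out["module"] == "M1"]["p"].iloc[0] < 0.05

    def test_fewer_than_three_days_rejected(self, rng):
        ms, meta = self._setup(rng)
        meta2 = meta[meta["day"].isin([25, 50])]
        ms2 = module_eigengenes_kme(
            pd.DataFrame(rng.normal(size=(4, len(meta2))), columns=meta2.index,
                         index=[f"g{i}" for i in range(4)]),
            pd.Series([1, 1, 0, 0], index=[f"g{i}" for i in range(4)]),
        )
        with pytest.raises(ValueError, match="3 distinct days"):
            module_trajectory_test(ms2, meta2)


class TestPreservation:
    def test_self_preservation_high_noise_low(self, rng):
        expr, truth = _blocky_expr(rng, n_blocks=2, block=40, n_noise=40,
                                   n_samples=50, noise=0.35)
        noise = pd.DataFrame(rng.normal(size=expr.shape), index=expr.index,
                             columns=[f"t{i}" for i in range(expr.shape[1])])
        z_self = module_preservation_lite(expr, truth, expr, n_perm=100, seed=0)
        z_noise = module_preservation_lite(expr, truth, noise, n_perm=100, seed=0)
        assert (z_self["z_summary"] > 10).all()
        assert (z_noise["z_summary"].abs() < 3).all()

    def test_permuted_labels_near_zero(self, rng):
        # permuted labels scored against an independent dataset: both the
        # density and the connectivity component are null by construction
        expr, truth = _blocky_expr(rng, n_blocks=2, block=30, n_noise=40, n_samples=40)
        noise = pd.DataFrame(rng.normal(size=expr.shape), index=expr.index,
                             columns=[f"t{i}" for i in range(expr.shape[1])])
        perm = pd.Series(rng.permutation(truth.values), index=truth.index)
        z = module_preservation_lite(expr, perm, noise, n_perm=100, seed=1)
        assert (z["z_summary"].abs() < 3).all()
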