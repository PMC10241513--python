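"""Biweight midcorrelation against closed-form and robustness oracles, TOM
against hand enumeration, eigengene conventions, and planted-module
recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pqtlmap import comodule


class TestBicor:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=30)
        assert comodule.bicor(x, x) == pytest.approx(1.0)

    def test_sign_flip_negates(self, rng):
        x, y = rng.normal(size=(2, 40))
        assert comodule.bicor(x, -y) == pytest.approx(-comodule.bicor(x, y), abs=1e-12)

    def test_robust_to_single_outlier(self):
        # 20-point fixture: one 10-sd outlier corrupts Pearson more than bicor
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = 0.8 * x + 0.6 * rng.normal(size=20)
        r_true = np.corrcoef(x, y)[0, 1]
        y_bad = y.copy()
        y_bad[0] = 10.0
        r_pearson = np.corrcoef(x, y_bad)[0, 1]
        r_bicor = comodule.bicor(x, y_bad)
        assert abs(r_bicor - r_true) < abs(r_pearson - r_true)

    def test_agrees_with_pearson_on_clean_gaussians(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=200)
            y = 0.5 * x + rng.normal(size=200)
            assert abs(comodule.bicor(x, y) - np.corrcoef(x, y)[0, 1]) < 0.05

    def test_pairwise_complete_and_minimum_pairs(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, np.nan])
        assert comodule.bicor(x, y) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            comodule.bicor(np.array([1.0, np.nan, 3.0]), np.array([np.nan, 2.0, 3.0]))

    def test_mad_zero_falls_back_to_pearson(self):
        x = np.array([0.0, 0.0, 0.0, 0.0, 1.0])  # MAD = 0
        y = np.array([0.1, -0.1, 0.0, 0.05, 2.0])
        r = comodule.bicor(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 15))
        r = comodule.bicor(x, y)
        assert -1.0 <= r <= 1.0
        assert comodule.bicor(y, x) == pytest.approx(r, abs=1e-12)


class TestBicorPvalue:
    def test_zero_correlation_p_is_one(self):
        assert comodule.bicor_pvalue(0.0, 25) == pytest.approx(1.0)

    def test_closed_form_t_transform(self):
        # r=0.5, n=20: t = 0.5*sqrt(18/0.75) = 2.4495, p(t_18) ~ 0.0248
        from scipy import stats

        t = 0.5 * np.sqrt(18 / 0.75)
        assert t == pytest.approx(2.4495, abs=1e-4)
        assert comodule.bicor_pvalue(0.5, 20) == pytest.approx(2 * stats.t.sf(t, 18), rel=1e-12)
        assert comodule.bicor_pvalue(0.5, 20) == pytest.approx(0.0248, abs=2e-4)

    def test_symmetric_in_sign(self):
        assert comodule.bicor_pvalue(-0.37, 30) == comodule.bicor_pvalue(0.37, 30)

    def test_perfect_correlation_p_zero(self):
        assert comodule.bicor_pvalue(1.0, 10) == 0.0


class TestTOM:
    def test_hand_enumerated_three_node_case(self):
        # beta=1 adjacency from a printed correlation matrix; TOM by explicit
        # sums, independent of the vectorised implementation
        r = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.5], [0.3, 0.5, 1.0]])
        A = np.abs(r) ** 1.0
        np.fill_diagonal(A, 0.0)
        T = comodule.tom_similarity(A)
        k = A.sum(axis=1)
        for i in range(3):
            for j in range(3):
                if i == j:
                    assert T[i, j] == 1.0
                    continue
                l_ij = sum(A[i, u] * A[u, j] for u in range(3) if u not in (i, j))
                expect = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
                assert T[i, j] == pytest.approx(expect, abs=1e-12)

    def test_bounded_symmetric_unit_diagonal(self, rng):
        r = np.clip(rng.uniform(-1, 1, size=(12, 12)), -1, 1)
        r = (r + r.T) / 2
        A = np.abs(r) ** 6
        T = comodule.tom_similarity(A)
        assert np.all((T >= 0) & (T <= 1))
        assert np.allclose(T, T.T)
        assert np.allclose(np.diag(T), 1.0)


def _two_module_table(rng, n=72, sizes=(20, 15), r=0.8, n_noise=30):
    rows, ids = [], []
    for mi, size in enumerate(sizes):
        driver = rng.normal(size=n)
        lam = np.sqrt(r)
        for k in range(size):
            rows.append(lam * driver + np.sqrt(1 - lam**2) * rng.normal(size=n))
            ids.append(f"mod{mi}_f{k}")
    for k in range(n_noise):
        rows.append(rng.normal(size=n))
        ids.append(f"noise{k}")
    return pd.DataFrame(rows, index=ids, columns=[f"s{i}" for i in range(n)])


class TestBuildModules:
    def test_recovers_planted_partition(self, rng):
        table = _two_module_table(rng)
        mods = comodule.build_modules(table, min_size=10)
        assert len(mods) == 2
        called = {f for m in mods for f in m.members}
        planted = {f for f in table.index if f.startswith("mod")}
        assert len(called & planted) / len(planted) >= 0.95
        assert all(not f.startswith("noise") for f in called)

    def test_labels_by_decreasing_size(self, rng):
        table = _two_module_table(rng)
        mods = comodule.build_modules(table, min_size=10)
        assert mods[0].label == "turquoise" and mods[1].label == "blue"
        assert len(mods[0].members) >= len(mods[1].members)

    def test_constant_features_dropped_with_warning(self, rng):
        table = _two_module_table(rng, n_noise=5)
        table.loc["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            mods = comodule.build_modules(table, min_size=10)
        assert all("flat" not in m.members for m in mods)


class TestEigengene:
    def test_identical_members_give_variance_one(self, rng):
        v = rng.normal(size=40)
        table = pd.DataFrame([v, v, v], index=list("abc"), columns=range(40))
        eig, ve = comodule.module_eigengene(table, list("abc"))
        assert ve == pytest.approx(1.0)
        z = (v - v.mean()) / v.std()
        assert np.allclose(eig.to_numpy(), z, atol=1e-8)

    def test_anticorrelated_pair_sign_convention(self, rng):
        x = rng.normal(size=30)
        table = pd.DataFrame([x, -x], index=["a", "b"], columns=range(30))
        eig, ve = comodule.module_eigengene(table, ["a", "b"])
        assert ve == pytest.approx(1.0)
        assert np.corrcoef(eig, x)[0, 1] > 0.99  # aligned with the first member

    def test_unit_variance_and_scale_invariance(self, rng):
        table = _two_module_table(rng, sizes=(12,), n_noise=0)
        members = list(table.index)
        eig, _ = comodule.module_eigengene(table, members)
        assert eig.to_numpy().std() == pytest.approx(1.0)
        scaled = table.copy()
        scaled.iloc[0] *= 37.0
        eig2, _ = comodule.module_eigengene(scaled, members)
        assert np.allclose(eig.to_numpy(), eig2.to_numpy(), atol=1e-10)

    def test_recovers_planted_driver(self, rng):
        n = 72
        driver = rng.normal(size=n)
        rows = [1.5 * driver + rng.normal(0, 0.5, n) for _ in range(20)]
        table = pd.DataFrame(rows, index=[f"f{i}" for i in range(20)], columns=range(n))
        eig, _ = comodule.module_eigengene(table, list(table.index))
        assert abs(comodule.bicor(eig.to_numpy(), driver)) > 0.9


class TestOverlap:
    def test_identical_and_disjoint_sets(self):
        bg = [f"f{i}" for i in range(100)]
        frac, p = comodule.module_hotspot_overlap(bg[:10], bg[:10], bg)
        assert frac == 1.0 and p < 1e-10
        frac, p = comodule.module_hotspot_overlap(bg[:10], bg[50:60], bg)
        assert frac == 0.0 and p > 0.5

    def test_partial_overlap_arithmetic(self):
        bg = [f"f{i}" for i in range(200)]
        module = bg[:30]
        hotspot = bg[5:31]  # 26 members, 25 inside the module
        frac, _ = comodule.module_hotspot_overlap(module, hotspot, bg)
        assert frac == pytest.approx(25 / 26, abs=1e-12)

    def test_empty_hotspot_rejected(self):
        with pytest.raises(ValueError):
            comodule.module_hotspot_overlap(["a"], [], ["a", "b"])
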