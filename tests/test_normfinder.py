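"""NormFinder: variance decomposition, stability values, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import refstab as rs
from refstab.errors import AnalysisError
from refstab.normfinder import _intra_group_variance
from .conftest import random_ct


def additive_ct(baselines, shifts, group_labels, effects=None, rng=None, sigma=0.0):
    L, n = len(baselines), len(shifts)
    vals = np.asarray(baselines, float)[:, None] + np.asarray(shifts, float)[None, :]
    if effects:
        for (gene_i, grp), delta in effects.items():
            for j, g in enumerate(group_labels):
                if g == grp:
                    vals[gene_i, j] += delta
    if sigma:
        vals = vals + rng.normal(0, sigma, size=vals.shape)
    return rs.from_arrays(
        vals,
        [f"g{i}" for i in range(L)],
        [{"sample_id": f"s{j}", "group": group_labels[j]} for j in range(n)],
    )


def lstsq_residual_variance(y_g):
    """Oracle: per-gene corrected residual mean square of a least-squares
    two-way (gene + sample) additive fit."""
    L, n = y_g.shape
    rows = []
    X_cols = []
    # dummy coding with explicit intercept, drop-first for identifiability
    for i in range(L):
        for j in range(n):
            row = [1.0]
            row += [1.0 if i == k else 0.0 for k in range(1, L)]
            row += [1.0 if j == k else 0.0 for k in range(1, n)]
            X_cols.append(row)
            rows.append(y_g[i, j])
    X = np.asarray(X_cols)
    beta, *_ = np.linalg.lstsq(X, np.asarray(rows), rcond=None)
    resid = (np.asarray(rows) - X @ beta).reshape(L, n)
    return (L / (L - 1)) * (resid**2).sum(axis=1) / (n - 1)


class TestStructuralZeroes:
    def test_noise_free_additive_data_scores_zero(self):
        labels = ["a"] * 3 + ["b"] * 3
        ct = additive_ct([18, 20, 22, 25], np.arange(6) * 0.3, labels)
        res = rs.normfinder_stability(ct)
        assert np.allclose(res.sv.to_numpy(), 0.0, atol=1e-12)
        assert np.allclose(res.d_hat.to_numpy(), 0.0, atol=1e-12)
        assert res.gamma2 == 0.0

    def test_d_hat_sums_to_zero_over_genes_per_group(self, rng):
        ct = random_ct(rng, n_genes=6, n_samples=16, groups=("a", "b", "c", "d"))
        res = rs.normfinder_stability(ct)
        assert np.allclose(res.d_hat.sum(axis=0).to_numpy(), 0.0, atol=1e-12)

    def test_shrinkage_never_exceeds_raw_deviation(self, trauma_ct):
        res = rs.normfinder_stability(trauma_ct)
        assert (np.abs(res.d_tilde.to_numpy()) <= np.abs(res.d_hat.to_numpy()) + 1e-15).all()
        assert (res.sigma2.to_numpy() >= 0).all()
        assert res.gamma2 >= 0
        assert (res.sv.to_numpy() >= 0).all()


class TestOracle:
    @given(st.integers(0, 10_000))
    def test_intra_group_variance_matches_least_squares_fit(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(3, 7))
        n = int(rng.integers(3, 9))
        y = rng.normal(20, 2, size=(L, n))
        ours = _intra_group_variance(y - y.mean(axis=1, keepdims=True))
        oracle = lstsq_residual_variance(y)
        assert np.allclose(ours, oracle, atol=1e-10)

    @given(st.integers(0, 10_000))
    def test_residual_zero_sum_constraints(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 1, size=(5, 8))
        r = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
        assert np.allclose(r.sum(axis=0), 0, atol=1e-12)
        assert np.allclose(r.sum(axis=1), 0, atol=1e-12)


class TestInvariances:
    @given(st.integers(0, 10_000))
    def test_per_sample_and_per_gene_constants_absorbed(self, seed):
        rng = np.random.default_rng(seed)
        ct = random_ct(rng, n_genes=5, n_samples=12, groups=("a", "b"))
        base = rs.normfinder_stability(ct)
        shifted = ct.copy()
        shifted.values.iloc[:, :] = (
            ct.values.to_numpy()
            + rng.normal(0, 2, size=ct.n_samples)[None, :]
            + rng.normal(0, 2, size=ct.n_genes)[:, None]
        )
        res = rs.normfinder_stability(shifted)
        assert np.allclose(base.sv.to_numpy(), res.sv.to_numpy(), atol=1e-9)
        assert np.allclose(base.d_hat.to_numpy(), res.d_hat.to_numpy(), atol=1e-9)

    def test_gene_order_permutation_invariance(self, trauma_ct):
        res = rs.normfinder_stability(trauma_ct)
        perm = list(reversed(trauma_ct.genes))
        res_p = rs.normfinder_stability(trauma_ct, genes=perm)
        assert np.allclose(res.sv.loc[perm].to_numpy(), res_p.sv.to_numpy(), atol=1e-12)


class TestRecovery:
    def test_planted_group_shift_ranks_last(self):
        """Two groups, 5 genes, one shifted by 1 cycle in group 2."""
        hits = 0
        n_sim = 100
        labels = ["a"] * 12 + ["b"] * 12
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            ct = additive_ct(
                [18, 20, 22, 24, 26],
                rng.normal(0, 0.5, 24),
                labels,
                effects={(0, "b"): 1.0},
                rng=rng,
                sigma=0.2,
            )
            res = rs.normfinder_stability(ct)
            hits += res.sv.idxmax() == "g0"
        assert hits / n_sim >= 0.95

    def test_single_group_sv_orders_by_noise(self):
        hits = 0
        n_sim = 200
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            sigmas = np.array([0.1, 0.2, 0.4, 0.1])
            vals = (
                np.array([18.0, 20, 22, 24])[:, None]
                + rng.normal(0, 0.5, 10)[None, :]
                + rng.normal(0, 1, size=(4, 10)) * sigmas[:, None]
            )
            ct = rs.from_arrays(
                vals, ["a", "b", "c", "d"], [{"sample_id": f"s{j}", "group": "x"} for j in range(10)]
            )
            res = rs.normfinder_stability(ct)
            hits += res.sv["c"] == res.sv.max()
        assert hits / n_sim >= 0.90


class TestErrorsAndModes:
    def test_grouped_with_single_group_suggests_ungrouped(self):
        ct = random_ct(np.random.default_rng(0), groups=("only",))
        with pytest.raises(AnalysisError, match="grouped=False"):
            rs.normfinder_stability(ct, grouped=True)
        res = rs.normfinder_stability(ct)  # auto-falls back to ungrouped
        assert not res.grouped

    def test_tiny_group_rejected(self):
        labels = ["a"] * 5 + ["b"]
        ct = additive_ct([18, 20, 22], np.zeros(6), labels)
        with pytest.raises(AnalysisError, match="fewer than 2"):
            rs.normfinder_stability(ct)

    def test_flat_between_groups_warns_and_falls_back(self):
        # noise present, but per-(gene, group) means forced equal -> gamma2 = 0
        labels = ["a"] * 4 + ["b"] * 4
        rng = np.random.default_rng(5)
        vals = np.array([18.0, 20, 22])[:, None] + rng.normal(0, 0.3, size=(3, 8))
        for grp in ("a", "b"):
            idx = [j for j, g in enumerate(labels) if g == grp]
            vals[:, idx] -= vals[:, idx].mean(axis=1, keepdims=True)
        ct = rs.from_arrays(
            vals + 20, ["x", "y", "z"], [{"sample_id": f"s{j}", "group": labels[j]} for j in range(8)]
        )
        with pytest.warns(UserWarning, match="gamma2 = 0"):
            res = rs.normfinder_stability(ct)
        assert res.gamma2 == 0
        assert np.allclose(res.sv.to_numpy(), 0.0)
        assert res.ranking.notna().all()


class TestIntergroupVariation:
    def test_noise_free_diagnostics_are_zero(self):
        labels = ["a"] * 3 + ["b"] * 3
        ct = additive_ct([18, 20, 22], np.arange(6) * 0.2, labels)
        tab = rs.intergroup_variation(ct)
        assert np.allclose(tab["d_hat"], 0.0, atol=1e-12)
        assert np.allclose(tab["intra_sd"], 0.0, atol=1e-12)

    def test_planted_shift_dominates_d_hat(self):
        hits = 0
        n_sim = 100
        for seed in range(n_sim):
            ct = rs.generate(rs.preset("paper_d3_hypothalamus", seed=seed))
            tab = rs.intergroup_variation(ct)
            worst = tab.loc[tab["d_hat"].abs().idxmax()]
            hits += worst["gene"] == "B2m"
        assert hits / n_sim >= 0.95

    def test_per_group_zero_sum(self, trauma_ct):
        tab = rs.intergroup_variation(trauma_ct)
        sums = tab.groupby("group")["d_hat"].sum()
        assert np.allclose(sums.to_numpy(), 0.0, atol=1e-12)
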