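"""GeNorm: M values, stepwise exclusion, V curve, suitability."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import refstab as rs
from refstab.errors import AnalysisError
from refstab.genorm import select_optimal_n
from .conftest import random_ct


def brute_force_m(ct_values, efficiency=2.0):
    """Independent oracle: all-pairs SD of log-ratios of relative quantities."""
    y = np.asarray(ct_values, dtype=float)
    logq = np.log2(efficiency) * (y.min(axis=1, keepdims=True) - y)
    L = y.shape[0]
    M = np.zeros(L)
    for j in range(L):
        sds = [np.std(logq[j] - logq[k], ddof=1) for k in range(L) if k != j]
        M[j] = np.mean(sds)
    return M


class TestRelativeQuantities:
    def test_definition(self, small_ct):
        rq = rs.relative_quantities(small_ct)
        assert rq.Q.loc["g1"].tolist() == [1.0, 0.5, 0.25]

    def test_constant_gene_is_all_ones(self):
        ct = rs.from_arrays(
            [[21, 21, 21], [20, 21, 22]],
            ["c", "v"],
            [{"sample_id": f"s{i}", "group": "a"} for i in range(3)],
        )
        assert (rs.relative_quantities(ct).Q.loc["c"] == 1.0).all()

    def test_per_gene_maximum_is_one(self, trauma_ct):
        rq = rs.relative_quantities(trauma_ct)
        assert np.allclose(rq.Q.max(axis=1), 1.0)

    def test_degenerate_efficiency_rejected(self, small_ct):
        with pytest.raises(AnalysisError, match="efficiency"):
            rs.relative_quantities(small_ct, efficiency=1.0)

    def test_missing_values_direct_to_complete_cases(self, trauma_ct):
        ct = trauma_ct.copy()
        ct.values.iloc[0, 0] = np.nan
        with pytest.raises(AnalysisError, match="complete_cases"):
            rs.relative_quantities(ct)


class TestMValues:
    def test_hand_computed_three_gene_example(self, small_ct):
        M = rs.m_values(rs.relative_quantities(small_ct))
        assert np.allclose(M.to_numpy(), [0.5, 0.5, 1.0])

    def test_constant_offset_pair_has_zero_m(self):
        ct = rs.from_arrays(
            [[20, 21, 22], [23, 24, 25]],
            ["g1", "g2"],
            [{"sample_id": f"s{i}", "group": "a"} for i in range(3)],
        )
        assert np.allclose(rs.m_values(rs.relative_quantities(ct)).to_numpy(), 0.0)

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ct = random_ct(rng, n_genes=int(rng.integers(4, 9)), n_samples=int(rng.integers(6, 31)))
        M = rs.m_values(rs.relative_quantities(ct))
        assert np.allclose(M.to_numpy(), brute_force_m(ct.values.to_numpy()), atol=1e-12)

    @given(st.integers(0, 10_000))
    def test_invariant_to_per_sample_shift(self, seed):
        rng = np.random.default_rng(seed)
        ct = random_ct(rng)
        shifted = ct.copy()
        shifted.values.iloc[:, :] = ct.values.to_numpy() + rng.normal(0, 3, size=ct.n_samples)[None, :]
        m0 = rs.m_values(rs.relative_quantities(ct)).to_numpy()
        m1 = rs.m_values(rs.relative_quantities(shifted)).to_numpy()
        assert np.allclose(m0, m1, atol=1e-9)

    def test_invariant_to_gene_reordering(self, trauma_ct):
        rq = rs.relative_quantities(trauma_ct)
        M = rs.m_values(rq)
        perm = list(reversed(trauma_ct.genes))
        M_perm = rs.m_values(rq, perm)
        assert np.allclose(M.loc[perm].to_numpy(), M_perm.to_numpy(), atol=1e-12)


class TestGenormRank:
    def test_single_exclusion_from_hand_example(self, small_ct):
        gn = rs.genorm_rank(rs.relative_quantities(small_ct))
        assert gn.removal_order == ["g3"]
        assert gn.M_final["g1"] == gn.M_final["g2"] == 0.0
        assert gn.ranking.tolist() == [1.5, 1.5, 3.0]
        assert gn.stability_order == ["g1", "g2", "g3"]

    def test_final_pair_shares_pairwise_v(self, trauma_ct):
        rq = rs.relative_quantities(trauma_ct)
        gn = rs.genorm_rank(rq)
        pair = [g for g in trauma_ct.genes if g not in gn.removal_order]
        assert len(pair) == 2
        pair_v = np.std(np.log2(rq.Q.loc[pair[0]] / rq.Q.loc[pair[1]]), ddof=1)
        assert gn.M_final[pair[0]] == pytest.approx(gn.M_final[pair[1]], abs=1e-15)
        assert gn.M_final[pair[0]] == pytest.approx(pair_v, abs=1e-12)

    def test_all_identical_genes_removed_in_input_order(self):
        base = np.array([20.0, 21.0, 22.0, 20.5])
        ct = rs.from_arrays(
            [base, base + 1, base + 2, base - 1],
            ["a", "b", "c", "d"],
            [{"sample_id": f"s{i}", "group": "x"} for i in range(4)],
        )
        gn = rs.genorm_rank(rs.relative_quantities(ct))
        assert gn.removal_order == ["a", "b"]  # ties broken by input order
        assert np.allclose(gn.M_final.to_numpy(), 0.0)

    def test_planted_group_shift_removed_first(self):
        hits = 0
        n_sim = 100
        for seed in range(n_sim):
            ct = rs.generate(rs.preset("paper_d3_bone", seed=seed))
            gn = rs.genorm_rank(rs.relative_quantities(ct))
            hits += gn.removal_order[0] == "Actb"
        assert hits / n_sim >= 0.95

    def test_two_genes_falls_back_with_warning(self, small_ct):
        rq = rs.relative_quantities(small_ct)
        with pytest.warns(UserWarning, match="fewer than 3"):
            gn = rs.genorm_rank(rq, panel=["g1", "g2"])
        assert gn.removal_order == []


class TestVCurve:
    def test_low_noise_panel_needs_two_genes(self):
        design = rs.preset("neutral", seed=3)
        ct = rs.generate(design)
        rq = rs.relative_quantities(ct)
        gn = rs.genorm_rank(rq)
        vc = rs.pairwise_variation_curve(rq, gn.stability_order)
        assert vc.V[2] < 0.15
        assert vc.optimal_n == 2

    def test_selection_rule_on_printed_values(self):
        # the liver-style curve: V2/3 already below the cutoff
        assert select_optimal_n({2: 0.134, 3: 0.10}, L=4) == 2
        with pytest.warns(UserWarning, match="no V"):
            assert select_optimal_n({2: 0.2, 3: 0.19}, L=4) == 4
        # boundary value accepted only with the inclusive option
        with pytest.warns(UserWarning, match="no V"):
            assert select_optimal_n({2: 0.15}, L=3) == 3
        assert select_optimal_n({2: 0.15}, L=3, cutoff_inclusive=True) == 2

    def test_noise_free_curve_is_zero(self):
        base = np.linspace(20, 23, 6)
        ct = rs.from_arrays(
            [base, base + 1, base + 2, base + 3],
            ["a", "b", "c", "d"],
            [{"sample_id": f"s{i}", "group": "x"} for i in range(6)],
        )
        rq = rs.relative_quantities(ct)
        gn = rs.genorm_rank(rq)
        vc = rs.pairwise_variation_curve(rq, gn.stability_order)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in vc.V.values())
        assert vc.optimal_n == 2

    def test_too_few_genes_rejected(self, small_ct):
        rq = rs.relative_quantities(small_ct)
        with pytest.raises(AnalysisError):
            rs.pairwise_variation_curve(rq, ["g1", "g2"])


class TestSuitability:
    @pytest.mark.parametrize(
        "M, homogeneous, expected",
        [
            (0.509, False, True),   # heterogeneous threshold 1.5
            (0.916, True, False),   # homogeneous threshold 0.5
            (0.0, True, True),
            (0.0, False, True),
        ],
    )
    def test_thresholds(self, M, homogeneous, expected):
        import pandas as pd

        flags, threshold = rs.flag_suitability(pd.Series({"g": M}), homogeneous=homogeneous)
        assert bool(flags["g"]) is expected
        assert threshold == (0.5 if homogeneous else 1.5)
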