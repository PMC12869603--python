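"""Differential ICC maps, permutation testing, FDR, masks and block summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fpconn as fp
from fpconn import differential as diff
from fpconn import reliability as rel
from fpconn.connectome import FPConnError
from tests.conftest import split_vectors


def _icc(values, n):
    np.fill_diagonal(values, np.nan)
    return rel.ICCMatrix(values, n)


class TestICCDiff:
    def test_equal_maps_give_zero(self):
        v = np.random.default_rng(0).uniform(0, 1, (4, 4))
        v = (v + v.T) / 2
        d = fp.compute_icc_diff(_icc(v.copy(), 4), _icc(v.copy(), 4))
        iu = np.triu_indices(4, k=1)
        np.testing.assert_allclose(d.values[iu], 0.0)

    def test_swap_negates(self):
        rng = np.random.default_rng(1)
        a, b = [(lambda m: (m + m.T) / 2)(rng.uniform(0, 1, (4, 4)))
                for _ in range(2)]
        d_ab = fp.compute_icc_diff(_icc(a.copy(), 4), _icc(b.copy(), 4))
        d_ba = fp.compute_icc_diff(_icc(b.copy(), 4), _icc(a.copy(), 4))
        iu = np.triu_indices(4, k=1)
        np.testing.assert_allclose(d_ab.values[iu], -d_ba.values[iu])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(FPConnError):
            fp.compute_icc_diff(_icc(np.zeros((3, 3)), 3),
                                _icc(np.zeros((4, 4)), 4))


class TestBHAdjust:
    def test_worked_example_family_of_three(self):
        adj = fp.bh_adjust(np.array([0.004, 0.009, 0.5]))
        np.testing.assert_allclose(adj, [0.012, 0.0135, 0.5])

    def test_equal_p_values_unchanged(self):
        adj = fp.bh_adjust(np.full(7, 0.03))
        np.testing.assert_allclose(adj, 0.03)

    def test_single_test_identity(self):
        assert fp.bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(FPConnError):
            fp.bh_adjust(np.array([0.1, 1.5]))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=100))
    def test_matches_statsmodels_reference(self, p_list):
        from statsmodels.stats.multitest import multipletests

        p = np.array(p_list)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(fp.bh_adjust(p), expected, atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 50)
        assert np.all(fp.bh_adjust(p) >= p - 1e-15)


def _null_cohort(seed):
    cfg = fp.CohortConfig(n_per_group=10, n_regions=21, n_timepoints=200,
                          network_sizes=(3, 3, 3, 3, 3, 3, 3),
                          fingerprint_share=0.3, group_share=0.0,
                          stability_diff_blocks=(), outcome_coupling=0.0,
                          seed=seed)
    ts, atlas, cov, _ = fp.generate_cohort(cfg)
    return split_vectors(ts, cov, scope="pooled")


class TestPermutationTest:
    def test_null_type_one_calibration(self):
        """Without a planted difference the raw p-values are uniform (about
        5% below 0.05) and no edge survives FDR at 0.01."""
        vecs = _null_cohort(5)
        cfg = diff.PermutationConfig(n_perm=500, seed=3, alpha=0.01,
                                     subsample=None)
        perm = diff.permutation_test_icc_diff(
            vecs["control"]["test"], vecs["control"]["retest"],
            vecs["patient"]["test"], vecs["patient"]["retest"], cfg)
        frac = float((perm.p_raw < 0.05).mean())
        assert 0.01 < frac < 0.10
        assert int((perm.p_adj < 0.01).sum()) == 0

    def test_deterministic_given_seed(self):
        vecs = _null_cohort(6)
        cfg = diff.PermutationConfig(n_perm=120, seed=9, subsample=None)
        args = (vecs["control"]["test"], vecs["control"]["retest"],
                vecs["patient"]["test"], vecs["patient"]["retest"])
        p1 = diff.permutation_test_icc_diff(*args, cfg)
        p2 = diff.permutation_test_icc_diff(*args, cfg)
        np.testing.assert_array_equal(p1.p_raw, p2.p_raw)
        np.testing.assert_array_equal(p1.observed, p2.observed)

    def test_planted_block_recovery(self, powered_cohort, powered_analysis):
        """A fully regenerated block component is recovered with >= 80%
        sensitivity at FDR 0.01 and without wrong-direction detections."""
        truth = powered_cohort["truth"]
        mask_c, mask_p = powered_analysis["masks"]
        planted = truth.true_differential_edges["control_gt_patient"]
        sens = (mask_c.edges & planted).sum() / planted.sum()
        n_det = mask_c.n_edges + mask_p.n_edges
        assert sens >= 0.8
        assert mask_p.n_edges <= 0.05 * n_det  # wrong-direction detections

    def test_subsampled_observed_statistic_supported(self):
        vecs = _null_cohort(7)
        cfg = diff.PermutationConfig(
            n_perm=100, seed=1,
            subsample=rel.ICCSubsampleConfig(n_iter=5, fraction=0.8))
        perm = diff.permutation_test_icc_diff(
            vecs["control"]["test"], vecs["control"]["retest"],
            vecs["patient"]["test"], vecs["patient"]["retest"], cfg)
        assert np.all(perm.p_raw >= 1 / 101)


class TestMasks:
    def _toy(self):
        # 4 regions, 6 edges; two significant positive edges sharing node 0
        values = np.zeros((4, 4))
        values[0, 1] = values[1, 0] = 0.5
        values[0, 2] = values[2, 0] = 0.4
        values[1, 3] = values[3, 1] = -0.3
        np.fill_diagonal(values, np.nan)
        dmat = diff.ICCDiffMatrix(values)
        p_adj = np.array([0.001, 0.002, 0.5, 0.5, 0.005, 0.9])
        perm = diff.EdgePermutationResult(
            p_raw=p_adj / 2, p_adj=p_adj, observed=dmat.edge_values(),
            n_perm=1000, seed=0, alpha=0.01)
        return dmat, perm

    def test_enumerated_counts_and_rois(self):
        dmat, perm = self._toy()
        mask_pos, mask_neg = fp.extract_edge_masks(dmat, perm, alpha=0.01)
        assert mask_pos.n_edges == 2
        assert mask_pos.n_rois == 3
        np.testing.assert_array_equal(mask_pos.roi_set, [0, 1, 2])
        assert mask_neg.n_edges == 1 and mask_neg.n_rois == 2

    def test_directions_partition_significant_edges(self):
        dmat, perm = self._toy()
        mask_pos, mask_neg = fp.extract_edge_masks(dmat, perm, alpha=0.01)
        sig = perm.p_adj < 0.01
        assert not np.any(mask_pos.edges & mask_neg.edges)
        np.testing.assert_array_equal(mask_pos.edges | mask_neg.edges, sig)

    def test_group_swap_swaps_masks(self):
        dmat, perm = self._toy()
        swapped = diff.ICCDiffMatrix(-dmat.values)
        perm_sw = diff.EdgePermutationResult(
            perm.p_raw, perm.p_adj, -perm.observed, 1000, 0, 0.01)
        a, b = fp.extract_edge_masks(dmat, perm)
        a2, b2 = fp.extract_edge_masks(swapped, perm_sw)
        np.testing.assert_array_equal(a.edges, b2.edges)
        np.testing.assert_array_equal(b.edges, a2.edges)

    def test_no_significant_edges(self):
        dmat, perm = self._toy()
        perm.p_adj = np.full(6, 0.5)
        a, b = fp.extract_edge_masks(dmat, perm)
        assert a.n_edges == b.n_edges == 0
        assert a.roi_set.size == 0

    def test_bad_alpha_rejected(self):
        dmat, perm = self._toy()
        with pytest.raises(FPConnError):
            fp.extract_edge_masks(dmat, perm, alpha=1.5)


def _block_atlas():
    rows = []
    r = 0
    for lab, s in zip(rel.NETWORK_LABELS, (3, 3, 3, 3, 3, 3, 3)):
        for _ in range(s):
            rows.append({"region_id": f"R{r:03d}", "region_name": lab,
                         "network": lab})
            r += 1
    return pd.DataFrame(rows)


class TestBlockSummary:
    def _setup(self, edges_with_diff):
        n = 21
        values = np.zeros((n, n))
        for (i, j), v in edges_with_diff.items():
            values[i, j] = values[j, i] = v
        np.fill_diagonal(values, np.nan)
        dmat = diff.ICCDiffMatrix(values)
        e = len(dmat.edge_values())
        sig = np.abs(dmat.edge_values()) > 0
        mask_pos = diff.EdgeMask("A_gt_B", sig & (dmat.edge_values() > 0), n)
        mask_neg = diff.EdgeMask("B_gt_A", sig & (dmat.edge_values() < 0), n)
        return dmat, (mask_pos, mask_neg)

    def test_single_block_takes_all_strength(self):
        dmat, masks = self._setup({(0, 1): 0.5, (1, 2): 0.3})  # within VN
        summary = fp.network_block_summary(dmat, masks, _block_atlas())
        assert summary.block_strengths.loc["VN", "VN"] == pytest.approx(1.0)
        assert summary.n_blocks_hit == 1
        assert summary.coverage_fraction == pytest.approx(1.0)

    def test_two_equal_blocks_split_evenly(self):
        # one VN-VN edge and one SMN-SMN edge of equal strength
        dmat, masks = self._setup({(0, 1): 0.4, (3, 4): 0.4})
        summary = fp.network_block_summary(dmat, masks, _block_atlas())
        assert summary.block_strengths.loc["VN", "VN"] == pytest.approx(0.5)
        assert summary.block_strengths.loc["SMN", "SMN"] == pytest.approx(0.5)
        assert summary.n_blocks_hit == 2

    def test_planted_block_dominates_summary(self, powered_cohort,
                                             powered_analysis):
        summary = fp.network_block_summary(
            powered_analysis["diff"], powered_analysis["masks"],
            powered_cohort["atlas"])
        strengths = summary.block_strengths
        assert strengths.loc["VN", "SMN"] == strengths.to_numpy().max()
        assert summary.coverage_fraction > 0.5
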