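"""Group differences in edgewise fingerprint reliability.

The differential map ``ICC_diff = ICC(group A) - ICC(group B)`` is tested
edge-by-edge with a subject-level label permutation that keeps every
subject's test/retest pair intact, followed by Benjamini-Hochberg FDR
control across all edges.  Significant edges are split by direction into
masks (A > B and B > A) whose unique endpoints form the discriminative ROI
sets, and summarized as normalized strengths over the 28 within/between
network blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .connectome import FPConnError, devectorize_fc, edge_index
from .reliability import ICCMatrix, ICCSubsampleConfig, icc_1_1, network_membership


@dataclass
class ICCDiffMatrix:
    """R x R symmetric observed ICC difference (A - B); diagonal NaN."""

    values: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def edge_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


@dataclass
class PermutationConfig:
    """Settings for the edgewise label-permutation test.

    ``subsample`` mirrors the subsampling used for the observed ICC maps;
    ``None`` computes plain full-sample ICCs inside both the observed and
    null statistics (fast mode).
    """

    n_perm: int = 1000
    seed: int = 0
    alpha: float = 0.01
    subsample: ICCSubsampleConfig | None = field(
        default_factory=ICCSubsampleConfig)


@dataclass
class EdgePermutationResult:
    p_raw: np.ndarray
    p_adj: np.ndarray
    observed: np.ndarray
    n_perm: int
    seed: int
    alpha: float


@dataclass
class EdgeMask:
    direction: str
    edges: np.ndarray
    n_regions: int

    @property
    def edge_pairs(self) -> list[tuple[int, int]]:
        pairs = edge_index(self.n_regions)
        return [pairs[k] for k in np.flatnonzero(self.edges)]

    @property
    def roi_set(self) -> np.ndarray:
        pairs = self.edge_pairs
        return np.unique([r for p in pairs for r in p]).astype(int)

    @property
    def n_edges(self) -> int:
        return int(self.edges.sum())

    @property
    def n_rois(self) -> int:
        return len(self.roi_set)


@dataclass
class NetworkBlockSummary:
    block_strengths: pd.DataFrame
    n_blocks_hit: int
    coverage_fraction: float


def compute_icc_diff(icc_a: ICCMatrix, icc_b: ICCMatrix) -> ICCDiffMatrix:
    """Elementwise ICC difference, group A minus group B."""
    if icc_a.values.shape != icc_b.values.shape:
        raise FPConnError("ICC matrices have mismatched shapes")
    return ICCDiffMatrix(icc_a.values - icc_b.values)


def _stack(vectors: Mapping[str, np.ndarray]) -> np.ndarray:
    return np.vstack([vectors[s] for s in vectors])


def _group_icc(t: np.ndarray, r: np.ndarray,
               subsample: ICCSubsampleConfig | None, seed: int) -> np.ndarray:
    if subsample is None:
        return icc_1_1(t, r)
    n = t.shape[0]
    cfg = ICCSubsampleConfig(subsample.n_iter, subsample.fraction, seed)
    n_sub = cfg.validate(n)
    rng = np.random.default_rng(seed)
    acc = np.zeros(t.shape[1])
    for _ in range(cfg.n_iter):
        idx = rng.choice(n, size=n_sub, replace=False)
        acc += icc_1_1(t[idx], r[idx])
    return acc / cfg.n_iter


def permutation_test_icc_diff(test_a: Mapping[str, np.ndarray],
                              retest_a: Mapping[str, np.ndarray],
                              test_b: Mapping[str, np.ndarray],
                              retest_b: Mapping[str, np.ndarray],
                              cfg: PermutationConfig) -> EdgePermutationResult:
    """Edgewise permutation test of the ICC difference between two groups.

    Whole subjects (their test and retest vectors together) are pooled and
    reassigned to pseudo-groups of the original sizes at each iteration,
    preserving the within-subject temporal pairing.  Per edge the two-sided
    p-value is the plus-one-corrected proportion of permuted |differences|
    at least as large as the observed one; p-values are then BH-adjusted
    across all edges.
    """
    if cfg.n_perm < 100:
        warnings.warn(f"n_perm={cfg.n_perm} < 100: permutation p-values are coarse")
    ta, ra = _stack(test_a), _stack(retest_a)
    tb, rb = _stack(test_b), _stack(retest_b)
    na, nb = ta.shape[0], tb.shape[0]
    if min(na, nb) < 3:
        raise FPConnError("need >= 3 subjects per group for the permutation test")
    t_pool = np.vstack([ta, tb])
    r_pool = np.vstack([ra, rb])
    rng = np.random.default_rng(cfg.seed)
    seed_obs_a, seed_obs_b = rng.integers(2**31, size=2)
    observed = (_group_icc(ta, ra, cfg.subsample, int(seed_obs_a))
                - _group_icc(tb, rb, cfg.subsample, int(seed_obs_b)))
    abs_obs = np.abs(observed)
    exceed = np.zeros(observed.size, dtype=int)
    n_total = na + nb
    for _ in range(cfg.n_perm):
        perm = rng.permutation(n_total)
        ia, ib = perm[:na], perm[na:]
        sa, sb = rng.integers(2**31, size=2)
        null = (_group_icc(t_pool[ia], r_pool[ia], cfg.subsample, int(sa))
                - _group_icc(t_pool[ib], r_pool[ib], cfg.subsample, int(sb)))
        exceed += (np.abs(null) >= abs_obs)
    p_raw = (1 + exceed) / (cfg.n_perm + 1)
    p_adj = bh_adjust(p_raw)
    return EdgePermutationResult(p_raw=p_raw, p_adj=p_adj, observed=observed,
                                 n_perm=cfg.n_perm, seed=cfg.seed, alpha=cfg.alpha)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted ascending, ``p_adj(i) = min_{j >= i} p(j) * m / j`` capped at 1,
    returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise FPConnError("p-values must be a 1-D array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise FPConnError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def extract_edge_masks(diff: ICCDiffMatrix, perm: EdgePermutationResult,
                       alpha: float | None = None) -> tuple[EdgeMask, EdgeMask]:
    """Directional masks of edges with FDR-significant ICC differences."""
    if alpha is None:
        alpha = perm.alpha
    if not 0 < alpha < 1:
        raise FPConnError(f"alpha must be in (0, 1), got {alpha}")
    diff_edges = diff.edge_values()
    sig = perm.p_adj < alpha
    a_gt_b = EdgeMask("A_gt_B", sig & (diff_edges > 0), diff.n_regions)
    b_gt_a = EdgeMask("B_gt_A", sig & (diff_edges < 0), diff.n_regions)
    return a_gt_b, b_gt_a


def network_block_summary(diff: ICCDiffMatrix,
                          masks: tuple[EdgeMask, EdgeMask],
                          atlas: pd.DataFrame) -> NetworkBlockSummary:
    """Summed |ICC_diff| of significant edges per network block, normalized.

    Strengths are normalized to the combined total over both directions;
    ``coverage_fraction`` is the share of the connectome-wide summed
    |ICC_diff| carried by significant edges.
    """
    members = network_membership(atlas)
    labels = list(members)
    region_net = np.empty(diff.n_regions, dtype=object)
    for lab, idx in members.items():
        region_net[idx] = lab
    pairs = edge_index(diff.n_regions)
    diff_edges = diff.edge_values()
    sig = masks[0].edges | masks[1].edges
    strengths = pd.DataFrame(0.0, index=labels, columns=labels)
    for k in np.flatnonzero(sig):
        i, j = pairs[k]
        li, lj = region_net[i], region_net[j]
        a, b = sorted([li, lj], key=labels.index)
        strengths.loc[a, b] += abs(diff_edges[k])
    total_sig = strengths.to_numpy().sum()
    n_hit = int((strengths.to_numpy() > 0).sum())
    if total_sig > 0:
        strengths = strengths / total_sig
    total_all = np.abs(diff_edges).sum()
    coverage = float(total_sig / total_all) if total_all > 0 else 0.0
    return NetworkBlockSummary(block_strengths=strengths, n_blocks_hit=n_hit,
                               coverage_fraction=coverage)
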