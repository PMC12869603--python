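"""Edgewise test-retest reliability via ICC(1,1) and its network profile.

Each FC edge is scored with the one-way random-effects intraclass
correlation across subjects, with k = 2 repeated measurements (the test and
retest halves of the scan):

    ICC(1,1) = (MS_B - MS_W) / (MS_B + (k - 1) * MS_W)

MS_B is the between-subject mean square (df N-1) and MS_W the
within-subject/residual mean square (df N(k-1)).  Negative values are kept:
they indicate within-subject fluctuations exceeding between-subject spread.
Edgewise estimates are stabilized by averaging over repeated random
subsamples of subjects, then summarized per canonical network and compared
between rankings with a pairwise concordance score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectome import NETWORK_LABELS, FPConnError, devectorize_fc, n_edges

logger = logging.getLogger(__name__)

#: interpretation bands for ICC values (lower-edge inclusive)
ICC_BANDS = (("poor", -np.inf, 0.4), ("fair", 0.4, 0.6),
             ("good", 0.6, 0.75), ("excellent", 0.75, np.inf))


@dataclass
class ICCSubsampleConfig:
    """Repeated random subsampling used to stabilize edgewise ICC estimates."""

    n_iter: int = 100
    fraction: float = 0.8
    seed: int = 0

    def validate(self, n_subjects: int) -> int:
        if not 0 < self.fraction <= 1:
            raise FPConnError(f"fraction must be in (0, 1], got {self.fraction}")
        n_sub = int(np.floor(self.fraction * n_subjects))
        if n_sub < 3:
            raise FPConnError(
                f"subsample of {n_sub} subjects (< 3) from {n_subjects}"
            )
        return n_sub


@dataclass
class ICCMatrix:
    """R x R symmetric matrix of edgewise ICC(1,1); diagonal stored as NaN."""

    values: np.ndarray
    n_subjects_used: int
    subsample_config: ICCSubsampleConfig | None = None

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def edge_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


@dataclass
class NetworkICCProfile:
    network_means: dict[str, float]
    whole_brain_mean: float
    ranking: tuple[str, ...]


@dataclass
class ConcordanceResult:
    w: float
    p_value: float
    n_perm: int
    seed: int


def icc_1_1(test: np.ndarray, retest: np.ndarray) -> np.ndarray:
    """Vectorized ICC(1,1) per column of two (subjects x edges) arrays.

    Edges where all 2N values are identical have an undefined ICC and are
    returned as NaN.
    """
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    if test.shape != retest.shape:
        raise FPConnError("test and retest arrays must share shape")
    n = test.shape[0]
    if n < 3:
        raise FPConnError(f"need >= 3 subjects for ICC, got {n}")
    k = 2
    subj_mean = (test + retest) / k
    grand = subj_mean.mean(axis=0)
    ss_b = k * np.sum((subj_mean - grand) ** 2, axis=0)
    ss_w = np.sum((test - subj_mean) ** 2 + (retest - subj_mean) ** 2, axis=0)
    ms_b = ss_b / (n - 1)
    ms_w = ss_w / (n * (k - 1))
    denom = ms_b + (k - 1) * ms_w
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, (ms_b - ms_w) / denom, np.nan)
    n_deg = int(np.sum(denom <= 0))
    if n_deg:
        logger.info("ICC undefined (all values identical) at %d edge(s)", n_deg)
    return icc


def _to_matrix(edge_icc: np.ndarray, n_regions: int) -> np.ndarray:
    mat = devectorize_fc(edge_icc, n_regions, diagonal=np.nan)
    return mat


def compute_edgewise_icc(test_vectors: Mapping[str, np.ndarray],
                         retest_vectors: Mapping[str, np.ndarray],
                         n_regions: int | None = None) -> ICCMatrix:
    """Full-sample edgewise ICC(1,1) across the subjects of one group."""
    order = list(test_vectors.keys())
    t = np.vstack([test_vectors[s] for s in order])
    r = np.vstack([retest_vectors[s] for s in order])
    icc = icc_1_1(t, r)
    if n_regions is None:
        n_regions = _infer_n_regions(icc.size)
    return ICCMatrix(_to_matrix(icc, n_regions), n_subjects_used=len(order))


def _infer_n_regions(n_edge: int) -> int:
    r = int(round((1 + np.sqrt(1 + 8 * n_edge)) / 2))
    if n_edges(r) != n_edge:
        raise FPConnError(f"{n_edge} is not a valid edge count R(R-1)/2")
    return r


def subsampled_icc(test_vectors: Mapping[str, np.ndarray],
                   retest_vectors: Mapping[str, np.ndarray],
                   cfg: ICCSubsampleConfig,
                   n_regions: int | None = None) -> ICCMatrix:
    """Mean edgewise ICC over repeated random subject subsamples.

    Each iteration draws ``floor(fraction * N)`` subjects without replacement
    and recomputes the full edgewise ICC; the iteration maps are averaged.
    """
    order = list(test_vectors.keys())
    t = np.vstack([test_vectors[s] for s in order])
    r = np.vstack([retest_vectors[s] for s in order])
    n = len(order)
    n_sub = cfg.validate(n)
    rng = np.random.default_rng(cfg.seed)
    acc = np.zeros(t.shape[1])
    for _ in range(cfg.n_iter):
        idx = rng.choice(n, size=n_sub, replace=False)
        acc += icc_1_1(t[idx], r[idx])
    mean_icc = acc / cfg.n_iter
    if n_regions is None:
        n_regions = _infer_n_regions(mean_icc.size)
    return ICCMatrix(_to_matrix(mean_icc, n_regions), n_subjects_used=n_sub,
                     subsample_config=cfg)


def icc_band(value: float) -> str:
    """Map an ICC value to its conventional interpretation band."""
    for name, lo, hi in ICC_BANDS:
        if lo <= value < hi:
            return name
    return "poor"


def icc_nodal_strength(icc: ICCMatrix) -> pd.DataFrame:
    """Per-node sum of ICC over incident edges, with percentile ranks.

    NaN entries (diagonal and degenerate edges) are excluded from the sums.
    Nodes above the 75th percentile are flagged as high-reliability hubs.
    """
    from scipy.stats import rankdata

    strengths = np.nansum(icc.values, axis=1)
    pct = (rankdata(strengths) - 1) / (len(strengths) - 1) * 100
    return pd.DataFrame({
        "node": np.arange(icc.n_regions),
        "strength": strengths,
        "percentile": pct,
        "high": pct > 75.0,
    })


def network_membership(atlas: pd.DataFrame) -> dict[str, np.ndarray]:
    """Region indices per network, in atlas row order."""
    nets = {}
    for label in atlas["network"].unique():
        nets[str(label)] = np.flatnonzero((atlas["network"] == label).to_numpy())
    return nets


def network_icc_profile(icc: ICCMatrix, atlas: pd.DataFrame,
                        tie_order: Sequence[str] = NETWORK_LABELS,
                        ) -> NetworkICCProfile:
    """Within-network mean ICC per network plus the whole-brain mean.

    Within-network means average the upper-triangle edges of the network's
    diagonal block; the ranking orders networks by decreasing mean, ties
    broken by the fixed canonical network order.
    """
    members = network_membership(atlas)
    means: dict[str, float] = {}
    for label, idx in members.items():
        if idx.size < 2:
            raise FPConnError(f"network {label} has < 2 regions")
        block = icc.values[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        means[label] = float(np.nanmean(block[iu]))
    iu = np.triu_indices(icc.n_regions, k=1)
    wb = float(np.nanmean(icc.values[iu]))
    order = {lab: k for k, lab in enumerate(tie_order)}
    ranking = tuple(sorted(means, key=lambda lab: (-means[lab], order.get(lab, 99))))
    return NetworkICCProfile(means, wb, ranking)


def pairwise_concordance(rank_a: Sequence[str], rank_b: Sequence[str]) -> float:
    """Proportion of label pairs ordered the same way in both rankings."""
    if set(rank_a) != set(rank_b):
        raise FPConnError("rankings must contain the same labels")
    labels = list(rank_a)
    pos_a = {lab: k for k, lab in enumerate(rank_a)}
    pos_b = {lab: k for k, lab in enumerate(rank_b)}
    n = len(labels)
    same = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = np.sign(pos_a[labels[i]] - pos_a[labels[j]])
            b = np.sign(pos_b[labels[i]] - pos_b[labels[j]])
            same += int(a == b)
            total += 1
    return same / total


def ranking_concordance(rank_a: Sequence[str], rank_b: Sequence[str],
                        n_perm: int = 1000, seed: int = 0) -> ConcordanceResult:
    """Concordance of two network rankings with a shuffle null.

    The null shuffles the second ranking; the one-sided p-value is the
    plus-one-corrected proportion of shuffles at least as concordant as
    observed.
    """
    w_obs = pairwise_concordance(rank_a, rank_b)
    rng = np.random.default_rng(seed)
    labels_b = list(rank_b)
    count = 0
    for _ in range(n_perm):
        perm = list(rng.permutation(labels_b))
        if pairwise_concordance(rank_a, perm) >= w_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return ConcordanceResult(w=w_obs, p_value=float(p), n_perm=n_perm, seed=seed)
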