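"""Connectome identifiability: the fingerprint matrix and its summary metrics.

The identifiability matrix ``M`` holds, for every ordered subject pair
``(s, i)``, the Pearson correlation between subject ``s``'s test-half FC
vector and subject ``i``'s retest-half FC vector.  Its diagonal measures
self-similarity (I_self), its off-diagonal similarity to others (I_others);
the gap between the two summarizes how individually distinctive ("identifiable")
connectomes are in a group:

* ``I_diff``       = mean(I_self) - mean(I_others)
* ``I_diff_norm``  = (mu_within - mu_between) / pooled SD, a scale-free
  effect size computed over the N diagonal and N^2 - N off-diagonal entries
* ``SR``           = percentage of subjects whose self-match beats every one
  of their cross-matches (success rate of identification)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .connectome import FPConnError


@dataclass
class IdentifiabilityMatrix:
    """N x N matrix of test-vs-retest FC-vector correlations."""

    m: np.ndarray
    subject_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.subject_order = tuple(self.subject_order)
        n = len(self.subject_order)
        if self.m.shape != (n, n):
            raise FPConnError(
                f"identifiability matrix shape {self.m.shape} does not match "
                f"{n} subjects"
            )

    @property
    def n_subjects(self) -> int:
        return self.m.shape[0]


@dataclass
class IdentifiabilityMetrics:
    i_self: np.ndarray
    i_others: np.ndarray
    i_diff: float
    i_diff_norm: float
    sr: float
    subject_order: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "i_self_mean": float(self.i_self.mean()),
            "i_self_sd": float(self.i_self.std(ddof=1)),
            "i_others_mean": float(self.i_others.mean()),
            "i_others_sd": float(self.i_others.std(ddof=1)),
            "i_diff": self.i_diff,
            "i_diff_norm": self.i_diff_norm,
            "sr": self.sr,
        }


@dataclass
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_iter: int
    seed: int
    paired: bool
    distribution: np.ndarray = field(repr=False, default=None)


def build_identifiability_matrix(test_vectors: Mapping[str, np.ndarray],
                                 retest_vectors: Mapping[str, np.ndarray],
                                 ) -> IdentifiabilityMatrix:
    """Correlate every subject's test FC vector with every retest FC vector."""
    order = tuple(test_vectors.keys())
    if set(order) != set(retest_vectors.keys()):
        raise FPConnError("test and retest vector sets name different subjects")
    t = np.vstack([test_vectors[s] for s in order])
    r = np.vstack([retest_vectors[s] for s in order])
    if t.shape[1] != r.shape[1]:
        raise FPConnError("test and retest edge counts differ")
    for label, mat in (("test", t), ("retest", r)):
        sd = mat.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise FPConnError(
                f"zero-variance {label} FC vector for subject {order[bad[0]]}"
            )
    tz = (t - t.mean(axis=1, keepdims=True)) / t.std(axis=1, keepdims=True)
    rz = (r - r.mean(axis=1, keepdims=True)) / r.std(axis=1, keepdims=True)
    m = (tz @ rz.T) / t.shape[1]
    return IdentifiabilityMatrix(np.clip(m, -1.0, 1.0), order)


def _within_between(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = m.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return np.diag(m).copy(), m[mask]


def _idiff_norm(m: np.ndarray) -> float:
    within, between = _within_between(m)
    nw, nb = within.size, between.size
    vw = within.var(ddof=1)
    vb = between.var(ddof=1)
    pooled = np.sqrt(((nw - 1) * vw + (nb - 1) * vb) / (nw + nb - 2))
    if pooled == 0:
        raise FPConnError("degenerate identifiability distribution (zero pooled SD)")
    return float((within.mean() - between.mean()) / pooled)


def success_rate(m: np.ndarray, mode: str = "row_and_column") -> float:
    """Percentage of subjects whose I_self strictly beats all cross-matches.

    ``row_and_column`` (default) requires the diagonal entry to exceed every
    off-diagonal entry in both the subject's row and column; ``row_only``
    checks the row only.  Ties count as identification failures.
    """
    n = m.shape[0]
    hits = 0
    for s in range(n):
        row = np.delete(m[s, :], s)
        col = np.delete(m[:, s], s)
        others = row if mode == "row_only" else np.concatenate([row, col])
        if m[s, s] > others.max():
            hits += 1
    return 100.0 * hits / n


def compute_identifiability_metrics(matrix: IdentifiabilityMatrix,
                                    sr_mode: str = "row_and_column",
                                    ) -> IdentifiabilityMetrics:
    """I_self, I_others, I_diff, I_diff_norm and SR from one matrix."""
    m = matrix.m
    n = m.shape[0]
    if n < 2:
        raise FPConnError("need at least 2 subjects for identifiability metrics")
    i_self = np.diag(m).copy()
    offrow = m.sum(axis=1) - i_self
    offcol = m.sum(axis=0) - i_self
    i_others = (offrow + offcol) / (2 * n - 2)
    i_diff = float(i_self.mean() - i_others.mean())
    return IdentifiabilityMetrics(
        i_self=i_self,
        i_others=i_others,
        i_diff=i_diff,
        i_diff_norm=_idiff_norm(m),
        sr=success_rate(m, sr_mode),
        subject_order=matrix.subject_order,
    )


def bootstrap_idiff_norm(m_a: IdentifiabilityMatrix,
                         m_b: IdentifiabilityMatrix | None = None,
                         paired: bool = False,
                         n_iter: int = 1000,
                         seed: int = 0,
                         resample_mode: str = "with_replacement",
                         ) -> BootstrapResult:
    """Bootstrap inference for I_diff_norm.

    With one matrix the statistic is its I_diff_norm; with two matrices it is
    the difference ``I_diff_norm(a) - I_diff_norm(b)``.  Each iteration
    resamples subject indices (with replacement by default) and recomputes
    the statistic on the induced submatrix; in paired mode the identical
    index draw is applied to both matrices (e.g. residualized vs raw data of
    the same subjects).  The two-tailed p-value tests a zero statistic using
    the mean-centered bootstrap distribution as the null.
    """
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} < 100: bootstrap p-values are coarse")
    if paired and m_b is not None and m_a.subject_order != m_b.subject_order:
        raise FPConnError("paired bootstrap requires identical subject orders")

    def stat(ma: np.ndarray, mb: np.ndarray | None) -> float:
        if mb is None:
            return _idiff_norm(ma)
        return _idiff_norm(ma) - _idiff_norm(mb)

    a = m_a.m
    b = m_b.m if m_b is not None else None
    observed = stat(a, b)
    rng = np.random.default_rng(seed)
    na = a.shape[0]
    nb = b.shape[0] if b is not None else 0
    draws = np.empty(n_iter)
    replace = resample_mode == "with_replacement"
    for k in range(n_iter):
        idx_a = rng.choice(na, size=na, replace=replace)
        sub_a = a[np.ix_(idx_a, idx_a)]
        if b is None:
            sub_b = None
        elif paired:
            sub_b = b[np.ix_(idx_a, idx_a)]
        else:
            idx_b = rng.choice(nb, size=nb, replace=replace)
            sub_b = b[np.ix_(idx_b, idx_b)]
        try:
            draws[k] = stat(sub_a, sub_b)
        except FPConnError:
            draws[k] = observed  # degenerate resample; neutral draw
    centered = np.abs(draws - draws.mean())
    p = (1 + int(np.sum(centered >= abs(observed)))) / (n_iter + 1)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return BootstrapResult(
        estimate=float(observed), ci_low=float(lo), ci_high=float(hi),
        p_value=float(p), n_iter=n_iter, seed=seed, paired=paired,
        distribution=draws,
    )
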