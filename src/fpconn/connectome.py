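"""Split-half functional connectomes, edge vectorization, and covariate residualization.

A subject's parcellated BOLD time series (time x region) is split into two
halves ("test" and "retest"); each half yields a region-by-region Pearson
correlation matrix (the functional connectome, FC).  Connectomes are
vectorized to their upper triangle and, optionally, residualized edge-by-edge
against demographic/clinical covariates before any fingerprinting analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

NETWORK_LABELS = ("VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN")

COVARIATE_COLUMNS = ("age", "sex", "education", "disease_duration", "onset_age")


class FPConnError(ValueError):
    """Base error for invalid inputs anywhere in the pipeline."""


@dataclass
class ParcellatedTimeSeries:
    """One subject's time x region signal matrix.

    ``group`` is ``"control"`` or ``"patient"``; ``region_ids`` gives the
    column order and must match the atlas.
    """

    subject_id: str
    group: str
    data: np.ndarray
    region_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FPConnError(f"{self.subject_id}: time series must be 2-D")
        if self.data.shape[1] != len(self.region_ids):
            raise FPConnError(
                f"{self.subject_id}: {self.data.shape[1]} columns but "
                f"{len(self.region_ids)} region ids"
            )
        if not np.all(np.isfinite(self.data)):
            raise FPConnError(f"{self.subject_id}: non-finite values in time series")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectomePair:
    """Test/retest FC matrices from the two halves of one scan."""

    subject_id: str
    fc_test: np.ndarray
    fc_retest: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.fc_test.shape[0]


@lru_cache(maxsize=32)
def edge_index(n_regions: int) -> tuple[tuple[int, int], ...]:
    """Ordered (i, j) region pairs of the row-major upper triangle (i < j).

    Cached so every stage of the pipeline shares the identical pair list.
    """
    iu, ju = np.triu_indices(n_regions, k=1)
    return tuple(zip(iu.tolist(), ju.tolist()))


def n_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def _pearson_matrix(block: np.ndarray, subject_id: str, half: str,
                    region_ids: Sequence[str]) -> np.ndarray:
    sd = block.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(str(region_ids[b]) for b in bad[:5])
        raise FPConnError(
            f"{subject_id}: region(s) {names} constant in {half} half; "
            "Pearson correlation undefined"
        )
    fc = np.corrcoef(block, rowvar=False)
    np.fill_diagonal(fc, 1.0)
    return np.clip(fc, -1.0, 1.0)


def split_point(n_timepoints: int) -> int:
    """First half gets floor(T/2) samples; the retest half gets the rest."""
    return n_timepoints // 2


def compute_split_fc(ts: ParcellatedTimeSeries) -> ConnectomePair:
    """Split the scan in half and compute one Pearson FC matrix per half."""
    t = ts.n_timepoints
    if t < 4:
        raise FPConnError(f"{ts.subject_id}: need >= 4 time points, got {t}")
    cut = split_point(t)
    fc_test = _pearson_matrix(ts.data[:cut], ts.subject_id, "test", ts.region_ids)
    fc_retest = _pearson_matrix(ts.data[cut:], ts.subject_id, "retest", ts.region_ids)
    return ConnectomePair(ts.subject_id, fc_test, fc_retest)


def vectorize_fc(fc: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Upper-triangle (i < j, row-major) edge vector of a symmetric matrix."""
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise FPConnError("FC matrix must be square")
    if not np.allclose(fc, fc.T, atol=atol):
        raise FPConnError(f"FC matrix asymmetric beyond tolerance {atol}")
    iu = np.triu_indices(fc.shape[0], k=1)
    return fc[iu].copy()


def devectorize_fc(values: np.ndarray, n_regions: int,
                   diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_fc`; the diagonal is filled with ``diagonal``."""
    values = np.asarray(values, dtype=float)
    if values.size != n_edges(n_regions):
        raise FPConnError(
            f"expected {n_edges(n_regions)} edges for R={n_regions}, got {values.size}"
        )
    fc = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    fc[iu] = values
    fc += fc.T
    np.fill_diagonal(fc, diagonal)
    return fc


def build_covariate_design(covariates: pd.DataFrame,
                           subject_ids: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate design matrix for the given subjects.

    Constant columns (e.g. disease duration zero-filled for controls) are
    dropped before fitting.  Returns the design and the retained column names
    (the leading intercept is implicit).
    """
    tab = covariates.set_index("subject_id").loc[list(subject_ids)]
    cols = [c for c in COVARIATE_COLUMNS if c in tab.columns]
    x = tab[cols].to_numpy(dtype=float)
    keep = [k for k in range(x.shape[1]) if np.ptp(x[:, k]) > 0]
    kept_names = [cols[k] for k in keep]
    design = np.column_stack([np.ones(len(subject_ids)), x[:, keep]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise FPConnError(
            "rank-deficient covariate design after dropping constant columns; "
            f"check collinearity among {kept_names}"
        )
    return design, kept_names


def residualize_edges(edge_vectors: Mapping[str, np.ndarray],
                      covariates: pd.DataFrame) -> dict[str, np.ndarray]:
    """Remove covariate effects from every edge by per-edge OLS.

    ``edge_vectors`` maps subject id -> edge vector for one group and one
    half (test or retest).  Each edge is regressed on intercept + covariates
    across the subjects of the group and replaced by its residual, so
    residuals are zero-mean at every edge.
    """
    ids = list(edge_vectors.keys())
    y = np.vstack([edge_vectors[s] for s in ids])
    design, _ = build_covariate_design(covariates, ids)
    if len(ids) < design.shape[1] + 2:
        raise FPConnError(
            f"need at least {design.shape[1] + 2} subjects for "
            f"{design.shape[1] - 1} covariates, got {len(ids)}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return {s: resid[k] for k, s in enumerate(ids)}
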