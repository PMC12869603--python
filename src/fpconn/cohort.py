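"""Synthetic cohorts of parcellated BOLD time series with planted structure.

Each subject's signal is drawn as multivariate normal with a covariance
assembled from interpretable components (all with unit per-region variance
before weighting):

* a group-common factor covariance (shared network structure),
* a subject-unique factor covariance -- the "fingerprint" -- reused across
  the two scan halves so split-half FC is individually stable,
* per-block low-spectral-norm perturbations confined to chosen
  network-pair blocks; for one designated group the perturbation is partly
  regenerated between halves, lowering test-retest reliability of exactly
  those edges while leaving marginal variances (hence mean FC) unchanged,
* optional linear covariate shifts on a sparse edge subset,
* isotropic noise that also absorbs the spectral budget of the hollow
  perturbations, keeping every covariance positive definite.

Clinical outcomes couple a planted-subnetwork connectivity score to the
probability of clinically meaningful motor improvement, so the downstream
responder classification has a controllable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectome import (COVARIATE_COLUMNS, NETWORK_LABELS, FPConnError,
                         ParcellatedTimeSeries, n_edges, split_point)

DIRECTIONS = ("control_gt_patient", "patient_gt_control")

#: spectral-norm safety factors relating block strength c to sigma_max of the
#: (possibly mixed) hollow perturbation
_KAPPA_BETWEEN = 1.6
_KAPPA_WITHIN = 2.5


@dataclass(frozen=True)
class StabilityBlock:
    """A network-pair block where one group's fingerprint is less stable.

    ``direction='control_gt_patient'`` attenuates the patient group (controls
    end up more reliable there); ``magnitude`` in [0, 1] is the fraction of
    the block component regenerated between scan halves.
    """

    network_i: str
    network_j: str
    direction: str
    magnitude: float


@dataclass
class CohortConfig:
    n_per_group: int = 23
    n_regions: int = 100
    n_timepoints: int = 400
    network_sizes: tuple[int, ...] = (15, 15, 14, 14, 14, 14, 14)
    fingerprint_share: float = 0.5
    group_share: float = 0.1
    noise_sd: float = 1.0
    signature_rank: int = 30
    group_rank: int = 10
    stability_diff_blocks: tuple[StabilityBlock, ...] = (
        StabilityBlock("DMN", "DMN", "control_gt_patient", 0.8),
        StabilityBlock("VN", "DMN", "patient_gt_control", 0.8),
    )
    block_strength: float | None = None
    covariate_effects: dict[str, float] = field(default_factory=dict)
    covariate_edge_fraction: float = 0.01
    outcome_coupling: float = 2.0
    responder_fraction: float = 13 / 23
    seed: int = 0

    def __post_init__(self) -> None:
        self.stability_diff_blocks = tuple(
            b if isinstance(b, StabilityBlock) else StabilityBlock(*b)
            for b in self.stability_diff_blocks
        )
        self.network_sizes = tuple(int(s) for s in self.network_sizes)
        self.validate()

    def validate(self) -> None:
        if sum(self.network_sizes) != self.n_regions:
            raise FPConnError(
                f"network_sizes sum {sum(self.network_sizes)} != "
                f"n_regions {self.n_regions}"
            )
        if len(self.network_sizes) != len(NETWORK_LABELS):
            raise FPConnError(
                f"expected {len(NETWORK_LABELS)} networks, got "
                f"{len(self.network_sizes)}"
            )
        for name in ("fingerprint_share", "group_share"):
            if getattr(self, name) < 0:
                raise FPConnError(f"{name} must be >= 0")
        if self.fingerprint_share + self.group_share > 1:
            raise FPConnError("fingerprint_share + group_share must be <= 1")
        if self.n_timepoints < 4:
            raise FPConnError("n_timepoints must be >= 4 (two halves of >= 2)")
        if not 0 < self.responder_fraction < 1:
            raise FPConnError("responder_fraction must be in (0, 1)")
        if self.noise_sd <= 0:
            raise FPConnError("noise_sd must be > 0")
        for b in self.stability_diff_blocks:
            if b.direction not in DIRECTIONS:
                raise FPConnError(f"unknown block direction {b.direction!r}")
            if not 0 <= b.magnitude <= 1:
                raise FPConnError("block magnitude must be in [0, 1]")
            for lab in (b.network_i, b.network_j):
                if lab not in NETWORK_LABELS:
                    raise FPConnError(f"unknown network label {lab!r}")
        if not 0 <= self.covariate_edge_fraction <= 1:
            raise FPConnError("covariate_edge_fraction must be in [0, 1]")
        # spectral budget of the hollow perturbations vs the noise floor
        if self.noise_variance() <= 0 and (self.stability_diff_blocks
                                           or self.covariate_effects):
            raise FPConnError(
                "no noise budget left for block/covariate perturbations "
                "(fingerprint_share + group_share = 1)"
            )

    def noise_variance(self) -> float:
        return self.noise_sd**2 * (1 - self.fingerprint_share - self.group_share)

    def block_strengths(self) -> list[float]:
        """Per-block strength c; auto-allocated from 60% of the noise floor."""
        n_b = len(self.stability_diff_blocks)
        if n_b == 0:
            return []
        kappas = [
            _KAPPA_WITHIN if b.network_i == b.network_j else _KAPPA_BETWEEN
            for b in self.stability_diff_blocks
        ]
        if self.block_strength is not None:
            cs = [self.block_strength] * n_b
        else:
            budget = 0.6 * self.noise_variance()
            cs = [budget / n_b / k for k in kappas]
        spent = sum(c * k for c, k in zip(cs, kappas))
        if spent > self.noise_variance() + 1e-12:
            raise FPConnError(
                f"block strengths need spectral budget {spent:.3f} but only "
                f"{self.noise_variance():.3f} noise variance is available"
            )
        return cs

    def as_dict(self) -> dict:
        d = asdict(self)
        d["stability_diff_blocks"] = [asdict(b)
                                      for b in self.stability_diff_blocks]
        return d


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort."""

    true_differential_edges: dict[str, np.ndarray]
    subject_signatures: dict[str, np.ndarray]
    covariate_betas: dict[str, np.ndarray]
    true_labels: dict[str, bool] | None = None


def make_atlas(config: CohortConfig) -> pd.DataFrame:
    rows = []
    r = 0
    for label, size in zip(NETWORK_LABELS, config.network_sizes):
        for k in range(size):
            rows.append({"region_id": f"R{r:03d}",
                         "region_name": f"{label}_{k + 1}",
                         "network": label})
            r += 1
    return pd.DataFrame(rows)


def _unit_row_loadings(rng: np.random.Generator, n: int, rank: int) -> np.ndarray:
    load = rng.standard_normal((n, rank))
    norms = np.linalg.norm(load, axis=1, keepdims=True)
    return load / norms


def _partial_isometry(rng: np.random.Generator, na: int, nb: int) -> np.ndarray:
    """Random na x nb matrix with orthonormal rows (spectral norm 1).

    When the larger dimension is a power of two a randomized Hadamard design
    is used, whose entries all share the magnitude 1/sqrt(max(na, nb)); the
    planted edge effects are then homogeneous across the block.  Otherwise a
    Gaussian partial isometry (SVD-orthogonalized) is drawn.
    """
    if na > nb:
        return _partial_isometry(rng, nb, na).T
    m = nb
    if m >= 2 and (m & (m - 1)) == 0:
        from scipy.linalg import hadamard

        h = hadamard(m) / np.sqrt(m)
        h = h[rng.permutation(m)][:, rng.permutation(m)]
        h = h * rng.choice([-1.0, 1.0], size=(m, 1))
        h = h * rng.choice([-1.0, 1.0], size=(1, m))
        return h[:na]
    g = rng.standard_normal((na, nb))
    u, _, vt = np.linalg.svd(g, full_matrices=False)
    return u @ vt


def _block_matrices(rng: np.random.Generator, b: StabilityBlock, c: float,
                    idx_a: np.ndarray, idx_b: np.ndarray, n_regions: int,
                    attenuate: bool) -> tuple[np.ndarray, np.ndarray]:
    """Hollow R x R perturbations for the two halves of one subject."""
    within = b.network_i == b.network_j
    m = b.magnitude if attenuate else 0.0
    if within:
        w1 = _partial_isometry(rng, idx_a.size, idx_a.size)
        wf = _partial_isometry(rng, idx_a.size, idx_a.size)
    else:
        w1 = _partial_isometry(rng, idx_a.size, idx_b.size)
        wf = _partial_isometry(rng, idx_a.size, idx_b.size)
    w2 = np.sqrt(1 - m) * w1 + np.sqrt(m) * wf
    out = []
    for w in (w1, w2):
        delta = np.zeros((n_regions, n_regions))
        if within:
            s = (w + w.T) / np.sqrt(2)
            np.fill_diagonal(s, 0.0)
            delta[np.ix_(idx_a, idx_a)] = c * s
        else:
            delta[np.ix_(idx_a, idx_b)] = c * w
            delta[np.ix_(idx_b, idx_a)] = c * w.T
        out.append(delta)
    return out[0], out[1]


def _block_edge_mask(idx_a: np.ndarray, idx_b: np.ndarray,
                     n_regions: int) -> np.ndarray:
    mat = np.zeros((n_regions, n_regions), dtype=bool)
    mat[np.ix_(idx_a, idx_b)] = True
    mat[np.ix_(idx_b, idx_a)] = True
    iu = np.triu_indices(n_regions, k=1)
    return mat[iu]


def _sample_covariates(rng: np.random.Generator,
                       config: CohortConfig) -> pd.DataFrame:
    """Demographics emulating an elderly PD cohort with matched controls."""
    rows = []
    for group, prefix, age_mu, age_sd, p_male in (
            ("control", "con", 64.0, 10.5, 0.304),
            ("patient", "pat", 68.5, 5.9, 0.348)):
        for k in range(config.n_per_group):
            age = float(np.clip(rng.normal(age_mu, age_sd), 40, 90))
            sex = int(rng.random() < p_male)
            edu = float(np.clip(rng.normal(16, 2.5), 8, 24))
            if group == "patient":
                dur = float(rng.uniform(2, 12))
                # reported onset age is not exactly age - duration (recall
                # imprecision); the jitter also keeps the design full rank
                onset = age - dur + float(rng.normal(0, 0.6))
            else:
                dur = 0.0
                onset = 0.0
            rows.append({"subject_id": f"{prefix}{k + 1:02d}", "group": group,
                         "age": round(age, 1), "sex": sex,
                         "education": round(edu, 1),
                         "disease_duration": round(dur, 1),
                         "onset_age": round(onset, 1)})
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig,
                    ) -> tuple[list[ParcellatedTimeSeries], pd.DataFrame,
                               pd.DataFrame, GroundTruth]:
    """Draw a two-group cohort of parcellated time series.

    Returns the time series (controls then patients), the atlas table, the
    covariate table, and the planted ground truth.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    r = config.n_regions
    atlas = make_atlas(config)
    members = {lab: np.flatnonzero((atlas["network"] == lab).to_numpy())
               for lab in NETWORK_LABELS}
    covariates = _sample_covariates(rng, config)
    subject_ids = covariates["subject_id"].tolist()
    groups = covariates["group"].tolist()

    fs, gs = config.fingerprint_share, config.group_share
    noise_var = config.noise_variance()
    cs = config.block_strengths()

    sigma_group = {
        g: _unit_row_loadings(rng, r, config.group_rank) for g in
        ("control", "patient")
    }
    sigma_group = {g: load @ load.T for g, load in sigma_group.items()}

    # sparse signed covariate effects on edges (same edges for every subject)
    e_total = n_edges(r)
    covariate_betas: dict[str, np.ndarray] = {}
    cov_z: dict[str, np.ndarray] = {}
    for name, beta in config.covariate_effects.items():
        if name not in COVARIATE_COLUMNS:
            raise FPConnError(f"unknown covariate {name!r} in covariate_effects")
        n_aff = int(round(config.covariate_edge_fraction * e_total))
        edges = rng.choice(e_total, size=n_aff, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_aff)
        vec = np.zeros(e_total)
        vec[edges] = beta * signs
        covariate_betas[name] = vec
        vals = covariates[name].to_numpy(dtype=float)
        sd = vals.std()
        cov_z[name] = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)

    iu = np.triu_indices(r, k=1)

    def cov_effect_matrix(s_idx: int) -> np.ndarray | None:
        if not covariate_betas:
            return None
        vec = np.zeros(e_total)
        for name, betas in covariate_betas.items():
            vec = vec + betas * cov_z[name][s_idx]
        mat = np.zeros((r, r))
        mat[iu] = vec
        return mat + mat.T

    true_edges = {d: np.zeros(e_total, dtype=bool) for d in DIRECTIONS}
    for b in config.stability_diff_blocks:
        mask = _block_edge_mask(members[b.network_i], members[b.network_j], r)
        true_edges[b.direction] |= mask

    cut = split_point(config.n_timepoints)
    timeseries: list[ParcellatedTimeSeries] = []
    signatures: dict[str, np.ndarray] = {}
    region_ids = atlas["region_id"].tolist()

    for s_idx, (sid, group) in enumerate(zip(subject_ids, groups)):
        load = _unit_row_loadings(rng, r, config.signature_rank)
        signatures[sid] = load
        base = fs * (load @ load.T) + gs * sigma_group[group]
        cov_mat = cov_effect_matrix(s_idx)
        deltas: list[tuple[np.ndarray, np.ndarray]] = []
        for b, c in zip(config.stability_diff_blocks, cs):
            attenuated_group = ("patient" if b.direction == "control_gt_patient"
                                else "control")
            deltas.append(_block_matrices(
                rng, b, c, members[b.network_i], members[b.network_j], r,
                attenuate=(group == attenuated_group)))
        halves = []
        for h, t_len in enumerate((cut, config.n_timepoints - cut)):
            sigma = base + noise_var * np.eye(r)
            for d1, d2 in deltas:
                sigma = sigma + (d1 if h == 0 else d2)
            if cov_mat is not None:
                sigma = sigma + cov_mat
            try:
                chol = np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError as exc:
                raise FPConnError(
                    "covariance not positive definite; reduce block_strength "
                    "or covariate_effects relative to the noise budget"
                ) from exc
            z = rng.standard_normal((t_len, r))
            halves.append(z @ chol.T)
        data = np.vstack(halves)
        timeseries.append(ParcellatedTimeSeries(sid, group, data, region_ids))

    truth = GroundTruth(true_differential_edges=true_edges,
                        subject_signatures=signatures,
                        covariate_betas=covariate_betas)
    return timeseries, atlas, covariates, truth


def planted_subnetwork_scores(timeseries: Sequence[ParcellatedTimeSeries],
                              truth: GroundTruth,
                              direction: str = "control_gt_patient",
                              group: str = "patient") -> dict[str, float]:
    """Mean |full-series FC| over the planted differential edges, per subject.

    This is the connectivity score of the planted discriminative subnetwork;
    the clinical-outcome generator couples responder probability to it.
    """
    edges = truth.true_differential_edges.get(direction)
    if edges is None or not edges.any():
        raise FPConnError(f"no planted edges in direction {direction!r}")
    scores = {}
    for ts in timeseries:
        if ts.group != group:
            continue
        fc = np.corrcoef(ts.data, rowvar=False)
        vec = fc[np.triu_indices(ts.n_regions, k=1)]
        scores[ts.subject_id] = float(np.abs(vec[edges]).mean())
    return scores


def generate_clinical_outcomes(scores: Mapping[str, float],
                               config: CohortConfig,
                               seed: int | None = None,
                               truth: GroundTruth | None = None) -> pd.DataFrame:
    """UPDRS-III baseline/follow-up scores with a planted responder mechanism.

    ``scores`` maps each patient to their planted-subnetwork connectivity
    score.  Baseline severity is drawn around the typical moderate-stage
    motor score (mean 37.8, SD 11.7); the probability of a >= 15% relative
    improvement increases with the subnetwork score when
    ``outcome_coupling > 0`` and is independent of it at 0.  The realized
    responder count equals ``round(responder_fraction * n)``.
    """
    if not scores:
        raise FPConnError("no patient features supplied for outcome generation")
    ids = list(scores.keys())
    n = len(ids)
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    vals = np.array([scores[s] for s in ids], dtype=float)
    sd = vals.std()
    z = (vals - vals.mean()) / sd if sd > 0 else np.zeros(n)
    latent = config.outcome_coupling * z + rng.standard_normal(n)
    n_resp = int(round(config.responder_fraction * n))
    n_resp = min(max(n_resp, 1), n - 1)
    responder_idx = np.argsort(-latent, kind="stable")[:n_resp]
    responder = np.zeros(n, dtype=bool)
    responder[responder_idx] = True
    baseline = np.clip(rng.normal(37.8, 11.7, size=n), 10, 80)
    # margins around the 15% boundary keep labels invariant to 0.1 rounding
    delta = np.where(responder, rng.uniform(16.5, 45, size=n),
                     rng.uniform(-10, 13.5, size=n))
    followup = baseline * (1 - delta / 100.0)
    if truth is not None:
        truth.true_labels = {s: bool(f) for s, f in zip(ids, responder)}
    return pd.DataFrame({
        "subject_id": ids,
        "updrs_bl": np.round(baseline, 1),
        "updrs_fu": np.round(followup, 1),
    })
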