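"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import fpconn as fp
from fpconn import connectome as conn
from fpconn.pipeline import _vector_sets


def split_vectors(timeseries, covariates=None, scope=None):
    """Per-group test/retest edge vectors, optionally residualized.

    ``scope='per_group'`` fits covariate regressions within each group,
    ``scope='pooled'`` across the whole cohort, ``None`` skips
    residualization.
    """
    groups = {t.subject_id: t.group for t in timeseries}
    pairs = [fp.compute_split_fc(t) for t in timeseries]
    vecs = _vector_sets(pairs, groups)
    if scope is None:
        return vecs
    out = {}
    if scope == "pooled":
        pooled = {h: conn.residualize_edges(
            {**vecs["control"][h], **vecs["patient"][h]}, covariates)
            for h in ("test", "retest")}
        for g in vecs:
            out[g] = {h: {s: pooled[h][s] for s in vecs[g][h]}
                      for h in ("test", "retest")}
    else:
        for g in vecs:
            cov_g = covariates[covariates["group"] == g]
            out[g] = {h: conn.residualize_edges(vecs[g][h], cov_g)
                      for h in ("test", "retest")}
    return out


@pytest.fixture(scope="session")
def powered_cohort():
    """Cohort with one strongly planted stability-difference block.

    Sized so the planted edges are recoverable through the permutation/FDR
    machinery: uniform-magnitude (Hadamard) block effects, full regeneration
    of the patient block component between halves, 40 subjects per group.
    """
    cfg = fp.CohortConfig(
        n_per_group=40, n_regions=26, n_timepoints=800,
        network_sizes=(8, 8, 2, 2, 2, 2, 2),
        fingerprint_share=0.1, group_share=0.0, signature_rank=10,
        stability_diff_blocks=(
            fp.StabilityBlock("VN", "SMN", "control_gt_patient", 1.0),),
        block_strength=0.5, outcome_coupling=0.0, seed=11)
    ts, atlas, cov, truth = fp.generate_cohort(cfg)
    vecs = split_vectors(ts, cov, scope="per_group")
    return {"config": cfg, "timeseries": ts, "atlas": atlas,
            "covariates": cov, "truth": truth, "vectors": vecs}


@pytest.fixture(scope="session")
def powered_analysis(powered_cohort):
    """Permutation test + directional masks on the powered cohort."""
    from fpconn import differential as diff

    vecs = powered_cohort["vectors"]
    cfg = diff.PermutationConfig(n_perm=5000, seed=3, alpha=0.01,
                                 subsample=None)
    perm = diff.permutation_test_icc_diff(
        vecs["control"]["test"], vecs["control"]["retest"],
        vecs["patient"]["test"], vecs["patient"]["retest"], cfg)
    icc_c = fp.compute_edgewise_icc(vecs["control"]["test"],
                                    vecs["control"]["retest"])
    icc_p = fp.compute_edgewise_icc(vecs["patient"]["test"],
                                    vecs["patient"]["retest"])
    dmat = fp.compute_icc_diff(icc_c, icc_p)
    mask_c, mask_p = fp.extract_edge_masks(dmat, perm)
    return {"perm": perm, "diff": dmat, "masks": (mask_c, mask_p)}


@pytest.fixture(scope="session")
def coupled_cohort():
    """23-patient cohort whose responder status is driven by the planted
    discriminative subnetwork (strong coupling)."""
    cfg = fp.CohortConfig(
        n_per_group=23, n_regions=30, n_timepoints=400,
        network_sizes=(8, 8, 4, 4, 2, 2, 2),
        fingerprint_share=0.1, group_share=0.0, signature_rank=10,
        stability_diff_blocks=(
            fp.StabilityBlock("VN", "SMN", "control_gt_patient", 1.0),
            fp.StabilityBlock("DAN", "VAN", "patient_gt_control", 1.0),),
        block_strength=0.27, outcome_coupling=4.0,
        responder_fraction=13 / 23, seed=21)
    ts, atlas, cov, truth = fp.generate_cohort(cfg)
    scores = fp.planted_subnetwork_scores(ts, truth)
    clinical = fp.generate_clinical_outcomes(scores, cfg, truth=truth)
    return {"config": cfg, "timeseries": ts, "atlas": atlas,
            "covariates": cov, "truth": truth, "clinical": clinical,
            "scores": scores}


@pytest.fixture(scope="session")
def coupled_features(coupled_cohort):
    """Topology features of the planted Controls>PD subnetwork, per patient."""
    from fpconn import topology as topo

    truth = coupled_cohort["truth"]
    cfg = coupled_cohort["config"]
    feats = {}
    for direction in ("control_gt_patient", "patient_gt_control"):
        mask = fp.EdgeMask("A_gt_B", truth.true_differential_edges[direction],
                           cfg.n_regions)
        rows = {}
        for ts in coupled_cohort["timeseries"]:
            if ts.group != "patient":
                continue
            fc = np.corrcoef(ts.data, rowvar=False)
            g = topo.apply_edge_mask(fc, mask)
            rows[ts.subject_id] = topo.compute_graph_features(g, seed=0).as_array()
        feats[direction] = pd.DataFrame.from_dict(
            rows, orient="index", columns=list(topo.FEATURE_NAMES))
    return feats
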