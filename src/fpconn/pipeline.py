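"""End-to-end orchestration: cohort -> connectomes -> fingerprints -> prediction.

Stages run in dependency order, every artifact is written as delimited text
or JSON under the output directory, and a run manifest records the exact
configuration plus a checksum per file, so a rerun with the same
configuration reproduces identical artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import cohort as coh
from . import connectome as conn
from . import differential as diff
from . import identifiability as ident
from . import io as fpio
from . import reliability as rel
from . import stats as gstats
from . import topology as topo
from .connectome import FPConnError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "connectomes", "identify", "icc", "diff", "features",
          "classify", "stats")


@dataclass
class PipelineConfig:
    """Normalized configuration of a full run.

    Exactly one of ``input_dir`` / ``simulate`` selects the cohort source.
    All stochastic stages draw their seeds deterministically from ``seed``.
    """

    output_dir: str = "fpconn_run"
    input_dir: str | None = None
    simulate: coh.CohortConfig | None = None
    stages_to_run: tuple[str, ...] = STAGES
    seed: int = 0
    residualize_scope: str = "per_group"
    subsample_n_iter: int = 100
    subsample_fraction: float = 0.8
    n_perm: int = 1000
    alpha: float = 0.01
    null_subsampling: bool = True
    bootstrap_n_iter: int = 1000
    threshold_percent: float = 15.0
    classifier_family: str = "random_forest"
    classifier_n_perm: int = 0
    mask_fallback_density: float = 0.2

    def stage_seed(self, stage: str) -> int:
        base = np.random.default_rng(self.seed)
        seeds = {s: int(v) for s, v in zip(STAGES, base.integers(2**31,
                                                                 size=len(STAGES)))}
        return seeds[stage]


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Parse and normalize a YAML pipeline configuration.

    Missing keys are defaulted; violations raise a single error listing
    every offending path.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    if not isinstance(raw, dict):
        raise FPConnError("pipeline config must be a mapping")
    errors: list[str] = []
    sim_cfg = None
    if raw.get("simulate") is not None:
        sim_raw = dict(raw["simulate"])
        if sim_raw.get("stability_diff_blocks") is not None:
            sim_raw["stability_diff_blocks"] = tuple(
                b if isinstance(b, coh.StabilityBlock)
                else coh.StabilityBlock(**b) if isinstance(b, dict)
                else coh.StabilityBlock(*b)
                for b in sim_raw["stability_diff_blocks"])
        if sim_raw.get("network_sizes") is not None:
            sim_raw["network_sizes"] = tuple(sim_raw["network_sizes"])
        try:
            sim_cfg = coh.CohortConfig(**sim_raw)
        except (TypeError, FPConnError) as exc:
            errors.append(f"simulate: {exc}")
    if raw.get("input_dir") and sim_cfg is not None:
        errors.append("exactly one of input_dir / simulate may be set")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    extra = set(raw) - known
    if extra:
        errors.append(f"unknown keys: {sorted(extra)}")
    kwargs = {k: v for k, v in raw.items() if k in known and k != "simulate"}
    if sim_cfg is not None:
        kwargs["simulate"] = sim_cfg
    if "stages_to_run" in kwargs:
        kwargs["stages_to_run"] = tuple(kwargs["stages_to_run"])
        bad = set(kwargs["stages_to_run"]) - set(STAGES)
        if bad:
            errors.append(f"stages_to_run: unknown stages {sorted(bad)}")
    cfg = None
    if not errors:
        cfg = PipelineConfig(**kwargs)
        if cfg.input_dir is None and cfg.simulate is None:
            cfg.simulate = coh.CohortConfig()
        if not 0 < cfg.subsample_fraction <= 1:
            errors.append("subsample.fraction must be in (0,1]")
        if not 0 < cfg.alpha < 1:
            errors.append("alpha must be in (0,1)")
    if errors:
        raise FPConnError("invalid pipeline config: " + "; ".join(errors))
    return cfg


def _vector_sets(pairs: Sequence[conn.ConnectomePair],
                 groups: dict[str, str]) -> dict:
    """Per-group test/retest edge-vector dictionaries."""
    out: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for p in pairs:
        g = groups[p.subject_id]
        out.setdefault(g, {"test": {}, "retest": {}})
        out[g]["test"][p.subject_id] = conn.vectorize_fc(p.fc_test)
        out[g]["retest"][p.subject_id] = conn.vectorize_fc(p.fc_retest)
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the requested stages and return the run manifest."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    requested = [s for s in STAGES if s in cfg.stages_to_run]
    artifacts: list[Path] = []
    ctx: dict = {}

    def need(key: str, stage: str):
        if key not in ctx:
            raise FPConnError(
                f"stage '{stage}' is missing upstream artifact '{key}'")
        return ctx[key]

    # --- cohort -----------------------------------------------------------
    if cfg.simulate is not None:
        sim = cfg.simulate
        timeseries, atlas, covariates, truth = coh.generate_cohort(sim)
        clinical = None
        if sim.stability_diff_blocks and any(
                b.direction == "control_gt_patient"
                for b in sim.stability_diff_blocks):
            scores = coh.planted_subnetwork_scores(timeseries, truth)
            clinical = coh.generate_clinical_outcomes(scores, sim, truth=truth)
        if "simulate" in requested:
            cohort_dir = out_dir / "cohort"
            fpio.write_fixture_set(timeseries, atlas, covariates, clinical,
                                   sim, cohort_dir)
            artifacts.extend(sorted(cohort_dir.iterdir()))
        ctx["truth"] = truth
    else:
        timeseries, atlas, covariates, clinical, _ = fpio.load_fixture_set(
            cfg.input_dir)
    ctx.update(timeseries=timeseries, atlas=atlas, covariates=covariates,
               clinical=clinical)
    groups = {ts.subject_id: ts.group for ts in timeseries}
    group_names = ("control", "patient")

    # --- connectomes ------------------------------------------------------
    if {"connectomes", "identify", "icc", "diff", "features",
            "classify"} & set(requested):
        pairs = [conn.compute_split_fc(ts) for ts in timeseries]
        vecs_raw = _vector_sets(pairs, groups)
        vecs_res = {}
        if cfg.residualize_scope == "pooled":
            pooled = {
                half: conn.residualize_edges(
                    {**vecs_raw["control"][half], **vecs_raw["patient"][half]},
                    ctx["covariates"])
                for half in ("test", "retest")
            }
            for g in group_names:
                vecs_res[g] = {half: {s: pooled[half][s]
                                      for s in vecs_raw[g][half]}
                               for half in ("test", "retest")}
        elif cfg.residualize_scope == "per_group":
            for g in group_names:
                cov_g = ctx["covariates"][ctx["covariates"]["group"] == g]
                vecs_res[g] = {
                    half: conn.residualize_edges(vecs_raw[g][half], cov_g)
                    for half in ("test", "retest")
                }
        else:
            raise FPConnError(
                f"unknown residualize_scope {cfg.residualize_scope!r}")
        ctx["vectors_raw"] = vecs_raw
        ctx["vectors_resid"] = vecs_res

    # --- identifiability --------------------------------------------------
    if "identify" in requested:
        vecs_raw = need("vectors_raw", "identify")
        seed = cfg.stage_seed("identify")
        report = {}
        for g in group_names:
            m_raw = ident.build_identifiability_matrix(
                vecs_raw[g]["test"], vecs_raw[g]["retest"])
            m_res = ident.build_identifiability_matrix(
                ctx["vectors_resid"][g]["test"],
                ctx["vectors_resid"][g]["retest"])
            met_raw = ident.compute_identifiability_metrics(m_raw)
            met_res = ident.compute_identifiability_metrics(m_res)
            boot = ident.bootstrap_idiff_norm(
                m_res, m_raw, paired=True, n_iter=cfg.bootstrap_n_iter,
                seed=seed)
            report[g] = {
                "raw": met_raw.as_dict(),
                "residualized": met_res.as_dict(),
                "residualized_minus_raw_idiff_norm": {
                    "estimate": boot.estimate, "ci": [boot.ci_low, boot.ci_high],
                    "p_value": boot.p_value},
            }
            ctx[f"identmatrix_{g}"] = m_res
            path = out_dir / f"identifiability_matrix_{g}.tsv"
            fpio.write_square_matrix(m_res.m, m_res.subject_order, path)
            artifacts.append(path)
        path = out_dir / "identifiability_metrics.json"
        fpio.write_json(report, path)
        artifacts.append(path)
        ctx["identifiability_report"] = report

    # --- edgewise ICC -----------------------------------------------------
    if {"icc", "diff"} & set(requested):
        vecs = need("vectors_resid", "icc")
        seed = cfg.stage_seed("icc")
        sub_cfg = rel.ICCSubsampleConfig(cfg.subsample_n_iter,
                                         cfg.subsample_fraction, seed)
        icc_maps = {}
        profiles = {}
        for g in group_names:
            icc_maps[g] = rel.subsampled_icc(vecs[g]["test"],
                                             vecs[g]["retest"], sub_cfg)
            profiles[g] = rel.network_icc_profile(icc_maps[g], ctx["atlas"])
            path = out_dir / f"icc_{g}.tsv"
            fpio.write_square_matrix(icc_maps[g].values,
                                     ctx["atlas"]["region_id"], path)
            artifacts.append(path)
        conc = rel.ranking_concordance(profiles["control"].ranking,
                                       profiles["patient"].ranking,
                                       n_perm=cfg.n_perm, seed=seed)
        path = out_dir / "icc_profiles.json"
        fpio.write_json({
            g: {"network_means": profiles[g].network_means,
                "whole_brain_mean": profiles[g].whole_brain_mean,
                "ranking": profiles[g].ranking} for g in group_names} | {
            "concordance": {"w": conc.w, "p_value": conc.p_value}}, path)
        artifacts.append(path)
        ctx["icc_maps"] = icc_maps
        ctx["icc_profiles"] = profiles

    # --- differential fingerprint ----------------------------------------
    if {"diff", "features", "classify"} & set(requested):
        icc_maps = need("icc_maps", "diff")
        vecs = ctx["vectors_resid"]
        seed = cfg.stage_seed("diff")
        subsample = (rel.ICCSubsampleConfig(cfg.subsample_n_iter,
                                            cfg.subsample_fraction, seed)
                     if cfg.null_subsampling else None)
        pcfg = diff.PermutationConfig(n_perm=cfg.n_perm, seed=seed,
                                      alpha=cfg.alpha, subsample=subsample)
        perm = diff.permutation_test_icc_diff(
            vecs["control"]["test"], vecs["control"]["retest"],
            vecs["patient"]["test"], vecs["patient"]["retest"], pcfg)
        dmat = diff.compute_icc_diff(icc_maps["control"], icc_maps["patient"])
        mask_cgtp, mask_pgtc = diff.extract_edge_masks(dmat, perm)
        summary = diff.network_block_summary(dmat, (mask_cgtp, mask_pgtc),
                                             ctx["atlas"])
        pairs_idx = conn.edge_index(dmat.n_regions)
        rid = ctx["atlas"]["region_id"].to_numpy()
        rows = []
        for k in np.flatnonzero(mask_cgtp.edges | mask_pgtc.edges):
            i, j = pairs_idx[k]
            rows.append({"region_i": rid[i], "region_j": rid[j],
                         "diff": dmat.edge_values()[k],
                         "p_raw": perm.p_raw[k], "p_adj": perm.p_adj[k],
                         "direction": ("control_gt_patient"
                                       if mask_cgtp.edges[k]
                                       else "patient_gt_control")})
        edges_df = pd.DataFrame(
            rows, columns=["region_i", "region_j", "diff", "p_raw", "p_adj",
                           "direction"])
        path = out_dir / "differential_edges.tsv"
        edges_df.to_csv(path, sep="\t", index=False)
        artifacts.append(path)
        path = out_dir / "icc_diff.tsv"
        fpio.write_square_matrix(dmat.values, rid, path)
        artifacts.append(path)
        path = out_dir / "network_block_summary.tsv"
        summary.block_strengths.to_csv(path, sep="\t")
        artifacts.append(path)
        ctx.update(diff_matrix=dmat, perm_result=perm,
                   mask_control_gt_patient=mask_cgtp,
                   mask_patient_gt_control=mask_pgtc)

    # --- subnetwork topology features -------------------------------------
    if {"features", "classify"} & set(requested):
        mask = need("mask_control_gt_patient", "features")
        seed = cfg.stage_seed("features")
        patient_ids = [ts.subject_id for ts in timeseries
                       if ts.group == "patient"]
        # full-series FC, residualized across patients
        full_vecs = {}
        for ts in timeseries:
            if ts.group != "patient":
                continue
            fc = np.corrcoef(ts.data, rowvar=False)
            full_vecs[ts.subject_id] = conn.vectorize_fc(np.clip(fc, -1, 1))
        cov_p = ctx["covariates"][ctx["covariates"]["group"] == "patient"]
        full_res = conn.residualize_edges(full_vecs, cov_p)
        feats = {}
        use_mask = mask.n_edges > 0
        if not use_mask:
            logger.warning(
                "empty discriminative mask; falling back to proportional "
                "thresholding at density %.2f", cfg.mask_fallback_density)
        for sid in patient_ids:
            fc = conn.devectorize_fc(full_res[sid], mask.n_regions,
                                     diagonal=0.0)
            if use_mask:
                g = topo.apply_edge_mask(fc, mask)
            else:
                g = topo.proportional_threshold(fc, cfg.mask_fallback_density)
            feats[sid] = topo.compute_graph_features(g, seed=seed).as_array()
        features = pd.DataFrame.from_dict(
            feats, orient="index", columns=list(topo.FEATURE_NAMES))
        features.index.name = "subject_id"
        path = out_dir / "topology_features.csv"
        features.to_csv(path)
        artifacts.append(path)
        ctx["features"] = features

    # --- classification ---------------------------------------------------
    if "classify" in requested:
        features = need("features", "classify")
        clinical = ctx.get("clinical")
        if clinical is None:
            raise FPConnError("stage 'classify' requires a clinical table")
        seed = cfg.stage_seed("classify")
        labelled = clf.label_responders(clinical, cfg.threshold_percent)
        labels = labelled.set_index("subject_id")["responder"]
        spec = clf.ModelSpec(family=cfg.classifier_family, seed=seed)
        report = clf.nested_loocv_classify(features, labels, spec)
        result = {"metrics": report.metrics,
                  "confusion_matrix": report.confusion_matrix,
                  "n_responders": int(labels.loc[features.index].sum())}
        if report.importances is not None:
            result["importances"] = clf.feature_importance_summary(
                report).to_dict()
        if cfg.classifier_n_perm > 0:
            sig = clf.permutation_significance(features, labels, spec,
                                               n_perm=cfg.classifier_n_perm,
                                               seed=seed)
            result["permutation"] = {"p_raw": sig.p_raw, "p_adj": sig.p_adj}
        path = out_dir / "classification.json"
        fpio.write_json(result, path)
        artifacts.append(path)
        path = out_dir / "per_fold_predictions.csv"
        report.per_fold_predictions.to_csv(path, index=False)
        artifacts.append(path)
        ctx["cv_report"] = report

    # --- summary statistics ------------------------------------------------
    if "stats" in requested:
        results = {}
        clinical = ctx.get("clinical")
        if clinical is not None and len(clinical) >= 3:
            cmp = gstats.compare_groups(clinical["updrs_bl"],
                                        clinical["updrs_fu"], paired=True)
            results["updrs_pre_post"] = asdict(cmp)
        cov = ctx["covariates"]
        ages = [cov.loc[cov["group"] == g, "age"].to_numpy()
                for g in group_names]
        results["age_control_vs_patient"] = asdict(
            gstats.compare_groups(ages[0], ages[1], paired=False))
        sex_table = pd.crosstab(cov["group"], cov["sex"]).to_numpy()
        if sex_table.shape[1] > 1:
            results["sex_chi_square"] = asdict(gstats.chi_square_test(sex_table))
        path = out_dir / "group_statistics.json"
        fpio.write_json(results, path)
        artifacts.append(path)

    manifest = {
        "config": {**{k: v for k, v in asdict(cfg).items()
                      if k != "simulate"},
                   "simulate": (cfg.simulate.as_dict()
                                if cfg.simulate is not None else None)},
        "stages_run": requested,
        "files": {str(p.relative_to(out_dir)): fpio.file_checksum(p)
                  for p in artifacts},
    }
    fpio.write_json(manifest, out_dir / "run_manifest.json")
    return manifest
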