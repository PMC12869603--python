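# fpconn

Functional-connectome fingerprinting for resting-state fMRI cohorts, and
prediction of therapy response from fingerprint-derived network topology.

`fpconn` is aimed at network-neuroscience researchers who work with
parcellated BOLD time series (e.g. Schaefer-400 regions grouped into the
seven canonical Yeo networks: VN, SMN, DAN, VAN, LN, FPN, DMN) and want to

1. quantify how individually distinctive each subject's functional
   connectome (FC) is,
2. map *where* on the connectome that distinctiveness lives,
3. test whether its spatial layout differs between a patient group and
   controls, and
4. use the affected subnetwork to predict which patients respond to an
   intervention.

Because clinical imaging cohorts are rarely shareable, the package also
ships a first-class synthetic-cohort generator that plants every effect the
pipeline is meant to recover (subject-unique covariance, block-localized
test–retest instability, covariate effects, an outcome mechanism), so the
entire analysis is testable end to end without any data download.

## The model

**Fingerprinting.** Each scan is split into halves ("test" and "retest");
each half yields a Pearson FC matrix whose vectorized upper triangle is one
connectivity profile. The identifiability matrix `M` holds
`M[s,i] = corr(FC_test(s), FC_retest(i))` over all subject pairs. From it:

- `I_self(s) = M[s,s]`, the self-match;
- `I_others(s) = Σ_{i≠s}(M[s,i] + M[i,s]) / (2N−2)`, the mean cross-match;
- `I_diff = mean(I_self) − mean(I_others)`;
- `I_diff-norm = (μ_within − μ_between) / SD_pooled`, a Cohen's-d-style
  effect size over the N diagonal vs N²−N off-diagonal entries;
- `SR` = percentage of subjects whose self-match strictly exceeds every
  cross-match in their row and column of `M`.

Edge vectors are first residualized edge-by-edge against age, sex,
education, disease duration and onset age (the latter two zero for
controls, whose constant columns are dropped from the design).

**Edgewise reliability.** Per edge, test–retest reliability across subjects
is the one-way random-effects intraclass correlation with k = 2 repeats,
`ICC(1,1) = (MS_B − MS_W) / (MS_B + MS_W)`, stabilized by averaging over
100 random 80% subject subsamples. Group differences (`ICC_diff`,
controls − patients) are tested by whole-subject label permutation and
Benjamini–Hochberg FDR; surviving edges form directional masks whose
strengths are aggregated over the 28 network blocks.

**Prediction.** Patients' (full-series, residualized) FC matrices are
masked to the discriminative subnetwork; eight weighted-graph measures
(strength, eigenvector centrality, characteristic path length, mean
first-passage time, modularity, participation coefficient, assortativity,
rich-club coefficient) feed a nested leave-one-out classification with
inner 5-fold grid search. Responders are patients with
`ΔUPDRS-III = (baseline − follow-up)/baseline × 100 ≥ 15`. Significance of
accuracy / ROC-AUC / PR-AUC comes from label-permutation with BH correction
across the three metrics.

## Worked example

```python
import fpconn as fp
from fpconn import connectome as conn

cfg = fp.CohortConfig(seed=1)          # 23+23 subjects, 100 regions, T=400
ts, atlas, cov, truth = fp.generate_cohort(cfg)

controls = [t for t in ts if t.group == "control"]
pairs = {t.subject_id: fp.compute_split_fc(t) for t in controls}
test = {s: fp.vectorize_fc(p.fc_test) for s, p in pairs.items()}
retest = {s: fp.vectorize_fc(p.fc_retest) for s, p in pairs.items()}
cov_c = cov[cov["group"] == "control"]
test = conn.residualize_edges(test, cov_c)
retest = conn.residualize_edges(retest, cov_c)

m = fp.build_identifiability_matrix(test, retest)
print(fp.compute_identifiability_metrics(m).as_dict())
```

Output (values rounded):

```
{'i_self_mean': 0.634, 'i_self_sd': 0.010,
 'i_others_mean': -0.029, 'i_others_sd': 0.002,
 'i_diff': 0.662, 'i_diff_norm': 11.37, 'sr': 100.0}
```

Every control is matched to themself across scan halves (`sr = 100`): the
self-similarity (≈ 0.63) towers over the near-zero residualized
between-subject similarity, and the standardized within/between gap
(`i_diff_norm` ≈ 11) summarizes that separation in pooled-SD units.

The full pipeline — simulate (or load), connectomes, identifiability, ICC,
differential masks, topology features, classification, summary statistics —
runs from one configuration:

```bash
fingerprint run --config config.yaml --out my_run --seed 7
```

All artifacts are delimited text or JSON, with a checksum manifest for
reproducibility; rerunning the same configuration reproduces identical
files.

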