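# jdr — joint dimension reduction for cross-cohort expression translation

Model systems (cancer cell lines, genetically engineered mouse models) are
measured on the same genes as the human tumors they are meant to represent,
but much of their expression variation is system-specific: culture
artefacts, absent microenvironment, species differences. Analyses and
drug-response models built on the raw model-system data inherit that
nuisance variation and translate poorly to patients.

`jdr` addresses this by decomposing two gene-aligned expression cohorts
into shared and cohort-specific structure with angle-based joint and
individual variation explained (AJIVE), and by building the downstream
translation analyses on the decomposed matrices. It is aimed at
computational biologists integrating a model-system cohort with a human
tumor cohort (e.g. breast cancer cell lines with primary breast tumors).

## The method

Each mean-centered cohort `X_k` (samples x genes) is modelled additively:

```
X_k = J_k + I_k + E_k
```

- `J_k` — joint variation, whose gene-space structure is shared with the
  partner cohort;
- `I_k` — individual variation, specific to cohort `k`;
- `E_k` — residual noise.

The fit is a two-stage SVD. First each block is truncated at an initial
signal rank `r_k` (chosen by a half-split bootstrap). Then the retained
metagenes are stacked, `M = [V_A'; V_B'] = U_M D_M V_M'`, and the
principal angles between the two metagene subspaces follow from the
singular values, `phi_i = arccos(sigma_i² − 1)`. Angles below a cutoff
calibrated on random subspaces mark the joint subspace; each block is
then reprojected through the joint basis and its orthogonal complement in
the block's retained row space, which splits every sample's sum of
squares exactly across `J`, `I`, `E`.

On top of the decomposition the package provides:

- per-sample and per-gene-set **variation profiles** (percent joint /
  individual / residual);
- a per-gene **joint statistic** `T_g = ln(max(σ²_J, s) / max(σ²_I, s))`
  with a pool-and-resplit permutation null and SAM-style per-tail FDR
  cutoffs, and cross-cohort translatability calls (fully joint /
  unidirectional / not joint);
- **translation models**: elastic-net response models trained on the
  original, joint or individual matrix with path-derived alpha grids and
  repeated-split selection, evaluated out of sample by ROC-AUC, plus
  bootstrap AUC comparison, median-expression signature scoring and
  Spearman drug-response association;
- a **synthetic-data generator** that plants known joint/individual
  structure, gene classes and a response, so every stage can be validated
  against ground truth.

## Worked example

Simulate a cell-line-like and a tumor-like cohort sharing a rank-3 joint
subspace (plus rank-2 individual structure each), decompose, and call
translatable genes:

```python
from jdr import (AJIVE, AjiveConfig, classify_translatability,
                 mean_center_genes, simulate_joint_blocks, snr_to_signal_sd)

signal_sd = snr_to_signal_sd(5.0, 120, 1000, 1.0)
cells, tumors, truth = simulate_joint_blocks(
    n_samples_a=120, n_samples_b=150, n_genes=1000,
    joint_rank=3, individual_ranks=(2, 2),
    signal_sd=signal_sd, noise_sd=1.0, seed=7,
)
cells, tumors = mean_center_genes(cells), mean_center_genes(tumors)

res = AJIVE(cells, tumors, rank_a=5, rank_b=5,
            config=AjiveConfig(n_random_draws=500, seed=0)).fit()
print(res.summary())
```

```
AJIVE decomposition
============================================================
joint rank: 3   angle cutoff: 81.54 deg
principal angles (deg): 10.7, 11.0, 12.2, 89.6, 89.9
------------------------------------------------------------
block                 r_k   % joint   % indiv   % resid
synthetic_A             5     42.90     25.46     31.65
synthetic_B             5     40.02     27.33     32.65
```

Three principal angles (10.7°–12.2°) fall far below the chance cutoff and
two sit near 90°: the planted joint rank 3 is recovered, with the planted
individual components correctly excluded. Roughly 40% of each block's
variation is shared, ~26% cohort-specific and ~32% noise, matching the
planted proportions.

```python
ta = res.joint_statistic_table("synthetic_A", n_perm=500, seed=1)
tb = res.joint_statistic_table("synthetic_B", n_perm=500, seed=2)
calls = classify_translatability(ta, tb)
print(calls["translatability"].value_counts().to_string())
```

```
translatability
not_joint      900
fully_joint    100
```

All 100 planted joint-acting genes — and no others — are called fully
joint (translatable) at the 5% FDR threshold in both cohorts.

The same pipeline is available from the shell: `jdr simulate`,
`jdr preprocess`, `jdr integrate`, `jdr select-rank`, `jdr joint-stat`,
`jdr variation`, `jdr predict`, `jdr evaluate` (see `jdr --help`).

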