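# tmtprofiler

Paired tumor/normal TMT proteomics analysis: reference-channel ratio
preprocessing, sample-wise expression statistics against individualized
PSM-binned null distributions, consensus-NMF molecular subtyping, cross-omics
subtype transfer, and ordinal prognostic scoring — plus a synthetic-cohort
generator that reproduces the statistical structure such studies assume, so
every stage is testable with known ground truth.

## The problem

Multiplexed isobaric labeling (TMT) quantifies up to 16 samples per LC-MS/MS
run as reporter-ion intensities relative to a pooled reference channel that
anchors ratios between runs ("sets"). Cohorts span dozens of sets with heavy
between-set missingness: a modest core of proteins is seen in every set, many
others only in some. When tumors come with patient-matched normal tissue in
the same set, the interesting question is *per patient*: which proteins are
over- or underexpressed in *this* tumor relative to *this* patient's mucosa —
the quantity that matters for, e.g., antibody-drug-conjugate target
specificity — rather than only pooled group contrasts.

## The statistics at the core

**Individualized paired statistic.** For tumor sample *i* and protein *j*,
the paired log-ratio is a\_{i,j} = log2 x\_{tumor,j} − log2 x\_{normal,j}.
Its null distribution H(i) is *pseudo-individual*: all log2 differences of
patient *i*'s normal sample versus every other normal sample in the same TMT
set, across all proteins. Because averaging a protein's PSM ratios shrinks
variance with the PSM count p, H(i) is filtered by the binning indicator

    B(p, p_j) = 1   iff   p_j / 2 < p < 2 p_j

so the null spread is estimated from proteins of similar PSM depth. The test
statistic is ã\_{i,j} = a\_{i,j} / sd(filtered null) and the p-value the
folded normal tail 1 − Φ(|ã\_{i,j}|) ∈ (0, 0.5]; calls are directional (over
if p < α and a > 0, under if p < α and a < 0) and deliberately uncorrected —
cohort conclusions rest on call *rates* across samples.

**Consensus NMF subtyping.** The most-variant quarter of the fully covered
proteins feeds repeated non-negative matrix factorization (generalized KL
divergence, multiplicative updates, `random_vcol` starts, k·100 iterations).
Co-assignment frequencies across runs form a consensus matrix C; its
cophenetic correlation and dispersion (1/n²)Σ 4(C−½)² guide the choice of k,
and average-linkage clustering of 1−C yields labels. Per-protein cluster
relevance is the Kim–Park entropy score of basis rows.

**Cross-omics transfer.** Features are gated on tabulated protein–mRNA
Spearman correlation (ρ ≥ 0.75), each layer is discretized by its own
per-feature quartiles with the middle quartiles pooled (low/medium/high), and
a probabilistic SVC assigns a subtype only when the maximum class probability
clears a floor (default 0.5). Compact marker panels come from resampled
recursive feature elimination.

**Prognosis.** Stage groups and proteomic clusters enter survival models as
quasi-continuous ordinal codes; the combined score S = (S_cluster/5)·(S_stage/6)
∈ [1/30, 1] merges both. Kaplan–Meier, log-rank, restricted-mean survival and
Cox fits are delegated to lifelines.

## Worked example

```python
from tmtprofiler import (CohortSpec, simulate_cohort, preprocess_cohort,
                         PairedExpressionModel, ConsensusNMF)

spec = CohortSpec(n_sets=6, channels_per_set=16, n_proteins=400,
                  common_core_fraction=0.5, n_subtypes=3, signature_size=15,
                  signature_effect=1.5, noise_sd=0.4, seed=7)
psms, sheet, truth = simulate_cohort(spec)

matrix, report = preprocess_cohort(psms, sheet)
profiles = PairedExpressionModel(matrix, sheet).fit(alpha=0.05)
print(profiles.summary().head(3))

nmf = ConsensusNMF.from_matrix(matrix, sheet, fraction=0.25,
                               k_range=range(2, 7), n_run=20).fit(seed=1)
print(nmf.summary())
```

prints

```
           n_tested  n_over  n_under  over_fraction  under_fraction
sample_id
T0001           315      28       14       0.088889        0.044444
T0002           315      28       17       0.088889        0.053968
T0003           315      23       21       0.073016        0.066667

   cophenetic  dispersion
k
2    0.982464    0.649479
3    1.000000    1.000000
4    0.989953    0.921762
5    0.970523    0.808681
6    0.993360    0.939939
```

Each tumor was tested against its own PSM-binned null over ~315 proteins
quantified in both members of its pair; over/under fractions sit above the
2×α background because three subtype signatures (15 proteins each, ±1.5
log2 units) are planted. The rank-selection table shows crisp, perfectly
reproducible consensus exactly at the planted k = 3 (dispersion and
cophenetic correlation both 1.0), and the k = 3 labels match the planted
subtypes exactly (adjusted Rand index 1.0).

The same stages are scriptable from a shell:

```bash
tmtprofiler simulate --config spec.json --out sim/ --seed 7
tmtprofiler preprocess --psm sim/psms.tsv --samples sim/samples.tsv --out prep/
tmtprofiler profile --matrix prep/ --samples sim/samples.tsv --out prof/
tmtprofiler cluster --matrix prep/ --samples sim/samples.tsv --k-min 2 --k-max 6 --out clust/
```

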