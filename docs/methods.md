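# Methods

This note documents the models, conventions and numerical choices behind
`tmtprofiler`, and what the synthetic-data studies do and do not demonstrate.

## Preprocessing model

Quantitation starts from PSM-level reporter intensities. Only PSMs flagged
unique are used. Each unique PSM's reporter intensity in a sample channel is
divided by the same PSM's intensity in the set's pooled-reference channel
(tag 134N), and the per-PSM ratios of a protein are averaged — arithmetic
mean of raw ratios by default, with a geometric (log-scale) mean available
(`log_mean=True`), since either reading of "averaging ratios" is defensible.
A PSM whose reference intensity is zero is dropped with a warning (its ratio
is undefined); a set without a reference channel is a hard error.

Samples whose median non-normalized ratio is 8-fold (configurable) below the
median of the other samples' medians are excluded — a threshold
operationalization of the ad-hoc removal of catastrophically under-loaded
samples.

Normalization uses an invariant protein subset: among proteins with 100%
sample coverage, each sample's log2 ratios are centered by the sample median
and proteins are ranked by the variance of the centered values (rank 1 = most
invariant). This variance criterion is a deliberately simple invariance
score; downstream code depends only on the ranking being a deterministic,
scale-invariant total order, which it is. Each sample is divided by its
median ratio over the top 40% most invariant proteins; afterwards that median
is exactly 1 and within-sample relative ratios are unchanged. The whole chain
is scale-invariant: multiplying any one channel's PSM intensities by a
constant leaves the normalized matrix unchanged to ≤1e-9 (verified).

## The paired expression statistic

For tumor sample *i* with paired normal *n(i)* in the same set, and protein
*j* quantified in both: a_{i,j} = log2 x_{i,j} − log2 x_{n(i),j}. The
pseudo-individual null H(i) pools log2 differences of n(i) against every
other normal sample of the same set over all shared proteins, each value
tagged with the protein's per-set PSM count. The PSM bin B(p, p_j) retains
values with p_j/2 < p < 2·p_j (strict bounds; B(p_j, p_j)=1 always). The
statistic is ã = a / sd and the p-value 1 − Φ(|ã|).

Conventions, chosen where the procedure leaves room:

- **sd estimator**: sample standard deviation, ddof=1; no centering of the
  null (a `center` switch subtracts the null mean first, off by default).
- **Minimum null size**: 5. Below it the bin is widened once (bounds doubled
  to p_j/4..4·p_j); if still under 5 the statistic is undefined and reported
  as NA — an sd from 1–2 values would be noise. NA is never significant.
- **PSM count scope**: p_j is the per-set count; the null is set-local, so
  binning against cohort-total counts would mix incomparable variances.
- **Calibration**: the p-value is a folded one-sided tail, uniform on
  (0, 0.5] under the null. Each *direction* (over, under) is therefore
  called at rate α; over- and under-calls together occur at 2α. The
  validation studies check the directional rate against α.
- **No multiple-testing correction**, by design: each tumor is tested
  against its own null, and cohort-level statements are call frequencies
  across samples (quasi-replication), not single hypothesis tests.
- Fig-style group-rate dispersion uses the population variance (divide by
  the number of groups), configurable via ddof.

Pooled two-group comparisons are a separate operation: Mann–Whitney U
(two-sided, scipy) on proteins with ≥20% non-missing pooled coverage,
Benjamini–Hochberg q-values (statsmodels).

## Consensus NMF

Input is the non-negative normalized ratio matrix (not log space) restricted
to tumor samples and the most-variant 25% of the invariance-ranked proteins —
a complete block by construction. Factorization minimizes the generalized KL
divergence by multiplicative updates; initialization is `random_vcol`: each
basis column is the mean of 5 randomly sampled data columns (coefficient rows
analogously from rows). Runs stop at exactly k·100 iterations with no early
stopping, mirroring the reference configuration; an optional relative-change
tolerance exists but is off by default. Per run, samples are assigned to the
argmax coefficient row; the consensus matrix is the mean connectivity over
n_run runs (100 by default; scaled-down studies state their n_run). Final
labels cut the average-linkage dendrogram of 1−C at k; the dendrogram route
(rather than the best-objective run) matches how consensus heatmaps are read.

Metrics: dispersion = (1/n²)Σ 4(C_ij−½)², which is 1 iff C is binary; note
the unit diagonal always contributes, so a matrix with all off-diagonal
entries ½ scores 1/n, not 0. Cophenetic correlation compares 1−C with the
dendrogram's cophenetic distances; for a degenerate (constant) distance
vector it is defined as 1 (perfect consensus). Kim–Park cluster relevance of
protein i is 1 + (1/log2 k) Σ_q q_iq log2 q_iq with q the row-normalized
basis loadings; scores are computed on the best-objective run's basis, since
averaging bases across runs without aligning components smears factors.

## Cross-omics subtype transfer

Features pass a correlation gate (tabulated cross-layer Spearman ρ ≥ 0.75,
inclusive). Each layer is discretized **by its own per-feature quartiles**
(linear-interpolation estimator) with the 2nd and 3rd quartiles pooled:
x < Q1 → low, Q1 ≤ x ≤ Q3 → medium, x > Q3 → high. Boundary values fall in
medium; constant features become all-medium with a warning. Tiering each
layer on its own distribution is what makes the transfer robust to unknown
scale relations between platforms, and the transform is exactly invariant
under strictly monotone transformations. Optional deduplication keeps a
single feature per correlated group (|Spearman| ≥ 0.7), visiting features in
a seeded shuffled order for reproducibility.

The reference classifier is an SVC (RBF kernel; linear for tiny IHC-style
panels) with pairwise-coupling probability calibration; any classifier
exposing class probabilities satisfies the contract. A sample is labeled only
when the maximum class probability reaches the floor (default 0.5), otherwise
"unclassified"; lowering the floor can only grow the classified fraction.

Marker panels: per resampling run, 20% of samples are held out, features are
ranked by recursive elimination of the smallest linear-SVC weight, and every
nested feature-set size is scored by 5-fold cross-validated accuracy. The
chosen size is the smallest within one standard error of the best score (a
parsimony rule; without it a flat CV curve under weak signal retains
arbitrarily many uninformative features and selection frequencies lose their
meaning; `parsimony=False` restores the raw argmax). Features are ranked by
selection frequency across runs, ties broken by mean CV accuracy where
selected, then lexicographically.

## Prognosis

Cluster and stage labels are encoded 1..m along their prognostic orderings
(muscle-invasive stages pooled via a configurable mapping) and treated as
quasi-continuous covariates. The combined score is multiplicative by default,
S = (S_cluster/5)(S_stage/6) ∈ [1/30, 1], strictly increasing in both codes;
an additive mode (S_cluster/5 + S_stage/6) is provided because the defining
expression admits either reading, and the chosen mode is recorded in the
output. Kaplan–Meier medians (inf when never reached), log-rank tests,
restricted-mean survival at a 24-month default horizon, and Cox fits with
per-unit hazard ratios and partial AIC all delegate to lifelines; the module
owns only the encodings and comparison contracts.

## Synthetic cohorts

The generator emulates the data structure the pipeline assumes, on the log2
scale: protein baselines N(16, 1.5²); per-sample loading offsets (sd tied to
`noise_sd` unless overridden, so a single knob governs technical
variability); per-PSM ionization offsets shared across channels (cancelling
in ratios); independent N(0, noise_sd²) measurement noise per (PSM, channel).
Averaging m PSM ratios shrinks protein-level noise like 1/√m, which is
exactly the PSM-count/variance coupling the binned null corrects for. The
reference channel is a cohort-wide pool: log2 of the mean linear intensity
across all sample channels, with per-(protein, set) lognormal pooling noise —
set-invariant up to noise. PSM counts per (protein, set) follow a truncated
discrete power law (exponent 1.8, cap 200), a typical heavy-tailed shotgun
profile. Missingness is protein-wise per set: a configurable core is present
in every set; other proteins draw per-set presence Bernoulli(detect_prob)
truncated to never span all sets, so the all-set core size is exact. Each of
k subtypes gets a signature of ±`signature_effect` (half over, half under)
drawn from the core; survival is exponential with per-subtype hazard
multipliers and uniform censoring; stages correlate mildly with subtype risk.
A fraction of decoy non-unique PSM rows with corrupted intensities is
included so misuse of non-unique PSMs is caught by tests. The mRNA layer is
built per gene as a Gaussian mixture of the standardized protein values with
Pearson weight 2·sin(πρ/6), which realizes a target Spearman ρ drawn from a
configurable law (default Beta(5, 3)).

What the generator does **not** emulate: peptide-to-protein inference and
search-engine FDR, reporter-ion isotope impurity, ratio compression from
co-isolation, tumor purity gradients, within-tumor biological heterogeneity
beyond the subtype signature (available via `tumor_bio_sd`, default 0 —
with real tumors, genuine patient-level biology widens tumor-vs-normal
contrasts beyond the technical null, which is precisely the signal the
statistic reports), batch drift within a set, or nonlinear protein–mRNA
relationships. Passing tests therefore certify the statistical machinery
under the stated model, not performance on any particular real cohort.

## Validation regimes and problem sizes

The acceptance studies (tests and `scripts/acceptance.py`) use these sizes,
chosen to exercise each property at desk scale:

- calibration: 20 null cohorts, 4 sets × 12 sample channels, 300 proteins;
- signature recovery: effect 2.0, noise 0.3, 3 subtypes × 10 proteins;
- NMF recovery: 10 replicate cohorts, 5 subtypes, ~152 tumor samples,
  120-feature blocks, n_run = 30 (scaled down from the default 100),
  k = 2..8;
- transfer: 200 tumor samples, 5 subtypes, gene-wise ρ ∈ [0.75, 0.95],
  floor scan 0.7/0.5/0.3;
- tier law: 3 × 10,000 standard-normal draws;
- survival: two exponential groups of 200 at hazard ratio 3; 100 null Cox
  replicates of n = 500.

## Known limitations

- The invariance criterion is a simple variance ranking, not a full
  invariant-selection model; rankings from more elaborate criteria would
  change which proteins normalize the data but not the pipeline's contracts.
- The folded-tail p-value is calibrated per direction; users comparing the
  *total* call rate against α should halve α or use the `center`d two-sided
  reading consciously.
- Consensus NMF with k·100 fixed iterations can under-converge for very
  large k on hard data; the optional tolerance trades fidelity to the
  reference configuration for convergence control.
- The SVC probability calibration is the standard pairwise-coupling scheme;
  probabilities near the floor are sensitive to calibration details, which
  is why the floor and the classified fraction are always reported together.
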