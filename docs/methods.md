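# Methods

## Scope and data model

The package analyzes targeted mRNA count panels (digital multiplexed gene
expression on the nCounter platform) for B-cell chronic lymphoproliferative
disorders. A cohort is a nonnegative genes × samples count matrix, a code
set assigning each probe a class (endogenous, housekeeping, positive
control, negative control), and a sample sheet (group label, IgVH mutation
status, optional flow-cytometry percentages). Raw counts are integers; the
matrix carries an explicit processing stage
(`raw → background_corrected → normalized`) so that, e.g., a supplied
already-normalized matrix can be declared as such and skip preprocessing.

## Preprocessing

**Background correction.** Negative-control probes measure nonspecific
hybridization. Per sample, the threshold is the negative-control mean plus
two standard deviations; it is subtracted from every non-control count and
results clamp at zero. Choices the platform literature leaves open, settled
here: the SD uses the n−1 denominator (small control sets); the background
is computed per sample, not pooled across the run (lane-specific
background is the platform norm); post-subtraction values stay fractional
(no re-rounding), preserving information for downstream ratio statistics;
negative-control rows are passed through unchanged for audit. At least two
negative probes are required or the SD is undefined.

**Reference-gene selection (geNorm).** For candidates *j*, *k* the
stability measure is `M_j = mean_{k≠j} SD_samples( log2(x_j / x_k) )`
(sample SD, n−1). The gene with the highest M is eliminated each round
until the requested number remain (default 3); the final pair is never
split. Ties eliminate the lexicographically greatest gene id, making the
ranking fully deterministic. Candidate counts ≤ 0 are replaced by a
pseudo-count (default 0.5) with a logged warning — the ranking stays
defined but flagged for review. M is invariant under per-sample scaling
(log-ratios cancel the scale), which is property-tested.

**Normalization.** Sample *s* is multiplied by `f_s = G / g_s`, where
`g_s` is the geometric mean of the selected reference genes in *s* and `G`
the geometric mean of all `g_s`. Anchoring at `G` makes the factors'
geometric mean exactly 1 and renders re-normalization idempotent. The
anchor is a single global scalar: any other choice (e.g. a fixed reference
value) changes every count by the same factor and no downstream ratio,
p-value, CV or classification. A consequence worth knowing: rescaling one
input column by *c* leaks `c^(1/n)` into the anchor, so normalized
matrices agree up to that one global scalar rather than bit-exactly.

**Positive-control QC.** Per sample, log2 counts are regressed on log2
nominal concentration; samples with R² below 0.95 are flagged. QC is
advisory only — no samples are dropped, matching a workflow that reports
no exclusions.

## Differential expression and signatures

Group comparisons report per-gene means, SDs and the ratio of linear
normalized means, with a two-sided pooled-variance Student t-test
(Welch and a log2-scale option are available behind flags; linear pooled-t
is the default because printed report statistics are linear-scale).
Genes with zero variance in both groups get p = 1 and a flag. No
multiple-testing correction is applied by default (an optional
Benjamini–Hochberg flag exists) — fidelity to the established cascade
comes first.

The filter cascade keeps a gene when (i) the higher-expressing group's
mean is at least the count floor (default 50), (ii) the ratio reaches the
fold-change threshold (default 2; ≤ 1/2 for down-regulation), and
(iii) p ≤ α (default 0.05). Survivors are monotone in all three
thresholds, and the down-direction on (A, B) equals the up-direction on
(B, A) — both property-tested. Signatures are assembled by exact set
algebra: the diagnostic signature is the intersection of the CLL-vs-PB
and CLL-vs-pure-B up-lists; the homogeneous core keeps diagnostic genes
with CV = SD/mean strictly below 0.5 across CLL samples; the
mutation-status signature is the union of both directions of the
mutated-vs-unmutated comparison, with borderline-IgVH samples excluded.
Every signature records its thresholds and comparisons so the list can be
re-derived from the same inputs.

A note on printed-table arithmetic: report tables print group means at
2 decimals and ratios at 1 decimal, rounded half away from zero. Most
printed ratio cells re-render exactly from the printed means; a few (e.g.
ADAM29 16.0 vs 1061/66 = 16.1) were evidently computed from unrounded
means and differ in the last digit. The worked examples use only cells
that re-render exactly.

## Classification and ratio markers

Embedding and clustering operate on `log2(x+1)`, per-gene z-scored
counts — the platform-standard transform for heatmaps/PCA; it is
configurable. PCA components carry a deterministic sign convention
(largest-magnitude loading positive). The unsupervised mode is
average-linkage hierarchical clustering on Euclidean distances, cut into
two clusters and mapped to the truth labels by maximum agreement; nearest
centroid on the same transform is the deterministic supervised rule for
labeling new samples.

Clonality: the kappa/lambda transcript ratio (kappa ÷ lambda throughout)
is compared to a polyclonal reference interval, mean ± 2 SD, either
supplied (published reference 0.89 ± 0.22, i.e. [0.45, 1.33]) or estimated
from the cohort's own polyclonal samples. Above the interval reads
monoclonal-kappa, below monoclonal-lambda. Swapping the chains inverts the
ratio, so the kappa↔lambda symmetry holds exactly for
reciprocal-symmetric intervals (low = 1/high), not for additively
symmetric ones — the property test uses [0.5, 2.0].

Marker calls: both LDOC1 and ADAM29 below the absence threshold give the
double-negative subclass; otherwise the higher marker wins. The absence
threshold defaults to 50 counts, reusing the expression floor rather than
introducing a second free parameter. The LPL/ADAM29 ratio uses a
pseudo-count of 1 in the denominator when ADAM29 is zero (flagged);
ratio > 1 reads unmutated-like — 1 is the natural separatrix of the
published group means (LPL/ADAM29 ≈ 16 in unmutated vs ≈ 0.09 in mutated)
and is configurable. For double-negative samples the call is
indeterminate. Protein–mRNA agreement uses Pearson correlation on
(flow-cytometry percent, normalized count) pairs with pairwise deletion
of missing values (Spearman available).

## Synthetic cohorts

The generator emulates the data-generating structure the analysis assumes,
with defaults mirroring the study design: 30 CLL samples (11 IgVH mutated,
17 unmutated, 2 borderline), 5 normal PB, 4 pure B-cell samples, and a
51-sample B-CLPD series (20 MCL, 22 MZL, 4 FL, 5 HCL). Counts follow
`round(f_s · μ_g · FC_{g, group(s)} · exp(ε))`, `ε ~ N(0, σ_g²)`, with
log-normal size factors `f_s` (log-SD 0.15). Log-normal multiplicative
noise (rather than, say, negative binomial) is used because the analysis
is mean/SD/CV-based on linear counts and log-normal gives directly
controllable CV = √(exp(σ²) − 1) for planting the observed CV structure.
Negative controls are Poisson(5), unaffected by biology; positive controls
are proportional to nominal concentration. Randomness flows through
per-gene and per-sample substreams spawned from one global seed, so adding
a gene does not reshuffle other counts and the same (config, seed) pair is
bit-identical.

Panel structure: nine housekeeping candidates in which the three planted
normalizers carry σ = 0.02 and the rest σ = 0.06 — reference genes on this
platform are stable to a few percent, the >2× gap makes the geNorm
selection well-determined, and the residual post-normalization CV of the
selected trio stays below 0.05; a B-cell panel with pure-B fold changes of
20–42 (and CLL fold changes reflecting which B-cell genes CLL keeps or
loses); a CLL panel of 13 homogeneous genes (σ = 0.3, CV ≈ 0.31, fold
changes 8–30) plus 5 heterogeneous genes (σ = 0.8, CV ≈ 0.95) — the CV
dichotomy that makes the core filter meaningful; genes lost in CLL; an
IgVH panel whose fold changes and dispersions follow the published
mutated/unmutated group means and SDs (ZAP70 2.6×, CD38 10.4×, LPL 11.7×,
ADAM29 16× the other way, …); LDOC1/ADAM29 with the present/absent
trichotomy (five double-negative CLL samples: two mutated, three
unmutated); light chains with a dominant clone (kappa with probability
0.6, minor chain suppressed 50-fold) in CLL/B-CLPD and a polyclonal ratio
drawn from N(0.89, 0.22²) otherwise; and ~150 neutral filler genes
(σ = 0.4) spanning baselines 20–20 000.

**Parameter-recovery design.** `recovery_config()` is the clean setting
under which signature derivation should recover the planted panels
essentially exactly: ten samples per control group, signature-panel fold
changes ≥ 4, every other endogenous gene neutral (no IgVH effects, no
marker dichotomy). The study-sized default (5 PB / 4 pure B) is
deliberately not that setting: with 4–5 reference samples, a linear pooled
t-test on a CV ≈ 1 gene caps its expected t-statistic near the α = 0.05
critical value however large the fold change, so one or two heterogeneous
planted genes sit at the detection boundary — the same small-n fragility a
real cohort of this shape has. Both behaviors are tested: exact recovery
(sensitivity ≥ 0.95, false-discovery proportion ≤ 0.05 over 20 seeds)
under the recovery design, and the downstream claims (core filter,
clustering, markers) at study size.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: probe-level effects (cross-hybridization,
hybridization kinetics, lane position), batch/center effects, the
correlation structure among real genes (counts are independent given group
and size factor), count overdispersion beyond log-normal, borderline-IgVH
biology (borderline samples get interpolated fold changes), and any
B-CLPD subtype structure beyond "B-cell-high, CLL-panel-neutral". Recovery
of planted effects validates the pipeline's statistics and bookkeeping,
not the biological validity of the published gene lists.

## Numerical and edge-case choices

Ratios with a zero denominator report infinity (flagged); genes with both
group means zero report NaN and never pass the cascade. CV for a
zero-mean gene is undefined and the gene is excluded with a flag. Genes
constant after the log transform are dropped from embeddings with a
warning. Report tables render ratios at one decimal, half away from zero,
and p-values at fixed precision per table. Cluster-to-label assignment
breaks ties toward the first mapping enumerated; geNorm ties eliminate the
lexicographically greatest gene. The pipeline's provenance record echoes
every stage's parameters and input hashes, and rerunning the same
configuration reproduces all derived outputs byte-identically.

## Problem sizes

Tests and the acceptance script run the full pipeline on cohorts of ~90
samples × ~225 genes; the 20-seed validation loops (recovery, clustering,
markers) complete in seconds. Empirical-moment checks use 200 samples;
these sizes give the loops' means stable second digits while keeping the
whole suite fast.

## Known limitations

The linear-scale Student t-test is kept as the default for fidelity even
where a log-scale or moderated test would have more power on skewed
counts (both alternatives are exposed; shrinkage/moderated testing is out
of scope). No multiplicity correction is applied by default, so
single-comparison survivor lists carry α-level false positives by design.
The polyclonal kappa/lambda interval is a normal approximation to a ratio
distribution and is only as good as its reference set. The
absence threshold (50) and LPL/ADAM29 cut (1.0) are pragmatic defaults,
not optimized decision boundaries.
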