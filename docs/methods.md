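# Methods

## Signal model and conventions

All coordinates are 1-based inclusive; lengths are `end − start + 1`; BED
export is the only 0-based half-open surface.  Chromosome labels are
normalized by stripping a leading `chr`; autosomes `1`..`22` drive every
wave computation, while `X`/`Y` markers are carried through but excluded
from bin features and from the moment-matching statistics.  Standard
deviations use ddof = 1 everywhere, so the Z-score identities
(per-marker mean 0, SD 1 over the fitting cluster) hold exactly under one
convention.  Missing values are NaN in memory and `NaN` on disk; any
unparseable numeric field is treated as missing rather than an error,
because array exports routinely contain no-calls.

## Quality control and PFB

A sample passes QC when its genotype call rate is ≥ 0.98 (markers with
non-missing BAF and, when a genotype column exists, genotype ≠ NC) and the
SD of its non-missing autosomal LRR is ≤ 0.2; both bounds inclusive.  QC is
applied per sample; an optional across-sample marker call-rate filter (same
0.98 default) is available for reference building.  The population B-allele
frequency is the per-marker mean of non-missing BAF across the cohort,
clamped into [0.01, 0.99] so exported tables remain usable by external
callers; unobserved markers default to 0.5.

## Wave reference

Autosomes are tiled from position 1 to the last marker in fixed bins
(default 1 Mb; the final partial bin keeps nominal width).  The clustering
feature is the per-bin mean LRR.  A bin is uninformative if it is empty in
any reference sample or if the across-sample SD of its bin means is ≤ 0.05
(inclusive); the across-sample reading was chosen because bins whose means
barely vary between samples carry no wave signal to cluster.  Residual
missing values among informative bins are mean-imputed per bin.

k-means uses Lloyd's algorithm with Euclidean distance, k-means++
initialization and 10 restarts, keeping the restart with the smallest total
*unsquared* point-to-centroid distance — the same quantity plotted on the
k-selection curve.  The cluster count is searched over k = 2..20; the curve
is extended down to k = 1 so the discrete second difference
`score(k−1) − 2·score(k) + score(k+1)` is defined at the lower end, and the
elbow is the interior k maximizing it, ties to the smallest k.  All
randomness derives from one integer seed through `numpy.random.SeedSequence`,
making reference construction bit-for-bit reproducible.

The frozen model stores, per cluster and per marker, the mean X̄ᵢ and SD Sᵢ
of LRR across member samples.  Sᵢ is floored at 1e-4 so Z-scores stay
finite at markers that happen to be constant within a cluster; every
cluster must have ≥ 2 members (ddof = 1).  Test samples never update the
model; reference members, when re-corrected, use the frozen statistics
including themselves — a simpler contract than leave-one-out refitting.

## Cluster assignment and mLRR

A query's informative-bin features (missing bins imputed with the reference
feature means) are compared to all reference samples; the cluster is the
majority label among the 5 nearest (Euclidean).  Vote ties go to the tied
label whose centroid is nearest, then to the smaller cluster index.  The
k = 5 default follows common k-NN practice; assignment accuracy on clearly
separated synthetic archetypes is ≈ 100%, so the choice is not delicate.

Z-scores are per marker: `zᵢ = (xᵢ − X̄ᵢ)/Sᵢ` — the only granularity that
cancels marker-wise wave structure.  The rescale back to LRR units is the
affine map `mlrrᵢ = (zᵢ − mean(z))·SD(lrr)/SD(z) + mean(lrr)` over jointly
present (autosomal) markers, which makes the corrected signal's first two
moments match the raw signal exactly; if SD(z) < 1e-12 the signal is
degenerate and every present marker receives the raw mean (scale recorded
as 0).  Rescaling is per sample and global — per-chromosome rescaling would
re-introduce chromosome-level offsets.

Note a structural consequence of moment matching: because the wave variance
has been removed from the signal but the target SD still contains it, the
residual (marker noise and any per-sample amplitude mismatch with the
cluster mean) is slightly inflated, by the factor SD(raw)/SD(noise).  Wave
suppression is therefore bounded below by the noise floor of whatever
statistic is used to measure it.

## HMM segmentation

States are copy numbers {0,1,2,3,4} with Gaussian LRR emissions; the
defaults (means −3.0, −0.66, 0, 0.40, 0.68; SDs 1.0, 0.28, 0.16, 0.21,
0.19) are canonical SNP-array values from the CNV-calling literature and
fully configurable — they are conventions, not fitted quantities.  The
stationary prior puts 0.995 on CN2 with the remainder split evenly.
Transitions depend on the distance d to the previous marker,
`a(s→t|d) = ρ(d)·[s=t] + (1−ρ(d))·prior[t]` with `ρ(d) = exp(−d/D)` and
D = 100 kb, so dense markers share state strongly while distant ones relax
to the prior; chromosome boundaries reset to the prior.  Viterbi ties break
toward CN2, then the smaller copy number.  An optional BAF term adds a
genotype-mixture log-density (components at the allelic fractions
achievable at each copy number, binomially weighted by the marker PFB,
truncated-Gaussian with SD 0.03; uniform for CN0); it is off by default so
the decoder's exhaustive-enumeration oracle stays simple, and there is no
copy-neutral LOH state, which is outside the screening scope.

Runs of equal non-diploid state become calls; confidence is the summed
per-marker emission log-likelihood advantage over CN2 (natural log), which
is additive under concatenation.

## Post-processing and screening

Within one caller, consecutive same-chromosome, same-direction calls whose
gap (intervening bases) is strictly below 200 kb are merged: span union,
marker counts and confidences summed, copy number of the longer
constituent.  Merging a deletion into a duplication is biologically
incoherent, hence the direction restriction.  Two callers' sets are
combined by union — every call survives; overlapping same-direction calls
collapse to their span union with confidence = max (caller confidence
scales are not commensurable) and marker count = max (summing would double
count shared markers).  The pipeline merges within caller, then combines,
then filters: n_snps > 10, length > 50 kb, confidence > 50, all strict.
A disorder is *detected* when direction-matching calls (and, if the
database row specifies one, copy-number-matching) cover a positive fraction
of the region; the minimum fraction is configurable.  The detected fraction
is the union length of call∩region over the region length.

## Synthetic cohorts

Waves are sums of 3 sinusoids per chromosome with periods 3–20 Mb and
random phases/amplitudes, rescaled per chromosome so the peak equals the
configured amplitude A (default 0.2 LRR units) — deterministic, cheap, and
period-matched to chromosome-scale drifts; archetypes are regenerated until
all pairwise correlations are < 0.5.  Each sample expresses its archetype
with a private factor s ~ Normal(1, 0.1), plus Normal(0, 0.15) marker
noise.  BAF is generated from binomial genotypes at cohort-fixed population
allele frequencies (Uniform(0.05, 0.95)), with Normal(0, 0.03) noise
clipped to [0, 1]; CN0 markers draw uniform BAF and genotype NC.  The
default genome is 22 chromosomes × 10 Mb × 500 markers (11,000 markers),
chosen so a 600-sample reference builds in seconds; real-genome dimensions
are plain configuration.

What the generator does *not* model: GC-dependent bias (waves here are
abstract smooth fields, not sequence-driven), sex-chromosome dosage, probe
clustering artifacts, and correlated (non-white) marker noise.  Passing
tests therefore demonstrate the machinery — cluster recovery, correction
identities, segmentation, screening logic — under the stated generative
model, not performance on any particular array product.

## Problem sizes and numerical choices

The acceptance computations use the default desk-scale genome: the
k-selection run builds 5 replicate cohorts of 600 samples (6 archetypes ×
100) at LRR noise SD 0.05 and searches k = 2..20 (~30 s total); deletion
recovery uses 100 carriers of 150-marker heterozygous deletions under
A = 0.3 waves against a 300-sample reference; the Viterbi decoder is
checked against exhaustive enumeration over all 5ⁿ paths for 200 chains of
up to 8 markers.  Known limitation: on CNV-free waved samples with the
default amplitude jitter (SD 0.1), per-bin wave suppression averages ~72%
but individual samples with a large amplitude mismatch retain proportionally
more residual wave — suppression of a fixed 70% for essentially all samples
would require smaller per-sample amplitude variation than the generator's
default, which is kept as the stated study condition.
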