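# Methods

This note documents the statistical model behind `bedmr`, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the package's numerical conventions.

## Data model and coordinates

All coordinates are 0-based, half-open (BED convention). SEG input may be
declared 1-based and/or log2-scaled via reader flags and is normalized on
read. Only autosome-style fixed chromosome sets are modeled; a genome is an
ordered list of (name, length).

A segmented profile must tile each chromosome exactly; adjacent segments
with identical ratios are merged during validation, so that every internal
boundary — a *breakpoint* — marks an actual copy-state transition.
Segmentation output (e.g. CBS) already has this property; merging only
protects against synthetic or foreign input. Chromosome ends are never
breakpoints.

## CNV windows and copy states

The window partition is the cut of each chromosome at the union of all
samples' breakpoint positions. This makes the partition a refinement of
every sample's segmentation: no sample changes copy ratio inside a window
(verified by a brute-force property test). Copy states use strict
thresholds — amplified above 1.1, deleted below 0.9, normal otherwise, with
a ratio exactly at a threshold called normal. The thresholds are empirical
allowances for measurement noise around 1 on ratio-scale array data and are
exposed as configuration, not constants.

## Breakpoint-enriched regions (BERs)

Breakpoints of all samples are pooled per chromosome **with multiplicity**
(a boundary shared by k samples contributes k kernels) and smoothed by a
Gaussian KDE. The bandwidth parameter is the **kernel standard deviation**;
the default 1 Mb is large relative to ~40 kb probe spacing, merging
segmentation jitter into single hotspots. The density is evaluated on a
50 kb grid (≥ 20 points per bandwidth, below the probe resolution) by exact
summation — no binning or FFT approximation — so the track equals direct
kernel summation to floating-point accuracy. No boundary correction is
applied; kernels are truncated at chromosome ends, which biases the density
downward within ~2 bandwidths of telomeres.

BER centers are strict interior local maxima of the gridded density. By
default every local maximum is a BER; `min_prominence` (a fraction of the
chromosome's maximum density, applied to topographic peak prominence)
suppresses shallow ripples of the background. The filter is per-chromosome,
so on a chromosome with no genuine hotspot the relative filter cannot
separate background ripples from "peaks" — calibration experiments should
plant hotspots on every chromosome they score, as the acceptance script
does.

## Trinary methylation calls

Fragment-level log-ratios are modeled as a three-component 1-D Gaussian
mixture (low / intermediate / high methylation) fitted by EM on the pooled
fragment × sample values. Initialization is a deterministic 1-D k-means
seeded from evenly spaced quantiles, so the fit does not depend on a random
seed at all. The E/M updates are standard; a variance floor
(max((10⁻³ × data range)², 10⁻¹²)) guards components collapsing onto
duplicated values and flips a `degenerate` flag when hit. The per-iteration
log-likelihood trace is retained and is non-decreasing (asserted in tests);
non-convergence within `max_iter` warns and returns the best-so-far model.

A value is called +1 when the posterior of the top component reaches
`posterior_cutoff` (default 0.8), −1 symmetrically for the bottom
component, else 0. The cutoff keeps ambiguous values uncalled instead of
forcing them into a tail state; 0.8 is a deliberate middle ground — high
enough that calls are confident, low enough that well-separated components
call their own centers. Non-finite inputs become missing calls. Pipelines
whose input already carries trinary calls bypass this module entirely.

## DMR detection (Hotelling's T²)

Each fragment's triplet (n₊₁, n₀, n₋₁) counts its calls across samples.
The null is the genome-wide triplet distribution, summarized by the mean μ₀
(and covariance B, reported but not used by the statistic) over all
fragments. For a window with n ≥ 4 fragments:

- μ_X = mean triplet, S = sample covariance (divisor n − 1);
- T² = n (μ_X − μ₀)ᵀ S⁺ (μ_X − μ₀) with S⁺ the Moore–Penrose
  pseudo-inverse;
- p = effective rank of S; F = ((n − p)/(p(n − 1))) T² with an
  F(p, n − p) null distribution.

The pseudo-inverse/rank treatment matters: with a complete call matrix each
triplet sums to the sample count, the three components are linearly
dependent and rank(S) = 2, while missing calls restore rank 3. Using the
rank as the dimension parameter keeps the statistic well defined in both
regimes. Degenerate windows (rank 0) are at the baseline (T² = 0, p = 1) or
deterministically off it (p = 0).

The i.i.d.-normal assumption behind the F transform is an approximation for
multinomial-count triplets; the null-calibration acceptance check (2000
null windows of 10 fragments at 40 samples) shows the resulting p-values
are near-uniform (KS statistic ≈ 0.02) and the q < 0.01 call rate is
conservative.

p-values are BH-adjusted across tested windows, and the 10⁻² significance
threshold is applied to the **adjusted** value (otherwise the FDR step
would be inert); a flag switches to raw-p thresholding. Direction is the
signed excess of the +1 versus −1 mean frequency relative to baseline
(ties broken toward the larger absolute component deviation); the score is
−log₁₀(p) for hyper- and +log₁₀(p) for hypo-methylated windows, so a
two-sided score track reads symmetric around zero with |score| > 2 marking
significance. p-values are floored at 10⁻³⁰⁰ to keep scores finite.

Windows with fewer than 4 fragments are skipped (n − 1 ≥ 3 is required by
the F transform at p ≤ 3); the baseline defaults to the tested call set's
own genome-wide estimate but can be supplied externally (e.g. from
normals).

## DMR–BER co-localization

Distances are measured from DMR window midpoint to BER center; DMRs on
BER-free chromosomes get infinite distance and are excluded from curves
(but counted). The observed statistic is the cumulative fraction of DMRs
within d of the nearest BER, on a 0–10 Mb grid at 0.1 Mb steps.

The null redraws DMR locations while keeping BERs (the genome architecture)
fixed, preserving each chromosome's DMR count. Three spacing families are
fitted to the observed inter-DMR distances: uniform on [0, max], normal by
moments, gamma by maximum likelihood (location pinned at 0, via
`scipy.stats.gamma.fit`). For the normal/gamma families randomized
locations come from a renewal walk — uniform start, successive spacings
cumulated, restarting from a fresh uniform start when the walk leaves the
chromosome (with a restart cap that turns persistent overflow into an
error). For the uniform family positions are drawn i.i.d. uniform — the
natural "random locations" null; a renewal walk with uniform increments
would not have uniform marginals.

Per grid distance, the observed cumulative count is ranked within the
`n_rand` null counts: p(d) = (1 + #{null ≥ obs}) / (n_rand + 1), bounded
below by 1/(n_rand+1) (hence the n_rand ≥ 100 warning). An alternative
`ranksum` mode tests observed vs pooled null distances truncated at d with
a one-sided Mann–Whitney test; both modes are exposed because the
literature's per-distance "Wilcoxon" construction is underdetermined, and
the rank-of-observed form is the one that is well defined for a single
observed curve. BH adjustment runs across grid points; d* is the distance
of minimal adjusted p. A fitted gamma hugs the observed spacing shape most
closely, so its randomizations are hardest to beat — the stringency
ordering (uniform least, gamma most stringent) is asserted on planted
signal in the tests.

BEDMRs are DMRs whose nearest BER lies within the call threshold — 1 Mb by
default, or d* when `use_dstar_threshold` is set.

## Alu enrichment

The genome is tiled with non-overlapping 100 kb windows ("non-overlapping
sliding window" resolves to a tiling; a stride flag would re-enable
overlap, and tiling keeps window counts independent). An element is counted
in the window containing its start, so boundary-spanning elements count
once. Families match by prefix (AluJ covers AluJb, AluJo, …).

A region of interest is padded symmetrically to span at least 3 whole
windows — a single window would give a one-element sample and a degenerate
rank-sum test. Its window counts are compared with all genome windows
(its own excluded) by a one-sided Mann–Whitney test; BH runs jointly across
regions × families and q < 0.001 flags enrichment. Each BEDMR is flagged
when an enriched region's midpoint lies within 3 Mb. Pooling windows per
region (rather than testing each window separately) is the primary reading;
it trades per-window resolution for a non-degenerate test.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical* structure the pipeline relies
on, at reference conditions chosen to mirror tumor-cohort array studies:

- cohort imbalance: 100 tumors / 10 normals by default;
- breakpoints: per sample and chromosome, Poisson-many positions
  (`background_bp_rate` per Mb) drawn from a mixture — probability
  `hotspot_weight` from a Gaussian around a planted hotspot (sd 200 kb by
  default), else uniform; segment ratios cycle normal (1.0 ± 0.03) →
  amplified (1.3 ± 0.05) → normal → deleted (0.7 ± 0.05) so the 1.1/0.9
  thresholds separate regimes;
- methylation: fragments every 20 kb (the fragment-per-CpG-island density
  of a MOMA-like platform is ~18 kb genome-wide); calls i.i.d. per sample
  from a baseline probability vector (0.25, 0.50, 0.25) — the canonical
  (10, 20, 10)-of-40 triplet — and, in planted windows (tumors only), from
  the shifted vector (0.75, 0.075, 0.175), i.e. the illustrative
  (30, 3, 7) triplet. Only windows with ≥ 4 fragments are eligible for
  planting, since smaller windows are untestable downstream;
- repeats: homogeneous Poisson background of one element per 3 kb (the
  genomic Alu insertion density), family labels AluJ/AluS/AluY at weights
  0.25/0.55/0.20 (AluS is the most abundant class), intensity multiplied
  by `alu_cluster_fold` inside planted clusters.

It does **not** emulate probe-level hybridization noise or segmentation
error (profiles are emitted as segments directly — segmentation is out of
scope), firestorm-like clustered amplicon patterns, chromosome-specific
breakpoint rates, GC/mappability structure, or correlated methylation
between neighboring fragments. Passing tests therefore demonstrate the
statistics recover planted signal under the stated generative model, not
robustness to platform artifacts.

Reproducibility: one global seed feeds per-stage substreams (stage name
CRC32-keyed into a `SeedSequence`), so a stage re-run in isolation sees the
same stream and two identical configs give byte-identical output bundles
(asserted end-to-end).

## Numerical conventions and edge cases

- Hotelling: `numpy.linalg.pinv/matrix_rank` with hermitian=True; T²
  clipped at 0 against round-off; exact-baseline windows short-circuit to
  p = 1.
- BH FDR: `statsmodels.stats.multitest.multipletests(method="fdr_bh")`.
- Gamma ML: `scipy.stats.gamma.fit(floc=0)`; non-positive spacings are
  dropped with a warning; near-constant spacings get an sd floor
  (normal) / a large-shape point-mass surrogate (gamma) and a degeneracy
  flag.
- KDE: exact chunked summation (2048 points per block) — O(n·grid) but
  cache-friendly; empty chromosomes yield empty tracks, not errors.
- Rank-sum: `scipy.stats.mannwhitneyu` (exact method where SciPy selects
  it; the 3-vs-10-window case is verified against full enumeration in the
  tests).
- Problem sizes in tests and the acceptance script (e.g. 2000 null windows,
  100 oracle windows, 1000 randomizations, 100-sample hotspot recovery)
  were chosen so the whole suite completes in well under a minute while
  keeping Monte-Carlo noise far from the asserted margins.

## Known limitations

- The F-distribution null is asymptotic in the normality of triplets;
  very small sample counts per fragment (≲ 10 samples) discretize the
  statistic and would need a permutation null instead.
- The per-chromosome prominence filter for BERs is relative; absolute
  density thresholds may suit cohorts with very uneven chromosome-level
  rearrangement rates better.
- Randomization nulls condition on per-chromosome DMR counts but not on
  masked/gapped regions; genomes with large assembly gaps would need a
  mask-aware redraw.
- The EM fit is global (one mixture for the whole matrix); platforms with
  strong per-sample intensity shifts should be normalized per sample before
  calling.
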