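# Methods

## Scope and data model

The package quantifies two things: (i) co-occurrence of fluorescence bands
between two antibody channels along traced polytene chromosome segments,
compared across genotype conditions; (ii) overlap and coverage structure of
two ChIP-seq peak sets. It starts from the traced line profile (a table of
positions in μm and per-channel intensities) and from standard BED/bedGraph
files; microscopy, image segmentation, read alignment and peak calling are
upstream of the package and out of scope.

The experimental design mirrored throughout is: per genotype condition,
≥ 5–6 larvae; per larva, three traced segments whose colocalization
percentages are averaged, so the larva is the independent unit entering the
condition comparison.

## Band detection

A band is a strict interior local maximum of one channel's trace. Two
conventions the trace data force us to fix:

- **Plateaus.** Digitized intensities produce runs of equal values. An
  interior plateau strictly above both flanking samples contributes exactly
  one candidate, at its midpoint sample (left midpoint for even-length
  runs). This is symmetric and deterministic. Trace endpoints are never
  maxima (one-sided neighborhoods).
- **Thresholding and pruning.** Candidates below 20% of the trace's own
  maximum (per segment, per channel) are discarded as background; the
  maximum is the trace's own because staining intensity is not comparable
  across preparations. Remaining candidates are accepted greedily in
  descending height order (ties broken by smaller position), each required
  to lie ≥ 0.6 μm from every previously accepted band. Distances are
  measured on the μm positions axis, not in samples, so resampled traces
  give the same bands.

An all-zero channel yields an empty band set (its relative threshold is
undefined); no baseline subtraction, smoothing or sub-sample interpolation
is applied — the statistic is about raw trace maxima.

## Colocalization and inference

Band matching across channels is one-to-one greedy by ascending pair
distance within a tolerance defaulting to the same 0.6 μm used for
within-channel separation (a single spatial resolution scale; one-to-one
matching prevents a wide band in one channel from being counted against two
bands in the other). The segment statistic is
100 · 2m / (n_A + n_B) with m matched pairs, so matched bands count on both
sides of the denominator and identical band sets score exactly 100%. A
segment with no bands in either channel is 0/0, flagged undefined, and
excluded from its larva's mean; a larva with no defined segments is dropped
with a warning.

The condition comparison permutes larva labels over the pooled per-larva
means, preserving group sizes, with the difference of means as statistic
and two-sided extremeness via |Δ|. With C(n, n_A) ≤ the permutation budget
the null is enumerated exhaustively (exact tail fraction; never zero since
the observed arrangement is in the tail); otherwise Monte-Carlo with the
add-one correction (count+1)/(N+1). Ties with the observed statistic are
counted as extreme, with a relative tolerance of 1e-9 absorbing float
round-off in the mean differences. All pooled values identical is reported
as p = 1 with a warning. For the default 6-vs-6 design, C(12,6) = 924, so
even modest budgets trigger the exact test; its p-values live on the 924
grid and the test is marginally conservative rather than anti-conservative.

`ColocalizationModel` / `ColocalizationResults` package this as a
model-object pair: the model holds the per-larva table and the control
label; `fit()` runs one permutation test per non-control condition and the
results object carries the estimates, tests, `summary()` and `plot()`.

## Synthetic profiles

The generator emulates what the analysis assumes about real traces, not the
optics: a constant background (default 10 intensity units), Gaussian bands
(σ = 0.2 μm) at rejection-sampled centers, additive Gaussian noise
(sd = 2) truncated at zero, and a smooth positive DNA-counterstain envelope
that carries no band information but keeps the file format faithful.
Defaults: 60 μm segments sampled at 0.05 μm, 10 bands per channel.

Key choices:

- **Planted truth is exact.** `coloc_fraction` ρ places round(ρ·n_B) B
  bands exactly at A centers (optional center jitter, default 0, separates
  generator truth from detector tolerance). Non-co-placed B centers are
  kept ≥ `min_band_spacing` from *all* A centers as well as from other B
  centers; with the default spacing (1.2 μm = 2× the matching tolerance)
  chance co-occurrence is excluded and ρ is the true colocalization
  fraction, not just a lower bound. Packing that cannot satisfy the spacing
  fails loudly after a bounded number of rejection-sampling attempts.
- **Band brightness spans faint to bright** (amplitudes uniform on 5–120
  over the background of 10). Faint bands near background are the reason a
  relative detection threshold exists at all, and their stochastic loss
  under the 20% threshold is the generator's model of measurement
  variability: it makes per-larva percentages vary the way repeated scoring
  of real preparations does. Were all bands bright, every simulated larva
  would recover the planted percentage exactly and any two equal conditions
  would be degenerate (zero variance), which no real experiment is.
- Grouped sampling spawns per-segment generators deterministically from a
  master seed, so a condition is reproducible bitwise.

What the generator does **not** emulate: spatially correlated background,
band asymmetry and width variation, tracing errors, chromosome stretching,
and larva-level biological variation in the true colocalization fraction
(all segments of a condition share one ρ). Passing recovery and calibration
tests therefore show the estimator and test behave correctly when the
model's assumptions hold; they do not certify the 0.6 μm/20% parameters as
optimal for any particular microscope or antibody.

## Simulation studies

- *Type-I calibration:* both conditions drawn from one normal distribution
  (mean 50, sd 10 percentage points, n = 6 per group), 2,000 replicates;
  empirical rejection at α = 0.05 is checked against the exact binomial 99%
  interval. The 6-vs-6 design puts the test in exhaustive mode, whose exact
  rejection rate at α = 0.05 is 44/924 ≈ 0.048.
- *Recovery:* ρ ∈ {0, 0.25, 0.5, 0.75, 1} at 6 larvae × 3 segments; the
  recovered mean percentage is monotone in ρ and within 10 points of 100ρ
  (faint-band loss biases extremes slightly toward the interior).
- *Power:* ρ = 0.9 vs ρ = 0.2 at n = 6 rejects at p < 0.01 in ≥ 95% of
  replicates; equal-ρ comparisons give p-values uniform up to the 924-grid
  discreteness.

Problem sizes (1,000 random traces for the detector reference comparison,
2,000 calibration replicates, 200 power replicates, 500 random peak-set
pairs) were chosen so each study estimates its rate with useful precision
while the whole verification runs in well under a minute per study on one
core.

## Genomic interval computations

BED and bedGraph are parsed strictly (0-based, half-open; malformed lines
reported by line number); bedGraph gaps are coverage 0. Peak sets are
merged on load so "percentage of peaks" is well-defined; strand is ignored
(transcription-factor-style peaks). A peak overlaps the other set iff it
shares ≥ 1 bp (parameterizable) with one of its intervals — adjacency under
half-open coordinates is not overlap. The sweep exploits that merged sorted
intervals have increasing ends, so the candidates for a query are one
contiguous index range found by two binary searches.

Coverage matrices take, per peak, the per-bp coverage over
[mid − w/2, mid + w/2) with w = 4,000 bp by default, midpoint =
floor((start+end)/2) (summit positions are not part of BED3), positions
outside the covered extent contributing 0, then log2(x + pseudocount) with
pseudocount 1 — so zero coverage maps to 0 and the transform is exactly
invertible, which the signal-conservation identity in the tests exploits.
Row sorting is a stable descending sort on the reference matrix's row
means, ties keeping coordinate order; composite profiles are column means.

## Known limitations

- Band positions are reported at sample resolution; no sub-sample peak
  interpolation (by design, but it bounds matching precision at the
  sampling step).
- The matching tolerance and detection distance share one default; traces
  with systematically wider bands would need both raised together.
- `CoverageTrack.window` materializes dense per-bp windows; fine for
  peak-window extraction at desk scale, not intended for whole-chromosome
  dense operations on large genomes.
- Percentages are inherently discrete (band counts), so permutation
  p-values on small designs are grid-valued; report them as computed rather
  than comparing to continuous-distribution critical values.
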