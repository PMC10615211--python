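# Methods

This note documents the models and procedures granulekit implements,
the defaults it fixes where the underlying laboratory workflow leaves a
choice open, and what its synthetic-data tests do and do not establish
about real instrument data.

## Particle-size data and distributions

The instrument observable is a granule diameter *d* in µm, delivered
either as a raw per-particle list or as counts on half-open diameter
bins `[lower, upper)`. A diameter exactly on an upper edge belongs to
the next bin; this convention is fixed so that binning a raw list
conserves the total particle number exactly. Bins must be strictly
increasing and non-overlapping; gaps are allowed (instrument exports
sometimes omit empty channels). All diameters are micrometres
throughout — there is no unit-conversion layer, by design, to prevent
silent unit errors.

The representative diameter of a bin is the **geometric mean** of its
edges. Granule size distributions are log-scale objects (they are
modelled as log-normal mixtures below), and the geometric mean is the
midpoint on that scale; for the narrow log-spaced bins of a typical
export the difference from the arithmetic midpoint is negligible, but
the choice matters for coarse grids.

Two relative distributions derive from the same counts:

- *number weighting* — a bin's share is its count;
- *volume weighting* — a bin's count is scaled by the sphere volume
  (π/6)d³ at the bin's representative diameter before normalising.

Shares are percentages summing to 100 (enforced to 1e-9).

**Percent of granules smaller than a threshold** (default 10 µm, a
conventional B-type proxy since the B population plus the smallest
A-type granules sit below it) is a strict-inequality count on raw
data. On binned data, bins entirely below the threshold count in full;
a straddling bin is split pro-rata by log-width — exact when the
threshold coincides with a bin edge, and a documented deterministic
interpolation otherwise. Both paths are provided because it is
generally unknown whether an instrument export was computed from raw
pulses or binned channels; the two agree to within one bin's share.

**Granules per mg fresh weight** follows volumetric-mode counting: the
counter analyses a fixed aliquot (typically 2 mL) of a suspension of
known total volume, so

    granules/mg = count × (total volume / analysed volume) / fresh weight.

A per-sample QC flag warns (never fails) below 100,000 measured
particles, the conventional floor for a well-powered size
distribution; the bound is inclusive.

## Log-normal mixture deconvolution

The volume-vs-diameter curve of mature wheat endosperm starch is
bimodal: a small-diameter B-type component and a large-diameter A-type
component. granulekit models the **volume-share density per unit
ln d** — shares divided by the log bin width — as a one- or
two-component normal mixture in ln d. Fitting the density rather than
the raw percent-vs-diameter curve makes the objective independent of
the binning grid: refitting the same sample exported on a different
grid gives the same parameters.

Estimation is bounded multi-start local least squares
(`scipy.optimize.least_squares`, trust-region reflective):

- starts: a fixed grid of σ ∈ {0.15, 0.3, 0.5} per component and
  B-weight ∈ {0.1, 0.3, 0.5}, centred on 5 µm and 20 µm medians with a
  small seeded jitter; 16 starts by default;
- bounds: median ∈ [0.5, 60] µm, σ ∈ [0.02, 1.5], weight ∈ (0, 1);
- tolerances: 1e-10 on the cost change, at most ~500 iterations per
  start; the lowest-SSE converged start wins, ties broken by start
  index. Given a seed the whole fit is deterministic.

Components are labelled by median: **B is always the smaller-median
component**, regardless of optimiser ordering, so relabelling of
starts never changes the reported phenotype. Derived metrics:

- **B-type granule volume percentage** = 100 × weight(B): the share of
  total starch volume held by B-type granules. A unimodal fit reports
  0 by definition.
- **mean diameter** per component = exp(μ + σ²/2). Because the fit is
  performed on the volume-weighted distribution, this is a
  volume-weighted mean diameter; users needing number-weighted moments
  can shift μ by −3σ² (the log-normal size-bias relation) before
  applying the same formula.

Number-weighted distributions are rejected as fit targets: the A-type
peak is so small on a number basis that a two-component fit to it is
unreliable.

### Model-order choice

Early-development samples (before B-type initiation, ~8–14 dpa) and
genotypes lacking B-type granules are unimodal, and a caller can force
a one-component fit. In automatic mode a two-component fit is demoted
to one component when any of three signs marks the second component as
spurious:

1. minor weight below 0.02 — too small to be a credible population;
2. Ashman's D = |μ_A − μ_B| / sqrt((σ_A² + σ_B²)/2) below 2 — two
   Gaussian components with D < 2 cannot produce a bimodal density, so
   the optimiser has merely split a single peak into two overlapping
   halves (this is the common failure mode on unimodal data, where the
   split can carry minor weights up to ~0.15);
3. SSE(two components) > 0.7 × SSE(one component) — a genuine second
   mode reduces the residual sum of squares several-fold, whereas a
   component that only absorbs counting noise barely improves it.

The weight floor alone proved insufficient in testing (signs 2 and 3
catch peak-splitting and noise-shoulder fits that pass it); the three
criteria together classify all synthetic presets correctly across
seeds. Each threshold is an exposed parameter.

## Amylose colorimetry and starch content

Apparent amylose content is the empirical exponential calibration
1.4935·exp(2.7029·A620/A535) of iodine-complex absorbances. The
constants are treated as fixed; the function is strictly increasing in
the ratio and depends on the absorbances only through it. Outputs are
**not clamped** to [0, 100]: an out-of-range value signals an assay
problem and is returned with a warning rather than hidden.

Starch content is reported in glucose equivalents — 100 × (mg glucose
released by amylase/amyloglucosidase digestion) / (mg sample) — with an
optional 162/180 anhydro-glucose correction for users who want polymer
mass instead of glucose equivalents.

## Pulldown enrichment

Per protein, three pulldown and three control replicate abundances
yield a ratio mean(pulldown)/mean(control), capped at 100, and a Welch
(unequal-variance) two-sample t-test on natural-log abundances, with a
p-value floor of 1e-17. Cap and floor mirror the saturated values that
proteomics software writes into exports and keep outputs comparable to
published tables; both are configurable. The Welch test is this
package's replacement for the proprietary background-based test used
by acquisition software — a documented substitute, not a
reimplementation, so exact p-value agreement with published tables is
not claimed (the printed reference list is used to validate the
*filter*, whose inputs are the printed ratios and p-values themselves).
Missing abundance values are rejected, not imputed.

Benjamini–Hochberg adjustment is the standard step-up procedure
(via `statsmodels`), and the default filter retains proteins with
ratio ≥ 2 and **raw** p < 0.05 — the criterion as conventionally
stated — with BH-adjusted filtering behind a flag. Degenerate
zero-variance rows get p = 1 when the group means agree and the floor
when they differ.

## Group comparisons

One-way ANOVA (scipy) with Tukey's HSD post hoc test; unbalanced
designs (replicate n varies between roughly 3 and 16 in typical
experiments) use the Tukey–Kramer studentized-range statistic. The
compact letter display uses the insert-and-absorb algorithm: start
with one letter column holding all groups; for each significantly
different pair, split every column containing both; absorb columns
that are subsets of others. Groups are processed and letters assigned
in descending-mean order, so the highest-mean group carries "a" — the
convention in crop-phenotyping tables. The all-identical degenerate
input maps to F = 0, p = 1.

## Synthetic data

Generators exist so every stage is testable without instrument data,
and their defaults define the conditions under which the test suite's
quantitative claims hold.

Granule populations are drawn from log-normal mixtures parameterised
on the **volume scale** — (median µm, σ of ln d, volume weight) as the
components would appear on a relative-volume plot — because that is the
scale of the downstream fit. Particle sampling uses the analytic
size-bias conversion: volume-weighting a log-normal LN(μ, σ) gives
LN(μ + 3σ², σ), so the number-scale median is the preset median
shifted by −3σ² in log, and number weights are
n_k ∝ v_k·exp(−3μ_k^num − 4.5σ_k²). A fit to the volume-weighted
distribution of a generated population therefore recovers the preset
parameters directly. Counts land on a default grid of 256 log-spaced
edges over 1.4–42 µm (a plausible measuring range for a 70 µm
aperture) either as a multinomial draw (counting noise) or as a
deterministic largest-remainder allocation. The raw-diameter sampler
truncates to the grid range by resampling (< 1e-3 tail mass for all
presets), so raw and binned draws describe the same population.

Genotype presets encode the **direction** of the reported mutant
phenotypes, not measured figure values:

| preset           | B component (median, σ, vol. weight) | A component |
|------------------|---------------------------------------|-------------|
| `WT`             | 5.0 µm, 0.30, 0.30                    | 21 µm, 0.22, 0.70 |
| `phs1_like`      | 7.5 µm, 0.30, 0.12                    | 21 µm, 0.22, 0.88 |
| `bgc1_like`      | —                                     | 21 µm, 0.22, 1.00 |
| `unimodal_early` | —                                     | 10 µm, 0.35, 1.00 |

i.e. the *phs1*-like preset has fewer (by volume) and larger B-type
granules; the *bgc1*-like preset lacks the B component entirely. The
developmental series (8, 14, 18, 22 dpa) is unimodal at 8/14 dpa with
a growing A median, and bimodal from 18 dpa with the B weight rising
toward the mature value — mutant series reach lower B weights with
larger B medians.

Proteomics tables spike `n_enriched` = 20 proteins (default log-fold
effect ln 4) into 200 background proteins with unit true ratio;
baseline log-abundances are N(ln 1e6, 1) and replicate scatter is
log-normal with CV 0.2 (σ_log = sqrt(ln(1+CV²))). Three replicates per
condition match the standard design. Under these defaults the filter's
mean sensitivity exceeds 0.9 and its false-discovery proportion stays
within 2α over 50 seeded runs.

**What the generators do not emulate:** instrument coincidence
effects, aperture noise and channel-edge artefacts; non-log-normal
tails of real granule populations; correlated replicate structure,
missing values and between-run normalisation in real proteomics data;
and any mechanistic model of granule initiation kinetics. Passing
parameter-recovery tests therefore establishes the correctness of the
estimators under the stated statistical model, not the adequacy of the
log-normal mixture for any particular real sample — that adequacy is a
modelling assumption carried over from standard practice in the field.

## Problem sizes and determinism

Parameter-recovery checks use 20 seeded simulations of 1e5 particles
(the QC floor for real samples) from a fixed bimodal truth; the
spiked-table power checks use 50 seeds; the null calibration 100
seeds. Every stochastic routine takes an explicit integer seed and is
bit-reproducible given it; multi-start fitting is deterministic
including its tie-break. All tolerances asserted by the tests (median
relative error ≤ 5% on log-parameters, ≤ 0.05 absolute on the B
weight, one bin's share for binned-vs-raw counting agreement) are
stated in the tests themselves.

## Known limitations

- Components beyond two are out of scope; compound-granule or
  multimodal distributions need a different model.
- The mixture is fitted to binned densities by least squares, not by
  maximum likelihood on raw particle lists; for very coarse grids the
  midpoint-density approximation biases σ slightly upward.
- The amylose calibration's validity range is inherited from its
  source assay and is not checked beyond the [0, 100] warning.
- Tie-handling in the letter display (groups with exactly equal means)
  follows stable sort order of the input, which is deterministic but
  arbitrary.
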