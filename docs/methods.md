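# Methods

## Problem setting

Capillary-electrophoresis STR genotyping reports every detected peak at
or above an *analytical threshold* (AT): the minimum height in relative
fluorescence units (RFU) at which a peak is considered distinguishable
from baseline noise. Kit manufacturers recommend conservative static
settings (commonly 150–200 RFU). For low-template DNA (≲ 32 pg input)
true allelic peaks routinely fall below such settings and drop out
(Type II error), while lowering the threshold indiscriminately admits
stutter, pull-up and instrument noise (Type I error). The package
implements the workflow of deriving per-dye ATs from the laboratory's
own negative-control baseline and quantifying the resulting error
trade-off.

## Negative-signal cleaning

Negative controls analyzed at a 1-RFU threshold yield a sizing table of
baseline signals. Two filters are applied before any statistics:

1. **Read region** — only signals with size inside the manufacturer's
   recommended window (closed interval, boundaries retained) are kept.
2. **ILS proximity** — signals within 2.0 bp (inclusive) of any
   internal-lane-standard fragment are removed, because the strong ILS
   peaks bleed into neighbouring dye channels; signals on the ILS dye
   itself are always excluded. Proximity is measured in base pairs, not
   scan points. The inclusive reading of "within 2 bases" is a choice;
   it removes marginally more signal, which is the conservative
   direction for a noise model.

For low-template positive profiles the cascade is instead: **locus
screening** (keep peaks inside some marker interval on their own dye;
off-ladder labels do not force removal, position alone decides) followed
by **pull-up removal** (drop a peak iff an allelic peak in a *different*
dye lies within ±0.3 bp and the peak's height is ≤ 5 % of that allelic
peak's height; both comparisons inclusive; when several allelic peaks
qualify positionally the tallest governs, which removes the most).

Every filter emits an audit report whose counts reconcile exactly
(input = removed + retained) with a closed set of removal reasons.

## Baseline statistics

Per dye, the heights of all retained negative signals are pooled across
injections. Reported are the count, the mean Ȳₙ and sample SD s_{Y,n}
(n − 1 denominator), the mean υ and sample SD τ of the natural-log
heights, percentiles (0.5, 0.95, 0.99) and the maximum. The number of
injections nₙ is carried separately: the t-based estimators below use
nₙ as the sample count even though the moments pool all signals — a
mixed convention that follows the published threshold table, which is
footnoted as computed from nine negative controls.

Negative controls are grouped by calendar quarter (S1 = Jan–Mar …
S4 = Oct–Dec) of their run date to track baseline drift. Group
comparisons (quarters, laboratories, cycle numbers) use a two-sided
Mann–Whitney U test with the asymptotic normal approximation and tie
correction — chosen because RFU heights are right-skewed and the test
is the field's default for such data — with p-values banded into the
conventional stars (\* 0.01 < p ≤ 0.05 through \*\*\*\* p ≤ 0.0001).

Lognormality of the heights is assessed by fitting Normal(υ, τ²) to the
log heights and computing a Kolmogorov–Smirnov statistic against the
fitted distribution. Because the parameters are estimated from the same
sample the p-value is approximate (Lilliefors situation); the statistic
is reported as a descriptive goodness-of-fit index, not a calibrated
test.

## Threshold estimators

Six per-dye threshold sets are produced:

| method | formula | interpretation |
|---|---|---|
| AT_ori | 175 RFU (configurable) | conventional static setting |
| AT1 | Ȳₙ + k·s_{Y,n} | k-sigma rule, k = 3 |
| AT2 | Ȳₙ + t(α, ν)·s_{Y,n}/√nₙ | upper confidence limit on the mean |
| AT3 | Ȳₙ + t(α, ν)·√(1 + 1/nₙ)·s_{Y,n} | prediction limit for a future signal |
| AT4 | 99 % empirical quantile | value separating 99 % of negative signals |
| AT5 | exp(υ + k·τ) | lognormal-model k-sigma rule |

with ν = nₙ − 1 and α = 0.99 one-sided. Design choices that the source
material leaves open, fixed here:

- **α = 0.99.** No confidence level is stated for the t-based methods;
  0.99 is consistent with the 99 % separation of AT4 and the ≈ 99.7 %
  one-sided coverage of k = 3.
- **τ is a standard deviation.** The lognormal estimator is sometimes
  written with τ called a variance; exponentiating υ + 3·(variance)
  would not reproduce the characteristic AT5-is-largest pattern, so τ
  is interpreted as the SD of log heights throughout (with the n − 1
  denominator, matching s_{Y,n}).
- **Quantile rule.** AT4 uses linear interpolation between order
  statistics (`numpy.quantile`, method "linear").
- **Rounding.** Reported thresholds are rounded *up* to integer RFU and
  floored at 1 (conservative for noise exclusion); raw real values are
  available with `rounding="none"`. Published threshold tables print
  integers but do not state their rounding rule, so exact back-derivation
  of printed values is not asserted anywhere.

Structural facts used as test invariants: AT2 < AT3 whenever s > 0
(1/√n < √(1+1/n)); AT1 ≤ AT3 whenever t(α, ν)·√(1+1/nₙ) ≥ k (true for
nₙ = 9, α = 0.99, k = 3); all five estimators are equivariant under
uniform height scaling (pre-rounding); on baseline-like data AT2 is the
per-dye minimum and AT5 the per-dye maximum of the five.

Dyes with fewer than two pooled signals are flagged per method rather
than failing the whole computation; AT_ori is always available.

## Evaluation against a reference genotype

A peak of a screened profile is **allelic** when its size lies within
±0.5 bp of the bin center of an expected allele at its annotated marker
(the bin half-width is the convention genotyping software applies), and
**non-allelic** otherwise. Expected alleles carry no dosage: a
homozygous marker contributes one expected allele, and detection is
presence/absence with no heterozygote-balance logic.

Rates per evaluation cell: TPR = detected/expected; the **FPR
denominator is a package convention** — non-allelic peaks divided by
expected alleles, capped at 1 — because the source material reports
total errors above 1 without defining a Type I denominator. This makes
the two error terms commensurate, bounds total error
(1 − TPR) + FPR by 2, and places a fully dropped-out artifact-free
profile at exactly 1.0. Comparisons across methods within this package
are unaffected by the convention; absolute FPR values are not
comparable to other software.

Threshold sweeps (1–200 RFU) exploit that peak labels are
threshold-independent: each replicate is classified once, the tallest
peak per detected allele fixes the threshold at which that allele drops
out, and counts at all thresholds follow from sorted height arrays.
Dropout curves are non-decreasing and non-allelic curves non-increasing
in the threshold by construction, and flatten at the count of alleles
absent from the raw data.

ROC comparison: per condition (template mass × cycle number), each
method's (FPR, TPR) point is ranked by Euclidean distance to the ideal
corner (0, 1); distances equal up to 10⁻⁹ count as tied and resolve
toward the lower FPR (the conservative side).

## Synthetic data

The generator emulates the published study design as its default stated
world: control-DNA dilutions of 31.25 / 15.625 / 7.8125 pg amplified at
27 / 29 / 31 cycles, three PCR replicates each injected three times
(81 positive tables), plus nine negative controls per cycle number
(27 negative tables).

- **Baseline noise** per dye: Poisson(10) signals per injection, sizes
  uniform over the read region, heights lognormal. Default per-dye
  parameters (log-mean 2.00–2.45, log-SD 0.25–0.38) put typical heights
  at 7–12 RFU with maxima of a few tens of RFU and make the blue dye
  lowest and the purple dye highest/broadest — the qualitative pattern
  reported for 6-dye chemistries. No published per-dye numbers exist;
  these values are fixed once and not tuned.
- **Allelic peaks**: median height 60 RFU at the 31.25 pg / 27-cycle
  reference, scaled linearly in template and ×2 per cycle, with a
  lognormal amplification factor (log-SD 1.0) drawn per allele per PCR
  replicate and a lognormal injection factor (log-SD 0.1) per CE
  replicate; peaks below 1 RFU are not emitted. The σ = 1.0 stochastic
  scale is what makes sub-32 pg profiles drop out substantially at
  16–32 RFU thresholds, the regime the evaluation studies.
- **Artifacts**: one stutter peak per allelic peak at the n−1 repeat
  position with ratio ~ Normal(0.08, 0.03) truncated at 0; cross-dye
  pull-up with probability 0.05 at ±U(0, 0.3) bp and U(1, 5) % height.
- **Cycle effect on baseline**: +0.04 log-units per cycle beyond 27,
  a mild version of the reported baseline inflation at 31 cycles.
- **Reproducibility**: one study seed drives per-table substreams via
  `numpy.random.SeedSequence.spawn`, so regeneration is byte-identical.

The example kit is synthetic: five analysis dyes plus an ILS channel,
read region 80–480 bp, ILS fragments every 20 bp, four tetranucleotide
markers per dye with ten bins each. Marker blocks are staggered 1.7 bp
per dye so allele bins of different dyes never coincide (minimum
cross-dye bin distance 0.6 bp), as in real multiplex designs. The
example genotype is likewise a synthetic stand-in (certified control-DNA
genotypes are not reproduced): every third marker homozygous, the rest
heterozygous.

What a green test on this world does *not* establish: real baselines
contain spikes, raised-baseline episodes and dye-specific artifacts the
generator omits; amplification efficiency is below the ×2-per-cycle
idealization; stutter ratios are locus-dependent; and heights here are
continuous rather than integer RFU. Quantitative results on synthetic
studies therefore validate the machinery and the qualitative orderings,
not any laboratory's actual thresholds.

## Numerical and degenerate-input conventions

- Sample SDs use the n − 1 denominator everywhere; a single observation
  yields SD 0 (not NaN), and zero signals yield NaN moments with an
  `undefined_mean` flag rather than an exception.
- Ceil-rounding passes through `round(x, 9)` first so that a value that
  is an integer up to float dust is not pushed up a full RFU.
- Sizes are physical 1-based bp coordinates; all intervals (read region,
  marker spans, bins, ILS window) are closed.
- Parsing is strict: unparseable rows are rejected with line numbers,
  never silently dropped; unknown dye labels are reported as a set.
- The `blocks` sizing-table dialect groups records per dye; a
  write/parse round trip preserves every field exactly (full-precision
  float formatting) with record order preserved within dye.

## Known limitations

- The FPR convention (above) is explicit but not the published one,
  which is unrecoverable from the source material.
- Printed threshold values from other laboratories cannot be reproduced
  bit-for-bit because their raw negative data and rounding rule are
  unavailable; only ratio bounds and method orderings are asserted.
- No stutter-ratio filter is implemented (genotyping software applies
  the kit's own); stutter exists only in the simulator and as labelled
  non-allelic peaks in evaluation.
- Quarterly grouping supports drift *description*; no seasonal model is
  fitted.
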