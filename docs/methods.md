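# Methods

## The model

The package simulates two-photon calcium-imaging sessions of hippocampal
CA1 pyramidal cells in a head-fixed mouse running a 1-D virtual corridor,
and benchmarks four place-cell classification methods on the simulated
ground truth.

A session is assembled from three layers:

1. **Locomotion.** A library of single traversals (runs from 0 to the end
   of a 200 cm track, sampled at 7.51 Hz) is either loaded from recorded
   position tables or synthesised.  A session trace concatenates
   `n_traversals` library segments drawn with replacement; velocity is the
   within-segment finite difference of position.  Frames with speed below
   2 cm/s (or below 10% of the maximum speed, the real-data convention)
   are excluded from all maps.

2. **Place fields.**  Each place cell's tuning is a Gaussian of position
   with centre μ, width 4σ (default σ = 12.5 cm, i.e. a 50 cm field) and
   peak ΔF/F (default 1.3).  *Reliability* P ∈ [0, 1] makes the cell
   active on exactly `round(P·n_traversals)` uniformly chosen traversals.
   *Variability* v displaces the field centre per traversal by a Gaussian
   offset whose SD is `v·width·√(π/2)`, so the mean absolute displacement
   is `v·width`; displaced centres are clipped to the track (a linear
   track has no meaningful wrap-around).  Cells may carry 1–4
   non-overlapping fields.

3. **Noise.**  Per-frame Poisson counts with rate λ = 235.1 are converted
   to ΔF/F by dividing by the mean of the first 100 frames and subtracting
   1, the same baseline convention applied to recorded traces (the
   subtraction makes a noiseless trace map to 0).  Under this recipe the
   noise has mean ≈ 1/(100λ) ≈ 4·10⁻⁵ and SD ≈ 1/√λ ≈ 0.065 ΔF/F.
   Optionally, location-independent calcium transients (fast rise,
   0.8 s exponential decay, amplitude equal to the default field peak)
   are added at a Bernoulli rate per frame (0–0.02; 0.0062 matches real
   recordings).

The default population is 20 place cells with centres spread evenly over
the track plus 80 noise-only cells.  Heterogeneous populations draw each
cell's width, peak, reliability and variability independently and
uniformly from the extents of the single-parameter sweeps
(width 20–200 cm, peak 0.1–2 ΔF/F, reliability 0–1, variability 0–1.5)
with a uniform field centre; these sweep extents are the only principled
bounds available, and the uniform law is the neutral choice.

## Fluorescence maps

Maps average ΔF/F over running frames in 40 equal 5 cm bins (half-open,
final bin closed).  5 cm resolves the default 50 cm field with 10 bins
while keeping tens of running frames per bin at 7.51 Hz; the bin count is
configurable.  Frames are assigned by instantaneous position without
interpolation, so a fast traversal can skip a bin — such bins are marked
missing (NaN) in that traversal's map, and a bin never visited in a
session is missing in the session map and excluded from peaks,
correlations and spatial information downstream.

## The four classification methods

All shuffles displace fluorescence only; the position stream and running
mask are shared with the unshuffled data.  "Top q%" criteria use the
nearest-rank percentile of the shuffle values with a *strict* inequality,
so a statistic that ties its shuffles (e.g. a constant trace) is never
classified — this makes the degenerate case well defined and keeps the
false-positive calibration conservative.

* **Peak.**  Statistic: maximum of the session map.  Null: the same
  statistic after circularly shifting the trace by a uniform random
  integer number of frames in [⌈5 s·rate⌉, T − ⌈5 s·rate⌉]
  (500 shuffles).  Classified if the true peak exceeds the 99th-percentile
  shuffle value.

* **Stability.**  Statistic: Pearson correlation between the maps of the
  two session halves (split at the midpoint frame; missing bins excluded
  pairwise).  Null: correlations of the cell's first-half map with
  second-half maps of 100 other cells drawn uniformly with replacement
  (self-draws are redirected, since a self-draw would inflate the null).
  Classified above the 95th percentile.

* **Combination.**  Candidate fields are maximal runs of contiguous bins
  above `baseline + 0.25·(map peak − baseline)` spanning ≥ 20 cm and
  < 120 cm, the span being measured between the centres of the run's
  first and last bins (the unbiased estimate of the threshold-crossing
  extent under random field/bin alignment; counting whole bin widths
  would inflate every field by one bin on average); a field must contain a bin ≥ 10% of the cell's session-mean
  fluorescence, have in-field/out-field mean ratio ≥ 4, and show a
  significant transient in-field on ≥ 20% of traversals.  Cells passing
  these criteria are then bootstrapped: the (preprocessed) trace is cut
  into 10 s chunks whose order is permuted (1000 shuffles; a time-shift
  bootstrap is available as a variant) and re-classified; the cell is a
  place cell only if fewer than 5% of shuffles also classify.  The
  bootstrap stops early once enough shuffles have passed to reject.
  The baseline used by the field threshold is the session mean of the
  windowed 8th-percentile baseline of the preprocessed trace (≈ 0 in
  subtract mode).  The chunk length is not fixed by the published method;
  10 s is of the order of a traversal and is configurable.

* **Information.**  Statistic: spatial information
  SI = Σᵢ fᵢ·log₂(fᵢ/f̄) over non-missing bins, with uniform occupancy
  assumed and f̄ the mean over those bins.  Map values are floored at 0
  before computing f̄ and 0·log 0 := 0, so SI ≥ 0 (log-sum inequality);
  f̄ = 0 defines SI = 0.  The null is the same time-shift scheme as the
  Peak method; classified above the 95th percentile (500 shuffles).

### Transient preprocessing

The Combination method's transient annotation computes a baseline as the
8th percentile of each non-overlapping ~15 s window, interpolated to
frames.  Because an 8th-percentile baseline sits ≈ 1.4 SD below the
typical trace level, excursions are measured from the *median* of the
baseline-subtracted trace: a transient starts above 2 SD and runs until
the trace first returns below 0.5 SD.  Without the median centring,
ordinary quiescent fluctuations of a noise-only trace would be flagged as
transients.  Three preprocessing modes are supported: `none` (default for
model data), `subtract` (baseline-subtract, then zero outside
transients) and `divide` (the historical variant; it raises an explicit
error whenever the baseline is non-positive, where division would flip
event signs).

## Evaluation

Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) against the
generator's truth labels.  Sweep points report means over repeats with
t-based 95% CIs.  Inter-method overlap on a dataset is the fraction of
cells labelled by both methods; the chance level is the product of the
two marginal detection fractions (the standard independence null), and
observed vs chance is compared per pair with paired t-tests,
Holm–Bonferroni corrected over the six pairs.  Cell characterisation
reports the FWHM of the session map (interpolated between bin centres
around the global argmax; 2√(2 ln 2)·σ ≈ 29 cm for the default field,
narrower than the 50 cm model width), the split-half correlation, SI,
the out/in-field fluorescence ratio over the FWHM extent (the FWHM
boundary is used because the 4σ model width is not observable for real
cells), and the percentile of the peak and stability statistics within
their own nulls.

## Synthetic locomotion

Recorded locomotion is preferred when available (the loader splits
position tables at resets to the track start and keeps only complete
traversals).  The synthesiser draws a per-traversal mean running speed
(15 ± 5 cm/s, floored at 5 cm/s — typical of head-fixed mice in virtual
corridors), modulates it frame-by-frame with an AR(1) jitter
(ρ = 0.9, 25% SD), and inserts pauses at 0.15 per running second with
exponential 8 s durations and sub-threshold creep speed.  The speed
irregularity matters: with perfectly constant speed a circular time shift
would be equivalent to a position shift and the shuffle nulls of the Peak
and Information methods would lose their power.  These defaults give
sessions of roughly 30 s per traversal, about half of whose frames pass
the running threshold — shorter than real 45-minute sessions, in which
mice spend long periods stationary; since stationary frames are excluded
from every map, this compression changes the total frame count but not
the occupancy statistics that drive the methods.

What the generator does *not* emulate: temporally correlated noise,
out-of-field firing, slow drifts of the field over a session (map
switching), inter-cell correlations, and reward/cue-locked behaviour.
Consequently, passing benchmarks here demonstrate correctness of the
methods' mechanics and their relative behaviour on idealised cells, not
performance on real recordings — in particular, structured within-session
field relocation, which penalises the Stability method on real data, is
absent by construction.  A related consequence: because the model's noise
is i.i.d. across frames and all cells share the occupancy stream, a noise
cell's split-half correlation is statistically exchangeable with its
cross-cell null draws, which pins the Stability method's false-positive
rate near its nominal level at *every* traversal count in this simulator.

## Numerical choices

* Percentile thresholds: nearest rank, strict inequality, ties → not
  classified.
* Missing bins: NaN, excluded pairwise in correlations and ignored in
  peaks/SI; a cell with fewer than two usable bins in a session half is
  skipped by the Stability method with a warning.
* In/out-field ratio with a non-positive out-field mean is treated as
  +∞ when the in-field mean is positive (the contrast criterion is
  satisfied a fortiori).
* Noise traces shorter than the 100-frame baseline window fall back to
  the full-trace mean with a warning.
* All randomness flows through `numpy.random.Generator`; populations
  spawn one child stream per cell, so results are reproducible
  cell-by-cell and byte-identical under a fixed master seed.

## Problem sizes

The bundled benchmarks run at desk scale: 10-repeat sweeps over
traversal counts {2, 5, 10, 20, 50, 100} and widths 20–200 cm,
20 heterogeneous populations of 100 cells, and the published shuffle
counts (500 time-shift shuffles, 1000 bootstrap shuffles, 100 stability
draws; the width-sweep tests use 200 time-shift shuffles).  The library
of synthetic traversals is 184 strong, matching the pooled traversal
count of the modelled experiment.
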