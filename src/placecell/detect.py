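"""The four place-cell classification methods and their null machinery.

* **Peak** — the maximum of the session fluorescence map must land in the
  top 1% of 500 circular time-shift shuffles (shifts of at least 5 s).
* **Stability** — the Pearson correlation between the fluorescence maps of
  the two session halves must exceed the 95th percentile of correlations
  with the second-half maps of 100 randomly drawn other cells.
* **Combination** — a candidate field (contiguous bins above baseline plus
  0.25 of the peak-to-baseline range, 20–120 cm wide, containing a bin of
  at least 10% of the session-mean fluorescence, in/out-field ratio >= 4,
  significant transients in the field on >= 20% of traversals) must survive
  a bootstrap: fewer than 5% of 1000 shuffles may also classify.
* **Information** — the spatial information of the session map (uniform
  occupancy assumed) must land in the top 5% of the same time-shift
  shuffle scheme as the Peak method.

"Top q%" thresholds use the nearest-rank percentile of the shuffle values
and a strict inequality, so a cell whose statistic ties its shuffles (e.g.
a constant trace) is never classified.  Shuffles displace fluorescence only;
the position stream and running mask are shared with the unshuffled data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EmptySessionError, ParameterError
from .maps import DEFAULT_N_BINS, bin_index, segment_traversals
from .synth import DEFAULT_FRAME_RATE, as_rng

DEFAULT_MIN_SHIFT_S = 5.0
PEAK_SHUFFLES = 500
PEAK_PERCENTILE = 99.0
INFO_SHUFFLES = 500
INFO_PERCENTILE = 95.0
STABILITY_DRAWS = 100
STABILITY_PERCENTILE = 95.0
TRANSIENT_WINDOW_S = 15.0
TRANSIENT_BASELINE_PCT = 8.0
TRANSIENT_ONSET_SD = 2.0
TRANSIENT_OFFSET_SD = 0.5


@dataclass
class DetectionResult:
    """Per-cell output of one classification method.

    ``statistic`` is the method's decision statistic (map peak, split-half
    r, spatial information, or the Combination shuffle-pass fraction);
    ``percentile`` is the rank of the true statistic within the cell's own
    null distribution (for Combination, 100·(1 − pass fraction)).
    """

    method: str
    labels: np.ndarray  # bool per cell
    statistic: np.ndarray
    percentile: np.ndarray
    n_shuffles: int
    threshold: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.labels.size


def nearest_rank(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q/100·n)-th smallest value."""
    v = np.sort(np.asarray(values))
    k = int(math.ceil(q / 100.0 * v.size))
    return v[max(0, k - 1)]


# ---------------------------------------------------------------------------
# shuffles
# ---------------------------------------------------------------------------


def _min_shift_frames(frame_rate: float, min_shift_s: float) -> int:
    return int(math.ceil(min_shift_s * frame_rate))


def _draw_shifts(rng: np.random.Generator, n: int, n_frames: int,
                 min_shift: int) -> np.ndarray:
    lo, hi = min_shift, n_frames - min_shift
    if hi < lo:
        raise ParameterError("trace too short for the minimum time shift")
    return rng.integers(lo, hi + 1, size=n)


def time_shift_shuffle(dff: np.ndarray, frame_rate: float = DEFAULT_FRAME_RATE,
                       min_shift_s: float = DEFAULT_MIN_SHIFT_S,
                       seed=None) -> np.ndarray:
    """Circularly shift a trace by a uniform random shift of >= min_shift_s.

    The shift is an integer number of frames in
    ``[ceil(min_shift_s·rate), T − ceil(min_shift_s·rate)]``, so the
    identity shift is excluded and the trace value multiset is preserved.
    """
    dff = np.asarray(dff)
    shift = _draw_shifts(as_rng(seed), 1, dff.size,
                         _min_shift_frames(frame_rate, min_shift_s))[0]
    return np.roll(dff, int(shift))


def chunk_shuffle(dff: np.ndarray, chunk_s: float = 10.0,
                  frame_rate: float = DEFAULT_FRAME_RATE,
                  seed=None) -> np.ndarray:
    """Cut a trace into consecutive chunks and permute their order.

    The last chunk may be shorter; the permutation is uniform over chunk
    orders and preserves the value multiset exactly.
    """
    dff = np.asarray(dff)
    idx = _chunk_permutation(dff.size, chunk_s, frame_rate, as_rng(seed))
    return dff[idx]


def _chunk_permutation(n_frames: int, chunk_s: float, frame_rate: float,
                       rng: np.random.Generator) -> np.ndarray:
    if chunk_s <= 0:
        raise ParameterError("chunk_s must be positive")
    clen = max(1, int(round(chunk_s * frame_rate)))
    starts = np.arange(0, n_frames, clen)
    order = rng.permutation(starts.size)
    return np.concatenate([np.arange(starts[i], min(starts[i] + clen, n_frames))
                           for i in order])


# ---------------------------------------------------------------------------
# binned session helper (shared by Peak / Information / Combination)
# ---------------------------------------------------------------------------


class BinnedSession:
    """Pre-sorted running-frame/bin bookkeeping for fast shuffle maps."""

    def __init__(self, position, mask, n_bins: int = DEFAULT_N_BINS,
                 track_length: float = 200.0):
        position = np.asarray(position, float)
        mask = np.asarray(mask, bool)
        self.n_frames = position.size
        self.n_bins = n_bins
        run = np.flatnonzero(mask)
        if run.size == 0:
            raise EmptySessionError("no running frames")
        bins = bin_index(position[run], n_bins, track_length)
        order = np.argsort(bins, kind="stable")
        self.run_idx = run[order]  # running frames sorted by bin
        sorted_bins = bins[order]
        counts = np.bincount(sorted_bins, minlength=n_bins)
        self.bins_present = np.flatnonzero(counts)
        self.counts = counts[self.bins_present].astype(float)
        self.starts = np.concatenate([[0], np.cumsum(self.counts)[:-1]]
                                     ).astype(np.intp)

    def maps_for_shifts(self, dff: np.ndarray,
                        shifts: np.ndarray) -> np.ndarray:
        """Session maps (rows: shifts, cols: occupied bins) of circularly
        shifted copies of one cell's trace.  Shift 0 gives the true map."""
        idx = (self.run_idx[None, :] + np.asarray(shifts)[:, None]) % self.n_frames
        vals = np.asarray(dff)[idx]
        sums = np.add.reduceat(vals, self.starts, axis=1)
        return sums / self.counts

    def map_of(self, trace: np.ndarray) -> np.ndarray:
        """Full-length (n_bins) session map of one trace, NaN where empty."""
        sums = np.add.reduceat(trace[self.run_idx], self.starts)
        out = np.full(self.n_bins, np.nan)
        out[self.bins_present] = sums / self.counts
        return out


# ---------------------------------------------------------------------------
# spatial information
# ---------------------------------------------------------------------------


def spatial_information(map_values: np.ndarray) -> float:
    """Spatial information SI = Σ_i f_i·log2(f_i / f̄) over non-missing bins.

    Uniform occupancy is assumed.  Values are floored at 0 before computing
    f̄ (the mean over non-missing bins) and 0·log(0) is taken as 0, so SI is
    non-negative; if f̄ = 0 the SI is defined as 0.
    """
    f = np.asarray(map_values, float)
    f = f[np.isfinite(f)]
    if f.size == 0:
        return 0.0
    return float(_si_rows(np.clip(f, 0.0, None)[None, :])[0])


def _si_rows(f: np.ndarray) -> np.ndarray:
    """Row-wise SI of non-negative map matrices (no NaNs)."""
    fbar = f.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        terms = np.where(f > 0, f * np.log2(f / fbar[:, None]), 0.0)
    # clamp float-epsilon negatives: SI is non-negative by the log-sum
    # inequality
    si = np.maximum(terms.sum(axis=1), 0.0)
    si[fbar <= 0] = 0.0
    return si


# ---------------------------------------------------------------------------
# Peak and Information methods
# ---------------------------------------------------------------------------


def _shuffle_statistic_method(method: str, dff, position, mask, *, n_bins,
                              track_length, frame_rate, n_shuffles,
                              percentile, min_shift_s, seed) -> DetectionResult:
    dff = np.atleast_2d(np.asarray(dff, float))
    session = BinnedSession(position, mask, n_bins, track_length)
    min_shift = _min_shift_frames(frame_rate, min_shift_s)
    rng = as_rng(seed)
    n_cells = dff.shape[0]
    stats = np.full(n_cells, np.nan)
    perc = np.full(n_cells, np.nan)
    thr = np.full(n_cells, np.nan)
    labels = np.zeros(n_cells, bool)
    for i in range(n_cells):
        shifts = np.concatenate([[0], _draw_shifts(rng, n_shuffles,
                                                   session.n_frames, min_shift)])
        maps = session.maps_for_shifts(dff[i], shifts)
        if method == "peak":
            vals = maps.max(axis=1)
        else:
            vals = _si_rows(np.clip(maps, 0.0, None))
        stat, null = vals[0], vals[1:]
        stats[i] = stat
        thr[i] = nearest_rank(null, percentile)
        labels[i] = stat > thr[i]
        perc[i] = 100.0 * np.mean(null < stat)
    return DetectionResult(method, labels, stats, perc, n_shuffles, thr)


def peak_method(dff, position, mask, n_bins: int = DEFAULT_N_BINS,
                track_length: float = 200.0,
                frame_rate: float = DEFAULT_FRAME_RATE,
                n_shuffles: int = PEAK_SHUFFLES,
                percentile: float = PEAK_PERCENTILE,
                min_shift_s: float = DEFAULT_MIN_SHIFT_S,
                seed=None) -> DetectionResult:
    """Classify cells by the session-map peak against time-shift shuffles."""
    return _shuffle_statistic_method(
        "peak", dff, position, mask, n_bins=n_bins, track_length=track_length,
        frame_rate=frame_rate, n_shuffles=n_shuffles, percentile=percentile,
        min_shift_s=min_shift_s, seed=seed)


def information_method(dff, position, mask, n_bins: int = DEFAULT_N_BINS,
                       track_length: float = 200.0,
                       frame_rate: float = DEFAULT_FRAME_RATE,
                       n_shuffles: int = INFO_SHUFFLES,
                       percentile: float = INFO_PERCENTILE,
                       min_shift_s: float = DEFAULT_MIN_SHIFT_S,
                       seed=None) -> DetectionResult:
    """Classify cells by spatial information against time-shift shuffles."""
    return _shuffle_statistic_method(
        "information", dff, position, mask, n_bins=n_bins,
        track_length=track_length, frame_rate=frame_rate,
        n_shuffles=n_shuffles, percentile=percentile,
        min_shift_s=min_shift_s, seed=seed)


# ---------------------------------------------------------------------------
# Stability method
# ---------------------------------------------------------------------------


def _nancorr(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return np.nan
    x, y = a[ok], b[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def half_session_maps(dff, position, mask, n_bins: int = DEFAULT_N_BINS,
                      track_length: float = 200.0,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Session maps of the two halves of the recording (split at the
    midpoint frame), full-length with NaN for unoccupied bins."""
    dff = np.atleast_2d(np.asarray(dff, float))
    mask = np.asarray(mask, bool)
    half = mask.size // 2
    frames = np.arange(mask.size)
    out = []
    for sel in (frames < half, frames >= half):
        m = mask & sel
        if not m.any():
            raise EmptySessionError("one session half has no running frames")
        session = BinnedSession(position, m, n_bins, track_length)
        maps = np.full((dff.shape[0], n_bins), np.nan)
        sums = np.add.reduceat(dff[:, session.run_idx], session.starts, axis=1)
        maps[:, session.bins_present] = sums / session.counts
        out.append(maps)
    return out[0], out[1]


def stability_method(dff, position, mask, n_bins: int = DEFAULT_N_BINS,
                     track_length: float = 200.0,
                     n_draws: int = STABILITY_DRAWS,
                     percentile: float = STABILITY_PERCENTILE,
                     seed=None) -> DetectionResult:
    """Classify cells by split-half map correlation against cross-cell nulls.

    The null for cell *i* correlates its first-half map with the second-half
    maps of ``n_draws`` other cells drawn uniformly with replacement
    (self-draws are redirected to other cells).  Cells with fewer than two
    bins observed in both halves are skipped with a warning.
    """
    dff = np.atleast_2d(np.asarray(dff, float))
    n_cells = dff.shape[0]
    if n_cells < 2:
        raise ParameterError("stability method needs at least 2 cells")
    first, second = half_session_maps(dff, position, mask, n_bins, track_length)
    rng = as_rng(seed)
    stats = np.full(n_cells, np.nan)
    perc = np.full(n_cells, np.nan)
    thr = np.full(n_cells, np.nan)
    labels = np.zeros(n_cells, bool)
    for i in range(n_cells):
        r = _nancorr(first[i], second[i])
        # uniform over the other n-1 cells, with replacement
        js = (i + 1 + rng.integers(0, n_cells - 1, size=n_draws)) % n_cells
        null = np.array([_nancorr(first[i], second[j]) for j in js])
        null = null[np.isfinite(null)]
        if not np.isfinite(r) or null.size == 0:
            warnings.warn(f"stability: cell {i} skipped (insufficient bins)",
                          stacklevel=2)
            continue
        stats[i] = r
        thr[i] = nearest_rank(null, percentile)
        labels[i] = r > thr[i]
        perc[i] = 100.0 * np.mean(null < r)
    return DetectionResult("stability", labels, stats, perc, n_draws, thr)


# ---------------------------------------------------------------------------
# transient detection and Combination preprocessing
# ---------------------------------------------------------------------------


@dataclass
class TransientMask:
    """Significant-transient annotation of one trace."""

    mask: np.ndarray  # bool per frame
    baseline: np.ndarray  # 8th-percentile baseline interpolated to frames
    sd: float  # SD of the baseline-subtracted trace


def _percentile_baseline(trace: np.ndarray, frame_rate: float,
                         window_s: float, pct: float) -> np.ndarray:
    n = trace.size
    wlen = int(round(window_s * frame_rate))
    if wlen >= n or wlen < 1:
        return np.full(n, np.percentile(trace, pct))
    starts = np.arange(0, n, wlen)
    centers, vals = [], []
    for s in starts:
        e = min(s + wlen, n)
        centers.append((s + e - 1) / 2.0)
        vals.append(np.percentile(trace[s:e], pct))
    return np.interp(np.arange(n), centers, vals)


def detect_significant_transients(dff: np.ndarray,
                                  frame_rate: float = DEFAULT_FRAME_RATE,
                                  window_s: float = TRANSIENT_WINDOW_S,
                                  onset_sd: float = TRANSIENT_ONSET_SD,
                                  offset_sd: float = TRANSIENT_OFFSET_SD,
                                  baseline_pct: float = TRANSIENT_BASELINE_PCT,
                                  ) -> TransientMask:
    """Mark significant calcium transients in one trace.

    The baseline is the 8th percentile of each non-overlapping ~15 s window,
    interpolated to frames (a single window if the session is shorter).  A
    transient starts where the baseline-subtracted trace exceeds
    ``onset_sd`` SDs and runs until it first returns below ``offset_sd``
    SDs.
    """
    trace = np.asarray(dff, float)
    baseline = _percentile_baseline(trace, frame_rate, window_s, baseline_pct)
    # the 8th-percentile baseline sits below the typical trace level, so
    # excursions are measured from the median of the baseline-subtracted
    # trace; otherwise quiescent fluctuations would count as transients
    resid = trace - baseline
    resid -= np.median(resid)
    sd = float(resid.std())
    mask = np.zeros(trace.size, bool)
    if sd == 0:
        return TransientMask(mask, baseline, sd)
    above = resid > onset_sd * sd
    below = resid < offset_sd * sd
    starts = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    if starts.size:
        below_idx = np.flatnonzero(below)
        nxt = np.searchsorted(below_idx, starts)
        ends = np.where(nxt < below_idx.size,
                        below_idx[np.minimum(nxt, below_idx.size - 1)],
                        trace.size)
        delta = np.zeros(trace.size + 1, int)
        np.add.at(delta, starts, 1)
        np.add.at(delta, ends, -1)
        mask = np.cumsum(delta[:-1]) > 0
    return TransientMask(mask, baseline, sd)


@dataclass
class PreprocessedTrace:
    """Combination-method preprocessing output for one cell."""

    trace: np.ndarray
    transient_mask: np.ndarray
    baseline_mean: float  # session mean of the baseline of `trace`


def combination_preprocess(dff: np.ndarray, mode: str = "none",
                           frame_rate: float = DEFAULT_FRAME_RATE,
                           window_s: float = TRANSIENT_WINDOW_S,
                           ) -> PreprocessedTrace:
    """Baseline-correct and transient-threshold a trace for the Combination
    method.

    ``none`` leaves the trace unchanged (transients are still annotated);
    ``divide`` divides by the windowed 8th-percentile baseline (and fails
    loudly if the baseline is ever non-positive, where division flips event
    signs); ``subtract`` subtracts the baseline instead.  In the divide and
    subtract modes fluorescence outside significant transients is set to 0.
    """
    trace = np.asarray(dff, float)
    tm = detect_significant_transients(trace, frame_rate, window_s)
    if mode == "none":
        out = trace.copy()
    elif mode == "subtract":
        out = np.where(tm.mask, trace - tm.baseline, 0.0)
    elif mode == "divide":
        if (tm.baseline <= 0).any():
            raise ParameterError(
                "divide-mode preprocessing with a non-positive baseline flips "
                "event signs; use mode='subtract'")
        out = np.where(tm.mask, trace / tm.baseline, 0.0)
    else:
        raise ParameterError(f"unknown preprocess mode {mode!r}")
    base_out = _percentile_baseline(out, frame_rate, window_s,
                                    TRANSIENT_BASELINE_PCT)
    return PreprocessedTrace(out, tm.mask, float(base_out.mean()))


# ---------------------------------------------------------------------------
# Combination method
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CombinationParams:
    """Thresholds of the Combination method (defaults as published)."""

    field_threshold_frac: float = 0.25  # of (map peak − baseline)
    min_width: float = 20.0  # cm, inclusive
    max_width: float = 120.0  # cm, exclusive
    min_bin_frac_of_mean: float = 0.10
    min_inout_ratio: float = 4.0
    min_traversal_frac: float = 0.20
    n_shuffles: int = 1000
    max_shuffle_pass_frac: float = 0.05
    preprocess_mode: str = "none"  # none | divide | subtract
    bootstrap_mode: str = "chunk"  # chunk | timeshift
    chunk_s: float = 10.0

    def __post_init__(self):
        if not 0 < self.min_width < self.max_width:
            raise ParameterError("need 0 < min_width < max_width")
        for name in ("field_threshold_frac", "min_bin_frac_of_mean",
                     "min_traversal_frac", "max_shuffle_pass_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ParameterError(f"{name} must be in (0, 1]")


def _bool_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of runs of True."""
    d = np.diff(np.concatenate([[0], x.astype(np.int8), [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts, ends))


def _candidate_runs(map_values: np.ndarray, baseline: float,
                    mean_fluor: float, bin_width: float,
                    params: CombinationParams) -> list[tuple[int, int]]:
    """Runs of contiguous above-threshold bins passing the map criteria.

    The spatial extent of a run is measured between the centres of its
    first and last bins — the unbiased estimate of the threshold-crossing
    extent under random field/bin alignment (counting whole bin widths
    would systematically overestimate it by one bin).
    """
    finite = np.isfinite(map_values)
    if not finite.any():
        return []
    peak = np.nanmax(map_values)
    thr = baseline + params.field_threshold_frac * (peak - baseline)
    above = np.where(finite, map_values > thr, False)
    out = []
    for i0, i1 in _bool_runs(above):
        width = (i1 - i0) * bin_width
        if width < params.min_width or width >= params.max_width:
            continue
        infield = map_values[i0:i1 + 1]
        if not (infield >= params.min_bin_frac_of_mean * mean_fluor).any():
            continue
        out_sel = np.ones(map_values.size, bool)
        out_sel[i0:i1 + 1] = False
        out_sel &= finite
        out_mean = map_values[out_sel].mean() if out_sel.any() else 0.0
        in_mean = np.nanmean(infield)
        if out_mean <= 0:
            ratio = np.inf if in_mean > 0 else 0.0
        else:
            ratio = in_mean / out_mean
        if ratio < params.min_inout_ratio:
            continue
        out.append((int(i0), int(i1)))
    return out


def _classify_map(map_values: np.ndarray, baseline: float, mean_fluor: float,
                  transients_by_bin: np.ndarray, n_traversals: int,
                  bin_width: float, params: CombinationParams) -> bool:
    """Apply the Combination field criteria to one session map.

    ``transients_by_bin`` is a (traversals, bins) boolean matrix marking
    traversals with a significant transient while the animal was in a bin.
    """
    for i0, i1 in _candidate_runs(map_values, baseline, mean_fluor,
                                  bin_width, params):
        frac = transients_by_bin[:, i0:i1 + 1].any(axis=1).mean()
        if frac >= params.min_traversal_frac:
            return True
    return False


def _transients_by_bin(transient_mask: np.ndarray, run_frames: np.ndarray,
                       tid0: np.ndarray, bins: np.ndarray, n_trav: int,
                       n_bins: int) -> np.ndarray:
    sel = transient_mask[run_frames]
    combined = tid0[sel] * n_bins + bins[sel]
    counts = np.bincount(combined, minlength=n_trav * n_bins)
    return counts.reshape(n_trav, n_bins) > 0


def combination_method(dff, position, mask,
                       traversal_id: np.ndarray | None = None,
                       params: CombinationParams | None = None,
                       n_bins: int = DEFAULT_N_BINS,
                       track_length: float = 200.0,
                       frame_rate: float = DEFAULT_FRAME_RATE,
                       seed=None) -> DetectionResult:
    """Run the full Combination method on a population.

    The statistic reported per cell is the bootstrap shuffle-pass fraction
    (NaN for cells rejected before the bootstrap); a cell is a place cell
    only if it satisfies the field criteria and fewer than
    ``max_shuffle_pass_frac`` of the shuffles do too.  The bootstrap stops
    early once enough shuffles have passed to reject the cell.
    """
    params = params or CombinationParams()
    dff = np.atleast_2d(np.asarray(dff, float))
    position = np.asarray(position, float)
    mask = np.asarray(mask, bool)
    if traversal_id is None:
        traversal_id = segment_traversals(position, track_length)
    n_trav = int(np.asarray(traversal_id).max())
    if n_trav < 1:
        raise EmptySessionError("no traversals")
    session = BinnedSession(position, mask, n_bins, track_length)
    bin_width = track_length / n_bins
    run = session.run_idx
    bins_run = bin_index(position[run], n_bins, track_length)
    tid0_run = np.asarray(traversal_id)[run] - 1
    rng = as_rng(seed)
    n_cells = dff.shape[0]
    n_cell_frames = dff.shape[1]
    min_shift = _min_shift_frames(frame_rate, DEFAULT_MIN_SHIFT_S)

    labels = np.zeros(n_cells, bool)
    stats = np.full(n_cells, np.nan)
    perc = np.full(n_cells, np.nan)
    fail_at = int(math.ceil(params.max_shuffle_pass_frac * params.n_shuffles))
    if params.bootstrap_mode == "chunk":
        clen = max(1, int(round(params.chunk_s * frame_rate)))
        segments = [np.arange(s, min(s + clen, n_cell_frames))
                    for s in range(0, n_cell_frames, clen)]
    elif params.bootstrap_mode != "timeshift":
        raise ParameterError(
            f"unknown bootstrap mode {params.bootstrap_mode!r}")
    for i in range(n_cells):
        pre = combination_preprocess(dff[i], params.preprocess_mode,
                                     frame_rate)
        mean_fluor = float(pre.trace[mask].mean())
        tmap = session.map_of(pre.trace)
        tbb = _transients_by_bin(pre.transient_mask, run, tid0_run,
                                 bins_run, n_trav, n_bins)
        if not _classify_map(tmap, pre.baseline_mean, mean_fluor, tbb,
                             n_trav, bin_width, params):
            continue
        passes = 0
        done = 0
        for _ in range(params.n_shuffles):
            if params.bootstrap_mode == "chunk":
                order = rng.permutation(len(segments))
                idx = np.concatenate([segments[j] for j in order])
            else:
                s = _draw_shifts(rng, 1, n_cell_frames, min_shift)[0]
                idx = (np.arange(n_cell_frames) + s) % n_cell_frames
            idx_run = idx[run]
            smap = np.full(n_bins, np.nan)
            sums = np.add.reduceat(pre.trace[idx_run], session.starts)
            smap[session.bins_present] = sums / session.counts
            runs = _candidate_runs(smap, pre.baseline_mean, mean_fluor,
                                   bin_width, params)
            if runs:
                # the (relatively expensive) transient tally is only
                # needed when a shuffle map already yields a candidate
                tmask_s = pre.transient_mask[idx]
                stbb = _transients_by_bin(tmask_s, run, tid0_run, bins_run,
                                          n_trav, n_bins)
                passes += any(
                    stbb[:, i0:i1 + 1].any(axis=1).mean()
                    >= params.min_traversal_frac for i0, i1 in runs)
            done += 1
            if passes >= fail_at:
                break
        frac = passes / done
        stats[i] = frac
        perc[i] = 100.0 * (1.0 - frac)
        labels[i] = frac < params.max_shuffle_pass_frac
    return DetectionResult("combination", labels, stats, perc,
                           params.n_shuffles)


# ---------------------------------------------------------------------------
# convenience front end
# ---------------------------------------------------------------------------

ALL_METHODS = ("peak", "stability", "combination", "information")


def detect_all(dff, position, velocity, *, methods=ALL_METHODS,
               n_bins: int = DEFAULT_N_BINS, track_length: float = 200.0,
               frame_rate: float = DEFAULT_FRAME_RATE,
               traversal_id: np.ndarray | None = None,
               mask: np.ndarray | None = None,
               mask_mode: str = "absolute",
               combination_params: CombinationParams | None = None,
               n_shuffles: dict | None = None,
               seed=None) -> dict[str, DetectionResult]:
    """Run the requested classification methods on one population.

    ``n_shuffles`` optionally overrides the per-method shuffle/draw counts,
    e.g. ``{"peak": 200}``.  Each method consumes an independent child
    random stream spawned from ``seed``.
    """
    from .maps import running_mask  # local import to avoid cycle at import

    if mask is None:
        mask = running_mask(velocity, mode=mask_mode)
    rng = as_rng(seed)
    streams = {m: r for m, r in zip(ALL_METHODS, rng.spawn(len(ALL_METHODS)))}
    overrides = n_shuffles or {}
    results: dict[str, DetectionResult] = {}
    for m in methods:
        if m == "peak":
            results[m] = peak_method(
                dff, position, mask, n_bins, track_length, frame_rate,
                n_shuffles=overrides.get("peak", PEAK_SHUFFLES),
                seed=streams[m])
        elif m == "information":
            results[m] = information_method(
                dff, position, mask, n_bins, track_length, frame_rate,
                n_shuffles=overrides.get("information", INFO_SHUFFLES),
                seed=streams[m])
        elif m == "stability":
            results[m] = stability_method(
                dff, position, mask, n_bins, track_length,
                n_draws=overrides.get("stability", STABILITY_DRAWS),
                seed=streams[m])
        elif m == "combination":
            params = combination_params or CombinationParams()
            if "combination" in overrides:
                from dataclasses import replace as _replace
                params = _replace(params,
                                  n_shuffles=overrides["combination"])
            results[m] = combination_method(
                dff, position, mask, traversal_id, params, n_bins,
                track_length, frame_rate, seed=streams[m])
        else:
            raise ParameterError(f"unknown method {m!r}")
    return results


def results_frame(results: dict[str, DetectionResult]):
    """Tidy per-cell × method table of labels, statistics and percentiles."""
    import pandas as pd

    rows = []
    for m, r in results.items():
        for i in range(r.n_cells):
            rows.append(dict(cell=i, method=m, label=bool(r.labels[i]),
                             statistic=r.statistic[i],
                             percentile=r.percentile[i],
                             n_shuffles=r.n_shuffles))
    return pd.DataFrame(rows)
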