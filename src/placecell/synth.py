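"""Synthetic place-cell populations on a 1-D virtual track.

The generator produces the three ingredients of a simulated session:

* a locomotion trace — traversals of a linear track at a fixed frame rate,
  either synthesised from simple speed statistics or loaded from recorded
  position tables, with stop periods (speed below the running threshold);
* Gaussian place fields with controllable centre, width (4·sigma), peak
  ΔF/F, per-traversal reliability and spatial variability;
* shot noise per frame, modelled as Poisson counts converted to ΔF/F by the
  same first-100-frame baseline normalisation applied to recorded traces.

All randomness flows through :class:`numpy.random.Generator` objects; an
integer seed is accepted everywhere and produces byte-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyLibraryError, InputError, ParameterError

# Track / acquisition defaults matching the modelled experiment.
DEFAULT_TRACK_LENGTH = 200.0  # cm
DEFAULT_FRAME_RATE = 7.51  # Hz
SPEED_THRESHOLD = 2.0  # cm/s, running threshold for model data
BASELINE_FRAMES = 100  # frames used for the dF/F baseline

# Place-field defaults: sigma 12.5 cm puts 95% of the Gaussian mass (4 sigma)
# inside the nominal 50 cm field width; the peak matches the dF/F peaks
# measured in CA1 two-photon data.
DEFAULT_SIGMA = 12.5  # cm
DEFAULT_PEAK = 1.3  # dF/F
DEFAULT_LAMBDA = 235.1  # Poisson rate per frame of the raw noise
DEFAULT_TRANSIENT_RATE = 0.0062  # calcium peaks per frame seen in real data
MAX_TRANSIENT_RATE = 0.02

DEFAULT_N_PLACE = 20
DEFAULT_N_NONPLACE = 80
DEFAULT_N_TRAVERSALS = 50
DEFAULT_LIBRARY_SIZE = 184  # traversals pooled over 8 recorded sessions


def as_rng(seed) -> np.random.Generator:
    """Return ``seed`` unchanged if it is already a Generator, else seed one."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# locomotion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeedParams:
    """Speed statistics for synthesised traversals.

    Mice in head-fixed virtual corridors run at 10–30 cm/s with strongly
    non-uniform speed and frequent stops; the per-frame AR(1) jitter and the
    inserted pauses reproduce that irregularity, which is what gives the
    time-shift shuffles their power (a constant-speed run would make a time
    shift equivalent to a position shift).
    """

    mean_run_speed: float = 15.0  # cm/s, traversal-average running speed
    sd_run_speed: float = 5.0  # cm/s, across traversals
    min_run_speed: float = 5.0  # cm/s floor for the traversal average
    jitter_frac: float = 0.25  # within-traversal AR(1) speed SD (fraction)
    jitter_ar: float = 0.9  # AR(1) coefficient of the speed jitter
    pause_rate: float = 0.15  # pause starts per running second
    mean_pause_s: float = 8.0  # exponential mean pause duration
    pause_speed: float = 0.5  # cm/s creep while paused (below threshold)


@dataclass
class TraversalLibrary:
    """A pool of single-traversal position segments at a fixed frame rate."""

    traversals: list[np.ndarray]
    frame_rate: float = DEFAULT_FRAME_RATE
    track_length: float = DEFAULT_TRACK_LENGTH

    def __post_init__(self):
        if not self.traversals:
            raise EmptyLibraryError("traversal library is empty")
        for t in self.traversals:
            if t.min() < 0 or t.max() > self.track_length + 1e-9:
                raise InputError("traversal positions outside [0, track_length]")

    @property
    def n_traversals(self) -> int:
        return len(self.traversals)


@dataclass
class LocomotionTrace:
    """Frame-indexed position/velocity with 1-based traversal IDs."""

    time: np.ndarray  # s
    position: np.ndarray  # cm
    velocity: np.ndarray  # cm/s
    traversal_id: np.ndarray  # int, 1-based, non-decreasing
    frame_rate: float = DEFAULT_FRAME_RATE
    track_length: float = DEFAULT_TRACK_LENGTH

    @property
    def n_frames(self) -> int:
        return self.position.size

    @property
    def n_traversals(self) -> int:
        return int(self.traversal_id[-1]) if self.traversal_id.size else 0


def _segment_velocity(position: np.ndarray, traversal_id: np.ndarray,
                      frame_rate: float) -> np.ndarray:
    """Finite-difference velocity that does not difference across segment
    boundaries (position resets between traversals are not real movement)."""
    v = np.empty_like(position, dtype=float)
    v[1:] = np.diff(position) * frame_rate
    v[0] = v[1] if position.size > 1 else 0.0
    starts = np.flatnonzero(np.diff(traversal_id)) + 1
    for s in starts:
        v[s] = v[s + 1] if s + 1 < v.size else v[s - 1]
    return v


def synthesize_traversal_library(
    n: int,
    track_length: float = DEFAULT_TRACK_LENGTH,
    frame_rate: float = DEFAULT_FRAME_RATE,
    speed: SpeedParams | None = None,
    seed=None,
) -> TraversalLibrary:
    """Synthesise ``n`` monotone 0 → ``track_length`` traversals.

    Each traversal draws an average running speed, modulates it frame by
    frame with an AR(1) jitter, and inserts sub-threshold-speed pauses at
    ``pause_rate`` per running second.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if frame_rate <= 0:
        raise ParameterError("frame_rate must be positive")
    sp = speed or SpeedParams()
    rng = as_rng(seed)
    dt = 1.0 / frame_rate
    traversals = []
    for _ in range(n):
        v_mean = max(sp.min_run_speed,
                     rng.normal(sp.mean_run_speed, sp.sd_run_speed))
        pos = [0.0]
        x = 0.0
        g = 0.0  # AR(1) state of the log-ish speed jitter
        sd_innov = sp.jitter_frac * math.sqrt(max(1e-12, 1 - sp.jitter_ar**2))
        pause_left = 0
        p_pause = sp.pause_rate * dt
        while x < track_length:
            if pause_left > 0:
                v = sp.pause_speed
                pause_left -= 1
            else:
                g = sp.jitter_ar * g + rng.normal(0.0, sd_innov)
                v = max(SPEED_THRESHOLD + 0.5, v_mean * math.exp(g))
                if sp.pause_rate > 0 and rng.random() < p_pause:
                    pause_left = max(1, round(rng.exponential(sp.mean_pause_s)
                                              * frame_rate))
            x = min(track_length, x + v * dt)
            pos.append(x)
        traversals.append(np.asarray(pos))
    return TraversalLibrary(traversals, frame_rate, track_length)


def load_traversal_library(
    table: pd.DataFrame | str,
    track_length: float = DEFAULT_TRACK_LENGTH,
    frame_rate: float | None = None,
) -> TraversalLibrary:
    """Extract complete traversals from a per-frame locomotion table.

    The table needs ``time_s`` and ``position_cm`` columns.  The position
    stream is split wherever it drops by more than half the track (a reset
    to the track start), rows outside [0, track_length] are rejected, and
    only segments that span the track (start below 10%, end above 90%) are
    kept as complete traversals.
    """
    if isinstance(table, (str,)) or hasattr(table, "__fspath__"):
        table = pd.read_csv(table, sep=None, engine="python")
    if not {"time_s", "position_cm"}.issubset(table.columns):
        raise InputError("locomotion table needs time_s and position_cm columns")
    pos = pd.to_numeric(table["position_cm"], errors="coerce").to_numpy(float)
    tim = pd.to_numeric(table["time_s"], errors="coerce").to_numpy(float)
    if np.isnan(pos).any() or np.isnan(tim).any():
        raise InputError("non-numeric values in locomotion table")
    keep = (pos >= 0) & (pos <= track_length)
    pos, tim = pos[keep], tim[keep]
    if pos.size < 2:
        raise EmptyLibraryError("no usable locomotion rows")
    if frame_rate is None:
        frame_rate = 1.0 / np.median(np.diff(tim))
    breaks = np.flatnonzero(np.diff(pos) < -track_length / 2) + 1
    segments = np.split(pos, breaks)
    traversals = [s for s in segments
                  if s.size > 1 and s[0] < 0.1 * track_length
                  and s[-1] > 0.9 * track_length]
    if not traversals:
        raise EmptyLibraryError("no complete traversal found in table")
    return TraversalLibrary(traversals, float(frame_rate), track_length)


def assemble_locomotion(library: TraversalLibrary, n_traversals: int,
                        seed=None) -> LocomotionTrace:
    """Concatenate ``n_traversals`` segments sampled with replacement."""
    if n_traversals < 1:
        raise ParameterError("n_traversals must be >= 1")
    rng = as_rng(seed)
    idx = rng.integers(0, library.n_traversals, size=n_traversals)
    segs = [library.traversals[i] for i in idx]
    position = np.concatenate(segs)
    traversal_id = np.repeat(np.arange(1, n_traversals + 1),
                             [s.size for s in segs])
    time = np.arange(position.size) / library.frame_rate
    velocity = _segment_velocity(position, traversal_id, library.frame_rate)
    return LocomotionTrace(time, position, velocity, traversal_id,
                           library.frame_rate, library.track_length)


# ---------------------------------------------------------------------------
# place fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlaceFieldSpec:
    """Gaussian place-field parameters for one cell.

    ``width`` is defined as 4·sigma (95% of the Gaussian mass).  Reliability
    is the probability of expressing the field on a traversal; variability is
    the average per-traversal displacement of the field centre expressed as a
    fraction of the width.
    """

    centers: tuple[float, ...] = (DEFAULT_TRACK_LENGTH / 2,)
    sigma: float = DEFAULT_SIGMA
    peak: float = DEFAULT_PEAK
    reliability: float = 1.0
    variability: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if self.peak < 0:
            raise ParameterError("peak must be non-negative")
        if not 0 <= self.reliability <= 1:
            raise ParameterError("reliability must be in [0, 1]")
        if self.variability < 0:
            raise ParameterError("variability must be non-negative")
        if not 1 <= len(self.centers) <= 4:
            raise ParameterError("1 to 4 place fields supported")

    @property
    def width(self) -> float:
        return 4.0 * self.sigma

    @property
    def n_fields(self) -> int:
        return len(self.centers)

    def validate(self, track_length: float) -> None:
        c = np.asarray(self.centers, float)
        if c.min() < 0 or c.max() > track_length:
            raise ParameterError("field centres outside the track")
        if len(c) > 1:
            spacing = np.diff(np.sort(c)).min()
            if spacing < self.width - 1e-9:
                raise ParameterError("multiple fields must not overlap "
                                     "(centre spacing >= 4*sigma)")
        if self.n_fields > math.floor(track_length / self.width):
            raise ParameterError("too many fields for this track/width")


def gaussian_field_profile(spec: PlaceFieldSpec,
                           positions: np.ndarray) -> np.ndarray:
    """Evaluate the (possibly multi-field) Gaussian profile at ``positions``.

    Fields are truncated, not wrapped, at the track edges: the profile is
    simply evaluated at the clamped-in-track position values.
    """
    x = np.asarray(positions, float)
    out = np.zeros_like(x)
    for c in spec.centers:
        out += spec.peak * np.exp(-((x - c) ** 2) / (2.0 * spec.sigma**2))
    return out


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Per-frame Poisson shot noise plus optional random calcium transients."""

    lam: float = DEFAULT_LAMBDA
    transient_rate: float = 0.0  # peaks per frame
    transient_tau_s: float = 0.8  # indicator decay constant
    transient_amplitude: float = DEFAULT_PEAK

    def __post_init__(self):
        if self.lam <= 0:
            raise ParameterError("lambda must be positive")
        if not 0 <= self.transient_rate <= MAX_TRANSIENT_RATE:
            raise ParameterError(
                f"transient_rate must be in [0, {MAX_TRANSIENT_RATE}]")

    def kernel(self, frame_rate: float) -> np.ndarray:
        """Unit-amplitude fast-rise, exponential-decay transient shape."""
        tau_frames = self.transient_tau_s * frame_rate
        n = max(1, int(math.ceil(-tau_frames * math.log(0.01))))
        return np.exp(-np.arange(n) / tau_frames)


def poisson_dff_noise(noise: NoiseModel, n_frames: int, seed=None,
                      baseline_frames: int = BASELINE_FRAMES) -> np.ndarray:
    """Draw a raw Poisson trace and convert it to ΔF/F.

    The raw counts are divided by the mean of the first ``baseline_frames``
    frames and shifted by −1, the same baseline convention used for recorded
    traces, so a noiseless trace maps to 0.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    rng = as_rng(seed)
    raw = rng.poisson(noise.lam, size=n_frames).astype(float)
    if n_frames < baseline_frames:
        warnings.warn("trace shorter than the baseline window; using the "
                      "full-trace mean as baseline", stacklevel=2)
        baseline = raw.mean()
    else:
        baseline = raw[:baseline_frames].mean()
    if baseline <= 0:
        raise ParameterError("zero baseline in noise trace")
    return raw / baseline - 1.0


def add_random_transients(trace: np.ndarray, rate: float,
                          kernel: np.ndarray, seed=None) -> np.ndarray:
    """Add Bernoulli(rate)-triggered calcium transients to a ΔF/F trace."""
    if not 0 <= rate <= MAX_TRANSIENT_RATE:
        raise ParameterError(f"rate must be in [0, {MAX_TRANSIENT_RATE}]")
    if rate == 0:
        return np.asarray(trace, float).copy()
    rng = as_rng(seed)
    events = (rng.random(trace.size) < rate).astype(float)
    sig = np.convolve(events, kernel)[: trace.size]
    return np.asarray(trace, float) + sig


# ---------------------------------------------------------------------------
# cells and populations
# ---------------------------------------------------------------------------


@dataclass
class CellRealisation:
    """Per-traversal realisation of one simulated place cell."""

    active: np.ndarray  # bool per traversal
    centers: np.ndarray  # (n_traversals, n_fields) cm


def simulate_cell(spec: PlaceFieldSpec, locomotion: LocomotionTrace,
                  noise: NoiseModel, seed=None,
                  ) -> tuple[np.ndarray, CellRealisation]:
    """Simulate one place cell's ΔF/F trace on a locomotion trace.

    Exactly ``round(reliability * n_traversals)`` traversals are active
    (a uniformly random subset).  On each active traversal the field centre
    is displaced by a Gaussian offset whose SD is chosen so that the mean
    absolute displacement equals ``variability * width``
    (SD = variability·width·sqrt(pi/2)); displaced centres are clipped to
    the track.
    """
    spec.validate(locomotion.track_length)
    rng = as_rng(seed)
    n_trav = locomotion.n_traversals
    n_active = int(round(spec.reliability * n_trav))
    active = np.zeros(n_trav, bool)
    active[rng.choice(n_trav, size=n_active, replace=False)] = True

    base = np.asarray(spec.centers, float)
    offset_sd = spec.variability * spec.width * math.sqrt(math.pi / 2.0)
    if offset_sd > 0:
        centers = base[None, :] + rng.normal(0.0, offset_sd,
                                             size=(n_trav, base.size))
        centers = np.clip(centers, 0.0, locomotion.track_length)
    else:
        centers = np.tile(base, (n_trav, 1))

    tid = locomotion.traversal_id - 1
    pos = locomotion.position
    sig = np.zeros(locomotion.n_frames)
    for f in range(base.size):
        c_at_frame = centers[tid, f]
        sig += spec.peak * np.exp(-((pos - c_at_frame) ** 2)
                                  / (2.0 * spec.sigma**2))
    sig *= active[tid]
    dff = sig + poisson_dff_noise(noise, locomotion.n_frames, rng)
    return dff, CellRealisation(active, centers)


@dataclass
class PopulationSpec:
    """Composition of a simulated cell population.

    ``field_layout`` controls automatic centre placement for the place cells:
    ``equidistant`` spreads centres evenly over the track, ``identical``
    stacks them all at the track midpoint, and ``explicit`` uses the supplied
    ``field_specs`` unchanged.  ``transient_cells`` selects which cells
    receive random calcium transients when the noise model's rate is > 0.
    """

    n_place: int = DEFAULT_N_PLACE
    n_nonplace: int = DEFAULT_N_NONPLACE
    field_specs: list[PlaceFieldSpec] | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    field_layout: str = "equidistant"
    transient_cells: str = "nonplace"  # or "all"

    @property
    def n_cells(self) -> int:
        return self.n_place + self.n_nonplace


def _auto_field_specs(pop: PopulationSpec, track_length: float,
                      template: PlaceFieldSpec) -> list[PlaceFieldSpec]:
    n_fields = template.n_fields
    if pop.field_layout == "identical":
        centers = np.full(pop.n_place, track_length / 2.0)
    elif pop.field_layout == "equidistant":
        if n_fields == 1:
            centers = (np.arange(pop.n_place) + 0.5) * track_length / pop.n_place
        else:
            # multi-field cells: fields one track-fraction apart, cells
            # staggered within the first fraction
            seg = track_length / n_fields
            centers = (np.arange(pop.n_place) + 0.5) * seg / pop.n_place
    else:
        raise ParameterError(f"unknown field_layout {pop.field_layout!r}")
    specs = []
    for c in centers:
        if n_fields == 1:
            cs = (float(c),)
        else:
            seg = track_length / n_fields
            cs = tuple(float(c + j * seg) for j in range(n_fields))
        specs.append(replace(template, centers=cs))
    return specs


@dataclass
class FluorescenceMatrix:
    """Cell × frame ΔF/F with ground-truth labels and per-cell metadata."""

    dff: np.ndarray  # (n_cells, n_frames)
    truth_labels: np.ndarray  # bool, True = place cell
    frame_rate: float = DEFAULT_FRAME_RATE
    cell_params: pd.DataFrame | None = None

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


def build_population(pop: PopulationSpec, locomotion: LocomotionTrace,
                     seed=None,
                     template: PlaceFieldSpec | None = None,
                     ) -> FluorescenceMatrix:
    """Simulate a full population on a shared locomotion trace.

    Place cells are simulated with :func:`simulate_cell`; non-place cells are
    pure noise plus optional random transients.  Each cell draws from its own
    spawned random stream, so populations are reproducible cell-by-cell.
    """
    specs = pop.field_specs
    if specs is None:
        specs = _auto_field_specs(pop, locomotion.track_length,
                                  template or PlaceFieldSpec())
    if len(specs) != pop.n_place:
        raise ParameterError("len(field_specs) must equal n_place")

    rng = as_rng(seed)
    streams = rng.spawn(pop.n_cells)
    n_frames = locomotion.n_frames
    dff = np.empty((pop.n_cells, n_frames))
    truth = np.zeros(pop.n_cells, bool)
    truth[: pop.n_place] = True
    kernel = pop.noise.kernel(locomotion.frame_rate) * pop.noise.transient_amplitude
    rows = []
    for i in range(pop.n_cells):
        r = streams[i]
        if i < pop.n_place:
            s = specs[i]
            trace, _ = simulate_cell(s, locomotion, pop.noise, r)
            if pop.noise.transient_rate > 0 and pop.transient_cells == "all":
                trace = add_random_transients(trace, pop.noise.transient_rate,
                                              kernel, r)
            rows.append(dict(cell=i, label="place", centers=s.centers,
                             sigma=s.sigma, peak=s.peak,
                             reliability=s.reliability,
                             variability=s.variability))
        else:
            trace = poisson_dff_noise(pop.noise, n_frames, r)
            if pop.noise.transient_rate > 0:
                trace = add_random_transients(trace, pop.noise.transient_rate,
                                              kernel, r)
            rows.append(dict(cell=i, label="nonplace", centers=None,
                             sigma=np.nan, peak=np.nan, reliability=np.nan,
                             variability=np.nan))
        dff[i] = trace
    meta = pd.DataFrame(rows)
    return FluorescenceMatrix(dff, truth, locomotion.frame_rate, meta)


DEFAULT_HETEROGENEOUS_RANGES = {
    "width": (20.0, 200.0),  # cm, matching the single-parameter sweep extent
    "peak": (0.1, 2.0),  # dF/F
    "reliability": (0.0, 1.0),
    "variability": (0.0, 1.5),
}


def sample_heterogeneous_spec(ranges: dict | None = None, n_cells: int = 100,
                              seed=None,
                              track_length: float = DEFAULT_TRACK_LENGTH,
                              noise: NoiseModel | None = None,
                              ) -> PopulationSpec:
    """Draw a heterogeneous all-place-cell population spec.

    Every cell gets independent uniform draws of width, peak, reliability and
    variability from ``ranges`` (defaults span the single-parameter sweeps)
    and a uniform field centre on the track.  No control cells are included.
    """
    rr = dict(DEFAULT_HETEROGENEOUS_RANGES)
    if ranges:
        rr.update(ranges)
    for k, (lo, hi) in rr.items():
        if hi < lo:
            raise ParameterError(f"inverted range for {k}")
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    rng = as_rng(seed)
    specs = []
    for _ in range(n_cells):
        w = rng.uniform(*rr["width"])
        specs.append(PlaceFieldSpec(
            centers=(float(rng.uniform(0, track_length)),),
            sigma=w / 4.0,
            peak=float(rng.uniform(*rr["peak"])),
            reliability=float(rng.uniform(*rr["reliability"])),
            variability=float(rng.uniform(*rr["variability"])),
        ))
    return PopulationSpec(n_place=n_cells, n_nonplace=0, field_specs=specs,
                          noise=noise or NoiseModel(),
                          field_layout="explicit")
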