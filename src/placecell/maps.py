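"""Fluorescence maps over location bins.

A fluorescence map is the calcium-imaging analogue of a firing-rate map: the
mean ΔF/F of a cell in each location bin, computed over running frames only.
Maps are built per session and per traversal; bins that the animal skipped
within a traversal (possible at a 7.51 Hz frame rate) are marked missing
(NaN), as is any bin with zero running occupancy over the whole session.

Bins are equal-width and half-open ``[a, b)`` with the final bin closed; the
default of 40 bins on a 200 cm track (5 cm bins) resolves the default 50 cm
field with 10 bins while keeping per-bin occupancy adequate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EmptySessionError, InputError
from .synth import BASELINE_FRAMES

DEFAULT_N_BINS = 40
FRACTION_SPEED_THRESHOLD = 0.10  # of max speed, real-data running criterion


def normalize_dff(raw: np.ndarray,
                  baseline_frames: int = BASELINE_FRAMES) -> np.ndarray:
    """Normalise raw intensities to ΔF/F (real-data convention).

    Each cell's trace is divided by the mean of its first ``baseline_frames``
    frames; no constant is subtracted.
    """
    raw = np.atleast_2d(np.asarray(raw, float))
    if raw.shape[1] < baseline_frames:
        raise InputError(f"need at least {baseline_frames} frames")
    baseline = raw[:, :baseline_frames].mean(axis=1)
    bad = np.flatnonzero(baseline <= 0)
    if bad.size:
        raise InputError(f"non-positive baseline for cells {bad.tolist()}")
    return raw / baseline[:, None]


def running_mask(velocity: np.ndarray, mode: str = "absolute",
                 threshold: float | None = None) -> np.ndarray:
    """Boolean per-frame mask of running periods.

    ``absolute`` keeps frames with speed >= 2 cm/s (model-data default);
    ``fraction`` keeps frames with speed >= 10% of the maximum speed
    (real-data default).  ``threshold`` overrides either default.
    """
    v = np.asarray(velocity, float)
    if mode == "absolute":
        thr = 2.0 if threshold is None else threshold
    elif mode == "fraction":
        frac = FRACTION_SPEED_THRESHOLD if threshold is None else threshold
        thr = frac * v.max()
    else:
        raise InputError(f"unknown running-mask mode {mode!r}")
    mask = v >= thr
    if not mask.any():
        raise EmptySessionError("all frames fall below the running threshold")
    return mask


def segment_traversals(position: np.ndarray,
                       track_length: float) -> np.ndarray:
    """Assign 1-based traversal IDs, splitting at position resets.

    A new traversal starts whenever the position drops by more than half the
    track length between consecutive frames; smaller backtracking does not
    split a traversal.
    """
    pos = np.asarray(position, float)
    resets = np.diff(pos) < -track_length / 2
    return 1 + np.concatenate([[0], np.cumsum(resets)]).astype(int)


def bin_index(position: np.ndarray, n_bins: int,
              track_length: float) -> np.ndarray:
    """Half-open equal-width bin index per frame; the last bin is closed."""
    idx = np.floor(np.asarray(position, float) / track_length * n_bins)
    return np.clip(idx, 0, n_bins - 1).astype(np.intp)


@dataclass
class FluorescenceMap:
    """Session and per-traversal mean-ΔF/F maps for a population.

    ``values`` is (cells, bins) with NaN for session-empty bins;
    ``per_traversal`` is (cells, traversals, bins) with NaN for bins the
    animal skipped within that traversal; ``occupancy`` counts running
    frames per bin and sums to the number of running frames.
    """

    values: np.ndarray
    bin_edges: np.ndarray
    occupancy: np.ndarray
    per_traversal: np.ndarray | None = None
    mean_rate: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1


def _grouped_means(dff2d: np.ndarray, group: np.ndarray, n_groups: int,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Mean of each dff column-group, NaN where the group is empty.

    ``group`` assigns one group per (running) frame column of ``dff2d``.
    """
    counts = np.bincount(group, minlength=n_groups)
    order = np.argsort(group, kind="stable")
    present = np.flatnonzero(counts)
    starts = np.concatenate([[0], np.cumsum(counts[present])[:-1]])
    out = np.full((dff2d.shape[0], n_groups), np.nan)
    if present.size:
        sums = np.add.reduceat(dff2d[:, order], starts, axis=1)
        out[:, present] = sums / counts[present]
    return out, counts


def compute_fluorescence_map(dff: np.ndarray, position: np.ndarray,
                             mask: np.ndarray, n_bins: int = DEFAULT_N_BINS,
                             track_length: float = 200.0,
                             traversal_id: np.ndarray | None = None,
                             per_traversal: bool = True) -> FluorescenceMap:
    """Bin running-frame ΔF/F into session and per-traversal maps."""
    if n_bins < 2:
        raise InputError("n_bins must be >= 2")
    dff = np.atleast_2d(np.asarray(dff, float))
    position = np.asarray(position, float)
    mask = np.asarray(mask, bool)
    if not (dff.shape[1] == position.size == mask.size):
        raise InputError("dff, position and mask must share the frame axis")
    if traversal_id is None:
        traversal_id = segment_traversals(position, track_length)

    run = np.flatnonzero(mask)
    if run.size == 0:
        raise EmptySessionError("no running frames")
    bins = bin_index(position[run], n_bins, track_length)
    dff_run = dff[:, run]
    values, occupancy = _grouped_means(dff_run, bins, n_bins)
    if not occupancy.all():
        warnings.warn("some location bins have zero session occupancy",
                      stacklevel=2)

    per_trav = None
    if per_traversal:
        tid = np.asarray(traversal_id)[run] - 1
        n_trav = int(np.asarray(traversal_id).max())
        combined = tid * n_bins + bins
        flat, _ = _grouped_means(dff_run, combined, n_trav * n_bins)
        per_trav = flat.reshape(dff.shape[0], n_trav, n_bins)

    edges = np.linspace(0.0, track_length, n_bins + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_rate = np.nanmean(values, axis=1)
    return FluorescenceMap(values, edges, occupancy, per_trav, mean_rate)
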