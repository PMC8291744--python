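"""Scoring, parameter sweeps, inter-method overlap and cell properties.

Detectors are scored against ground truth with sensitivity = TP/(TP+FN)
and specificity = TN/(TN+FP).  Sweeps rebuild a fresh population (with a
fresh locomotion draw) for every grid value × repeat and report per-point
means with t-based 95% confidence intervals.  Overlap between method pairs
is compared to the chance level pA·pB with paired t-tests and
Holm–Bonferroni correction over the six pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import detect as _detect
from . import synth as _synth
from .detect import ALL_METHODS, CombinationParams, detect_all
from .errors import InputError, ParameterError
from .maps import DEFAULT_N_BINS, compute_fluorescence_map, running_mask
from .synth import (DEFAULT_LIBRARY_SIZE, DEFAULT_N_TRAVERSALS, NoiseModel,
                    PlaceFieldSpec, PopulationSpec, as_rng)

# ---------------------------------------------------------------------------
# confusion counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @classmethod
    def from_labels(cls, labels, truth) -> "ConfusionCounts":
        labels = np.asarray(labels, bool)
        truth = np.asarray(truth, bool)
        if labels.size != truth.size:
            raise InputError("labels and truth differ in length")
        return cls(tp=int((labels & truth).sum()),
                   tn=int((~labels & ~truth).sum()),
                   fp=int((labels & ~truth).sum()),
                   fn=int((~labels & truth).sum()))


def confusion(labels, truth) -> ConfusionCounts:
    """Tally detector labels against ground truth."""
    return ConfusionCounts.from_labels(labels, truth)


def sensitivity(cc: ConfusionCounts) -> float:
    """TP/(TP+FN); NaN when there are no true place cells."""
    denom = cc.tp + cc.fn
    return cc.tp / denom if denom else float("nan")


def specificity(cc: ConfusionCounts) -> float:
    """TN/(TN+FP); NaN when there are no true non-place cells."""
    denom = cc.tn + cc.fp
    return cc.tn / denom if denom else float("nan")


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

SWEEP_PARAMETERS = ("n_traversals", "width", "peak", "n_fields",
                    "reliability", "variability", "pct_place",
                    "transient_rate", "layout")


@dataclass
class SweepResult:
    """Tidy per-repeat sweep data plus a mean/CI summary table."""

    parameter: tuple[str, ...]
    data: pd.DataFrame  # one row per grid point × repeat × method
    summary: pd.DataFrame  # means and 95% CI per grid point × method


def _t_ci(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return (float("nan"), float("nan"))
    m = x.mean()
    h = sstats.t.ppf(0.975, x.size - 1) * sstats.sem(x)
    return (m - h, m + h)


def _population_for(params: dict[str, float | str], track_length: float,
                    ) -> tuple[PopulationSpec, int, PlaceFieldSpec]:
    """Translate sweep parameter values into a PopulationSpec + traversal
    count, starting from the default 20/80 model."""
    n_trav = int(params.get("n_traversals", DEFAULT_N_TRAVERSALS))
    width = float(params.get("width", 4 * _synth.DEFAULT_SIGMA))
    template = PlaceFieldSpec(
        centers=tuple([track_length / 2] * int(params.get("n_fields", 1))),
        sigma=width / 4.0,
        peak=float(params.get("peak", _synth.DEFAULT_PEAK)),
        reliability=float(params.get("reliability", 1.0)),
        variability=float(params.get("variability", 0.0)),
    )
    n_place = int(round(float(params.get("pct_place", 20.0))))
    noise = NoiseModel(transient_rate=float(params.get("transient_rate", 0.0)))
    pop = PopulationSpec(n_place=n_place, n_nonplace=100 - n_place,
                         noise=noise,
                         field_layout=str(params.get("layout", "equidistant")))
    return pop, n_trav, template


def run_sweep(parameter, values, *, n_repeats: int = 10,
              methods=ALL_METHODS, library=None,
              n_bins: int = DEFAULT_N_BINS,
              combination_params: CombinationParams | None = None,
              n_shuffles: dict | None = None, seed=None) -> SweepResult:
    """Sweep one parameter (or a pair) of the default model.

    ``parameter`` is a name from :data:`SWEEP_PARAMETERS` or a tuple of two
    names; ``values`` is the matching grid (tuples for 2-D sweeps).  Every
    grid point × repeat builds a fresh locomotion draw and population from a
    child random stream of ``seed``, runs the requested detectors and scores
    them against ground truth.
    """
    names = (parameter,) if isinstance(parameter, str) else tuple(parameter)
    for nm in names:
        if nm not in SWEEP_PARAMETERS:
            raise ParameterError(f"unknown sweep parameter {nm!r}")
    rng = as_rng(seed)
    if library is None:
        library = _synth.synthesize_traversal_library(
            DEFAULT_LIBRARY_SIZE, seed=rng)
    rows = []
    for value in values:
        vals = (value,) if isinstance(parameter, str) else tuple(value)
        pdict = dict(zip(names, vals))
        for rep in range(n_repeats):
            child = rng.spawn(1)[0]
            pop, n_trav, template = _population_for(pdict,
                                                    library.track_length)
            loco = _synth.assemble_locomotion(library, n_trav, child)
            fl = _synth.build_population(pop, loco, child, template=template)
            res = detect_all(fl.dff, loco.position, loco.velocity,
                             methods=methods, n_bins=n_bins,
                             track_length=library.track_length,
                             frame_rate=library.frame_rate,
                             traversal_id=loco.traversal_id,
                             combination_params=combination_params,
                             n_shuffles=n_shuffles, seed=child)
            for m, r in res.items():
                cc = confusion(r.labels, fl.truth_labels)
                row = {f"param_{k}": v for k, v in pdict.items()}
                row.update(repeat=rep, method=m,
                           sensitivity=sensitivity(cc),
                           specificity=specificity(cc),
                           tp=cc.tp, tn=cc.tn, fp=cc.fp, fn=cc.fn,
                           frac_detected=(cc.tp + cc.fp) / max(1, fl.n_cells))
                rows.append(row)
    data = pd.DataFrame(rows)
    keys = [f"param_{nm}" for nm in names] + ["method"]
    parts = []
    for key, g in data.groupby(keys, dropna=False):
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        for col in ("sensitivity", "specificity", "frac_detected"):
            x = g[col].to_numpy()
            lo, hi = _t_ci(x)
            rec[f"{col}_mean"] = np.nanmean(x) if np.isfinite(x).any() else np.nan
            rec[f"{col}_ci_low"], rec[f"{col}_ci_high"] = lo, hi
        rec["n_repeats"] = len(g)
        parts.append(rec)
    return SweepResult(names, data, pd.DataFrame(parts))


# ---------------------------------------------------------------------------
# inter-method overlap
# ---------------------------------------------------------------------------


@dataclass
class OverlapTable:
    """Observed vs chance-level overlap for every method pair."""

    table: pd.DataFrame  # per pair: means, t statistic, raw and Holm p
    per_dataset: pd.DataFrame  # per pair × dataset observed/expected


def overlap_analysis(labels_per_dataset: list[dict[str, np.ndarray]],
                     ) -> OverlapTable:
    """Compare observed pairwise overlap to the independence chance level.

    ``labels_per_dataset`` holds, per dataset, each method's boolean label
    vector over the same cells.  Observed overlap is the fraction of cells
    labelled by both methods; the chance level is the product of the two
    marginal detection fractions.  With >= 2 datasets the observed and
    expected values are compared per pair with a paired t-test,
    Holm–Bonferroni corrected over all pairs.
    """
    if not labels_per_dataset:
        raise InputError("no datasets supplied")
    methods = list(labels_per_dataset[0].keys())
    pairs = [(a, b) for i, a in enumerate(methods)
             for b in methods[i + 1:]]
    rows = []
    for d, labels in enumerate(labels_per_dataset):
        for a, b in pairs:
            la = np.asarray(labels[a], bool)
            lb = np.asarray(labels[b], bool)
            pa, pb = la.mean(), lb.mean()
            rows.append(dict(dataset=d, method_a=a, method_b=b,
                             observed=(la & lb).mean(), expected=pa * pb,
                             frac_a=pa, frac_b=pb))
    per_dataset = pd.DataFrame(rows)
    recs = []
    for (a, b), g in per_dataset.groupby(["method_a", "method_b"], sort=False):
        rec = dict(method_a=a, method_b=b,
                   observed_mean=g["observed"].mean(),
                   expected_mean=g["expected"].mean(),
                   n_datasets=len(g))
        if len(g) >= 2:
            t, p = sstats.ttest_rel(g["observed"], g["expected"])
            rec["t"], rec["p_raw"] = float(t), float(p)
        else:
            rec["t"] = rec["p_raw"] = float("nan")
        recs.append(rec)
    table = pd.DataFrame(recs)
    if table["p_raw"].notna().all() and len(table) > 0:
        from statsmodels.stats.multitest import multipletests

        table["p_holm"] = multipletests(table["p_raw"], method="holm")[1]
    else:
        table["p_holm"] = float("nan")
    return OverlapTable(table, per_dataset)


# ---------------------------------------------------------------------------
# cell properties
# ---------------------------------------------------------------------------


def fwhm(map_values: np.ndarray, bin_edges: np.ndarray,
         ) -> tuple[float, float, float]:
    """Full width at half maximum of a session map around its global peak.

    Crossings of the half-maximum level are linearly interpolated between
    bin centres; if a side never drops below half-max the field is taken to
    extend to the track edge.  Returns (width, left, right), all NaN for a
    flat or empty map.  The FWHM of a Gaussian field is 2·sqrt(2·ln 2)·sigma,
    narrower than the nominal 4·sigma model width.
    """
    v = np.asarray(map_values, float)
    centers = 0.5 * (np.asarray(bin_edges[:-1]) + np.asarray(bin_edges[1:]))
    finite = np.isfinite(v)
    if finite.sum() < 2 or np.nanmax(v) == np.nanmin(v):
        return (float("nan"),) * 3
    k = int(np.nanargmax(v))
    half = v[k] / 2.0

    def _cross(idx_range, edge_value):
        prev_c, prev_v = centers[k], v[k]
        for j in idx_range:
            vj = v[j] if np.isfinite(v[j]) else -np.inf
            if vj < half:
                # linear interpolation between the last above-half centre
                # and this one
                if np.isfinite(v[j]):
                    t = (prev_v - half) / (prev_v - vj)
                    return prev_c + t * (centers[j] - prev_c)
                return 0.5 * (prev_c + centers[j])
            prev_c, prev_v = centers[j], vj
        return edge_value

    left = _cross(range(k - 1, -1, -1), bin_edges[0])
    right = _cross(range(k + 1, v.size), bin_edges[-1])
    return (float(right - left), float(left), float(right))


def characterize_cells(dff, position, velocity, *,
                       n_bins: int = DEFAULT_N_BINS,
                       track_length: float = 200.0,
                       frame_rate: float = _synth.DEFAULT_FRAME_RATE,
                       mask: np.ndarray | None = None,
                       n_shuffles: int = 100, n_draws: int = 100,
                       seed=None) -> pd.DataFrame:
    """Per-cell properties: FWHM, split-half stability, spatial information,
    out/in-field fluorescence ratio, and peak/stability shuffle percentiles.

    The out/in ratio divides the mean fluorescence outside the FWHM field by
    the mean inside (lower = cleaner field); percentiles locate each cell's
    true statistic within its own shuffle null.
    """
    dff = np.atleast_2d(np.asarray(dff, float))
    if mask is None:
        mask = running_mask(velocity)
    fmap = compute_fluorescence_map(dff, position, mask, n_bins, track_length,
                                    per_traversal=False)
    rng = as_rng(seed)
    s_peak, s_stab = rng.spawn(2)
    pk = _detect.peak_method(dff, position, mask, n_bins, track_length,
                             frame_rate, n_shuffles=n_shuffles, seed=s_peak)
    st = _detect.stability_method(dff, position, mask, n_bins, track_length,
                                  n_draws=n_draws, seed=s_stab)
    centers = 0.5 * (fmap.bin_edges[:-1] + fmap.bin_edges[1:])
    rows = []
    for i in range(dff.shape[0]):
        v = fmap.values[i]
        w, left, right = fwhm(v, fmap.bin_edges)
        if math.isnan(w):
            out_in = float("nan")
        else:
            inside = (centers >= left) & (centers <= right) & np.isfinite(v)
            outside = ~((centers >= left) & (centers <= right)) & np.isfinite(v)
            in_mean = v[inside].mean() if inside.any() else float("nan")
            out_mean = v[outside].mean() if outside.any() else float("nan")
            out_in = out_mean / in_mean if in_mean else float("nan")
        rows.append(dict(cell=i, fwhm_cm=w,
                         stability_r=st.statistic[i],
                         spatial_information=_detect.spatial_information(v),
                         out_in_ratio=out_in,
                         peak_percentile=pk.percentile[i],
                         stability_percentile=st.percentile[i]))
    return pd.DataFrame(rows)


def centroid_distances(centroids: np.ndarray, labels,
                       ) -> tuple[float, float]:
    """Mean place-cell→place-cell and place-cell→non-place-cell centroid
    distances (pixels).  PC–PC is NaN with fewer than two place cells."""
    centroids = np.asarray(centroids, float)
    labels = np.asarray(labels, bool)
    if centroids.shape[0] != labels.size:
        raise InputError("centroids and labels differ in length")
    pc = centroids[labels]
    npc = centroids[~labels]
    if pc.shape[0] >= 2:
        d = pc[:, None, :] - pc[None, :, :]
        dist = np.sqrt((d**2).sum(-1))
        pc_pc = float(dist[np.triu_indices(pc.shape[0], 1)].mean())
    else:
        pc_pc = float("nan")
    if pc.shape[0] >= 1 and npc.shape[0] >= 1:
        d = pc[:, None, :] - npc[None, :, :]
        pc_npc = float(np.sqrt((d**2).sum(-1)).mean())
    else:
        pc_npc = float("nan")
    return pc_pc, pc_npc
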