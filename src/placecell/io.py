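"""Configuration, file readers/writers and the end-to-end pipeline.

Every paper-facing constant of the model and the detectors is a named field
of :class:`RunConfig` with its default value, and configs round-trip through
YAML.  All tables are delimited text (comma by default, tab accepted);
fluorescence matrices can also be stored as ``.npz`` archives.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import (ALL_METHODS, CombinationParams, detect_all,
                     results_frame)
from .errors import InputError
from .evaluate import (characterize_cells, confusion, run_sweep, sensitivity,
                       specificity)
from .maps import running_mask, segment_traversals
from .synth import (FluorescenceMatrix, LocomotionTrace, NoiseModel,
                    PlaceFieldSpec, PopulationSpec, _segment_velocity,
                    assemble_locomotion, build_population,
                    synthesize_traversal_library)

logger = logging.getLogger("placecell")


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with published defaults."""

    # track / acquisition
    track_length: float = 200.0  # cm
    frame_rate: float = 7.51  # Hz
    n_bins: int = 40
    # running mask
    speed_mode: str = "absolute"  # "absolute" (model) or "fraction" (real)
    speed_threshold: float = 2.0  # cm/s
    speed_fraction: float = 0.10  # of max speed, fraction mode
    # locomotion
    library_size: int = 184
    n_traversals: int = 50
    # population
    n_place: int = 20
    n_nonplace: int = 80
    sigma: float = 12.5  # cm
    peak: float = 1.3  # dF/F
    reliability: float = 1.0
    variability: float = 0.0
    n_fields: int = 1
    field_layout: str = "equidistant"
    noise_lambda: float = 235.1
    transient_rate: float = 0.0  # peaks/frame (real data: 0.0062)
    transient_tau_s: float = 0.8
    baseline_frames: int = 100
    # Peak / Information methods
    peak_shuffles: int = 500
    peak_percentile: float = 99.0
    info_shuffles: int = 500
    info_percentile: float = 95.0
    min_shift_s: float = 5.0
    # Stability method
    stability_draws: int = 100
    stability_percentile: float = 95.0
    # Combination method
    comb_field_threshold_frac: float = 0.25
    comb_min_width: float = 20.0  # cm
    comb_max_width: float = 120.0  # cm, exclusive
    comb_min_bin_frac: float = 0.10
    comb_min_inout_ratio: float = 4.0
    comb_min_traversal_frac: float = 0.20
    comb_shuffles: int = 1000
    comb_max_pass_frac: float = 0.05
    comb_preprocess: str = "none"
    comb_bootstrap: str = "chunk"
    comb_chunk_s: float = 10.0
    # run control
    seed: int = 0
    outdir: str = "results"
    methods: tuple[str, ...] = ALL_METHODS
    input_locomotion: str | None = None
    input_fluorescence: str | None = None
    sweep: dict | None = None  # {parameter, values, n_repeats, methods}

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "methods" in raw:
            raw = dict(raw, methods=tuple(raw["methods"]))
        return cls(**raw)

    def digest(self) -> str:
        js = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(js.encode()).hexdigest()[:16]

    # -- derived objects --------------------------------------------------
    def combination_params(self) -> CombinationParams:
        return CombinationParams(
            field_threshold_frac=self.comb_field_threshold_frac,
            min_width=self.comb_min_width, max_width=self.comb_max_width,
            min_bin_frac_of_mean=self.comb_min_bin_frac,
            min_inout_ratio=self.comb_min_inout_ratio,
            min_traversal_frac=self.comb_min_traversal_frac,
            n_shuffles=self.comb_shuffles,
            max_shuffle_pass_frac=self.comb_max_pass_frac,
            preprocess_mode=self.comb_preprocess,
            bootstrap_mode=self.comb_bootstrap, chunk_s=self.comb_chunk_s)

    def population_spec(self) -> tuple[PopulationSpec, PlaceFieldSpec]:
        template = PlaceFieldSpec(
            centers=tuple([self.track_length / 2] * self.n_fields),
            sigma=self.sigma, peak=self.peak, reliability=self.reliability,
            variability=self.variability)
        pop = PopulationSpec(
            n_place=self.n_place, n_nonplace=self.n_nonplace,
            noise=NoiseModel(lam=self.noise_lambda,
                             transient_rate=self.transient_rate,
                             transient_tau_s=self.transient_tau_s),
            field_layout=self.field_layout)
        return pop, template

    def shuffle_overrides(self) -> dict:
        return {"peak": self.peak_shuffles, "information": self.info_shuffles,
                "stability": self.stability_draws,
                "combination": self.comb_shuffles}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_locomotion(path, track_length: float = 200.0,
                    frame_rate: float | None = None) -> LocomotionTrace:
    """Read a per-frame locomotion CSV (time_s, position_cm[, velocity_cm_s]).

    A missing velocity column is recomputed by finite difference with a
    warning; traversal IDs are assigned by splitting at position resets.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("time_s", "position_cm"):
        if col not in df.columns:
            raise InputError(f"locomotion file missing column {col!r}")
    t = pd.to_numeric(df["time_s"], errors="coerce").to_numpy(float)
    pos = pd.to_numeric(df["position_cm"], errors="coerce").to_numpy(float)
    if np.isnan(t).any() or np.isnan(pos).any():
        raise InputError("non-numeric cells in locomotion file")
    if frame_rate is None:
        frame_rate = float(1.0 / np.median(np.diff(t)))
    tid = segment_traversals(pos, track_length)
    if "velocity_cm_s" in df.columns:
        vel = pd.to_numeric(df["velocity_cm_s"], errors="coerce").to_numpy(float)
        if np.isnan(vel).any():
            raise InputError("non-numeric cells in velocity column")
    else:
        warnings.warn("velocity column missing; recomputed by finite "
                      "difference", stacklevel=2)
        vel = _segment_velocity(pos, tid, frame_rate)
    return LocomotionTrace(t, pos, vel, tid, frame_rate, track_length)


def write_locomotion(path, loco: LocomotionTrace) -> None:
    pd.DataFrame({"time_s": loco.time, "position_cm": loco.position,
                  "velocity_cm_s": loco.velocity,
                  "traversal_id": loco.traversal_id}).to_csv(path,
                                                             index=False)


def read_fluorescence(path) -> np.ndarray:
    """Read a cells × frames ΔF/F matrix (CSV with a header row, or .npz
    with a ``dff`` array)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return np.asarray(z["dff"], float)
    df = pd.read_csv(path, sep=None, engine="python")
    arr = df.to_numpy()
    try:
        return np.asarray(arr, float)
    except (TypeError, ValueError) as e:
        raise InputError(f"non-numeric cells in fluorescence file: {e}")


def write_fluorescence(path, dff: np.ndarray) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, dff=dff)
    else:
        pd.DataFrame(dff, columns=[str(i) for i in range(dff.shape[1])]
                     ).to_csv(path, index=False)


def read_inputs(locomotion_path, fluorescence_path,
                config: RunConfig | None = None,
                ) -> tuple[LocomotionTrace, FluorescenceMatrix]:
    """Read and cross-validate a locomotion/fluorescence file pair."""
    cfg = config or RunConfig()
    loco = read_locomotion(locomotion_path, cfg.track_length)
    dff = read_fluorescence(fluorescence_path)
    if dff.ndim != 2:
        raise InputError("fluorescence matrix must be 2-D (cells x frames)")
    if dff.shape[1] != loco.n_frames:
        raise InputError(
            f"frame-count mismatch: fluorescence has {dff.shape[1]} frames, "
            f"locomotion has {loco.n_frames}")
    truth = np.zeros(dff.shape[0], bool)  # unknown for real data
    return loco, FluorescenceMatrix(dff, truth, loco.frame_rate)


def write_map(path, fmap) -> None:
    """Write a session map: metadata row with bin edges, then one row per
    cell with missing bins as empty fields."""
    with open(path, "w") as fh:
        fh.write("# bin_edges_cm," +
                 ",".join(f"{e:g}" for e in fmap.bin_edges) + "\n")
        pd.DataFrame(fmap.values).to_csv(fh, index=False, na_rep="")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def simulate_session(config: RunConfig, seed=None,
                     ) -> tuple[LocomotionTrace, FluorescenceMatrix]:
    """Build the configured synthetic locomotion trace and population."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lib = synthesize_traversal_library(config.library_size,
                                       config.track_length,
                                       config.frame_rate, seed=rng)
    loco = assemble_locomotion(lib, config.n_traversals, rng)
    pop, template = config.population_spec()
    fl = build_population(pop, loco, rng, template=template)
    return loco, fl


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """simulate (or load) → map → detect (all methods) → evaluate → write.

    Writes ``labels.csv``, ``statistics.csv``, ``properties.csv``,
    ``summary.json`` and ``run.log`` into the output directory and returns
    the summary dictionary.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        logger.info("start seed=%d config=%s version=%s", config.seed,
                    config.digest(), __version__)
        if config.input_locomotion and config.input_fluorescence:
            loco, fl = read_inputs(config.input_locomotion,
                                   config.input_fluorescence, config)
            truth_known = False
        else:
            loco, fl = simulate_session(config)
            truth_known = True
        logger.info("session: %d cells x %d frames, %d traversals",
                    fl.n_cells, fl.n_frames, loco.n_traversals)
        mask = running_mask(loco.velocity, config.speed_mode,
                            config.speed_threshold
                            if config.speed_mode == "absolute"
                            else config.speed_fraction)
        results = detect_all(
            fl.dff, loco.position, loco.velocity, methods=config.methods,
            n_bins=config.n_bins, track_length=config.track_length,
            frame_rate=config.frame_rate, traversal_id=loco.traversal_id,
            mask=mask, combination_params=config.combination_params(),
            n_shuffles=config.shuffle_overrides(),
            seed=np.random.default_rng(config.seed).spawn(1)[0])
        frame = results_frame(results)
        frame.pivot(index="cell", columns="method", values="label"
                    ).to_csv(out / "labels.csv")
        frame.to_csv(out / "statistics.csv", index=False)
        props = characterize_cells(
            fl.dff, loco.position, loco.velocity, n_bins=config.n_bins,
            track_length=config.track_length, frame_rate=config.frame_rate,
            mask=mask, seed=np.random.default_rng(config.seed).spawn(2)[1])
        props.to_csv(out / "properties.csv", index=False)
        summary = {"seed": config.seed, "config": config.digest(),
                   "version": __version__, "n_cells": int(fl.n_cells),
                   "n_frames": int(fl.n_frames),
                   "methods": {}}
        for m, r in results.items():
            entry = {"n_place": int(r.labels.sum())}
            if truth_known:
                cc = confusion(r.labels, fl.truth_labels)
                entry.update(sensitivity=sensitivity(cc),
                             specificity=specificity(cc))
            summary["methods"][m] = entry
            logger.info("method %s: %d cells labelled place", m,
                        entry["n_place"])
        if config.sweep:
            sw = dict(config.sweep)
            res = run_sweep(sw["parameter"], sw["values"],
                            n_repeats=int(sw.get("n_repeats", 10)),
                            methods=tuple(sw.get("methods", config.methods)),
                            n_bins=config.n_bins,
                            combination_params=config.combination_params(),
                            n_shuffles=config.shuffle_overrides(),
                            seed=config.seed)
            res.data.to_csv(out / "sweep.csv", index=False)
            res.summary.to_csv(out / "sweep_summary.csv", index=False)
            summary["sweep"] = {"parameter": sw["parameter"],
                                "n_rows": len(res.data)}
        summary["elapsed_s"] = round(time.time() - t0, 2)
        (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     sort_keys=True))
        logger.info("done in %.1fs", summary["elapsed_s"])
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()


def make_fixtures(outdir, seed: int = 0) -> dict:
    """Write a small example dataset (10 traversals, 4 place + 16 noise
    cells) that runs through the whole pipeline in seconds."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    lib = synthesize_traversal_library(10, seed=rng)
    loco = assemble_locomotion(lib, 10, rng)
    pop = PopulationSpec(n_place=4, n_nonplace=16)
    fl = build_population(pop, loco, rng)
    write_locomotion(out / "locomotion.csv", loco)
    write_fluorescence(out / "fluorescence.csv", fl.dff)
    fl.cell_params.to_csv(out / "cells.csv", index=False)
    return {"locomotion": str(out / "locomotion.csv"),
            "fluorescence": str(out / "fluorescence.csv"),
            "n_cells": fl.n_cells, "n_frames": fl.n_frames, "seed": seed}
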