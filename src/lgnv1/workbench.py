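"""Run orchestration: configuration, persistence, seeded pipelines.

A :class:`RunConfig` plus a single integer seed fully determines a run:
the seed is expanded through :class:`numpy.random.SeedSequence` into
independent per-stage streams (ensemble synthesis, training, the two
STA probe runs), so repeating a run reproduces every artifact bit for
bit.  Weights are persisted as NPZ archives written with fixed zip
metadata so that save -> load -> save is byte-identical.
"""

from __future__ import annotations

import hashlib
import io
import json
import time
import zipfile
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .learning import TrainingSchedule, train
from .network import ModelConfig, WeightSet
from .stimuli import make_whitened_ensemble

__all__ = [
    "RunConfig",
    "RunManifest",
    "StateSchemaError",
    "save_state",
    "load_state",
    "expand_seed",
    "run_pipeline",
]

STATE_SCHEMA_VERSION = 1


class StateSchemaError(ValueError):
    """Raised when a persisted state file has the wrong schema or shapes."""


@dataclass(frozen=True)
class StimuliConfig:
    """Training-ensemble settings."""

    n_images: int = 10
    image_size: int = 512
    filter_kind: str = "whitening"
    cutoff_cycles_per_image: float = 200.0
    variance_target: float = 0.2


@dataclass(frozen=True)
class AnalysisConfig:
    """Receptive-field / metrics settings."""

    sta_K: int = 70_000
    probe_filters: tuple[str, ...] = ("whitening", "lowpass")
    run_sta: bool = True
    run_metrics: bool = True
    run_contrast_invariance: bool = False


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    model: ModelConfig = field(default_factory=ModelConfig)
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule.desk_scale)
    stimuli: StimuliConfig = field(default_factory=StimuliConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"]["lr_stages"] = [list(s) for s in self.schedule.lr_stages]
        d["analysis"]["probe_filters"] = list(self.analysis.probe_filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sched = dict(d.get("schedule", {}))
        if "lr_stages" in sched:
            sched["lr_stages"] = tuple(tuple(s) for s in sched["lr_stages"])
        ana = dict(d.get("analysis", {}))
        if "probe_filters" in ana:
            ana["probe_filters"] = tuple(ana["probe_filters"])
        return cls(
            model=ModelConfig(**d.get("model", {})),
            schedule=TrainingSchedule(**sched),
            stimuli=StimuliConfig(**d.get("stimuli", {})),
            analysis=AnalysisConfig(**ana),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of a completed pipeline run."""

    config_hash: str
    package_version: str
    seed: int
    stage_seeds: dict
    artifacts: dict
    wall_time_s: float

    def write(self, path) -> None:
        """Write atomically (temp file + rename)."""
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
        tmp.replace(path)


def expand_seed(seed: int, n: int = 4) -> list[int]:
    """Expand one global seed into independent per-stage 31-bit seeds."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


def _deterministic_npz(path, arrays: dict, meta: dict) -> None:
    """Write an NPZ archive with fixed zip timestamps (byte-reproducible)."""
    path = Path(path)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, np.asarray(arr))
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())
        info = zipfile.ZipInfo("meta.json", date_time=(1980, 1, 1, 0, 0, 0))
        zf.writestr(info, json.dumps(meta, sort_keys=True))


def save_state(weights: WeightSet, config: ModelConfig, path) -> None:
    """Persist weights + model config to a version-tagged NPZ archive."""
    meta = {"schema_version": STATE_SCHEMA_VERSION, "model": asdict(config)}
    arrays = {name: getattr(weights, name) for name in WeightSet._FIELDS}
    _deterministic_npz(path, arrays, meta)


def load_state(path) -> tuple[WeightSet, ModelConfig]:
    """Load a persisted state, re-validating shapes and Dale's law."""
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        names = set(zf.namelist())
        if "meta.json" not in names:
            raise StateSchemaError(f"{path}: missing meta.json")
        meta = json.loads(zf.read("meta.json"))
        if meta.get("schema_version") != STATE_SCHEMA_VERSION:
            raise StateSchemaError(
                f"{path}: schema version {meta.get('schema_version')} "
                f"!= expected {STATE_SCHEMA_VERSION}"
            )
        arrays = {}
        for name in WeightSet._FIELDS:
            key = f"{name}.npy"
            if key not in names:
                raise StateSchemaError(f"{path}: missing dataset {name}")
            arrays[name] = np.load(io.BytesIO(zf.read(key)))
    config = ModelConfig(**meta["model"])
    shape = (2 * config.n_lgn, config.n_cortex)
    for name, arr in arrays.items():
        if arr.shape != shape:
            raise StateSchemaError(
                f"{path}: dataset {name} has shape {arr.shape}, expected {shape}"
            )
    weights = WeightSet(**arrays)
    try:
        weights.validate_dale()
    except ValueError as exc:
        raise StateSchemaError(f"{path}: integrity error: {exc}") from exc
    return weights, config


def run_pipeline(config: RunConfig, outdir) -> RunManifest:
    """Execute the full pipeline: stimuli -> training -> analysis -> report.

    Writes the trained weights, the per-epoch training trace, Gabor-fit
    tables for synaptic fields (and STA receptive fields when enabled),
    the overlap/push-pull tables, and a JSON population summary; returns
    (and writes) the run manifest.
    """
    from . import metrics, rf_analysis

    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = expand_seed(config.seed, 4)
    stage_seeds = {
        "ensemble": seeds[0],
        "train": seeds[1],
        "sta_whitening": seeds[2],
        "sta_lowpass": seeds[3],
    }
    artifacts: dict[str, str] = {}
    stage = "stimuli"
    try:
        ensemble = make_whitened_ensemble(
            config.stimuli.n_images,
            config.stimuli.image_size,
            seeds[0],
            cutoff=config.stimuli.cutoff_cycles_per_image,
            variance_target=config.stimuli.variance_target,
        )

        stage = "training"
        weights, trace = train(config.model, config.schedule, ensemble, seeds[1])
        weights_path = outdir / "weights.npz"
        save_state(weights, config.model, weights_path)
        artifacts["weights"] = str(weights_path)
        trace_path = outdir / "trace.csv"
        trace.to_dataframe().to_csv(trace_path, index=False)
        artifacts["trace"] = str(trace_path)

        stage = "rf_analysis"
        sfs = rf_analysis.synaptic_fields(weights)
        sf_fits = rf_analysis.fit_population(sfs)
        sf_table = rf_analysis.population_table(sf_fits)
        sf_path = outdir / "synaptic_field_fits.csv"
        sf_table.to_csv(sf_path, index=False)
        artifacts["synaptic_field_fits"] = str(sf_path)
        if config.analysis.run_sta:
            for probe, probe_seed in (
                ("whitening", seeds[2]),
                ("lowpass", seeds[3]),
            ):
                if probe not in config.analysis.probe_filters:
                    continue
                rfs = rf_analysis.sta_receptive_field(
                    weights, config.model, probe,
                    K=config.analysis.sta_K, seed=probe_seed,
                    variance_target=config.stimuli.variance_target,
                )
                table = rf_analysis.population_table(
                    rf_analysis.fit_population(rfs.fields)
                )
                p = outdir / f"rf_fits_{probe}.csv"
                table.to_csv(p, index=False)
                artifacts[f"rf_fits_{probe}"] = str(p)

        stage = "metrics"
        summary: dict = {"n_cells": config.model.n_cortex}
        if config.analysis.run_metrics:
            overlap = metrics.overlap_population(weights, config.model)
            overlap.to_csv(outdir / "overlap.csv", index=False)
            artifacts["overlap"] = str(outdir / "overlap.csv")
            pushpull = metrics.push_pull_population(weights, config.model)
            pushpull.to_csv(outdir / "pushpull.csv", index=False)
            artifacts["pushpull"] = str(outdir / "pushpull.csv")
            r_off, r_on = metrics.feedback_correlation(weights)
            summary.update(
                n_overlap_analyzed=int(len(overlap)),
                n_overlap_below_0p1=int((overlap["overlap"] < 0.1).sum()),
                pushpull_median=float(pushpull["index"].median())
                if len(pushpull) else None,
                r_feedback_off=r_off,
                r_feedback_on=r_on,
                n_gabor_qc_pass=int(sf_table["qc_pass"].sum()),
            )
            if config.analysis.run_contrast_invariance:
                tuning = metrics.contrast_invariance_population(
                    weights, config.model, sf_fits
                )
                import pandas as pd

                slopes = pd.DataFrame(
                    {"cell": [t.cell for t in tuning],
                     "slope": [t.slope for t in tuning]}
                )
                slopes.to_csv(outdir / "tuning_slopes.csv", index=False)
                artifacts["tuning_slopes"] = str(outdir / "tuning_slopes.csv")
                finite = slopes["slope"].dropna()
                summary["tuning_slope_median"] = (
                    float(finite.median()) if len(finite) else None
                )
        summary_path = outdir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        artifacts["summary"] = str(summary_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = RunManifest(
        config_hash=config.config_hash(),
        package_version=__version__,
        seed=config.seed,
        stage_seeds=stage_seeds,
        artifacts=artifacts,
        wall_time_s=time.time() - t0,
    )
    manifest.write(outdir / "manifest.json")
    return manifest
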