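"""End-to-end orchestration: schema validation, exclusion filtering, run bundles.

The shared trial-table schema is the one emitted by
:mod:`attnwarp.experiment_design` with the response columns appended by
:mod:`attnwarp.synthetic_observer`.  Real exports with other column names
can be ingested through a column-mapping config (``column_map`` in the run
config or :func:`ingest_table`); no network access happens here.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .experiment_design import EXPERIMENTS, design_experiment
from .population_geometry import GainProfile, PopulationSpec, analyze_geometry
from .sdt_model import fit_bias_model, summarize
from .synthetic_observer import CohortSpec, ObserverParams, simulate_cohort, simulate_dataset

__all__ = [
    "SCHEMA_COLUMNS",
    "RESPONSE_COLUMNS",
    "SchemaError",
    "PipelineStageError",
    "DEFAULT_EXCLUSION_THRESHOLDS",
    "validate_trial_table",
    "read_trial_table",
    "write_trial_table",
    "ingest_table",
    "apply_exclusions",
    "RunConfig",
    "config_hash",
    "run_pipeline",
]

SCHEMA_COLUMNS = [
    "experiment",
    "trial_index",
    "D",
    "distractor_direction",
    "delta",
    "foil_direction",
    "trial_kind",
    "salient_direction",
    "target_hue",
    "distractor_hue",
    "foil_hue",
    "target_position",
    "target_side",
    "set_size",
]
RESPONSE_COLUMNS = ["subject_id", "choice", "search_correct"]

_VOCAB = {
    "experiment": set(EXPERIMENTS),
    "distractor_direction": {"cw", "ccw"},
    "foil_direction": {"toward", "away", "none"},
    "trial_kind": {"both", "search_report", "similarity_report"},
    "salient_direction": {"cw", "ccw", "none"},
    "target_side": {"left", "right", "none"},
    "choice": {"target", "foil"},
}

DEFAULT_EXCLUSION_THRESHOLDS = {"E1": 0.70, "E2": 0.70, "E3": 0.70, "E4": 0.40}


class SchemaError(ValueError):
    """A trial table failed schema validation."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_trial_table(df: pd.DataFrame, require_responses: bool = False) -> None:
    """Raise :class:`SchemaError` unless ``df`` matches the shared schema."""
    needed = list(SCHEMA_COLUMNS) + (RESPONSE_COLUMNS if require_responses else [])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    for col, vocab in _VOCAB.items():
        if col not in df.columns:
            continue
        vals = set(df[col].dropna().unique())
        bad = vals - vocab
        if bad:
            raise SchemaError(f"column {col!r} has values outside {sorted(vocab)}: {sorted(bad)}")
    hues = df["target_hue"].to_numpy(dtype=float)
    if np.any((hues < 0) | (hues >= 360)):
        raise SchemaError("target_hue must lie in [0, 360)")
    if "search_correct" in df.columns:
        sc = df["search_correct"].dropna().to_numpy(dtype=float)
        if np.any(~np.isin(sc, (0.0, 1.0))):
            raise SchemaError("search_correct must be 0/1")


def write_trial_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_trial_table(path, require_responses: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_trial_table(df, require_responses=require_responses)
    return df


def ingest_table(path, column_map: Mapping[str, str]) -> pd.DataFrame:
    """Read an external export, renaming columns via ``column_map``.

    ``column_map`` maps schema names to the file's column names.  Schema
    columns absent from the map and the file are filled with neutral
    defaults where possible.
    """
    raw = pd.read_csv(path)
    rename = {src: dst for dst, src in column_map.items() if src in raw.columns}
    df = raw.rename(columns=rename)
    for col, default in (
        ("trial_kind", "both"),
        ("salient_direction", "none"),
        ("target_side", "none"),
        ("subject_id", 0),
    ):
        if col not in df.columns:
            df[col] = default
    validate_trial_table(df, require_responses=False)
    return df


def apply_exclusions(
    table: pd.DataFrame, thresholds: Optional[Mapping[str, float]] = None
):
    """Drop subjects whose mean search accuracy falls below their
    experiment's threshold.

    Returns ``(filtered_table, report)`` where the report lists every
    subject with accuracy, threshold and exclusion flag.
    """
    if "search_correct" not in table.columns or "subject_id" not in table.columns:
        raise SchemaError("apply_exclusions needs subject_id and search_correct columns")
    thr = dict(DEFAULT_EXCLUSION_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    acc = (
        table.groupby(["subject_id", "experiment"])["search_correct"]
        .mean()
        .reset_index(name="search_accuracy")
    )
    acc["threshold"] = acc["experiment"].map(thr)
    acc["excluded"] = acc["search_accuracy"] < acc["threshold"]
    bad = set(
        zip(acc.loc[acc["excluded"], "subject_id"], acc.loc[acc["excluded"], "experiment"])
    )
    keep = ~table.apply(
        lambda r: (r["subject_id"], r["experiment"]) in bad, axis=1
    ) if bad else pd.Series(True, index=table.index)
    return table[keep].reset_index(drop=True), acc


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    experiment: str = "E1"
    seed: int = 0
    n_observers: int = 1
    observer: Dict[str, object] = field(default_factory=dict)
    cohort: Optional[Dict[str, object]] = None
    exclusion_thresholds: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_THRESHOLDS)
    )
    fit: Optional[Dict[str, object]] = field(
        default_factory=lambda: {"bias_per_distance": True, "lapse": 0.0}
    )
    geometry: Optional[Dict[str, object]] = None
    data_path: Optional[str] = None  # analyze an existing table instead of simulating
    column_map: Optional[Dict[str, str]] = None
    out_dir: str = "attnwarp_out"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise SchemaError(f"unknown experiment {self.experiment!r}")
        if self.data_path is not None and not Path(self.data_path).exists():
            raise SchemaError(f"data_path does not exist: {self.data_path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> Dict[str, object]:
        return {
            "experiment": self.experiment,
            "seed": self.seed,
            "n_observers": self.n_observers,
            "observer": self.observer,
            "cohort": self.cohort,
            "exclusion_thresholds": self.exclusion_thresholds,
            "fit": self.fit,
            "geometry": self.geometry,
            "data_path": self.data_path,
            "column_map": self.column_map,
            "out_dir": self.out_dir,
        }


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _bias_keys_to_float(d):
    return {float(k): float(v) for k, v in d.items()} if d else None


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """design -> simulate/ingest -> exclude -> summarize -> fit -> geometry.

    Writes every artifact (CSV/JSON) plus a ``run.json`` record with the
    package version, config, config hash, seeds, exclusion decisions and
    fit convergence flags.  Deterministic stages are bit-identical across
    reruns with the same config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record: Dict[str, object] = {
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": config_hash(config),
        "seed": config.seed,
    }
    bundle: Dict[str, object] = {"record": record}

    with _stage("design"):
        design = design_experiment(config.experiment, config.seed)
        write_trial_table(design, out / "design.csv")
        bundle["design"] = design

    with _stage("simulate"):
        if config.data_path is not None:
            if config.column_map:
                data = ingest_table(config.data_path, config.column_map)
            else:
                data = read_trial_table(config.data_path, require_responses=True)
        elif config.n_observers > 1 or config.cohort is not None:
            spec_kwargs = dict(config.cohort or config.observer)
            spec_kwargs["bias_by_D"] = _bias_keys_to_float(spec_kwargs.get("bias_by_D"))
            cohort = CohortSpec(**spec_kwargs)
            data = simulate_cohort(config.n_observers, design, cohort, seed=config.seed)
        else:
            obs_kwargs = dict(config.observer)
            obs_kwargs["bias_by_D"] = _bias_keys_to_float(obs_kwargs.get("bias_by_D"))
            sa = obs_kwargs.get("search_accuracy")
            if isinstance(sa, dict):
                obs_kwargs["search_accuracy"] = _bias_keys_to_float(sa)
            params = ObserverParams(**obs_kwargs)
            data = simulate_dataset(design, params, seed=config.seed)
        validate_trial_table(data, require_responses=True)
        write_trial_table(data, out / "trials.csv")
        bundle["trials"] = data

    with _stage("exclusions"):
        filtered, report = apply_exclusions(data, config.exclusion_thresholds)
        report.to_csv(out / "exclusions.csv", index=False)
        record["n_excluded"] = int(report["excluded"].sum())
        bundle["exclusions"] = report
        bundle["filtered"] = filtered

    with _stage("summarize"):
        summaries = summarize(filtered)
        summaries.to_csv(out / "summaries.csv", index=False)
        bundle["summaries"] = summaries

    if config.fit is not None:
        with _stage("fit"):
            fit = fit_bias_model(summaries, **config.fit)
            (out / "fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
            record["fit_converged"] = fit.converged
            record["fit_boundary"] = fit.boundary
            bundle["fit"] = fit

    if config.geometry is not None:
        with _stage("geometry"):
            geo_cfg = dict(config.geometry)
            spec = PopulationSpec(**geo_cfg.get("population", {}))
            gain = GainProfile(**geo_cfg.get("gain", {}))
            result = analyze_geometry(
                spec,
                gain,
                target=float(geo_cfg.get("target", 0.0)),
                foil_delta=float(geo_cfg.get("foil_delta", 10.0)),
                grid_step=float(geo_cfg.get("grid_step", 1.0)),
            )
            result.write(out / "geometry")
            record["geometry_metrics"] = result.metrics()
            bundle["geometry"] = result

    (out / "run.json").write_text(json.dumps(record, indent=2, default=str))
    return bundle
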