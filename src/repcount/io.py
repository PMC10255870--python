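"""File formats: series CSV, corpus JSON Lines, YAML run config,
JSON model checkpoints and CSV training histories.

All formats are plain text and carry a ``format_version`` field where
they have a header or manifest.  The series CSV is a wide dialect (one
row per sample, ``index,label,ch_0,...``); a column mapping adapts
exports with other column names.
"""

from __future__ import annotations

import dataclasses
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import CountingRegressor, TrainingHistory
from .segment import SequenceCorpus, WeakSequence
from .series import DenseLabelTrack, MultichannelSeries

__all__ = [
    "FormatError",
    "read_series_csv",
    "write_series_csv",
    "read_corpus",
    "write_corpus",
    "save_checkpoint",
    "load_checkpoint",
    "write_history_csv",
    "default_run_config",
    "load_run_config",
    "dump_run_config",
]

FORMAT_VERSION = 1


def _package_version() -> str:
    try:
        return version("repcount")
    except PackageNotFoundError:  # pragma: no cover - editable edge case
        return "unknown"


class FormatError(ValueError):
    """Raised when an input file does not match its expected format."""


# --------------------------------------------------------------------- #
# series CSV


def write_series_csv(
    path: str | Path, series: MultichannelSeries, track: DenseLabelTrack
) -> None:
    if len(track) != series.n_samples:
        raise ValueError("label track length must match the series")
    frame = pd.DataFrame(series.samples, columns=series.channel_names)
    frame.insert(0, "label", track.labels)
    frame.insert(0, "index", np.arange(series.n_samples))
    frame.to_csv(path, index=False)


def read_series_csv(
    path: str | Path,
    column_mapping: dict | None = None,
    sample_rate_hz: float = 98.0,
) -> tuple[MultichannelSeries, DenseLabelTrack]:
    """Read a wide series CSV.

    ``column_mapping`` adapts foreign exports: ``{"label": <label column
    name>, "channels": [<ordered channel columns>]}``.  By default the
    label column is ``label`` and every ``ch_*`` column (in file order)
    is a channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"series CSV not found: {path}")
    frame = pd.read_csv(path)
    mapping = column_mapping or {}
    label_col = mapping.get("label", "label")
    if label_col not in frame.columns:
        raise FormatError(f"missing label column '{label_col}' in {path}")
    channel_cols = mapping.get(
        "channels", [c for c in frame.columns if c.startswith("ch_")]
    )
    if not channel_cols:
        raise FormatError(f"no channel columns found in {path}")
    for col in channel_cols:
        if col not in frame.columns:
            raise FormatError(f"missing channel column '{col}' in {path}")
    values = np.empty((len(frame), len(channel_cols)))
    for j, col in enumerate(channel_cols):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any() or numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna())[0])
            raise FormatError(f"non-numeric value in column '{col}' at data row {row}")
        values[:, j] = numeric.to_numpy()
    labels = pd.to_numeric(frame[label_col], errors="coerce")
    if labels.isna().any():
        row = int(np.flatnonzero(labels.isna())[0])
        raise FormatError(f"non-numeric label at data row {row}")
    series = MultichannelSeries(
        samples=values, sample_rate_hz=sample_rate_hz, channel_names=list(channel_cols)
    )
    track = DenseLabelTrack(labels=labels.to_numpy(dtype=np.int64))
    return series, track


# --------------------------------------------------------------------- #
# corpus JSONL (+ sidecar manifest)


def _manifest_path(path: Path) -> Path:
    return path.with_name(path.name + ".manifest.json")


def write_corpus(path: str | Path, corpus: SequenceCorpus) -> None:
    """One JSON record per sequence, plus a sidecar manifest file."""
    path = Path(path)
    with open(path, "w") as fh:
        for seq, split in zip(corpus.sequences, corpus.splits):
            record = {
                "source_id": seq.source_id,
                "start": seq.start,
                "end": seq.end,
                "weak_count": seq.weak_count,
                "split": split,
                "samples": seq.samples.tolist(),
            }
            fh.write(json.dumps(record) + "\n")
    manifest = {
        "format_version": FORMAT_VERSION,
        "rng_seed": corpus.rng_seed,
        "n_sequences": len(corpus),
        "channel_names": corpus.channel_names,
        **corpus.manifest,
    }
    with open(_manifest_path(path), "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


def read_corpus(path: str | Path) -> SequenceCorpus:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"corpus file not found: {path}")
    sequences: list[WeakSequence] = []
    splits: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
                sequences.append(
                    WeakSequence(
                        samples=np.asarray(record["samples"], dtype=np.float64),
                        start=record["start"],
                        end=record["end"],
                        weak_count=record["weak_count"],
                        source_id=record.get("source_id", "series"),
                    )
                )
                splits.append(record["split"])
            except (json.JSONDecodeError, KeyError, ValueError, TypeError) as exc:
                raise FormatError(f"malformed corpus record at line {lineno}: {exc}") from exc
    manifest: dict = {}
    rng_seed = None
    channel_names: list[str] = []
    mpath = _manifest_path(path)
    if mpath.exists():
        with open(mpath) as fh:
            manifest = json.load(fh)
        rng_seed = manifest.pop("rng_seed", None)
        channel_names = manifest.pop("channel_names", [])
        manifest.pop("format_version", None)
        manifest.pop("n_sequences", None)
    return SequenceCorpus(
        sequences=sequences,
        splits=splits,
        rng_seed=rng_seed,
        channel_names=channel_names,
        manifest=manifest,
    )


# --------------------------------------------------------------------- #
# model checkpoints


def save_checkpoint(path: str | Path, model: CountingRegressor) -> None:
    """Serialize a fitted model (config + parameters) as JSON."""
    if not hasattr(model, "params_"):
        raise ValueError("model has no parameters; fit or build it first")
    payload = {
        "format_version": FORMAT_VERSION,
        "library_version": _package_version(),
        "config": model.get_params(),
        "n_features_in": int(model.n_features_in_),
        "mask_threshold": float(getattr(model, "mask_threshold_", model.mask_threshold)),
        "params": {k: v.tolist() for k, v in model.params_.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def load_checkpoint(path: str | Path, n_channels: int | None = None) -> CountingRegressor:
    """Restore a model; refuses a channel-count mismatch if
    ``n_channels`` is given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"malformed checkpoint {path}: {exc}") from exc
    model = CountingRegressor(**payload["config"])
    model.params_ = {k: np.asarray(v, dtype=np.float64) for k, v in payload["params"].items()}
    model.n_features_in_ = int(payload["n_features_in"])
    model.mask_threshold_ = float(payload.get("mask_threshold", model.mask_threshold))
    from . import _net

    model.n_parameters_ = _net.n_parameters(model.params_)
    if n_channels is not None and n_channels != model.n_features_in_:
        raise FormatError(
            f"checkpoint expects {model.n_features_in_} channels, data has {n_channels}"
        )
    return model


def write_history_csv(path: str | Path, history: TrainingHistory) -> None:
    frame = pd.DataFrame(
        {
            "epoch": np.arange(len(history)),
            "train_loss": history.train_loss,
            "val_loss": history.val_loss,
            "steepness": history.steepness,
        }
    )
    frame.to_csv(path, index=False)


# --------------------------------------------------------------------- #
# run configuration (YAML, nested sections, defaults for every field)


def default_run_config() -> dict:
    from .synthetic import SyntheticConfig

    synthetic = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(SyntheticConfig()).items()
        if k not in ("class_names", "seed")
    }
    model = {
        k: v
        for k, v in CountingRegressor().get_params().items()
        if k not in ("random_state", "verbose")
    }
    return {
        "format_version": FORMAT_VERSION,
        "seed": 0,
        "synthetic": synthetic,
        "segmentation": {
            "n_sequences": 380,
            "replication": 4,
            "n_test": 50,
            "val_fraction": 0.1,
            "min_len": None,
        },
        "model": model,
        "io": {
            "column_mapping": {"label": "label", "channels": None},
            "sample_rate_hz": 98.0,
        },
    }


def _merge(defaults: dict, overrides: dict, trail: str = "") -> dict:
    out = dict(defaults)
    for key, value in overrides.items():
        where = f"{trail}{key}"
        if key not in defaults:
            raise FormatError(f"unknown configuration key: {where}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, trail=where + ".")
        else:
            out[key] = value
    return out


def load_run_config(path: str | Path | None = None) -> dict:
    """Load a YAML run config, overlaying it on the defaults.  Unknown
    keys are rejected so typos fail loudly."""
    config = default_run_config()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        if not isinstance(overrides, dict):
            raise FormatError(f"config root must be a mapping: {path}")
        config = _merge(config, overrides)
    return config


def dump_run_config(path: str | Path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
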