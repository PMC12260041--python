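"""Feature-table serialization, YAML configuration and the encoder adapter.

The canonical on-disk input is a feature table: one sample per row with
columns ``sample_id, label, feat_0 ... feat_{d-1}``, label 1 = case (m),
0 = control (h). CSV (comma, UTF-8, mandatory header, '.' decimal), TSV and
JSONL dialects are supported. Readers reject malformed rows rather than
coerce them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignment import KernelConfig
from .synthetic import DomainDataset
from .training import TrainConfig

FORMATS = ("csv", "tsv", "jsonl")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in FORMATS:
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def read_feature_table(path: str | Path, format: str | None = None) -> DomainDataset:
    """Read a feature table into a DomainDataset, preserving row order.

    Errors cite 1-based data row numbers.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    if fmt == "jsonl":
        rows = [json.loads(line) for line in path.read_text().splitlines() if line.strip()]
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t")
    required = {"sample_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    feat_cols = [c for c in df.columns if c.startswith("feat_")]
    if not feat_cols:
        raise ValueError(f"{path.name}: no feat_* columns")
    feat_cols.sort(key=lambda c: int(c.split("_", 1)[1]))
    labels = pd.to_numeric(df["label"], errors="coerce").to_numpy()
    for i, lab in enumerate(labels, start=1):
        if lab not in (0, 1):
            raise ValueError(f"{path.name}: non-binary label {df['label'].iloc[i-1]!r} on row {i}")
    features = df[feat_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(features)
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0][0]) + 1
        raise ValueError(f"{path.name}: non-finite feature value on row {row}")
    return DomainDataset(
        name=path.stem,
        features=features,
        labels=labels.astype(int),
        sample_ids=[str(s) for s in df["sample_id"]],
    )


def write_feature_table(data: DomainDataset, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    d = data.features.shape[1]
    df = pd.DataFrame(data.features, columns=[f"feat_{j}" for j in range(d)])
    df.insert(0, "label", data.labels)
    df.insert(0, "sample_id", data.sample_ids)
    if fmt == "jsonl":
        with open(path, "w") as fh:
            for rec in df.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
    else:
        df.to_csv(path, sep="," if fmt == "csv" else "\t", index=False)


@dataclass
class RunConfig:
    """TrainConfig plus run plumbing (stream manifest, output dir, logging)."""

    train: TrainConfig
    stream_manifest: str | None = None
    out_dir: str | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "train": self.train.to_dict(),
            "stream_manifest": self.stream_manifest,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }

    def content_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config; unknown keys are rejected, not ignored."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    top_known = {"train", "stream_manifest", "out_dir", "log_level"}
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    train_raw = dict(raw.get("train", {}))
    train_known = {f.name for f in fields(TrainConfig)}
    unknown = set(train_raw) - train_known
    if unknown:
        raise ValueError(f"unknown train config keys: {sorted(unknown)}")
    if "kernel" in train_raw and isinstance(train_raw["kernel"], dict):
        train_raw["kernel"] = KernelConfig(**train_raw["kernel"])
    if "hidden_dims" in train_raw:
        train_raw["hidden_dims"] = tuple(train_raw["hidden_dims"])
    return RunConfig(
        train=TrainConfig(**train_raw),
        stream_manifest=raw.get("stream_manifest"),
        out_dir=raw.get("out_dir"),
        log_level=raw.get("log_level", "INFO"),
    )


def save_run_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def embed_transcripts(texts: list[str], encoder_id: str) -> np.ndarray:
    """Adapter contract for users holding transcript-corpus licenses.

    Embeds each transcript with a pre-trained multilingual sentence encoder
    and returns one fixed-width row per text, ready to be written as a
    feature table. The encoder stack is an optional dependency; when it is
    not installed this raises with a pointer to the feature-table /
    synthetic paths, which are the tested core.
    """
    if not texts:
        return np.zeros((0, 0))
    try:
        import transformers  # noqa: F401
        import torch  # noqa: F401
    except ImportError as exc:
        raise RuntimeError(
            f"transcript encoder {encoder_id!r} unavailable: the optional "
            "transformers/torch stack is not installed. Precompute embeddings "
            "elsewhere and load them with read_feature_table(), or use the "
            "synthetic generators in udil.synthetic."
        ) from exc
    raise NotImplementedError(
        "encoder execution is outside the tested core; precompute embeddings "
        "and load them as feature tables"
    )
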