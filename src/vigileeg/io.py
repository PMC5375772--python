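"""Persistence and the online detection loop.

Recordings are stored either as EDF (16-bit, physical µV scaling declared in
the header) or as CSV with a header row of channel labels; per-second
vigilance labels live in a sidecar TSV (columns t, label) because EDF
annotation dialects vary. Feature matrices and evaluation reports serialise
to TSV/JSON; trained models to versioned JSON (see
:meth:`vigileeg.svm.SvmModel.save`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import edf as _edf
from .features import DEFAULT_BANDS, FeatureMatrix, extract_features
from .recording import CHANNELS_1020, EEGRecording
from .svm import SvmModel, decision_values
from .wavelet import DEFAULT_KEEP, denoise


# ---------------------------------------------------------------- recordings

def write_recording(recording: EEGRecording, path, fmt: Optional[str] = None) -> None:
    fmt = fmt or _infer_format(path)
    if fmt == "edf":
        _edf.write_edf(path, recording.data, recording.fs, recording.channels)
    elif fmt == "csv":
        df = pd.DataFrame(recording.data.T, columns=list(recording.channels))
        df.to_csv(path, index=False, float_format="%.6g")
        # store fs on a comment-free sidecar line is fragile; embed in name of
        # a companion JSON instead
        Path(str(path) + ".meta.json").write_text(
            json.dumps({"fs": recording.fs})
        )
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def read_recording(path, fmt: Optional[str] = None, fs: Optional[int] = None) -> EEGRecording:
    """Read an EDF or CSV recording into a validated EEGRecording.

    CSV needs a sampling rate: either a ``<file>.meta.json`` sidecar written
    by :func:`write_recording` or the ``fs`` argument.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "edf":
        data, fs_read, labels, _meta = _edf.read_edf(path)
        return EEGRecording(fs=fs_read, channels=tuple(labels), data=data,
                            meta={"source": str(path)})
    if fmt == "csv":
        df = pd.read_csv(path)
        if df.columns.str.contains("Unnamed").any() or not len(df.columns):
            raise ValueError("malformed header: expected channel-label columns")
        unknown = [c for c in df.columns if c not in CHANNELS_1020]
        if unknown:
            raise ValueError(f"malformed header: unknown channel(s) {unknown}")
        if fs is None:
            meta_path = Path(str(path) + ".meta.json")
            if not meta_path.exists():
                raise ValueError("CSV needs fs= argument or .meta.json sidecar")
            fs = int(json.loads(meta_path.read_text())["fs"])
        return EEGRecording(fs=fs, channels=tuple(df.columns),
                            data=df.to_numpy().T, meta={"source": str(path)})
    raise ValueError(f"unsupported format {fmt!r}")


def _infer_format(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer recording format from {path!r}")


# -------------------------------------------------------------------- labels

def write_labels(labels: Sequence[int], path) -> None:
    """Per-second ±1 vigilance labels as a two-column TSV (t, label)."""
    labels = np.asarray(labels, dtype=int)
    pd.DataFrame({"t": np.arange(len(labels)), "label": labels}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if not {"t", "label"} <= set(df.columns):
        raise ValueError("label sidecar needs columns t, label")
    return df.sort_values("t")["label"].to_numpy(dtype=int)


def label_sidecar_path(recording_path) -> Path:
    return Path(str(recording_path) + ".labels.tsv")


# ------------------------------------------------------------------ features

def write_features(feats: FeatureMatrix, path) -> None:
    cols = {"t": feats.t_index}
    for j, name in enumerate(feats.band_names):
        cols[name] = feats.X[:, j]
    cols["label"] = feats.y
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_features(path, r: int, channel: str) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    band_names = tuple(c for c in df.columns if c not in ("t", "label"))
    return FeatureMatrix(
        X=df[list(band_names)].to_numpy(),
        y=df["label"].to_numpy(dtype=int),
        r=r, channel=channel, band_names=band_names,
        t_index=df["t"].to_numpy(dtype=int),
    )


# ------------------------------------------------------------------- reports

def write_report(report, path, fmt: Optional[str] = None) -> None:
    fmt = fmt or ("json" if str(path).endswith(".json") else "tsv")
    records = report.as_records(percent=False)
    if fmt == "tsv":
        pd.DataFrame(records).to_csv(path, sep="\t", index=False)
    else:
        Path(path).write_text(json.dumps(
            {"rows": records, "metadata": report.metadata}, indent=1,
            default=_json_default,
        ))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


# ----------------------------------------------------------------- detection

@dataclass
class WarningEvent:
    """Alarm emitted at an alert->drowsy transition of the predicted stream."""

    t: int                  # second index of the transition
    decision_value: float


def detect(
    recording: EEGRecording,
    model: SvmModel,
    r: int,
    channel: Optional[str] = None,
    bands=DEFAULT_BANDS,
    keep=DEFAULT_KEEP,
) -> Tuple[np.ndarray, np.ndarray, List[WarningEvent]]:
    """Run the full pipeline on a recording with a trained model.

    Returns (seconds scored, predicted ±1 labels, warning events). One label
    is produced for each second t >= r; a warning fires at every transition
    of the predicted stream from alert (+1) into drowsy (-1), including a
    drowsy prediction at the very first scored second.
    """
    channel = channel or model.channel
    if channel is None:
        raise ValueError("no channel given and model carries none")
    if recording.n_seconds < r + 1:
        raise ValueError(
            f"recording ({recording.n_seconds} s) shorter than r+1 = {r + 1} s"
        )
    clean = denoise(recording, keep)
    dummy_labels = np.ones(clean.n_seconds, dtype=int)
    feats = extract_features(clean, dummy_labels, channel=channel, r=r,
                             bands=bands)
    X = feats.X
    if model.scaling is not None:
        from .features import apply_scaling
        X = apply_scaling(X, model.scaling)
    f_vals = decision_values(model, X)
    pred = np.where(f_vals > 0, 1, -1).astype(int)
    events = []
    prev = 1   # assume alert before the stream starts
    for t, (p, f) in enumerate(zip(pred, f_vals)):
        if p == -1 and prev == 1:
            events.append(WarningEvent(t=int(feats.t_index[t]),
                                       decision_value=float(f)))
        prev = p
    return feats.t_index, pred, events


# -------------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """End-to-end settings, loadable from YAML and validated on load."""

    fs: int = 512
    channels: tuple = CHANNELS_1020
    keep_levels: tuple = tuple(sorted(DEFAULT_KEEP))
    r: int = 4
    C: float = 32.0
    g: float = 2.0
    kernel: str = "rbf"
    folds: int = 3
    seed: int = 0

    def __post_init__(self):
        from .wavelet import LEVEL_NAMES
        if self.fs <= 2 * max(b.high for b in DEFAULT_BANDS):
            raise ValueError("fs too low for the beta band")
        bad = [c for c in self.channels if c not in CHANNELS_1020]
        if bad:
            raise ValueError(f"unknown channels {bad}")
        bad = [k for k in self.keep_levels if k not in LEVEL_NAMES]
        if bad:
            raise ValueError(f"unknown wavelet levels {bad}")
        if self.r < 0 or self.folds < 2 or self.C <= 0 or self.g < 0:
            raise ValueError("invalid r / folds / C / g")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("channels", "keep_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
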