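"""Recordings, configuration and artifact I/O shared by all analysis stages.

A :class:`Recording` is the common in-memory container for multichannel
time series (EEG in microvolts or synthetic signals in arbitrary units):
a channels x samples float matrix plus a sampling rate, ordered channel
labels and a free-text condition tag.  EDF and BrainVision files are read
through :mod:`mne`; a plain-text "matrix" dialect (one header line with
the sampling rate and labels, then one row per channel) is provided for
diff-friendly fixtures and round-trip serialization.

:class:`AnalysisConfig` collects every tunable of the pipeline —
discretization bins, surrogate count, window geometry, significance level,
hub-imbalance threshold and microstate count — with the defaults the
analysis is calibrated for (30 surrogates, 5-s windows, 80% overlap,
5% significance, 10% imbalance, 4 microstates).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger("corehub")

__all__ = [
    "Recording",
    "AnalysisConfig",
    "ValidationError",
    "ParameterError",
    "read_recording",
    "write_recording",
    "bandpass_filter",
    "rereference_average",
    "read_config",
    "write_config",
]


class ValidationError(ValueError):
    """Raised when loaded or constructed data violates a type invariant."""


class ParameterError(ValueError):
    """Raised when an operation is called with out-of-contract parameters."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """Multichannel time series: channels x samples, with labels and rate."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("recording data must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        self.channel_labels = [str(c) for c in self.channel_labels]
        n_ch, n_samp = self.data.shape
        if len(self.channel_labels) != n_ch:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {n_ch} channels"
            )
        if len(set(self.channel_labels)) != n_ch:
            raise ValidationError("duplicate channel labels")
        if n_ch < 2 or n_samp < 2:
            raise ValidationError("need at least 2 channels and 2 samples")
        bad = ~np.isfinite(self.data)
        if bad.any():
            ch, samp = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at channel {self.channel_labels[ch]!r} "
                f"(row {ch}), sample {samp}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class AnalysisConfig:
    """Pipeline tunables; defaults are the calibrated analysis settings."""

    n_bins: int = 8
    n_surrogates: int = 30
    seed: int = 0
    window_length_s: float = 5.0
    window_overlap: float = 0.8
    significance_level: float = 0.05
    imbalance_threshold: float = 0.10
    n_microstates: int = 4
    distance_mapping: str = "reciprocal"  # or "neglog"
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ParameterError("n_bins must be >= 2")
        if self.n_surrogates < 1:
            raise ParameterError("n_surrogates must be >= 1")
        if self.window_length_s <= 0:
            raise ParameterError("window_length_s must be positive")
        if not 0 <= self.window_overlap < 1:
            raise ParameterError("window_overlap must lie in [0, 1)")
        if not 0 < self.significance_level < 1:
            raise ParameterError("significance_level must lie in (0, 1)")
        if self.imbalance_threshold <= 0:
            raise ParameterError("imbalance_threshold must be positive")
        if self.n_microstates < 1:
            raise ParameterError("n_microstates must be >= 1")
        if self.distance_mapping not in ("reciprocal", "neglog"):
            raise ParameterError("distance_mapping must be 'reciprocal' or 'neglog'")


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix == ".vhdr":
        return "brainvision"
    return "matrix"


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from EDF, a BrainVision triplet, or the matrix dialect.

    The matrix dialect is a delimited numeric table (rows = channels,
    columns = samples) preceded by one header line of the form
    ``fs=<Hz>; labels=<comma-separated>[; condition=<tag>]``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read recording: no such file {path}")
    fmt = format or _detect_format(path)
    if fmt == "matrix":
        return _read_matrix(path)
    if fmt in ("edf", "brainvision"):
        import mne

        reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_brainvision
        try:
            raw = reader(str(path), preload=True, verbose="error")
        except Exception as exc:  # pragma: no cover - backend-specific messages
            raise IOError(f"cannot read recording {path}: {exc}") from exc
        data = raw.get_data() * 1e6  # volts -> microvolts
        return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))
    raise ParameterError(f"unknown recording format {fmt!r}")


def _read_matrix(path: Path) -> Recording:
    with open(path) as fh:
        header = fh.readline().strip()
        if header.startswith("#"):
            header = header[1:].strip()
        fields: dict[str, str] = {}
        for part in header.split(";"):
            part = part.strip()
            if "=" in part:
                key, _, value = part.partition("=")
                fields[key.strip()] = value.strip()
        if "fs" not in fields or "labels" not in fields:
            raise IOError(f"{path}: matrix header must carry 'fs=' and 'labels='")
        fs = float(fields["fs"])
        labels = [s.strip() for s in fields["labels"].split(",")]
        condition = fields.get("condition", "")
        try:
            data = np.loadtxt(fh, ndmin=2)
        except ValueError as exc:
            raise IOError(f"{path}: cannot parse numeric body: {exc}") from exc
    bad = ~np.isfinite(data)
    if bad.any():
        ch, samp = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: non-finite value at channel index {ch}, sample {samp}"
        )
    return Recording(data, fs, labels, condition)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording in the matrix dialect (text, channels as rows)."""
    path = Path(path)
    header = f"fs={rec.fs:g}; labels={','.join(rec.channel_labels)}"
    if rec.condition:
        header += f"; condition={rec.condition}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, rec.data, fmt="%.17g", delimiter="\t")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def bandpass_filter(rec: Recording, low: float, high: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass copy of a recording.

    Forward-backward (``sosfiltfilt``) filtering keeps the phase of each
    channel intact, so directed-connectivity estimates downstream are not
    biased by filter delay.
    """
    from scipy.signal import butter, sosfiltfilt

    if not 0 < low < high:
        raise ParameterError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= rec.fs / 2:
        raise ParameterError(
            f"high cutoff {high} Hz is at or above Nyquist ({rec.fs / 2} Hz)"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sosfiltfilt(sos, rec.data, axis=1)
    return Recording(filtered, rec.fs, list(rec.channel_labels), rec.condition)


def rereference_average(rec: Recording) -> Recording:
    """Re-reference every sample to the common average across channels.

    Off by default throughout the pipeline; apply explicitly when emulating
    average-referenced EEG.
    """
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return Recording(data, rec.fs, list(rec.channel_labels), rec.condition)


# ---------------------------------------------------------------------------
# Configuration files (flat key=value)
# ---------------------------------------------------------------------------

_CONFIG_TYPES = {f.name: f.type for f in dataclasses.fields(AnalysisConfig)}


def write_config(cfg: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(cfg):
            fh.write(f"{f.name}={getattr(cfg, f.name)}\n")


def read_config(path: str | Path) -> AnalysisConfig:
    values: dict[str, object] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in _CONFIG_TYPES:
                raise ParameterError(f"unknown config key {key!r}")
            if key in ("n_bins", "n_surrogates", "seed", "n_microstates"):
                values[key] = int(raw)
            elif key == "bonferroni":
                values[key] = raw.lower() in ("1", "true", "yes")
            elif key == "distance_mapping":
                values[key] = raw
            else:
                values[key] = float(raw)
    return AnalysisConfig(**values)
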