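"""Windowed hub dynamics: sliding windows, per-type counts, peaks.

The recording is segmented into sliding windows (5 s, 80% overlap by
default) and the connectivity pipeline runs inside each window.  Hub
membership plays two roles here.  At the recording level, the per-window
BC values form each node's sampling distribution for the Mann-Whitney
hub test — that fixed hub set feeds the static core analyses.  Inside a
single window only one BC value per node exists, so the count series
uses the window-local analogue of "statistically higher than the rest":
a node is counted when its BC exceeds the across-node mean by more than
the one-sided normal quantile of the configured significance level, and
is then typed from that window's NTE matrix.  Counts therefore vary both
in composition (who is hub-like this window) and in type (which way each
one leans), which is what the peak analysis needs.

Peaks of a count series are samples that exceed mean + 1 SD of the series
AND are local maxima; co-occurrence of peaks across hub types is
summarized by the product-moment (phi) correlation of the indicator
series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, connectivity_matrix
from .graph_metrics import betweenness, identify_hubs, weight_to_distance
from .hub_typing import HUB_TYPES, classify_hub, degrees
from .io_core import AnalysisConfig, ParameterError, Recording, logger

__all__ = [
    "Window",
    "WindowSeries",
    "sliding_windows",
    "windowed_connectivity",
    "windowed_betweenness",
    "hub_count_series",
    "detect_peaks",
    "peak_flags",
    "peak_correlation",
    "write_window_series",
]


@dataclass
class Window:
    """One sliding-window view of a recording."""

    index: int
    start: int  # sample index in the parent recording
    recording: Recording

    @property
    def start_s(self) -> float:
        return self.start / self.recording.fs


def sliding_windows(rec: Recording, length_s: float, overlap: float) -> list[Window]:
    """Sliding windows of ``length_s`` seconds with fractional ``overlap``.

    The step is length*(1-overlap) samples (floored, minimum 1); a
    trailing partial window is dropped.  A window longer than the
    recording yields a single full-recording window with a warning.
    """
    if not 0 <= overlap < 1:
        raise ParameterError("overlap must lie in [0, 1)")
    length = int(round(length_s * rec.fs))
    if length < 2:
        raise ParameterError("window must span at least 2 samples")
    if length > rec.n_samples:
        warnings.warn(
            "window longer than recording: returning one full-recording window",
            stacklevel=2,
        )
        return [Window(0, 0, rec)]
    # floor, but guard the float representation of e.g. 500 * 0.2
    step = max(1, int(np.floor(length * (1.0 - overlap) + 1e-9)))
    windows = []
    for w, start in enumerate(range(0, rec.n_samples - length + 1, step)):
        view = Recording(
            rec.data[:, start:start + length],
            rec.fs,
            list(rec.channel_labels),
            rec.condition,
        )
        windows.append(Window(w, start, view))
    return windows


def windowed_connectivity(
    windows: list[Window], cfg: AnalysisConfig
) -> list[ConnectivityMatrix]:
    """One NTE matrix per window; window w uses seed (cfg.seed, w).

    Deriving each window's surrogate stream from the recording seed plus
    the window index keeps the whole windowed analysis reproducible while
    decorrelating surrogates across windows.
    """
    out = []
    min_len = 10 * cfg.n_bins ** 2
    for w in windows:
        if w.recording.n_samples < min_len:
            logger.warning(
                "window %d has %d samples; NTE histograms are sparse below ~%d",
                w.index, w.recording.n_samples, min_len,
            )
        rng = np.random.default_rng([cfg.seed, w.index])
        out.append(connectivity_matrix(w.recording, cfg, rng))
    return out


def windowed_betweenness(cms: list[ConnectivityMatrix]) -> pd.DataFrame:
    """Windows x nodes frame of betweenness values."""
    rows = []
    for cm in cms:
        bc = betweenness(weight_to_distance(cm))
        rows.append(bc)
    return pd.DataFrame(rows)


@dataclass
class WindowSeries:
    """Per-window hub-type counts with peak thresholds and intermediates."""

    window_starts: np.ndarray
    window_length: int
    fs: float
    counts: dict[str, np.ndarray]
    thresholds: dict[str, float] = field(default_factory=dict)
    hub_flags: pd.DataFrame | None = None
    bc_samples: pd.DataFrame | None = None
    window_types: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.thresholds:
            self.thresholds = {
                t: float(np.mean(s) + np.std(s)) for t, s in self.counts.items()
            }


def hub_count_series(
    windows: list[Window],
    cfg: AnalysisConfig,
    cms: list[ConnectivityMatrix] | None = None,
) -> WindowSeries:
    """HD/HC/HN count series over windows.

    Within a single window there is one BC value per node, so the
    rank-test hub criterion cannot apply; the window-local analogue flags
    a node whose BC in that window exceeds the pooled BC distribution of
    the whole recording (all nodes, all windows) by more than z standard
    deviations, with z the one-sided normal quantile at the configured
    significance level.  Judging each window against the recording-level
    baseline — the same pooling the Mann-Whitney hub test uses — lets
    the total count per window track how many genuinely central nodes
    that window has.  Each flagged node is then typed from that window's
    NTE matrix.  The recording-level Mann-Whitney hub table is attached
    as ``hub_flags`` for the static analyses.

    Precomputed per-window matrices may be passed to avoid recomputation.
    """
    from scipy.stats import norm

    if cms is None:
        cms = windowed_connectivity(windows, cfg)
    bc = windowed_betweenness(cms)
    flags = identify_hubs(bc, cfg.significance_level, cfg.bonferroni)
    z = float(norm.ppf(1.0 - cfg.significance_level))
    n_win = len(windows)
    counts = {t: np.zeros(n_win, dtype=int) for t in HUB_TYPES}
    type_rows = []
    bc_values = bc.to_numpy(dtype=float)
    nodes = list(bc.columns)
    cut = bc_values.mean() + z * bc_values.std()
    for wi, cm in enumerate(cms):
        row = {}
        bc_w = bc_values[wi]
        for node, bc_node in zip(nodes, bc_w):
            if bc_node <= cut:
                continue
            od, id_ = degrees(cm, node)
            t = classify_hub(od, id_, cfg.imbalance_threshold)
            counts[t][wi] += 1
            row[node] = t
        type_rows.append(row)
    return WindowSeries(
        window_starts=np.array([w.start for w in windows]),
        window_length=windows[0].recording.n_samples if windows else 0,
        fs=windows[0].recording.fs if windows else 0.0,
        counts=counts,
        hub_flags=flags,
        bc_samples=bc,
        window_types=pd.DataFrame(type_rows),
    )


def detect_peaks(series: np.ndarray, k_sd: float = 1.0) -> np.ndarray:
    """True where the series exceeds mean + k_sd*SD and is a local maximum.

    Endpoints are compared to their single neighbor; a constant series has
    SD 0 and the strict threshold comparison flags nothing.
    """
    s = np.asarray(series, dtype=float)
    if s.size < 2:
        raise ParameterError("peak detection needs at least 2 samples")
    threshold = s.mean() + k_sd * s.std()
    above = s > threshold
    local_max = np.ones(s.size, dtype=bool)
    local_max[:-1] &= s[:-1] >= s[1:]
    local_max[1:] &= s[1:] >= s[:-1]
    return above & local_max


def peak_flags(ws: WindowSeries, k_sd: float = 1.0) -> dict[str, np.ndarray]:
    """Per-type peak indicator series of a window series."""
    return {t: detect_peaks(ws.counts[t], k_sd) for t in ws.counts}


def peak_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment (phi) correlation of two peak-indicator series.

    Returns NaN — a distinguished "undefined" value — when either series
    is constant (no peaks at all, or all peaks).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("indicator series lengths differ")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("constant indicator series: peak correlation undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def write_window_series(ws: WindowSeries, path, k_sd: float = 1.0) -> None:
    flags = peak_flags(ws, k_sd)
    df = pd.DataFrame({"window_start_s": ws.window_starts / ws.fs})
    for t in ws.counts:
        df[f"n_{t}"] = ws.counts[t]
    for t in flags:
        df[f"peak_{t}"] = flags[t].astype(int)
    df.to_csv(path, sep="\t", index=False)
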