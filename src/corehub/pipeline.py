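"""End-to-end convenience layer: recording -> hubs, core and dynamics.

Runs the full chain once for a recording: windowed NTE matrices, windowed
betweenness, Mann-Whitney hub identification, typing on the
full-recording matrix, and the per-type count series.  The individual
stages remain available in their own modules; this wrapper only wires
them together with consistent seeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, connectivity_matrix
from .dynamics import (
    Window,
    WindowSeries,
    hub_count_series,
    sliding_windows,
    windowed_connectivity,
)
from .hub_typing import hub_table
from .io_core import AnalysisConfig, Recording

__all__ = ["AnalysisResult", "analyze_recording"]


@dataclass
class AnalysisResult:
    """All derived artifacts of one recording under one config."""

    recording: Recording
    config: AnalysisConfig
    connectivity: ConnectivityMatrix  # full-recording NTE matrix
    windows: list[Window]
    window_matrices: list[ConnectivityMatrix]
    window_series: WindowSeries
    hubs: pd.DataFrame  # per-node hub table (typing from the full matrix)

    @property
    def hub_labels(self) -> list[str]:
        return list(self.hubs.loc[self.hubs["is_hub"], "node"])


def analyze_recording(rec: Recording, cfg: AnalysisConfig | None = None) -> AnalysisResult:
    """Full pipeline for one recording (deterministic given cfg.seed)."""
    cfg = cfg or AnalysisConfig()
    windows = sliding_windows(rec, cfg.window_length_s, cfg.window_overlap)
    cms = windowed_connectivity(windows, cfg)
    series = hub_count_series(windows, cfg, cms=cms)
    # the full-recording matrix gets its own surrogate stream, distinct
    # from every window's [seed, window_index] stream
    full_cm = connectivity_matrix(rec, cfg, np.random.default_rng([cfg.seed, 2**31 - 1]))
    ht = hub_table(full_cm, series.hub_flags, cfg.imbalance_threshold)
    return AnalysisResult(
        recording=rec,
        config=cfg,
        connectivity=full_cm,
        windows=windows,
        window_matrices=cms,
        window_series=series,
        hubs=ht,
    )
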