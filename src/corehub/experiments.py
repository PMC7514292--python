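"""Reproducible recovery studies on synthetic ground truth.

These drivers wire the generators to the full pipeline and score the
outcome against the planted structure.  They define the package's
standard validation conditions:

* **Hub recovery** — 15-node networks with 2 planted sources and 1
  planted sink (T = 10,000 at 250 Hz, default analysis config).  A trial
  succeeds when every planted source is flagged as a hub and typed HD
  and the planted sink is flagged and typed HC.  The same run scores the
  resilience direction: removing the detected HD hubs should change the
  characteristic path length more than removing the detected HC or HN
  hubs.

* **Triggered-window complexity** — 16-node recordings switching
  between a quiescent background-only regime and an engaged-core regime
  (2 sources plus a relay-sink) in a one-block-in-three duty cycle
  (6 blocks, T = 18,000 at 250 Hz).  The pooled BC baseline is set by
  the quiescent majority, so during engaged blocks the divergent sources
  and the convergent relay all clear the window-local hub cut together
  and their count series peak in the same windows.  Microstate EEG is
  generated with fast template switching planted inside those
  common-trigger windows; a trial succeeds when the mean quaternary LZ
  complexity of common windows exceeds that of single-type windows
  after the full fit/backfit/complexity chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import peak_flags
from .io_core import AnalysisConfig
from .microstates import backfit, fit_microstates, windowed_complexity
from .pipeline import analyze_recording
from .graph_metrics import removal_impact
from .synthetic import (
    MicrostateSimSpec,
    orthogonal_templates,
    plant_hub_network,
    simulate_alternating,
    simulate_microstate_eeg,
    simulate_var,
)

__all__ = ["HubRecoveryTrial", "ComplexityTrial",
           "hub_recovery_trial", "complexity_trial"]


@dataclass
class HubRecoveryTrial:
    """Outcome of one planted-hub recovery run."""

    seed: int
    roles_recovered: bool  # sources flagged+HD and sink flagged+HC
    impact_hd: float | None  # |percent change of l| removing detected HD hubs
    impact_hc: float | None
    impact_hn: float | None

    @property
    def hd_impact_dominates(self) -> bool | None:
        others = [i for i in (self.impact_hc, self.impact_hn) if i is not None]
        if self.impact_hd is None or not others:
            return None
        return all(self.impact_hd > o for o in others)


def hub_recovery_trial(
    seed: int,
    n_nodes: int = 15,
    n_sources: int = 2,
    n_sinks: int = 1,
    n_samples: int = 10_000,
    fs: float = 250.0,
    cfg: AnalysisConfig | None = None,
) -> HubRecoveryTrial:
    """Simulate a planted network, run the pipeline, score the recovery."""
    spec = plant_hub_network(n_nodes, n_sources, n_sinks, seed,
                             n_samples=n_samples, fs=fs)
    rec = simulate_var(spec)
    cfg = cfg or AnalysisConfig(seed=seed)
    res = analyze_recording(rec, cfg)
    ht = res.hubs
    typed = dict(zip(ht["node"], ht["hub_type"]))
    flagged = dict(zip(ht["node"], ht["is_hub"]))
    recovered = all(flagged[s] and typed[s] == "HD" for s in spec.sources) and \
        all(flagged[s] and typed[s] == "HC" for s in spec.sinks)
    groups = {
        t: [n for n in ht.loc[ht["is_hub"], "node"] if typed[n] == t]
        for t in ("HD", "HC", "HN")
    }
    impacts = {}
    for t, nodes in groups.items():
        impacts[t] = (
            abs(removal_impact(res.connectivity, nodes)) if nodes else None
        )
    return HubRecoveryTrial(
        seed=seed,
        roles_recovered=bool(recovered),
        impact_hd=impacts["HD"],
        impact_hc=impacts["HC"],
        impact_hn=impacts["HN"],
    )


@dataclass
class ComplexityTrial:
    """Outcome of one triggered-window complexity run."""

    seed: int
    n_common: int
    n_single: int
    mean_common: float | None
    mean_single: float | None

    @property
    def decided(self) -> bool:
        return self.mean_common is not None and self.mean_single is not None

    @property
    def common_exceeds_single(self) -> bool | None:
        if not self.decided:
            return None
        return self.mean_common > self.mean_single


def complexity_trial(
    seed: int,
    n_nodes: int = 16,
    n_samples: int = 18_000,
    fs: float = 250.0,
    n_blocks: int = 6,
    pattern: str = "AAB",
    snr: float = 5.0,
    n_ms_channels: int = 19,
    cfg: AnalysisConfig | None = None,
) -> ComplexityTrial:
    """Quiescent/engaged-core switching -> triggered-window complexity."""
    spec_a = plant_hub_network(n_nodes, 0, 0, seed, n_samples=n_samples, fs=fs)
    spec_b = plant_hub_network(n_nodes, 2, 1, seed + 1, n_samples=n_samples,
                               fs=fs, sink_out_degree=3)
    rec, _ = simulate_alternating(spec_a, spec_b, n_blocks=n_blocks, seed=seed,
                                  pattern=pattern)

    cfg = cfg or AnalysisConfig(seed=seed)
    res = analyze_recording(rec, cfg)
    ws = res.window_series
    flags = peak_flags(ws)
    n_types = np.sum([flags[t] for t in flags], axis=0)
    n_common = int((n_types >= 2).sum())
    n_single = int((n_types == 1).sum())
    if n_common == 0 or n_single == 0:
        return ComplexityTrial(seed, n_common, n_single, None, None)

    fast = [
        (ws.window_starts[wi] / fs, (ws.window_starts[wi] + ws.window_length) / fs)
        for wi in np.nonzero(n_types >= 2)[0]
    ]
    templates = orthogonal_templates(cfg.n_microstates, n_ms_channels, seed=seed)
    mspec = MicrostateSimSpec(
        templates=templates, snr=snr, fs=fs,
        duration_s=rec.n_samples / fs, seed=seed, fast_segments=fast,
    )
    ms_rec, _ = simulate_microstate_eeg(mspec)
    model = fit_microstates(ms_rec, k=cfg.n_microstates, seed=seed)
    seq = backfit(ms_rec, model)
    wc = windowed_complexity(seq, ws)
    common = wc.loc[wc["group"] == "common", "c_norm"]
    single = wc.loc[wc["group"] != "common", "c_norm"]
    if common.empty or single.empty:
        return ComplexityTrial(seed, n_common, n_single, None, None)
    return ComplexityTrial(
        seed, n_common, n_single, float(common.mean()), float(single.mean())
    )
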