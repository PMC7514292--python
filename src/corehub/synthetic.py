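"""Ground-truth generators for every recovery test in the toolkit.

Two families of fixtures:

* **Coupled autoregressive networks.**  A first-order linear VAR
  x(t+1) = A x(t) + eps with A = ar_coeff * I plus planted directed
  couplings.  Directionality is unambiguous ground truth for transfer
  entropy, and a spectral-radius guard keeps every fixture stationary.
  :func:`plant_hub_network` builds specs with known information sources
  (nodes driving half the network), sinks (driven by as many nodes) and
  a sparse random background, so the hub-detection and typing pipeline
  can be scored against planted roles.  A coupled logistic-map variant
  provides a nonlinear robustness check.

* **Template-driven microstate EEG.**  A hidden state switches among k
  fixed scalp topographies with geometric dwell times; each sample is
  the active template scaled by a random positive amplitude plus
  Gaussian noise at a stated SNR.  The true label sequence is returned
  alongside the recording, and dwell times can be locally shortened
  inside chosen segments to plant fast-switching episodes.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .io_core import ParameterError, Recording

__all__ = [
    "CouplingSpec",
    "MicrostateSimSpec",
    "RegimeSwitchResult",
    "simulate_var",
    "simulate_logistic",
    "plant_hub_network",
    "simulate_regime_switch",
    "simulate_microstate_eeg",
    "orthogonal_templates",
]

_BURN_IN = 500


@dataclass
class CouplingSpec:
    """Planted directed-coupling structure for a stationary VAR network."""

    n_nodes: int
    edges: list[tuple[str, str, float]]  # (source, target, coupling)
    ar_coeff: float = 0.4
    noise_sd: float = 1.0
    n_samples: int = 10_000
    fs: float = 250.0
    seed: int = 0
    condition: str = ""
    sources: list[str] = field(default_factory=list)  # planted ground truth
    sinks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ParameterError("need at least 2 nodes")
        if not 0 <= self.ar_coeff < 1:
            raise ParameterError("ar_coeff must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        labels = set(self.labels)
        for src, tgt, c in self.edges:
            if src == tgt:
                raise ParameterError(f"self-edge on {src!r} not allowed")
            if src not in labels or tgt not in labels:
                raise ParameterError(f"edge ({src}, {tgt}) names unknown node")
            if not 0 < c < 1:
                raise ParameterError("coupling strengths must lie in (0, 1)")

    @property
    def labels(self) -> list[str]:
        return [f"N{i:02d}" for i in range(self.n_nodes)]

    def system_matrix(self) -> np.ndarray:
        idx = {lab: i for i, lab in enumerate(self.labels)}
        a = np.eye(self.n_nodes) * self.ar_coeff
        for src, tgt, c in self.edges:
            a[idx[tgt], idx[src]] += c
        return a

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.system_matrix())).max())


def simulate_var(spec: CouplingSpec, seed: int | None = None) -> Recording:
    """Simulate the VAR network; 500 burn-in samples are discarded."""
    a = spec.system_matrix()
    radius = spec.spectral_radius()
    if radius >= 1.0:
        raise ParameterError(
            f"unstable system: spectral radius {radius:.3f} >= 1"
        )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_nodes
    total = spec.n_samples + _BURN_IN
    noise = rng.normal(0.0, spec.noise_sd, size=(total, n))
    x = np.zeros((total, n))
    state = np.zeros(n)
    for t in range(total):
        state = a @ state + noise[t]
        x[t] = state
    return Recording(
        x[_BURN_IN:].T, spec.fs, spec.labels, spec.condition
    )


def simulate_logistic(spec: CouplingSpec, r: float = 3.9,
                      seed: int | None = None) -> Recording:
    """Coupled logistic maps on the same planted edge structure.

    x_i(t+1) = (1 - e_i) f(x_i(t)) + (e_i / deg_i) sum_j c f(x_j(t)) with
    f(x) = r x (1 - x); the total incoming coupling of a node plays the
    role of e_i.  A nonlinear robustness counterpart to the Gaussian VAR.
    """
    idx = {lab: i for i, lab in enumerate(spec.labels)}
    n = spec.n_nodes
    cin = np.zeros((n, n))
    for src, tgt, c in spec.edges:
        cin[idx[tgt], idx[src]] += c
    eps = np.minimum(cin.sum(axis=1), 0.9)
    with np.errstate(invalid="ignore", divide="ignore"):
        mix = np.where(cin.sum(axis=1, keepdims=True) > 0,
                       cin / np.maximum(cin.sum(axis=1, keepdims=True), 1e-12), 0.0)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    total = spec.n_samples + _BURN_IN
    x = np.empty((total, n))
    state = rng.uniform(0.1, 0.9, size=n)
    for t in range(total):
        fx = r * state * (1.0 - state)
        state = (1.0 - eps) * fx + eps * (mix @ fx)
        state = np.clip(state, 0.0, 1.0)
        x[t] = state
    return Recording(x[_BURN_IN:].T, spec.fs, spec.labels, spec.condition)


def plant_hub_network(
    n_nodes: int,
    n_sources: int,
    n_sinks: int,
    seed: int,
    source_coupling: float = 0.45,
    sink_coupling: float = 0.25,
    background_coupling: float = 0.12,
    background_out_degree: int = 3,
    sink_out_degree: int = 1,
    hub_bias: float = 0.7,
    ar_coeff: float = 0.25,
    **spec_kwargs,
) -> CouplingSpec:
    """Coupling spec with planted sources, sinks and sparse background.

    Each source drives ceil((n-1)/2) random targets; each sink is driven
    by the same number of random drivers.  The sparse background gives
    every node a few weaker outgoing edges, with a preferential-attachment
    bias toward the sources (``hub_bias`` is the probability that a
    background edge targets a source): divergent brain hubs are relays —
    well-reached nodes with dominant out-flow — not isolated
    broadcasters, so background traffic funnels into them.  Sinks keep a
    single weak dispersal edge (``sink_out_degree``), matching their
    collector role.  Couplings are scaled down deterministically if the
    implied system matrix approaches instability.
    """
    if n_sources + n_sinks >= n_nodes:
        raise ParameterError("sources + sinks must be fewer than nodes")
    rng = np.random.default_rng(seed)
    labels = [f"N{i:02d}" for i in range(n_nodes)]
    source_labels = labels[:n_sources]
    sink_labels = labels[n_sources:n_sources + n_sinks]
    fan = int(np.ceil((n_nodes - 1) / 2))

    edges: dict[tuple[str, str], float] = {}
    for src in source_labels:
        candidates = [l for l in labels if l != src]
        targets = rng.choice(len(candidates), size=fan, replace=False)
        for t in targets:
            edges[(src, candidates[t])] = source_coupling
    for sink in sink_labels:
        candidates = [l for l in labels if l != sink]
        drivers = rng.choice(len(candidates), size=fan, replace=False)
        for d in drivers:
            key = (candidates[d], sink)
            edges[key] = max(edges.get(key, 0.0), sink_coupling)
    for node in labels:
        degree = sink_out_degree if node in sink_labels else background_out_degree
        placed = tries = 0
        while placed < degree and tries < 50 * degree:
            tries += 1
            if source_labels and node not in source_labels and rng.random() < hub_bias:
                target = source_labels[rng.integers(n_sources)]
            else:
                target = labels[rng.integers(n_nodes)]
            if target == node or (node, target) in edges:
                continue
            edges[(node, target)] = background_coupling
            placed += 1

    def build(scale: float) -> CouplingSpec:
        return CouplingSpec(
            n_nodes=n_nodes,
            edges=[(s, t, c * scale) for (s, t), c in edges.items()],
            ar_coeff=ar_coeff,
            seed=seed,
            sources=source_labels,
            sinks=sink_labels,
            **spec_kwargs,
        )

    scale = 1.0
    spec = build(scale)
    while spec.spectral_radius() >= 0.95:
        scale *= 0.85
        spec = build(scale)
    return spec


def permute_nodes(spec: CouplingSpec, mapping: dict[str, str]) -> CouplingSpec:
    """Relabel a coupling structure (e.g., to move planted roles between
    regimes); nodes absent from ``mapping`` keep their labels."""
    labels = set(spec.labels)
    if not set(mapping) <= labels or not set(mapping.values()) <= labels:
        raise ParameterError("mapping names unknown nodes")
    if len(set(mapping.values())) != len(mapping):
        raise ParameterError("mapping is not one-to-one")
    rename = lambda n: mapping.get(n, n)
    return CouplingSpec(
        n_nodes=spec.n_nodes,
        edges=[(rename(s), rename(t), c) for s, t, c in spec.edges],
        ar_coeff=spec.ar_coeff,
        noise_sd=spec.noise_sd,
        n_samples=spec.n_samples,
        fs=spec.fs,
        seed=spec.seed,
        condition=spec.condition,
        sources=[rename(s) for s in spec.sources],
        sinks=[rename(s) for s in spec.sinks],
    )


class RegimeSwitchResult(NamedTuple):
    recording: Recording
    switch_sample: int


def simulate_regime_switch(
    spec_a: CouplingSpec,
    spec_b: CouplingSpec,
    switch_at: float,
    seed: int | None = None,
) -> RegimeSwitchResult:
    """Concatenate two regimes: A up to floor(switch_at * n), then B.

    Regime B continues from A's final state (no second burn-in), so the
    switch is a change in coupling structure, not a signal discontinuity.
    """
    if spec_a.n_nodes != spec_b.n_nodes or spec_a.fs != spec_b.fs:
        raise ParameterError("regime specs must share node count and rate")
    if not 0 < switch_at < 1:
        raise ParameterError("switch_at must lie in (0, 1)")
    for spec in (spec_a, spec_b):
        radius = spec.spectral_radius()
        if radius >= 1.0:
            raise ParameterError(
                f"unstable system: spectral radius {radius:.3f} >= 1"
            )
    n_samples = spec_a.n_samples
    switch = int(np.floor(switch_at * n_samples))
    rng = np.random.default_rng(spec_a.seed if seed is None else seed)
    n = spec_a.n_nodes
    a_mat = spec_a.system_matrix()
    b_mat = spec_b.system_matrix()
    total = n_samples + _BURN_IN
    noise = rng.normal(0.0, spec_a.noise_sd, size=(total, n))
    x = np.empty((total, n))
    state = np.zeros(n)
    for t in range(total):
        mat = a_mat if t < _BURN_IN + switch else b_mat
        state = mat @ state + noise[t]
        x[t] = state
    rec = Recording(x[_BURN_IN:].T, spec_a.fs, spec_a.labels,
                    spec_a.condition or "switch")
    return RegimeSwitchResult(rec, switch)


def simulate_alternating(
    spec_a: CouplingSpec,
    spec_b: CouplingSpec,
    n_blocks: int = 4,
    seed: int | None = None,
    pattern: str = "AB",
) -> tuple[Recording, list[int]]:
    """Switch between two coupling regimes in equal blocks.

    ``pattern`` (a string over {A, B}, cycled across the blocks) sets the
    duty cycle — e.g. the default "AB" alternates evenly, while "AAB"
    spends one block in three in regime B.  Returns the recording and
    the list of switch samples.  Each regime change is a pure change of
    coupling structure; the state evolves continuously through every
    switch.
    """
    if set(pattern) - {"A", "B"} or not pattern:
        raise ParameterError("pattern must be a nonempty string over {A, B}")
    if spec_a.n_nodes != spec_b.n_nodes or spec_a.fs != spec_b.fs:
        raise ParameterError("regime specs must share node count and rate")
    if n_blocks < 2:
        raise ParameterError("need at least 2 blocks")
    for spec in (spec_a, spec_b):
        radius = spec.spectral_radius()
        if radius >= 1.0:
            raise ParameterError(
                f"unstable system: spectral radius {radius:.3f} >= 1"
            )
    n_samples = spec_a.n_samples
    bounds = [int(np.floor(k * n_samples / n_blocks)) for k in range(1, n_blocks)]
    mats = {"A": spec_a.system_matrix(), "B": spec_b.system_matrix()}
    rng = np.random.default_rng(spec_a.seed if seed is None else seed)
    n = spec_a.n_nodes
    total = n_samples + _BURN_IN
    noise = rng.normal(0.0, spec_a.noise_sd, size=(total, n))
    x = np.empty((total, n))
    state = np.zeros(n)
    block = 0
    for t in range(total):
        rel = t - _BURN_IN
        if block < len(bounds) and rel >= bounds[block]:
            block += 1
        state = mats[pattern[block % len(pattern)]] @ state + noise[t]
        x[t] = state
    rec = Recording(x[_BURN_IN:].T, spec_a.fs, spec_a.labels,
                    spec_a.condition or "alternating")
    return rec, bounds


# ---------------------------------------------------------------------------
# Microstate EEG
# ---------------------------------------------------------------------------


@dataclass
class MicrostateSimSpec:
    """Template-switching EEG generator settings."""

    templates: np.ndarray  # (k, n_channels), rows unit-norm
    mean_dwell_ms: float = 100.0
    snr: float = 5.0
    fs: float = 250.0
    duration_s: float = 60.0
    seed: int = 0
    # optional planted fast-switching episodes: [(start_s, stop_s)], with
    # their own mean dwell
    fast_segments: list[tuple[float, float]] = field(default_factory=list)
    fast_dwell_ms: float = 20.0

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=np.float64)
        if self.templates.ndim != 2 or self.templates.shape[0] < 2:
            raise ParameterError("need a (k>=2, channels) template matrix")
        if self.snr <= 0:
            raise ParameterError("snr must be positive")
        if self.mean_dwell_ms * self.fs / 1000.0 < 2:
            raise ParameterError("mean dwell must span at least 2 samples")

    @property
    def k(self) -> int:
        return self.templates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]


def orthogonal_templates(k: int, n_channels: int, seed: int = 0) -> np.ndarray:
    """k orthonormal, zero-mean (average-referenced) topographies."""
    if k > n_channels - 1:
        raise ParameterError("at most n_channels - 1 orthogonal zero-mean maps")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(k, n_channels))
    x -= x.mean(axis=1, keepdims=True)  # zero-sum subspace is closed below
    # Gram-Schmidt within the zero-sum subspace
    for i in range(k):
        for j in range(i):
            x[i] -= (x[i] @ x[j]) * x[j]
        x[i] /= np.linalg.norm(x[i])
    return x


def simulate_microstate_eeg(
    spec: MicrostateSimSpec, seed: int | None = None
) -> tuple[Recording, np.ndarray]:
    """Generate switching-topography EEG; returns (recording, true labels).

    Dwell times are geometric with the stated mean (shorter inside any
    planted fast segments); each sample is the active template scaled by
    a positive random amplitude, plus white Gaussian noise with SD set so
    that RMS(signal)/RMS(noise) equals the stated SNR.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = int(round(spec.duration_s * spec.fs))
    dwell_mean = np.full(n, spec.mean_dwell_ms * spec.fs / 1000.0)
    for start_s, stop_s in spec.fast_segments:
        i0, i1 = int(start_s * spec.fs), int(stop_s * spec.fs)
        dwell_mean[max(i0, 0):min(i1, n)] = max(
            spec.fast_dwell_ms * spec.fs / 1000.0, 2.0
        )

    labels = np.empty(n, dtype=np.int64)
    t = 0
    current = int(rng.integers(spec.k))
    while t < n:
        dwell = max(2, int(rng.geometric(1.0 / dwell_mean[t])))
        stop = min(t + dwell, n)
        labels[t:stop] = current
        t = stop
        if t < n:
            nxt = int(rng.integers(spec.k - 1))
            current = nxt if nxt < current else nxt + 1  # forbid self-switch

    amplitude = np.abs(rng.normal(1.0, 0.25, size=n)) + 0.1
    signal = amplitude[:, None] * spec.templates[labels]  # (n, C)
    signal_rms = float(np.sqrt((signal ** 2).mean()))
    noise_sd = signal_rms / spec.snr if np.isfinite(spec.snr) else 0.0
    data = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    rec = Recording(
        data.T, spec.fs, [f"CH{i:02d}" for i in range(spec.n_channels)],
        "microstate-sim",
    )
    return rec, labels
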