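"""Directed effective connectivity via normalized transfer entropy (NTE).

Transfer entropy from a source Y to a target X,

    TE_{Y->X} = sum_t p(x_{t+1}, x_t, y_t)
                      log2[ p(x_{t+1} | x_t, y_t) / p(x_{t+1} | x_t) ],

measures how much the present of Y reduces uncertainty about the next
sample of X beyond what X's own present already explains.  It is zero
under causal independence (the generalized Markov property
p(x_{t+1}|x_t,y_t) = p(x_{t+1}|x_t)) and asymmetric in general.

Probabilities are plug-in (maximum-likelihood) joint histograms over
single-lag symbol triplets; signals are discretized per channel into
equal-width bins.  The finite-sample bias of the plug-in estimate is
removed by subtracting the mean TE of seeded random permutations of the
source (surrogates destroy all temporal structure while keeping the
marginal), and the result is made scale-free by dividing by the target's
conditional entropy H(x_{t+1}|x_t):

    NTE_{Y->X} = ( TE_{Y->X} - <TE_{Y~->X}> ) / H(x_{t+1}|x_t).

Negative post-subtraction values are floored at zero so the connectivity
matrix is a valid nonnegative graph; a deterministic target (H = 0)
yields NTE = 0 with a logged warning.

The matrix orientation is fixed: ``weights[i, j]`` holds NTE_{j -> i}
(columns are information senders, rows are receivers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .io_core import (
    AnalysisConfig,
    ParameterError,
    Recording,
    ValidationError,
    logger,
)

__all__ = [
    "SymbolSeries",
    "ConnectivityMatrix",
    "discretize",
    "transfer_entropy",
    "conditional_entropy",
    "nte",
    "connectivity_matrix",
    "write_connectivity",
    "read_connectivity",
]

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Symbolization
# ---------------------------------------------------------------------------


@dataclass
class SymbolSeries:
    """Discretized signal: integer symbols in [0, n_bins)."""

    symbols: np.ndarray
    n_bins: int
    source_channel: str = ""

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.ndim != 1 or self.symbols.size < 2:
            raise ValidationError("symbol series must be 1-D with length >= 2")
        if self.n_bins < 2:
            raise ParameterError("n_bins must be >= 2")
        if self.symbols.min() < 0 or self.symbols.max() >= self.n_bins:
            raise ValidationError("symbols out of range [0, n_bins)")

    def __len__(self) -> int:
        return self.symbols.size


def discretize(signal: np.ndarray, n_bins: int, source_channel: str = "") -> SymbolSeries:
    """Equal-width binning of a signal over its own [min, max] range.

    The maximum value maps to the top bin; a constant signal maps to
    all-zero symbols (a valid degenerate series, not an error).
    """
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ParameterError("signal must be 1-D with length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        sym = np.zeros(x.size, dtype=np.int64)
    else:
        sym = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.int64)
        np.clip(sym, 0, n_bins - 1, out=sym)
    return SymbolSeries(sym, n_bins, source_channel)


# ---------------------------------------------------------------------------
# Plug-in entropies over symbol triplets
# ---------------------------------------------------------------------------


def _te_stack(idx_x: np.ndarray, y_stack: np.ndarray, n_bins: int) -> np.ndarray:
    """Plug-in TE (bits) for one target against a stack of source variants.

    ``idx_x`` is the combined target index x_{t+1}*B + x_t of length L;
    ``y_stack`` is (m, L) with one row per source variant (row 0 usually
    the real source, remaining rows surrogates).  Returns m TE values.

    Uses TE = H(x+,x) - H(x) - H(x+,x,y) + H(x,y); the log2(L) terms of
    the plug-in entropies cancel, so only the sum of c*log(c) over the
    joint counts is needed per marginal.
    """
    B = n_bins
    m, L = y_stack.shape
    offsets = (np.arange(m, dtype=np.int64) * (B * B * B))[:, None]
    flat = offsets + idx_x[None, :] * B + y_stack
    counts = np.bincount(flat.ravel(), minlength=m * B * B * B)
    counts = counts.reshape(m, B, B, B)  # (variant, x_next, x_cur, y)

    s_xyz = xlogy(counts, counts).sum(axis=(1, 2, 3))
    counts_xy = counts.sum(axis=1)  # (variant, x_cur, y)
    s_xy = xlogy(counts_xy, counts_xy).sum(axis=(1, 2))
    counts_x1x = counts[0].sum(axis=2)  # (x_next, x_cur); same for all variants
    s_x1x = xlogy(counts_x1x, counts_x1x).sum()
    counts_x = counts_x1x.sum(axis=0)  # (x_cur,)
    s_x = xlogy(counts_x, counts_x).sum()

    te = (-s_x1x + s_x + s_xyz - s_xy) / (L * _LN2)
    # clip tiny negative rounding noise; plug-in TE is nonnegative
    return np.maximum(te, 0.0)


def _check_pair(x: SymbolSeries, y: SymbolSeries) -> None:
    if len(x) != len(y):
        raise ParameterError(
            f"series lengths differ: {len(x)} vs {len(y)}"
        )


def transfer_entropy(x: SymbolSeries, y: SymbolSeries) -> float:
    """TE_{Y->X} in bits from plug-in joint histograms (single-lag states)."""
    _check_pair(x, y)
    B = max(x.n_bins, y.n_bins)
    idx_x = x.symbols[1:] * B + x.symbols[:-1]
    return float(_te_stack(idx_x, y.symbols[None, :-1], B)[0])


def conditional_entropy(x: SymbolSeries) -> float:
    """H(x_{t+1} | x_t) in bits: the target's own next-step uncertainty."""
    B = x.n_bins
    L = len(x) - 1
    flat = x.symbols[1:] * B + x.symbols[:-1]
    counts = np.bincount(flat, minlength=B * B).astype(np.float64)
    s_x1x = xlogy(counts, counts).sum()
    counts_x = counts.reshape(B, B).sum(axis=0)
    s_x = xlogy(counts_x, counts_x).sum()
    return float((s_x - s_x1x) / (L * _LN2))


# ---------------------------------------------------------------------------
# Normalized transfer entropy
# ---------------------------------------------------------------------------


def _surrogate_permutations(
    rng: np.random.Generator, n_surrogates: int, length: int
) -> np.ndarray:
    """(n_surrogates, length) permutation index arrays, seeded."""
    return np.array([rng.permutation(length) for _ in range(n_surrogates)])


def nte(
    x_raw: np.ndarray,
    y_raw: np.ndarray,
    cfg: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Surrogate-normalized transfer entropy from raw signals, Y -> X."""
    cfg = cfg or AnalysisConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    x = discretize(x_raw, cfg.n_bins)
    y = discretize(y_raw, cfg.n_bins)
    _check_pair(x, y)
    B = cfg.n_bins
    L = len(x) - 1
    idx_x = x.symbols[1:] * B + x.symbols[:-1]
    perms = _surrogate_permutations(rng, cfg.n_surrogates, L)
    y_cur = y.symbols[:-1]
    y_stack = np.vstack([y_cur[None, :], y_cur[perms]])
    te = _te_stack(idx_x, y_stack, B)
    h = conditional_entropy(x)
    if h == 0.0:
        logger.warning("target series is deterministic (H=0); NTE defined as 0")
        return 0.0
    return max(0.0, float((te[0] - te[1:].mean()) / h))


# ---------------------------------------------------------------------------
# Connectivity matrix
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityMatrix:
    """N x N directed NTE weights; ``weights[i, j]`` = NTE_{j -> i}."""

    weights: np.ndarray
    channel_labels: list[str]
    params: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        n = len(self.channel_labels)
        if self.weights.shape != (n, n):
            raise ValidationError(
                f"weights shape {self.weights.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("non-finite connectivity weights")
        if (self.weights < 0).any():
            raise ValidationError("negative connectivity weights")
        if np.abs(np.diag(self.weights)).max(initial=0.0) != 0.0:
            raise ValidationError("connectivity diagonal must be exactly zero")

    @property
    def n_nodes(self) -> int:
        return len(self.channel_labels)

    def index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ParameterError(f"unknown channel label {label!r}") from None


def connectivity_matrix(
    rec: Recording,
    cfg: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ConnectivityMatrix:
    """Full pairwise NTE matrix of a recording (columns send, rows receive).

    One set of seeded surrogate permutations is drawn per call and shared
    across all channel pairs; this keeps the estimate deterministic for a
    given config/seed and avoids re-permuting per pair.
    """
    cfg = cfg or AnalysisConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = rec.n_channels
    if n < 3:
        warnings.warn(
            "fewer than 3 channels: downstream graph metrics are degenerate",
            stacklevel=2,
        )
    B = cfg.n_bins
    syms = np.stack([discretize(row, B).symbols for row in rec.data])
    L = rec.n_samples - 1
    idx_x = syms[:, 1:] * B + syms[:, :-1]  # per-target combined index
    h = np.empty(n)
    for i in range(n):
        h[i] = conditional_entropy(SymbolSeries(syms[i], B))
    perms = _surrogate_permutations(rng, cfg.n_surrogates, L)

    weights = np.zeros((n, n))
    for j in range(n):  # sender
        y_cur = syms[j, :-1]
        y_stack = np.vstack([y_cur[None, :], y_cur[perms]])
        for i in range(n):  # receiver
            if i == j:
                continue
            te = _te_stack(idx_x[i], y_stack, B)
            if h[i] == 0.0:
                continue  # deterministic target: NTE defined as 0
            weights[i, j] = max(0.0, (te[0] - te[1:].mean()) / h[i])
    return ConnectivityMatrix(weights, list(rec.channel_labels), cfg)


# ---------------------------------------------------------------------------
# Serialization (delimited text; orientation stated in the header)
# ---------------------------------------------------------------------------


def write_connectivity(cm: ConnectivityMatrix, path) -> None:
    import dataclasses

    cfg_str = ";".join(
        f"{f.name}={getattr(cm.params, f.name)}" for f in dataclasses.fields(cm.params)
    )
    with open(path, "w") as fh:
        fh.write("# corehub connectivity matrix: rows=receivers, cols=senders "
                 "(weights[i,j] = NTE_{j->i})\n")
        fh.write(f"# labels={','.join(cm.channel_labels)}\n")
        fh.write(f"# config={cfg_str}\n")
        np.savetxt(fh, cm.weights, fmt="%.17g", delimiter="\t")


def read_connectivity(path) -> ConnectivityMatrix:
    labels: list[str] | None = None
    cfg = AnalysisConfig()
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("labels="):
                labels = body[len("labels="):].split(",")
            elif body.startswith("config="):
                cfg = _parse_config_line(body[len("config="):])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        weights = np.loadtxt(fh, ndmin=2)
    if labels is None:
        raise IOError(f"{path}: missing '# labels=' header")
    return ConnectivityMatrix(weights, labels, cfg)


def _parse_config_line(text: str) -> AnalysisConfig:
    values: dict[str, object] = {}
    for part in text.split(";"):
        if "=" not in part:
            continue
        key, _, raw = part.partition("=")
        key = key.strip()
        raw = raw.strip()
        if key in ("n_bins", "n_surrogates", "seed", "n_microstates"):
            values[key] = int(raw)
        elif key == "bonferroni":
            values[key] = raw.lower() in ("1", "true", "yes")
        elif key == "distance_mapping":
            values[key] = raw
        elif key in (
            "window_length_s",
            "window_overlap",
            "significance_level",
            "imbalance_threshold",
        ):
            values[key] = float(raw)
    return AnalysisConfig(**values)
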