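"""EEG microstate segmentation and quaternary Lempel-Ziv complexity.

The multichannel signal is condensed into the global field power

    GFP_t = sqrt( sum_i (EEG_{i,t} - <EEG_t>)^2 / N_ch ),

the spatial standard deviation about the instantaneous channel mean.
Topographies at local GFP maxima — moments of strong, stable fields —
are clustered by polarity-invariant modified k-means into k = 4 template
maps (microstates A-D); assignment uses squared spatial correlation so a
map and its sign-flip belong to the same state, and each template update
takes the first principal axis of its assigned maps.  Back-fitting labels
every sample with the template of maximal squared spatial correlation,
giving a quaternary symbol sequence.

Sequence irregularity is measured by the Lempel-Ziv (LZ76) complexity:
the number of phrases in the exhaustive-history parse, with the
normalized form c(n) * log_alpha(n) / n (log base = alphabet size) for
comparability across window lengths.  Within the triggered-window
analysis, windows carrying hub-count peaks are grouped by trigger type
(HD-only / HC-only / HN-only / common when >= 2 types peak) and the
complexity of each window's label subsequence is reported per group.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .dynamics import WindowSeries, peak_flags
from .io_core import ParameterError, Recording, ValidationError, logger

__all__ = [
    "MicrostateModel",
    "MicrostateSequence",
    "LZComplexity",
    "gfp",
    "gfp_peaks",
    "fit_microstates",
    "backfit",
    "lz_complexity",
    "windowed_complexity",
    "write_microstate_model",
    "read_microstate_model",
    "write_microstate_sequence",
    "read_microstate_sequence",
]


# ---------------------------------------------------------------------------
# Global field power
# ---------------------------------------------------------------------------


def gfp(rec: Recording) -> np.ndarray:
    """Per-sample spatial SD across channels (population normalization)."""
    if rec.n_channels < 2:
        raise ParameterError("GFP needs at least 2 channels")
    return rec.data.std(axis=0)


def gfp_peaks(rec: Recording) -> np.ndarray:
    """Sample indices of strict local maxima of the GFP curve."""
    g = gfp(rec)
    interior = (g[1:-1] > g[:-2]) & (g[1:-1] > g[2:])
    return np.nonzero(interior)[0] + 1


# ---------------------------------------------------------------------------
# Microstate model
# ---------------------------------------------------------------------------


@dataclass
class MicrostateModel:
    """k unit-norm template topographies with canonical letter labels."""

    templates: np.ndarray  # (k, n_channels)
    channel_labels: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=np.float64)
        if self.templates.ndim != 2:
            raise ValidationError("templates must be a (k, channels) matrix")
        k, n_ch = self.templates.shape
        if n_ch != len(self.channel_labels):
            raise ValidationError("template width does not match channel labels")
        norms = np.linalg.norm(self.templates, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValidationError("templates must be unit-normalized")
        if self.labels is None:
            self.labels = list(string.ascii_uppercase[:k])

    @property
    def k(self) -> int:
        return self.templates.shape[0]


@dataclass
class MicrostateSequence:
    """Per-sample microstate labels (ints into the model) plus GFP."""

    states: np.ndarray  # int per sample
    gfp: np.ndarray
    labels: list[str]
    flat: np.ndarray | None = None  # samples with zero topographic variance

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        self.gfp = np.asarray(self.gfp, dtype=np.float64)
        if self.states.shape != self.gfp.shape:
            raise ValidationError("state and GFP series lengths differ")
        if (self.gfp < 0).any():
            raise ValidationError("GFP must be nonnegative")

    @property
    def letters(self) -> np.ndarray:
        return np.asarray(self.labels)[self.states]

    def __len__(self) -> int:
        return self.states.size


def _center_normalize(maps: np.ndarray) -> np.ndarray:
    """Average-reference each map (row) and scale to unit norm."""
    x = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(norms > 0, x / np.where(norms > 0, norms, 1.0), 0.0)
    return x


def fit_microstates(
    rec: Recording,
    k: int = 4,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> MicrostateModel:
    """Polarity-invariant modified k-means on GFP-peak topographies.

    Assignment maximizes squared spatial correlation (so template polarity
    is irrelevant); each template update is the first principal axis of
    its assigned maps; iteration stops when the relative change in global
    explained variance (GEV) drops below ``tol``.  Deterministic for a
    given seed.
    """
    peaks = gfp_peaks(rec)
    if peaks.size < k:
        raise ParameterError(
            f"only {peaks.size} GFP peaks for k={k} microstates"
        )
    if peaks.size < 10 * k:
        logger.warning(
            "only %d GFP peaks for k=%d: templates may be unstable", peaks.size, k
        )
    maps = _center_normalize(rec.data[:, peaks].T)  # (P, C)
    g = gfp(rec)[peaks]
    rng = np.random.default_rng(seed)
    templates = maps[rng.choice(peaks.size, size=k, replace=False)]

    prev_gev = -np.inf
    for _ in range(max_iter):
        corr = templates @ maps.T  # (k, P)
        assign = np.argmax(corr ** 2, axis=0)
        for j in range(k):
            sel = maps[assign == j]
            if sel.shape[0] == 0:
                templates[j] = maps[rng.integers(maps.shape[0])]
                continue
            # principal axis of the assigned maps (channels x channels, small)
            cov = sel.T @ sel
            evals, evecs = np.linalg.eigh(cov)
            t = evecs[:, -1]
            templates[j] = t / np.linalg.norm(t)
        corr = templates @ maps.T
        best = np.max(corr ** 2, axis=0)
        gev = float((g ** 2 * best).sum() / (g ** 2).sum())
        if prev_gev > -np.inf and abs(gev - prev_gev) <= tol * max(prev_gev, 1e-12):
            break
        prev_gev = gev
    return MicrostateModel(templates, list(rec.channel_labels))


def backfit(rec: Recording, model: MicrostateModel) -> MicrostateSequence:
    """Label every sample with the best-matching template.

    Squared spatial correlation decides (polarity-invariant); exact ties
    — including flat, zero-variance topographies — go to the lowest
    template index, and flat samples are flagged.
    """
    if rec.n_channels != model.templates.shape[1]:
        raise ParameterError(
            f"recording has {rec.n_channels} channels, model expects "
            f"{model.templates.shape[1]}"
        )
    maps = _center_normalize(rec.data.T)  # (T, C)
    flat = np.linalg.norm(maps, axis=1) == 0
    corr2 = (model.templates @ maps.T) ** 2  # (k, T)
    states = np.argmax(corr2, axis=0)  # argmax takes the lowest index on ties
    if flat.any():
        logger.warning("%d flat (zero-GFP) samples labeled by the tie rule",
                       int(flat.sum()))
    return MicrostateSequence(states, gfp(rec), list(model.labels), flat)


# ---------------------------------------------------------------------------
# Lempel-Ziv (LZ76) complexity
# ---------------------------------------------------------------------------


class LZComplexity(NamedTuple):
    count: int
    normalized: float


def lz_complexity(seq: np.ndarray, alphabet_size: int) -> LZComplexity:
    """LZ76 exhaustive-history phrase count c(n) and c(n)*log_a(n)/n.

    Implementation follows the classic two-pointer scan (no substring
    primitives): the current phrase grows while it can be copied from the
    history, and a new phrase starts at the first symbol that cannot.
    """
    s = np.asarray(seq)
    if s.dtype.kind in "US":
        _, s = np.unique(s, return_inverse=True)
    s = s.astype(np.int64)
    n = s.size
    if n == 0:
        raise ParameterError("empty sequence")
    if alphabet_size < 2:
        raise ParameterError("alphabet size must be >= 2")
    if s.min() < 0 or s.max() >= alphabet_size:
        raise ValidationError("symbols outside the stated alphabet")

    c = 1
    phrase_start = 1  # index where the current (second) phrase begins
    i = 0            # candidate copy source within the history
    k = 1            # current match length
    k_max = 1
    if n == 1:
        return LZComplexity(1, 0.0)
    while True:
        if s[i + k - 1] == s[phrase_start + k - 1]:
            k += 1
            if phrase_start + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == phrase_start:
                c += 1
                phrase_start += k_max
                if phrase_start + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    norm = c * (np.log(n) / np.log(alphabet_size)) / n if n > 1 else 0.0
    return LZComplexity(int(c), float(norm))


# ---------------------------------------------------------------------------
# Triggered-window complexity
# ---------------------------------------------------------------------------


def windowed_complexity(
    seq: MicrostateSequence,
    ws: WindowSeries,
    k_sd: float = 1.0,
    alphabet_size: int | None = None,
) -> pd.DataFrame:
    """Complexity of the label subsequence in every peak-triggered window.

    Windows are grouped by trigger: a single peaking hub type names the
    group (HD/HC/HN); two or more peaking types form the "common" group.
    The grouping is a partition — each triggered window appears exactly
    once.  Untriggered windows are skipped.
    """
    alphabet_size = alphabet_size or len(seq.labels)
    flags = peak_flags(ws, k_sd)
    types = sorted(flags)
    rows = []
    for wi, start in enumerate(ws.window_starts):
        triggered = [t for t in types if flags[t][wi]]
        if not triggered:
            continue
        group = triggered[0] if len(triggered) == 1 else "common"
        stop = int(start) + ws.window_length
        sub = seq.states[int(start):stop]
        lz = lz_complexity(sub, alphabet_size)
        rows.append(
            {
                "window": wi,
                "start_s": float(start) / ws.fs,
                "group": group,
                "c": lz.count,
                "c_norm": lz.normalized,
            }
        )
    if not rows:
        warnings.warn("no peak-triggered windows", stacklevel=2)
        return pd.DataFrame(columns=["window", "start_s", "group", "c", "c_norm"])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_microstate_model(model: MicrostateModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# labels={','.join(model.labels)}\n")
        fh.write(f"# channels={','.join(model.channel_labels)}\n")
        np.savetxt(fh, model.templates.T, fmt="%.17g", delimiter="\t")


def read_microstate_model(path) -> MicrostateModel:
    labels = channels = None
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("labels="):
                labels = body[len("labels="):].split(",")
            elif body.startswith("channels="):
                channels = body[len("channels="):].split(",")
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        mat = np.loadtxt(fh, ndmin=2)
    if labels is None or channels is None:
        raise IOError(f"{path}: missing labels/channels header")
    return MicrostateModel(mat.T, channels, labels)


def write_microstate_sequence(seq: MicrostateSequence, path, fs: float = 0.0) -> None:
    with open(path, "w") as fh:
        fh.write(f"# labels={','.join(seq.labels)}\n")
        if fs:
            fh.write(f"# fs={fs:g}\n")
        fh.write("state\tgfp\n")
        for st, g in zip(seq.states, seq.gfp):
            fh.write(f"{seq.labels[st]}\t{g:.17g}\n")


def read_microstate_sequence(path) -> MicrostateSequence:
    labels = None
    states = []
    gfp_vals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("labels="):
                    labels = body[len("labels="):].split(",")
                continue
            if not line or line.startswith("state"):
                continue
            lab, _, g = line.partition("\t")
            states.append(lab)
            gfp_vals.append(float(g))
    if labels is None:
        raise IOError(f"{path}: missing '# labels=' header")
    index = {lab: i for i, lab in enumerate(labels)}
    return MicrostateSequence(
        np.array([index[s] for s in states]), np.array(gfp_vals), labels
    )
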