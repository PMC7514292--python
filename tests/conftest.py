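"""Shared fixtures: independent brute-force oracles and small recordings.

The oracles deliberately use naive algorithms (exhaustive path
enumeration, dictionary histograms, substring scans) so they share no
code path with the implementations they check.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import permutations

import numpy as np
import pytest

from corehub import AnalysisConfig, Recording


# ---------------------------------------------------------------------------
# Information-theory oracles (dictionary histograms, direct formulas)
# ---------------------------------------------------------------------------


def te_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in TE_{Y->X} by direct evaluation of the defining sum."""
    x = list(x)
    y = list(y)
    n = len(x) - 1
    triples = Counter((x[t + 1], x[t], y[t]) for t in range(n))
    pairs_xx = Counter((x[t + 1], x[t]) for t in range(n))
    pairs_xy = Counter((x[t], y[t]) for t in range(n))
    singles_x = Counter(x[t] for t in range(n))
    te = 0.0
    for (x1, x0, y0), c in triples.items():
        p_xyz = c / n
        p_cond_xy = c / pairs_xy[(x0, y0)]
        p_cond_x = pairs_xx[(x1, x0)] / singles_x[x0]
        te += p_xyz * math.log2(p_cond_xy / p_cond_x)
    return te


def cond_entropy_bruteforce(x: np.ndarray) -> float:
    """H(x_{t+1}|x_t) by direct evaluation."""
    x = list(x)
    n = len(x) - 1
    pairs = Counter((x[t + 1], x[t]) for t in range(n))
    singles = Counter(x[t] for t in range(n))
    h = 0.0
    for (x1, x0), c in pairs.items():
        p = c / n
        h -= p * math.log2(c / singles[x0])
    return h


# ---------------------------------------------------------------------------
# Graph oracles (exhaustive simple-path enumeration)
# ---------------------------------------------------------------------------

_TIE_TOL = 1e-9


def _all_simple_paths(dist: np.ndarray, src: int, dst: int):
    """Yield (length, path) for every simple path src -> dst."""
    n = dist.shape[0]

    def extend(node, visited, length):
        if node == dst:
            yield length, tuple(visited)
            return
        for nxt in range(n):
            if nxt in visited or not np.isfinite(dist[node, nxt]) or nxt == node:
                continue
            yield from extend(nxt, visited + [nxt], length + dist[node, nxt])

    yield from extend(src, [src], 0.0)


def betweenness_bruteforce(dist: np.ndarray) -> np.ndarray:
    """BC per node by enumerating every simple path and counting ties."""
    n = dist.shape[0]
    bc = np.zeros(n)
    for k in range(n):
        for j in range(n):
            if k == j:
                continue
            paths = list(_all_simple_paths(dist, k, j))
            if not paths:
                continue
            best = min(length for length, _ in paths)
            shortest = [p for length, p in paths if length <= best + _TIE_TOL]
            for i in range(n):
                if i in (k, j):
                    continue
                through = sum(1 for p in shortest if i in p[1:-1])
                bc[i] += through / len(shortest)
    return bc / ((n - 1) * (n - 2))


def cpl_bruteforce(dist: np.ndarray) -> float:
    """Mean shortest simple-path length over reachable ordered pairs."""
    n = dist.shape[0]
    total = 0.0
    count = 0
    for k in range(n):
        for j in range(n):
            if k == j:
                continue
            lengths = [length for length, _ in _all_simple_paths(dist, k, j)]
            if lengths:
                total += min(lengths)
                count += 1
    if count == 0:
        raise ValueError("no reachable pairs")
    return total / count


# ---------------------------------------------------------------------------
# LZ76 oracle (naive substring scan)
# ---------------------------------------------------------------------------


def lz76_bruteforce(symbols) -> int:
    """Exhaustive-history phrase count via naive substring containment."""
    s = "".join(str(int(v)) for v in symbols)
    n = len(s)
    c = 0
    pos = 0
    while pos < n:
        k = 1
        # grow the phrase while it can be copied from the history
        # (occurrences may start anywhere before the phrase's last symbol)
        while pos + k <= n and s[pos:pos + k] in s[: pos + k - 1]:
            k += 1
        if pos + k > n:  # ran off the end while still reproducible
            c += 1
            break
        c += 1
        pos += k
    return c


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def te_oracle():
    return te_bruteforce


@pytest.fixture
def cond_entropy_oracle():
    return cond_entropy_bruteforce


@pytest.fixture
def bc_oracle():
    return betweenness_bruteforce


@pytest.fixture
def cpl_oracle():
    return cpl_bruteforce


@pytest.fixture
def lz_oracle():
    return lz76_bruteforce


@pytest.fixture
def small_recording() -> Recording:
    rng = np.random.default_rng(42)
    return Recording(rng.normal(size=(3, 200)), fs=100.0,
                     channel_labels=["A", "B", "C"], condition="RS")


@pytest.fixture
def default_config() -> AnalysisConfig:
    return AnalysisConfig(seed=7)
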