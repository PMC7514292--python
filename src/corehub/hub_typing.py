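"""Divergent/convergent/neutral hub classification and core composition.

Each node's directed strength splits into an output degree OD (sum of
outgoing NTE) and an input degree ID (sum of incoming NTE); the net
entropy K = OD - ID is positive for information sources and negative for
sinks, and sums to exactly zero over the whole network (every edge adds
the same weight to one OD and one ID).

A hub whose OD exceeds ID by more than the imbalance threshold
(multiplicative, 10% by default: OD > 1.1*ID) is divergent (HD); the
mirror-image case is convergent (HC); anything in between — including
boundary equality and the degenerate OD = ID = 0 — is neutral (HN).
The multiplicative reading keeps the classification invariant to uniform
rescaling of the weights, which the unit-free NTE ratios require.
Typing applies only to nodes flagged as hubs; K is reported for every
node for diagnostics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .io_core import ParameterError

__all__ = [
    "degrees",
    "net_entropy",
    "classify_hub",
    "hub_table",
    "core_composition",
    "mean_net_entropy",
    "write_hub_table",
    "read_hub_table",
]

HUB_TYPES = ("HD", "HC", "HN")


def degrees(cm: ConnectivityMatrix, node: str) -> tuple[float, float]:
    """(OD, ID): summed outgoing and incoming NTE of a node.

    With the matrix convention weights[i, j] = NTE_{j->i}, a node's
    outgoing weights live in its column and incoming weights in its row.
    """
    i = cm.index(node)
    od = float(cm.weights[:, i].sum())
    id_ = float(cm.weights[i, :].sum())
    return od, id_


def net_entropy(cm: ConnectivityMatrix, node: str) -> float:
    """K = OD - ID: net directed contribution of a node, in NTE units."""
    od, id_ = degrees(cm, node)
    return od - id_


def classify_hub(od: float, id_: float, threshold: float = 0.10) -> str:
    """HD if OD > (1+threshold)*ID, HC if ID > (1+threshold)*OD, else HN."""
    if od < 0 or id_ < 0:
        raise ParameterError("degrees must be nonnegative")
    if threshold <= 0:
        raise ParameterError("imbalance threshold must be positive")
    if od > id_ * (1.0 + threshold):
        return "HD"
    if id_ > od * (1.0 + threshold):
        return "HC"
    return "HN"


def hub_table(
    cm: ConnectivityMatrix,
    hub_flags: dict[str, bool] | pd.DataFrame,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-node table: label, is_hub, K, OD, ID, hub_type ('none' for non-hubs).

    ``hub_flags`` is either a {label: bool} mapping or the frame returned
    by :func:`corehub.graph_metrics.identify_hubs`.
    """
    if isinstance(hub_flags, pd.DataFrame):
        hub_flags = dict(zip(hub_flags["node"], hub_flags["is_hub"]))
    threshold = threshold if threshold is not None else cm.params.imbalance_threshold
    rows = []
    for label in cm.channel_labels:
        od, id_ = degrees(cm, label)
        is_hub = bool(hub_flags.get(label, False))
        rows.append(
            {
                "node": label,
                "is_hub": is_hub,
                "K": od - id_,
                "OD": od,
                "ID": id_,
                "hub_type": classify_hub(od, id_, threshold) if is_hub else "none",
            }
        )
    return pd.DataFrame(rows)


def core_composition(ht: pd.DataFrame) -> dict[str, float]:
    """Fractions of HD/HC/HN among flagged hubs (sums to 1)."""
    hubs = ht[ht["is_hub"]]
    if hubs.empty:
        raise ParameterError("no hubs flagged: core composition undefined")
    n = len(hubs)
    return {t: float((hubs["hub_type"] == t).sum()) / n for t in HUB_TYPES}


def mean_net_entropy(ht: pd.DataFrame, hub_type: str) -> float | None:
    """Mean K over hubs of one type; None when that type is absent.

    Hub types need not all be present in a given network, so callers must
    treat the None ("absent type") result as first-class.
    """
    if hub_type not in HUB_TYPES:
        raise ParameterError(f"unknown hub type {hub_type!r}")
    sel = ht[(ht["is_hub"]) & (ht["hub_type"] == hub_type)]
    if sel.empty:
        return None
    return float(sel["K"].mean())


def write_hub_table(ht: pd.DataFrame, path) -> None:
    ht.to_csv(path, sep="\t", index=False)


def read_hub_table(path) -> pd.DataFrame:
    ht = pd.read_csv(path, sep="\t")
    ht["is_hub"] = ht["is_hub"].astype(bool)
    return ht
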