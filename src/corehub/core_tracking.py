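"""Connective-core preservation across conditions: Γ, Λ and transitions.

The connective core of a condition is its set of typed hubs — members are
(node, type) pairs, so a node that stays a hub but switches type counts
as a change.  For cores A and B of two conditions:

    homogeneity   Γ = 2 n(A ∩ B) / (n(A) + n(B))
    heterogeneity Λ = (n(A \\ B) + n(B \\ A)) / (n(A) + n(B))

The relative complements make Λ the exact complement of Γ (Γ + Λ = 1),
partitioning the core into an invariant sub-structure (hubs that keep
their type) and a variant one.  The transition table gives the full
accounting: each node that is a hub in at least one condition contributes
one transition "type_before -> type_after", with NH marking non-hub
status, and the fractions sum to 1.  Nodes that are hubs in neither
condition are excluded (there is no NH -> NH transition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_core import ParameterError

__all__ = [
    "CoreTransition",
    "hub_set",
    "homogeneity",
    "heterogeneity",
    "transition_table",
    "write_core_transition",
]

HubSet = set[tuple[str, str]]


def hub_set(ht: pd.DataFrame) -> HubSet:
    """Typed hub set {(node, hub_type)} of a hub table."""
    hubs = ht[ht["is_hub"]]
    return set(zip(hubs["node"], hubs["hub_type"]))


def _check_sets(a: HubSet, b: HubSet) -> None:
    if not a and not b:
        raise ParameterError("both hub sets empty: Γ/Λ undefined")


def homogeneity(a: HubSet, b: HubSet) -> float:
    """Γ: stable fraction of the combined core (1 = identical, 0 = disjoint)."""
    _check_sets(a, b)
    return 2.0 * len(a & b) / (len(a) + len(b))


def heterogeneity(a: HubSet, b: HubSet) -> float:
    """Λ: variable fraction of the combined core; Γ + Λ = 1 by construction."""
    _check_sets(a, b)
    return (len(a - b) + len(b - a)) / (len(a) + len(b))


@dataclass
class CoreTransition:
    """Hub-set comparison across two conditions."""

    condition_pair: tuple[str, str]
    gamma: float
    lambda_: float
    transition_fractions: dict[str, float] = field(default_factory=dict)

    @property
    def invariant_fraction(self) -> float:
        return sum(
            f for t, f in self.transition_fractions.items()
            if t.split("->")[0] == t.split("->")[1]
        )


def _node_type(ht: pd.DataFrame) -> dict[str, str]:
    out = {}
    for row in ht.itertuples():
        out[row.node] = row.hub_type if row.is_hub else "NH"
    return out


def transition_table(
    before: pd.DataFrame,
    after: pd.DataFrame,
    condition_pair: tuple[str, str] = ("", ""),
) -> CoreTransition:
    """Full transition accounting between two conditions' hub tables.

    Every node that is a hub in at least one condition contributes one
    "t1 -> t2" transition (t in {HD, HC, HN, NH}); fractions sum to 1.
    """
    t_before = _node_type(before)
    t_after = _node_type(after)
    if set(t_before) != set(t_after):
        raise ParameterError("hub tables cover different channel sets")
    counts: dict[str, int] = {}
    total = 0
    for node, t1 in t_before.items():
        t2 = t_after[node]
        if t1 == "NH" and t2 == "NH":
            continue
        counts[f"{t1}->{t2}"] = counts.get(f"{t1}->{t2}", 0) + 1
        total += 1
    if total == 0:
        raise ParameterError("no hubs in either condition")
    fractions = {t: c / total for t, c in counts.items()}
    gamma = homogeneity(hub_set(before), hub_set(after))
    return CoreTransition(
        condition_pair=condition_pair,
        gamma=gamma,
        lambda_=heterogeneity(hub_set(before), hub_set(after)),
        transition_fractions=fractions,
    )


def write_core_transition(ct: CoreTransition, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# conditions={ct.condition_pair[0]},{ct.condition_pair[1]}\n")
        fh.write(f"# gamma={ct.gamma:.17g}\n")
        fh.write(f"# lambda={ct.lambda_:.17g}\n")
        fh.write("transition\tfraction\n")
        for t, f in sorted(ct.transition_fractions.items()):
            fh.write(f"{t}\t{f:.17g}\n")
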