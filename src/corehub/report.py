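"""Group-level rank tests over per-subject results.

Per-subject metrics (mean K per hub type, core fractions, peak
correlations, ...) are compared across conditions with the availability
rule: the paired Friedman test when every subject contributes a value to
every group, and Kruskal-Wallis otherwise (hub types are not always
present in every subject, so complete pairing cannot be assumed).
Post-hoc pairwise comparisons after a rejection use two-sided rank-sum
tests with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import friedmanchisquare, kruskal, mannwhitneyu

from .io_core import ParameterError

__all__ = ["GroupResult", "compare_groups"]


@dataclass
class GroupResult:
    """Outcome of a group comparison (test chosen by the availability rule)."""

    test: str
    statistic: float
    p_value: float
    alpha: float
    groups: list[str]
    posthoc: pd.DataFrame | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_groups(
    values: pd.DataFrame,
    paired: bool = True,
    alpha: float = 0.05,
) -> GroupResult:
    """Compare >= 2 groups of per-subject values (columns = groups).

    ``paired=True`` requests the Friedman test, which requires complete
    cases; if any subject misses a group (NaN), the comparison falls back
    to Kruskal-Wallis on the available values, mirroring the conditional
    use of unpaired tests when a hub type is absent.  Post-hoc pairwise
    rank-sum tests (Bonferroni-corrected) are attached when the omnibus
    test rejects.
    """
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(values)
    if values.shape[1] < 2:
        raise ParameterError("need at least 2 groups to compare")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    groups = [str(c) for c in values.columns]
    complete = not values.isna().any().any()

    if paired and complete and values.shape[1] >= 3:  # Friedman needs >= 3 groups
        cols = [values[c].to_numpy(dtype=float) for c in values.columns]
        if np.ptp(np.concatenate(cols)) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = friedmanchisquare(*cols)
            if np.isnan(stat):  # every subject fully tied across groups
                stat, p = 0.0, 1.0
        test = "friedman"
    else:
        cols = [values[c].dropna().to_numpy(dtype=float) for c in values.columns]
        cols = [c for c in cols if c.size > 0]
        if len(cols) < 2:
            raise ParameterError("fewer than 2 non-empty groups")
        if np.ptp(np.concatenate(cols)) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = kruskal(*cols)
        test = "kruskal-wallis"

    posthoc = None
    if p < alpha:
        pairs = list(combinations(range(len(groups)), 2))
        rows = []
        for i, j in pairs:
            a = values.iloc[:, i].dropna().to_numpy(dtype=float)
            b = values.iloc[:, j].dropna().to_numpy(dtype=float)
            if np.ptp(np.concatenate([a, b])) == 0:
                pp = 1.0
            else:
                pp = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
            rows.append(
                {
                    "group_a": groups[i],
                    "group_b": groups[j],
                    "p_raw": pp,
                    "p_bonferroni": min(1.0, pp * len(pairs)),
                }
            )
        posthoc = pd.DataFrame(rows)

    return GroupResult(
        test=test,
        statistic=float(stat),
        p_value=float(p),
        alpha=alpha,
        groups=groups,
        posthoc=posthoc,
    )
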