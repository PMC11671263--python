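"""Floral-organ curvation rates and group comparisons.

The curvation rate of an organ is its flattened length divided by its
natural (projected) length: a flat organ scores 1.0 and stronger
curling gives larger values, so curled sepals rank above flat petals.
The reciprocal convention is available behind a flag for comparison
with sources that define the ratio the other way around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from scipy import stats


@dataclass
class OrganMeasurement:
    hybrid_id: str
    organ: str  # sepal | petal
    organ_index: int
    flat_length_mm: float
    natural_length_mm: float

    def __post_init__(self) -> None:
        if self.flat_length_mm <= 0 or self.natural_length_mm <= 0:
            raise ValueError("lengths must be positive")
        if self.flat_length_mm < self.natural_length_mm:
            warnings.warn(
                f"{self.hybrid_id} {self.organ}{self.organ_index}: flat length "
                "below natural length — expected only for uncurled organs")


def curvation_rate(flat_mm: float, natural_mm: float, reciprocal: bool = False) -> float:
    """flat / natural (or natural / flat with ``reciprocal``)."""
    if natural_mm <= 0 or flat_mm <= 0:
        raise ValueError("lengths must be positive")
    return natural_mm / flat_mm if reciprocal else flat_mm / natural_mm


def measurement_rates(measurements: pd.DataFrame, reciprocal: bool = False) -> pd.DataFrame:
    """Append a curvation_rate column to a measurement table with
    flat_length_mm / natural_length_mm columns."""
    out = measurements.copy()
    out["curvation_rate"] = [
        curvation_rate(f, n, reciprocal)
        for f, n in zip(out["flat_length_mm"], out["natural_length_mm"])
    ]
    return out


def compare_groups(values: pd.Series, groups: pd.Series,
                   alpha: float = 0.05) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pairwise Welch t-tests with a compact letter display.

    Groups with fewer than two observations are excluded (with a
    warning).  Letters are assigned greedily over groups ordered by
    descending mean: a group joins every existing letter whose members
    it does not differ from; groups sharing a letter are pairwise
    non-significant at ``alpha``.
    """
    by_group = {g: values[groups == g].to_numpy(float) for g in pd.unique(groups)}
    usable = {}
    for g, x in by_group.items():
        if len(x) < 2:
            warnings.warn(f"group {g!r} has <2 observations; excluded")
        else:
            usable[g] = x

    rows = []
    nonsig: dict[str, set[str]] = {g: {g} for g in usable}
    for g1, g2 in combinations(sorted(usable), 2):
        t, p = stats.ttest_ind(usable[g1], usable[g2], equal_var=False)
        rows.append((g1, g2, float(t), float(p)))
        if p >= alpha:
            nonsig[g1].add(g2)
            nonsig[g2].add(g1)
    pairs = pd.DataFrame(rows, columns=["group1", "group2", "t_stat", "p_value"])

    order = sorted(usable, key=lambda g: -usable[g].mean())
    letter_sets: list[set[str]] = []  # each is a clique of mutually non-sig groups
    for g in order:
        joined = False
        for members in letter_sets:
            if all(other in nonsig[g] for other in members):
                members.add(g)
                joined = True
        if not joined:
            letter_sets.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in usable}
    for i, members in enumerate(letter_sets):
        for g in members:
            letters[g] += alphabet[i]
    return pairs, letters
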