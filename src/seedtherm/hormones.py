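"""Bookkeeping over GA/ABA metabolite tables.

Gibberellin biosynthesis proceeds from the common precursor GA12 down two
parallel branches: the 13-non-hydroxylated pathway (GA15 -> GA24 -> GA9 ->
bioactive GA4/GA7) and the 13-hydroxylated pathway (GA44 -> GA19 -> GA20 ->
bioactive GA1/GA3).  ABA is catabolized via phaseic acid (PA) to
dihydrophaseic acid (DPA).  This module sums bioactive pools, partitions
the GA pathway, and tracks bioactive-GA/ABA ratios and their fold changes
over imbibition — it is deliberately unit-agnostic (any mass-normalized
content works) because all headline outputs are ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BIOACTIVE_GA",
    "NON13OH_GA",
    "OH13_GA",
    "RECOGNIZED_METABOLITES",
    "HormoneProfile",
    "PathwayPartition",
    "bioactive_ga",
    "pathway_partition",
    "ga_aba_ratio",
]

BIOACTIVE_GA = ("GA4", "GA7", "GA1", "GA3")
#: 13-non-hydroxylated branch (precursors + its bioactive products).
NON13OH_GA = ("GA15", "GA24", "GA9", "GA4", "GA7")
#: 13-hydroxylated branch.
OH13_GA = ("GA44", "GA19", "GA20", "GA1", "GA3")
#: GA12 is the common precursor of both branches and belongs to neither.
RECOGNIZED_METABOLITES = frozenset(
    ("GA12",) + NON13OH_GA + OH13_GA + ("ABA", "PA", "DPA"))


@dataclass(frozen=True)
class HormoneProfile:
    """Metabolite contents of one sample.

    ``contents`` maps metabolite name -> content (>= 0; below-detection
    values are encoded as 0 and listed in ``below_detection``).  Unknown
    metabolite names are rejected unless whitelisted via ``extra_allowed``.
    """

    sample: str
    contents: Mapping[str, float]
    below_detection: frozenset[str] = frozenset()
    extra_allowed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        allowed = RECOGNIZED_METABOLITES | self.extra_allowed
        unknown = set(self.contents) - allowed
        if unknown:
            raise ValueError(
                f"sample {self.sample!r}: unrecognized metabolites "
                f"{sorted(unknown)}; recognized names are "
                f"{sorted(RECOGNIZED_METABOLITES)} (extend via "
                "extra_allowed)")
        for name, value in self.contents.items():
            if value < 0:
                raise ValueError(f"sample {self.sample!r}: negative content "
                                 f"for {name}")

    def get(self, name: str) -> float:
        return float(self.contents.get(name, 0.0))


def _sum_species(profile: HormoneProfile, species: Sequence[str],
                 warn_label: str | None = None) -> float:
    missing = [s for s in species if s not in profile.contents]
    if missing and warn_label:
        warnings.warn(f"sample {profile.sample!r}: {warn_label} species "
                      f"absent and treated as 0: {missing}", stacklevel=3)
    return float(sum(profile.get(s) for s in species))


def bioactive_ga(profile: HormoneProfile) -> float:
    """Sum of the bioactive gibberellins GA4 + GA7 + GA1 + GA3.

    Metabolites absent from the profile contribute 0 with a warning.
    """
    return _sum_species(profile, BIOACTIVE_GA, warn_label="bioactive GA")


@dataclass(frozen=True)
class PathwayPartition:
    """Branch sums of the GA pathway for one sample."""

    non_13oh: float
    oh13: float
    dominant: str | None = field(default=None)

    @property
    def total(self) -> float:
        return self.non_13oh + self.oh13


def pathway_partition(profile: HormoneProfile) -> PathwayPartition:
    """Partition GA species into the two hydroxylation branches.

    GA12 (common precursor) is excluded from both sums; conservation holds
    as ``non_13oh + oh13 + GA12 == total recognized GA pool``.  The
    ``dominant`` flag names the larger branch (None on a tie).
    """
    non13 = _sum_species(profile, NON13OH_GA)
    oh13 = _sum_species(profile, OH13_GA)
    if non13 > oh13:
        dominant = "non_13oh"
    elif oh13 > non13:
        dominant = "13oh"
    else:
        dominant = None
    return PathwayPartition(non_13oh=non13, oh13=oh13, dominant=dominant)


def ga_aba_ratio(profiles: Sequence[HormoneProfile],
                 times: Sequence[float]) -> pd.DataFrame:
    """Bioactive-GA/ABA ratio per time point and fold change vs dry seed.

    ``times`` are imbibition times (h) aligned with ``profiles``; a t = 0
    (dry) sample with ABA > 0 is required as the fold-change reference.
    ABA exhausted to 0 at a later time yields an explicit ``inf`` ratio.
    """
    if len(profiles) != len(times):
        raise ValueError("profiles and times must have equal length")
    t = np.asarray(times, float)
    if 0.0 not in t:
        raise ValueError("a t = 0 (dry seed) sample is required")
    order = np.argsort(t)
    rows = []
    for i in order:
        p = profiles[i]
        ga = bioactive_ga(p)
        aba = p.get("ABA")
        if t[i] == 0.0 and aba <= 0:
            raise ValueError("dry-seed sample must have ABA > 0")
        ratio = ga / aba if aba > 0 else float("inf")
        rows.append({"sample": p.sample, "time_h": float(t[i]),
                     "bioactive_ga": ga, "aba": aba, "ratio": ratio})
    frame = pd.DataFrame(rows)
    ratio0 = float(frame.loc[frame["time_h"] == 0.0, "ratio"].iloc[0])
    if ratio0 == 0.0:
        frame["fold_vs_dry"] = np.where(frame["ratio"] > 0, np.inf, np.nan)
        frame.loc[frame["time_h"] == 0.0, "fold_vs_dry"] = np.nan
    else:
        frame["fold_vs_dry"] = frame["ratio"] / ratio0
    return frame
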