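"""G_max estimation and dormancy-layer decomposition.

The maximal germination percentage (G_max) of a treated population reveals
which dormancy layers the treatment releases.  Comparing the ladder of
treatment G_max values — water, GA or after-ripening, and the full-release
combination (GA + ethylene + nitrate) — decomposes the viable population
into non-dormant (ND), nondeep physiological dormancy (nPD) and deeper PD
(dPD) fractions.  The full-release value doubles as the viability ceiling,
since no viability stain is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import GerminationRecord

__all__ = [
    "estimate_gmax",
    "TreatmentGmaxTable",
    "DormancyDecomposition",
    "decompose_layers",
    "compare_states",
]

#: Treatment labels understood by :func:`decompose_layers`.
WATER = "water"
RELEASE_NPD = ("ar", "ga", "ar_or_ga")   # any of these releases nPD
FULL = "ga_e_kno3"
SCARIFIED = "scarified"


def estimate_gmax(records: Sequence[GerminationRecord],
                  event: str = "er") -> tuple[float, float | None]:
    """Final-time germination percentage, mean ± SEM across dishes.

    Returns ``(percent, sem)``; the SEM is ``None`` for a single dish.
    """
    if not records:
        raise ValueError("estimate_gmax: empty input")
    col = "er_count" if event == "er" else "tr_count"
    frame = pd.DataFrame([(r.dish, r.time_d, getattr(r, col), r.dish_size)
                          for r in records],
                         columns=["dish", "time", "count", "size"])
    finals = frame.sort_values("time").groupby("dish").last()
    pcts = 100.0 * finals["count"] / finals["size"]
    sem = (float(pcts.std(ddof=1) / math.sqrt(len(pcts)))
           if len(pcts) > 1 else None)
    return float(pcts.mean()), sem


@dataclass(frozen=True)
class TreatmentGmaxTable:
    """Treatment label -> G_max percent (with optional SEM per label)."""

    gmax: Mapping[str, float]
    sem: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for label, value in self.gmax.items():
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"G_max[{label!r}] = {value} outside "
                                 "[0, 100]")
        full = self.gmax.get(FULL)
        if full is not None:
            worst = max((v for k, v in self.gmax.items() if k != FULL),
                        default=0.0)
            if worst > full + 1e-9:
                raise ValueError("full-release G_max must be >= every "
                                 "partial-release value")


@dataclass(frozen=True)
class DormancyDecomposition:
    """Layer fractions of the viable population (sum to 1)."""

    f_nd: float
    f_npd: float
    f_dpd: float
    viable_fraction: float   # G_max(full release) / 100

    def __post_init__(self) -> None:
        fractions = (self.f_nd, self.f_npd, self.f_dpd)
        if any(f < 0 for f in fractions):
            raise ValueError("fractions must be non-negative")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def of_all_seeds(self) -> dict[str, float]:
        """The same fractions expressed over all seeds sown."""
        v = self.viable_fraction
        return {"f_nd": self.f_nd * v, "f_npd": self.f_npd * v,
                "f_dpd": self.f_dpd * v, "non_viable": 1.0 - v}


def decompose_layers(table: TreatmentGmaxTable | Mapping[str, float],
                     *, tolerance: float = 1e-9) -> DormancyDecomposition:
    """Dormancy-layer fractions from a treatment G_max ladder.

    Requires ``water``, an nPD-releasing entry (``ar`` and/or ``ga``; if
    both are present their maximum defines the nPD-released level) and the
    full-release entry ``ga_e_kno3``.  With G_w <= G_ga <= G_full:

        viable  = G_full / 100
        f_nd    = G_w  / G_full
        f_npd   = (G_ga - G_w) / G_full
        f_dpd   = 1 - G_ga / G_full

    Sampling noise that drives a difference slightly negative is clipped
    at zero with a warning; ``G_ga < G_water`` beyond ``tolerance`` (in
    percentage points) is an inconsistency error.  Scarification is not
    part of the decomposition (coat removal can exceed nPD release); when
    present it is surfaced as a diagnostic via :func:`compare_states`.
    """
    if isinstance(table, Mapping):
        table = TreatmentGmaxTable(gmax=dict(table))
    gmax = dict(table.gmax)
    if WATER not in gmax or FULL not in gmax:
        raise ValueError(f"table must contain {WATER!r} and {FULL!r}")
    npd_entries = [gmax[k] for k in RELEASE_NPD if k in gmax]
    if not npd_entries:
        raise ValueError("table must contain an AR or GA release entry")
    g_w, g_ga, g_full = gmax[WATER], max(npd_entries), gmax[FULL]
    if g_full <= 0:
        raise ValueError("full-release G_max must be positive")
    if g_ga < g_w - tolerance:
        raise ValueError(
            f"inconsistent ladder: GA/AR G_max ({g_ga}) below water "
            f"({g_w})")
    g_ga = max(g_ga, g_w)

    f_nd = g_w / g_full
    f_npd = (g_ga - g_w) / g_full
    f_dpd = 1.0 - g_ga / g_full
    if f_dpd < 0:
        if f_dpd < -tolerance / 100.0:
            warnings.warn("GA/AR release exceeds full release within "
                          "sampling noise; deeper-PD fraction clipped to 0",
                          stacklevel=2)
        f_npd += f_dpd
        f_dpd = 0.0
    return DormancyDecomposition(f_nd=f_nd, f_npd=f_npd, f_dpd=f_dpd,
                                 viable_fraction=g_full / 100.0)


def compare_states(gmax_by_state: Mapping[str, Mapping[str, float]]
                   ) -> pd.DataFrame:
    """Tidy pairwise contrasts of G_max values across states.

    ``gmax_by_state`` maps a state label (e.g. ``"FH_black_1"``) to its
    treatment -> G_max mapping.  Every pair of states is contrasted on the
    treatments they share: difference and ratio, nothing more.  Mismatched
    treatment sets are allowed; an empty intersection is an error.
    """
    states = list(gmax_by_state)
    if len(states) < 2:
        raise ValueError("need at least two states to contrast")
    rows = []
    for i, a in enumerate(states):
        for b in states[i + 1:]:
            shared = sorted(set(gmax_by_state[a]) & set(gmax_by_state[b]))
            if not shared:
                raise ValueError(f"states {a!r} and {b!r} share no "
                                 "treatment labels")
            for treatment in shared:
                va, vb = gmax_by_state[a][treatment], \
                    gmax_by_state[b][treatment]
                rows.append({
                    "state_a": a, "state_b": b, "treatment": treatment,
                    "gmax_a": va, "gmax_b": vb,
                    "difference": va - vb,
                    "ratio": va / vb if vb != 0 else np.inf})
    return pd.DataFrame(rows)
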