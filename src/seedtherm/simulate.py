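"""Monte-Carlo petri-dish germination experiments.

Reproduces the structure of replicate dish assays: a few dishes of ~30
seeds each are imbibed at a set of constant temperatures under continuous
light and scored at fixed (typically daily) times for the two visible
germination events, testa rupture (TR) and endosperm rupture (ER).  Seed
fates are drawn from the population thermal-time model; dormancy state and
pharmacological treatments act through the viable fraction and the TR->ER
lag, following the working model of germination control: light gates
germination entirely, GA or after-ripening releases the nondeep dormancy
layer, ethylene plus nitrate (on top of GA) releases the deeper layer, and
ABA delays ER only, leaving TR untouched.

The scored germination event (ER, radicle emergence) is governed by the
thermal-time thresholds; TR precedes it by a lognormal lag.  Exogenous ABA
stretches that lag, so under a fixed random stream an ABA treatment shifts
every ER time while leaving the TR time-course bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import NEVER, SeedDraw, SeedPopulationParams, time_to_germination

__all__ = [
    "TreatmentFlags",
    "DormancyState",
    "TreatmentRules",
    "ExperimentDesign",
    "GerminationRecord",
    "aba_lag_multiplier",
    "apply_treatment",
    "draw_seed",
    "simulate_experiment",
    "write_dataset",
]

#: Minimum TR time (d); keeps TR strictly positive when the lag would
#: otherwise push it past zero at very fast germination.
_MIN_TR_TIME = 0.05


@dataclass(frozen=True)
class TreatmentFlags:
    """Imbibition treatment of one experiment (water-in-light control by
    default)."""

    light: bool = True
    after_ripened: bool = False
    scarified: bool = False
    ga: bool = False
    fluridone: bool = False
    aba_conc: float = 0.0  # µM
    ethylene: bool = False
    nitrate: bool = False
    cold_stratified: bool = False

    def __post_init__(self) -> None:
        if self.aba_conc < 0:
            raise ValueError("aba_conc must be >= 0")

    @property
    def treatment_id(self) -> str:
        parts = []
        if not self.light:
            parts.append("dark")
        for name, tag in [("after_ripened", "AR"), ("scarified", "scar"),
                          ("ga", "GA"), ("fluridone", "FLU"),
                          ("ethylene", "E"), ("nitrate", "KNO3"),
                          ("cold_stratified", "cold")]:
            if getattr(self, name):
                parts.append(tag)
        if self.aba_conc > 0:
            parts.append(f"ABA{self.aba_conc:g}uM")
        return "+".join(parts) if parts else "water"


@dataclass(frozen=True)
class DormancyState:
    """Partition of the viable population into dormancy layers.

    ``f_nd`` germinates in plain water; ``f_npd`` (nondeep physiological
    dormancy) additionally germinates after AR storage or GA treatment;
    ``f_dpd`` (deeper PD) requires GA plus ethylene plus nitrate.
    """

    f_nd: float
    f_npd: float
    f_dpd: float

    def __post_init__(self) -> None:
        for f in (self.f_nd, self.f_npd, self.f_dpd):
            if not 0.0 <= f <= 1.0:
                raise ValueError("dormancy fractions must lie in [0, 1]")
        if abs(self.f_nd + self.f_npd + self.f_dpd - 1.0) > 1e-9:
            raise ValueError("dormancy fractions must sum to 1")


@dataclass(frozen=True)
class TreatmentRules:
    """Configurable treatment effect sizes not fixed by the layer model."""

    #: Fraction of viable seeds released by micropylar seed-coat removal.
    scarified_release: float = 15.0 / 19.0
    #: Extra released fraction when fluridone accompanies GA (FLU alone is
    #: a no-op).
    flu_ga_increment: float = 0.05
    #: ABA concentration (µM) at which the lag stretch is half-saturated.
    aba_half_saturation_um: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.scarified_release <= 1.0:
            raise ValueError("scarified_release must lie in [0, 1]")
        if self.flu_ga_increment < 0:
            raise ValueError("flu_ga_increment must be >= 0")
        if self.aba_half_saturation_um <= 0:
            raise ValueError("aba_half_saturation_um must be positive")


DEFAULT_RULES = TreatmentRules()


def aba_lag_multiplier(aba_conc: float, params: SeedPopulationParams,
                       rules: TreatmentRules = DEFAULT_RULES) -> float:
    """Factor by which ABA at ``aba_conc`` µM stretches the TR->ER lag.

    Saturating dose response ``1 + (M - 1) * c / (c + K)`` with ceiling
    ``M = params.lag_multiplier_aba`` and half-saturation ``K``; 1 at zero
    ABA.
    """
    if aba_conc < 0:
        raise ValueError("aba_conc must be >= 0")
    c, k = aba_conc, rules.aba_half_saturation_um
    return 1.0 + (params.lag_multiplier_aba - 1.0) * c / (c + k)


def apply_treatment(state: DormancyState, flags: TreatmentFlags,
                    base: SeedPopulationParams,
                    rules: TreatmentRules = DEFAULT_RULES
                    ) -> SeedPopulationParams:
    """Effective population parameters under a dormancy state + treatment.

    ``base.p_viable`` is the viability ceiling of the population (the
    germination fraction under full dormancy release); the treatment
    selects which dormancy layers are released and the effective viable
    fraction is ceiling x released.  Darkness blocks germination outright.
    ABA does not alter the returned parameters: its lag stretch is applied
    at simulation time (see :func:`aba_lag_multiplier`), which is what
    keeps TR times invariant under matched random streams.
    """
    if not flags.light:
        return replace(base, p_viable=0.0)
    if flags.scarified:
        released = rules.scarified_release
    elif flags.ga and flags.ethylene and flags.nitrate:
        released = state.f_nd + state.f_npd + state.f_dpd
    elif flags.ga or flags.after_ripened:
        released = state.f_nd + state.f_npd
        if flags.ga and flags.fluridone:
            released = min(1.0, released + rules.flu_ga_increment)
    else:
        # fluridone alone (or water) releases nothing beyond the ND layer
        released = state.f_nd
    return replace(base, p_viable=base.p_viable * released)


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of one simulated germination assay."""

    temperatures: Sequence[float]
    n_dishes: int = 3
    seeds_per_dish: int = 30
    scoring_times: Sequence[float] = field(
        default_factory=lambda: tuple(float(d) for d in range(1, 15)))
    treatment: TreatmentFlags = field(default_factory=TreatmentFlags)
    rng_seed: int = 0
    #: Lognormal shape (SD of log lag) of the TR->ER lag distribution.
    lag_sigma_log: float = 0.25

    def __post_init__(self) -> None:
        if len(self.temperatures) == 0:
            raise ValueError("design needs at least one temperature")
        if self.n_dishes <= 0 or self.seeds_per_dish <= 0:
            raise ValueError("dish and seed counts must be positive")
        times = np.asarray(self.scoring_times, dtype=float)
        if times.size == 0 or np.any(np.diff(times) <= 0) or times[0] <= 0:
            raise ValueError("scoring_times must be positive and strictly "
                             "increasing")
        if self.lag_sigma_log < 0:
            raise ValueError("lag_sigma_log must be >= 0")


@dataclass(frozen=True)
class GerminationRecord:
    """Cumulative TR/ER counts of one dish at one scoring time."""

    dish: str
    temperature_C: float
    time_d: float
    tr_count: int
    er_count: int
    dish_size: int
    treatment_id: str = "water"

    def __post_init__(self) -> None:
        if not 0 <= self.er_count <= self.tr_count <= self.dish_size:
            raise ValueError(
                f"dish {self.dish!r} at t={self.time_d}: counts must obey "
                f"0 <= ER ({self.er_count}) <= TR ({self.tr_count}) <= size "
                f"({self.dish_size})")


def draw_seed(rng: np.random.Generator,
              params: SeedPopulationParams) -> SeedDraw:
    """Draw one seed's thresholds (comonotonic, rejection-truncated).

    A single uniform rank maps to both thresholds; draws with a
    non-positive thermal time or a ceiling at/below ``T_base`` are
    physically invalid and redrawn.
    """
    from scipy.stats import norm

    while True:
        q = rng.uniform(1e-12, 1.0 - 1e-12)
        z = norm.ppf(q)
        theta = params.theta_cold_50 + params.sigma_theta * z
        t_c = params.T_c_50 - params.sigma_Tc * z
        if theta > 0 and t_c > params.T_base:
            return SeedDraw(theta_cold=theta, T_c=t_c, quantile_rank=q)


def simulate_experiment(design: ExperimentDesign,
                        params: SeedPopulationParams
                        ) -> list[GerminationRecord]:
    """Realize one assay; bit-identical output for identical ``rng_seed``.

    Per seed: viability ~ Bernoulli(p_viable); the germination (ER) time is
    the thermal-time :func:`~seedtherm.model.time_to_germination` of the
    seed's threshold draw; TR precedes ER by a lognormal lag with median
    ``er_lag_50`` which an ABA treatment stretches by
    :func:`aba_lag_multiplier` (ER delayed, TR unchanged).  Events enter the
    cumulative counts at the first scoring time at or after they occur.

    Each (temperature, dish) pair gets its own child stream spawned from
    the root seed, so dishes are independent and reordering temperatures
    does not perturb other dishes.
    """
    times = np.asarray(design.scoring_times, dtype=float)
    m_aba = aba_lag_multiplier(design.treatment.aba_conc, params)
    tid = design.treatment.treatment_id

    root = np.random.SeedSequence(design.rng_seed)
    children = iter(root.spawn(len(design.temperatures) * design.n_dishes))

    records: list[GerminationRecord] = []
    for temp in design.temperatures:
        for dish_i in range(design.n_dishes):
            rng = np.random.default_rng(next(children))
            dish_id = f"T{temp:g}_d{dish_i + 1}"
            er_times = np.full(design.seeds_per_dish, NEVER)
            tr_times = np.full(design.seeds_per_dish, NEVER)
            for s in range(design.seeds_per_dish):
                viable = rng.random() < params.p_viable
                seed = draw_seed(rng, params)
                lag_z = rng.standard_normal()
                if not viable:
                    continue
                t_germ = time_to_germination(temp, seed, params)
                if not math.isfinite(t_germ):
                    continue
                lag0 = params.er_lag_50 * math.exp(
                    design.lag_sigma_log * lag_z)
                tr_times[s] = max(t_germ - lag0, _MIN_TR_TIME)
                er_times[s] = tr_times[s] + lag0 * m_aba
            for t in times:
                records.append(GerminationRecord(
                    dish=dish_id, temperature_C=float(temp), time_d=float(t),
                    tr_count=int(np.sum(tr_times <= t)),
                    er_count=int(np.sum(er_times <= t)),
                    dish_size=design.seeds_per_dish, treatment_id=tid))
    return records


def write_dataset(records: Sequence[GerminationRecord],
                  path: str | Path) -> None:
    """Write records as the long-format CSV used throughout the package.

    Round-trips losslessly through
    :func:`seedtherm.io.read_germination_csv`.
    """
    from .io import records_to_frame

    records_to_frame(records).to_csv(path, index=False)
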