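"""Population-based thermal-time threshold model of seed germination.

A seed population is described by three cardinal temperatures and two
thermal-time constants.  Below the optimum temperature the germination rate
of the seed that occupies population quantile ``g`` rises linearly with
temperature,

    GR(T) = (T - T_base) / theta_cold(g),

where ``theta_cold(g)`` (degree-days, °C·d) is normally distributed across
the population around its median ``theta_cold_50``.  Above the optimum the
rate falls linearly towards the seed's ceiling temperature,

    GR(T) = (T_c(g) - T) / theta_warm,

with ``T_c(g)`` normally distributed around ``T_c_50`` and ``theta_warm``
shared by all seeds.  ``T_base`` is likewise shared.  Time to germination is
the reciprocal rate; a seed with zero rate never germinates.

The two threshold distributions are coupled comonotonically: one uniform
quantile rank maps to both thresholds, so seeds with small thermal-time
requirements also have high ceiling temperatures.  Each seed switches from
the sub- to the supra-optimal line at its own intersection temperature,
which keeps its rate profile continuous and zero exactly at ``T_base`` and
at its own ``T_c``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "SeedPopulationParams",
    "SeedDraw",
    "estimate_topt",
    "seed_at_quantile",
    "germination_rate",
    "time_to_germination",
    "predict_cumulative",
]

#: Marker returned by :func:`time_to_germination` for seeds that never
#: germinate at the given temperature (not viable, T <= T_base or T >= T_c).
NEVER = math.inf


def estimate_topt(T_base: float, theta_cold_50: float, T_c_50: float,
                  theta_warm: float) -> float:
    """Optimum temperature implied by the two median rate lines.

    Solves ``(T - T_base)/theta_cold_50 = (T_c_50 - T)/theta_warm``; the
    intersection of the ascending sub-optimal and descending supra-optimal
    median-percentile regression lines.  Lies strictly between ``T_base``
    and ``T_c_50``.
    """
    if theta_cold_50 <= 0 or theta_warm <= 0:
        raise ValueError("thermal-time constants must be positive")
    if T_c_50 <= T_base:
        raise ValueError(
            f"degenerate cardinal temperatures: T_c_50 ({T_c_50}) must "
            f"exceed T_base ({T_base})")
    return (theta_warm * T_base + theta_cold_50 * T_c_50) / (
        theta_warm + theta_cold_50)


@dataclass(frozen=True)
class SeedPopulationParams:
    """Thermal-time threshold parameters for one seed morph/seedlot/state.

    Parameters
    ----------
    T_base : float
        Base temperature (°C), shared by all seeds; rate is zero at or
        below it.
    theta_cold_50 : float
        Median sub-optimal thermal-time constant (°C·d).
    sigma_theta : float
        SD of the thermal-time constant across the population (°C·d).
    T_c_50 : float
        Median ceiling temperature (°C).
    sigma_Tc : float
        SD of the ceiling temperature across the population (°C).
    theta_warm : float
        Supra-optimal thermal-time constant (°C·d), shared by all seeds.
    p_viable : float
        Fraction of seeds capable of germinating in the given dormancy
        state / treatment.
    er_lag_50 : float
        Median lag (d) between testa rupture (TR) and endosperm rupture
        (ER, completed germination).
    lag_multiplier_aba : float
        Saturating upper bound for the factor by which exogenous ABA
        stretches the TR->ER lag (dimensionless, >= 1).
    """

    T_base: float
    theta_cold_50: float
    sigma_theta: float
    T_c_50: float
    sigma_Tc: float
    theta_warm: float
    p_viable: float = 1.0
    er_lag_50: float = 1.0
    lag_multiplier_aba: float = 3.0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, asdict(self).values())):
            raise ValueError("parameters must be finite")
        if self.theta_cold_50 <= 0 or self.theta_warm <= 0:
            raise ValueError("thermal-time constants must be positive")
        if self.sigma_theta < 0 or self.sigma_Tc < 0:
            raise ValueError("threshold SDs must be non-negative")
        if self.T_c_50 <= self.T_base:
            raise ValueError("T_c_50 must exceed T_base")
        if not 0.0 <= self.p_viable <= 1.0:
            raise ValueError("p_viable must lie in [0, 1]")
        if self.er_lag_50 < 0:
            raise ValueError("er_lag_50 must be non-negative")
        if self.lag_multiplier_aba < 1:
            raise ValueError("lag_multiplier_aba must be >= 1")
        # implied optimum must be admissible
        t_opt = estimate_topt(self.T_base, self.theta_cold_50,
                              self.T_c_50, self.theta_warm)
        if not self.T_base < t_opt < self.T_c_50:
            raise ValueError("implied T_opt outside (T_base, T_c_50)")

    @property
    def T_opt(self) -> float:
        """Optimum temperature of the median seed (°C)."""
        return estimate_topt(self.T_base, self.theta_cold_50,
                             self.T_c_50, self.theta_warm)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SeedPopulationParams":
        return cls(**d)


@dataclass(frozen=True)
class SeedDraw:
    """One seed's realized thresholds.

    Both thresholds derive from the same ``quantile_rank`` (comonotonic
    coupling): ``theta_cold`` increases and ``T_c`` decreases with the rank,
    so rank 0+ is the fastest seed in every regime.
    """

    theta_cold: float
    T_c: float
    viable: bool = True
    quantile_rank: float = 0.5

    def __post_init__(self) -> None:
        if self.theta_cold <= 0:
            raise ValueError("theta_cold must be positive")
        if not 0.0 < self.quantile_rank < 1.0:
            raise ValueError("quantile_rank must lie in (0, 1)")


def seed_at_quantile(q: float, params: SeedPopulationParams, *,
                     viable: bool = True) -> SeedDraw:
    """Seed occupying quantile rank ``q`` of the (viable) population.

    ``theta_cold = theta_cold_50 + sigma_theta * Phi^-1(q)`` and
    ``T_c = T_c_50 - sigma_Tc * Phi^-1(q)``; at q = 0.5 this is the median
    seed.  Useful as the exact (noiseless) inverse of
    :func:`predict_cumulative`.
    """
    z = norm.ppf(q)
    theta = params.theta_cold_50 + params.sigma_theta * z
    t_c = params.T_c_50 - params.sigma_Tc * z
    return SeedDraw(theta_cold=theta, T_c=t_c, viable=viable,
                    quantile_rank=q)


def _split_temperature(seed: SeedDraw, params: SeedPopulationParams) -> float:
    """Temperature at which this seed's two rate lines intersect."""
    return (params.theta_warm * params.T_base
            + seed.theta_cold * seed.T_c) / (params.theta_warm
                                             + seed.theta_cold)


def germination_rate(T: float, seed: SeedDraw,
                     params: SeedPopulationParams) -> float:
    """Germination rate (d^-1) of one seed at temperature ``T`` (°C).

    Piecewise linear: the sub-optimal line up to the seed's own regime
    split, the supra-optimal line above it; clipped at zero outside
    ``(T_base, T_c)``.
    """
    if not math.isfinite(T):
        raise ValueError(f"temperature must be finite, got {T!r}")
    if not seed.viable:
        raise ValueError("germination_rate is defined for viable seeds only")
    if T <= _split_temperature(seed, params):
        return max(0.0, (T - params.T_base) / seed.theta_cold)
    return max(0.0, (seed.T_c - T) / params.theta_warm)


def time_to_germination(T: float, seed: SeedDraw,
                        params: SeedPopulationParams) -> float:
    """Days to germination; :data:`NEVER` (inf) when the seed cannot.

    Reciprocal of :func:`germination_rate`; non-viable seeds and
    temperatures at/outside the seed's ``(T_base, T_c)`` window never
    germinate.
    """
    if not math.isfinite(T):
        raise ValueError(f"temperature must be finite, got {T!r}")
    if not seed.viable:
        return NEVER
    if T <= _split_temperature(seed, params):
        rate = max(0.0, (T - params.T_base) / seed.theta_cold)
    else:
        rate = max(0.0, (seed.T_c - T) / params.theta_warm)
    return 1.0 / rate if rate > 0 else NEVER


def _cdf_or_step(x: np.ndarray, sigma: float) -> np.ndarray:
    """Phi(x / sigma), degenerating to a unit step when sigma == 0."""
    if sigma > 0:
        return norm.cdf(x / sigma)
    return np.where(x >= 0, 1.0, 0.0)


def predict_cumulative(T: float, times, params: SeedPopulationParams
                       ) -> np.ndarray:
    """Expected cumulative germinated fraction at each scoring time.

    Closed form over the comonotonic threshold distributions.  A seed of
    rank g has germinated by time t iff

        theta_cold(g) <= (T - T_base) * t   and
        T_c(g)        >= T + theta_warm / t,

    both of which are events {g <= .}; the germinated fraction is therefore
    ``p_viable * min(g1, g2)`` with the two normal CDFs g1, g2.  At genuinely
    sub-optimal temperatures the ceiling constraint is slack and this
    reduces to ``p_viable * Phi(((T - T_base) t - theta_cold_50) /
    sigma_theta)``.  Zero-SD distributions degenerate to step functions.
    """
    if not math.isfinite(T):
        raise ValueError(f"temperature must be finite, got {T!r}")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-d sequence")
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending and non-negative")

    if T <= params.T_base:
        return np.zeros_like(t)

    with np.errstate(divide="ignore"):
        # sub-optimal accumulation constraint
        g1 = _cdf_or_step((T - params.T_base) * t - params.theta_cold_50,
                          params.sigma_theta)
        # ceiling constraint; theta_warm / t -> inf at t = 0, so g2(0) = 0
        g2 = _cdf_or_step(params.T_c_50 - T - params.theta_warm
                          / np.where(t > 0, t, np.nan), params.sigma_Tc)
    g2 = np.where(t > 0, g2, 0.0)
    return params.p_viable * np.minimum(g1, g2)
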