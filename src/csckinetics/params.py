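"""Parameter containers and surviving-fraction algebra.

The kinetic model tracks three compartments per unit tumor volume: cancer
stem-like cells (CSCs, ``u``), non-stem tumor cells (TCs, ``v``) and dead
cells (``w``).  All rates are per day; all characteristic times are in days.

A CSC divides at rate ``m_u = ln2/T_u``; a division is symmetric (two CSCs)
with probability ``delta``, otherwise asymmetric (one CSC + one TC).  TCs
divide at ``m_v = ln2/T_v`` and die by programmed death at ``m_a = ln2/T_a``.
On a treated day a single 2 Gy fraction kills CSCs and TCs with surviving
fractions ``SF_u`` and ``SF_v``, expressed as continuous kill rates
``gamma_u = -ln SF_u`` and ``gamma_v = -ln SF_v`` acting over that day; on
untreated days both kill rates are zero.  Dead cells are cleared from the
imaged volume at ``gamma_w = ln2/T_h``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "LN2",
    "KineticParameters",
    "DerivedRates",
    "StepCoefficients",
    "InvalidParameterError",
    "InfeasibleSurvivingFractionError",
    "derive_rates",
    "step_coefficients",
    "sf_total",
    "solve_sf_v",
]

LN2 = math.log(2.0)


class InvalidParameterError(ValueError):
    """A kinetic parameter violates its domain constraint."""


class InfeasibleSurvivingFractionError(ValueError):
    """The implied TC surviving fraction falls outside (0, 1]."""


@dataclass(frozen=True)
class KineticParameters:
    """Rate and fraction parameters of the three-compartment model.

    Parameters
    ----------
    delta : float
        Probability of symmetric CSC division (self-renewal rate), in [0, 1].
    p : float
        Initial CSC proportion ``U0 / (U0 + V0)``, in [0, 1].
    t_u, t_v : float
        CSC and TC doubling times, days (> 0).
    t_a : float
        Half-time of programmed TC death, days (> 0).
    t_h : float
        Half-time of dead-cell clearance, days (> 0).
    sf_u, sf_v : float
        CSC and TC surviving fractions per 2 Gy fraction, in (0, 1].
    """

    delta: float
    p: float
    t_u: float
    t_v: float
    t_a: float
    t_h: float
    sf_u: float
    sf_v: float

    def __post_init__(self) -> None:
        for name in ("t_u", "t_v", "t_a", "t_h"):
            value = getattr(self, name)
            if not (value > 0.0) or not math.isfinite(value):
                raise InvalidParameterError(
                    f"{name} must be a positive finite time in days, got {value!r}"
                )
        for name in ("delta", "p"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {value!r}")
        for name in ("sf_u", "sf_v"):
            value = getattr(self, name)
            if not (0.0 < value <= 1.0):
                raise InvalidParameterError(f"{name} must lie in (0, 1], got {value!r}")

    @classmethod
    def with_shared_doubling_time(
        cls,
        *,
        delta: float,
        p: float,
        sf_u: float,
        sf_v: float,
        t_h: float,
        doubling_time: float,
    ) -> "KineticParameters":
        """Build parameters with ``T_u = T_v = T_a`` set to one doubling time.

        This is the configuration used for fitting: the CSC doubling time, TC
        doubling time and programmed-death half-time all take the histology's
        potential doubling time.
        """
        return cls(
            delta=delta,
            p=p,
            t_u=doubling_time,
            t_v=doubling_time,
            t_a=doubling_time,
            t_h=t_h,
            sf_u=sf_u,
            sf_v=sf_v,
        )

    def replace(self, **changes: float) -> "KineticParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class DerivedRates:
    """Per-day rates derived from :class:`KineticParameters` for one day.

    ``gamma_u`` and ``gamma_v`` are nonzero only on treated days.
    """

    m_u: float
    m_v: float
    m_a: float
    gamma_u: float
    gamma_v: float
    gamma_w: float


@dataclass(frozen=True)
class StepCoefficients:
    """Exponential-rate coefficients of the one-day analytic update.

    ``a`` is the net CSC rate (self-renewal minus radiation kill), ``b`` the
    asymmetric-division inflow rate into the TC compartment, and ``c`` the net
    TC rate.
    """

    a: float
    b: float
    c: float


def derive_rates(params: KineticParameters, treated: bool) -> DerivedRates:
    """Convert characteristic times and surviving fractions to per-day rates.

    On an untreated day the radiation kill rates are zero (equivalent to
    setting both surviving fractions to 1 for that day); division, programmed
    death and dead-cell clearance run every day.
    """
    return DerivedRates(
        m_u=LN2 / params.t_u,
        m_v=LN2 / params.t_v,
        m_a=LN2 / params.t_a,
        gamma_u=-math.log(params.sf_u) if treated else 0.0,
        gamma_v=-math.log(params.sf_v) if treated else 0.0,
        gamma_w=LN2 / params.t_h,
    )


def step_coefficients(
    rates: DerivedRates, delta: float, convention: str = "ode"
) -> StepCoefficients:
    """Compute the exponential coefficients A, B, C of the daily update.

    ``convention="ode"`` (default) uses the coefficients implied by the
    governing differential equations: ``C = m_v - m_a - gamma_v``.
    ``convention="printed"`` reproduces an alternative published algebraic
    form, ``C = m_v + m_a - gamma_v``, kept only as a compatibility switch;
    it is inconsistent with the differential system and with the numerical
    integrator.
    """
    if not (0.0 <= delta <= 1.0):
        raise InvalidParameterError(f"delta must lie in [0, 1], got {delta!r}")
    if convention == "ode":
        c = rates.m_v - rates.m_a - rates.gamma_v
    elif convention == "printed":
        c = rates.m_v + rates.m_a - rates.gamma_v
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return StepCoefficients(
        a=delta * rates.m_u - rates.gamma_u,
        b=(1.0 - delta) * rates.m_u,
        c=c,
    )


def death_inflow_rate(rates: DerivedRates, convention: str = "ode") -> float:
    """Rate at which TCs feed the dead-cell compartment.

    The differential system moves TCs into the dead pool by programmed death
    plus radiation kill, ``m_a + gamma_v`` (default).  The "printed"
    compatibility convention uses ``m_v + gamma_v``; the two coincide when
    ``T_a = T_v``, the shared-doubling-time configuration used in fitting.
    """
    if convention == "ode":
        return rates.m_a + rates.gamma_v
    if convention == "printed":
        return rates.m_v + rates.gamma_v
    raise ValueError(f"unknown convention {convention!r}")


def sf_total(p: float, sf_u: float, sf_v: float) -> float:
    """Population surviving fraction of the CSC/TC mixture after one fraction.

    ``SF_T = p * SF_u + (1 - p) * SF_v`` — the convex combination of the two
    subpopulations' surviving fractions weighted by the CSC proportion.
    """
    for name, value in (("p", p), ("sf_u", sf_u), ("sf_v", sf_v)):
        if not (0.0 <= value <= 1.0):
            raise InvalidParameterError(f"{name} must lie in [0, 1], got {value!r}")
    return p * sf_u + (1.0 - p) * sf_v


def solve_sf_v(sf_t: float, p: float, sf_u: float) -> float:
    """Solve the mixing relation for the TC surviving fraction.

    Given the histology-level surviving fraction ``SF_T`` and a candidate
    ``(p, SF_u)``, returns ``SF_v = (SF_T - p*SF_u) / (1 - p)``.  Raises
    :class:`InfeasibleSurvivingFractionError` when the implied value falls
    outside (0, 1], which bounds the feasible region during fitting.
    """
    if not (0.0 <= p < 1.0):
        raise InvalidParameterError(
            f"p must lie in [0, 1); the mixture is degenerate at p=1 (got {p!r})"
        )
    if not (0.0 < sf_t <= 1.0) or not (0.0 < sf_u <= 1.0):
        raise InvalidParameterError("sf_t and sf_u must lie in (0, 1]")
    sf_v = (sf_t - p * sf_u) / (1.0 - p)
    if 1.0 < sf_v <= 1.0 + 1e-12:  # round-off from an exact sf_v = 1
        sf_v = 1.0
    if not (0.0 < sf_v <= 1.0):
        raise InfeasibleSurvivingFractionError(
            f"implied sf_v={sf_v:.6g} outside (0, 1] for sf_t={sf_t}, p={p}, sf_u={sf_u}"
        )
    return sf_v
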