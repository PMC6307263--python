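"""Least-squares estimation of radiobiological parameters from volume series.

The estimation compares the measured daily tumor volumes, normalized to the
first imaging day, with the modelled total burden ``G_i/G_0`` and minimizes

    R = sqrt( (1/n) * sum_i | M_i/M_0 - G_i/G_0 | )

over the free parameters (delta, p, T_h, SF_u).  The TC surviving fraction is
not free: it is tied to the histology-level surviving fraction SF_T through
the mixing relation, so every candidate must keep the implied SF_v inside
(0, 1].  All three growth times (T_u, T_v, T_a) share the histology's
doubling time; by default the potential doubling time T_pot.

Note the objective sums absolute deviations under the root, not squares, so
it is non-smooth at the optimum; the search is therefore derivative-free
(bounded Nelder-Mead from a coarse multi-start grid).
"""

from __future__ import annotations

import datetime as dt
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .params import (
    InfeasibleSurvivingFractionError,
    KineticParameters,
    solve_sf_v,
)
from .schedule import TreatmentCourse, simulate_course

__all__ = [
    "VolumeSeries",
    "HistologyPreset",
    "FitConfig",
    "FitResult",
    "FittingError",
    "objective_R",
    "fit_parameters",
    "doubling_time_comparison",
    "stability_scan",
    "percent_error_stats",
]

#: feasible search box for (delta, p, sf_u, t_h); delta and sf_u ranges match
#: the documented stability-scan ranges, t_h generously brackets reported fits
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "delta": (0.001, 0.2),
    "p": (0.001, 0.995),
    "sf_u": (0.001, 1.0),
    "t_h": (0.1, 20.0),
}

_INFEASIBLE_PENALTY = 10.0


class FittingError(RuntimeError):
    """The optimization could not produce a feasible estimate."""


@dataclass(frozen=True)
class VolumeSeries:
    """Dated tumor-volume measurements in cm^3; the first defines ``M_0``."""

    dates: tuple[dt.date, ...]
    volumes: np.ndarray

    def __post_init__(self) -> None:
        vols = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "volumes", vols)
        if len(self.dates) != len(vols):
            raise ValueError("dates and volumes must have equal length")
        if len(vols) == 0:
            raise ValueError("volume series is empty")
        if not np.all(vols > 0.0):
            raise ValueError("all measured volumes must be positive")
        if any((b - a).days <= 0 for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("measurement dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.dates)

    @classmethod
    def from_course(cls, course: TreatmentCourse) -> "VolumeSeries":
        """Extract the measured volumes attached to a course's imaging days."""
        pairs = [
            (d.date, d.measured_volume)
            for d in course.days
            if d.measured_volume is not None
        ]
        if not pairs:
            raise ValueError("course carries no measured volumes")
        dates, vols = zip(*pairs)
        return cls(dates=tuple(dates), volumes=np.array(vols, dtype=float))

    def normalized(self) -> np.ndarray:
        return self.volumes / self.volumes[0]


@dataclass(frozen=True)
class HistologyPreset:
    """Histology-level constants entering the fit.

    ``sf_t`` is the population surviving fraction per 2 Gy; ``t_pot`` the
    potential doubling time (the default growth time for the model, since it
    accounts for quiescent cells); ``t_div`` the in-vitro cell division time
    and ``t_vol`` the clinical volume doubling time, both kept as alternative
    growth-time candidates for the fitness comparison.  All times in days.
    """

    name: str
    sf_t: float
    t_pot: float
    t_div: float
    t_vol: float

    def __post_init__(self) -> None:
        if not (0.0 < self.sf_t < 1.0):
            raise ValueError(f"sf_t must lie in (0, 1), got {self.sf_t!r}")
        for attr in ("t_pot", "t_div", "t_vol"):
            if not (getattr(self, attr) > 0.0):
                raise ValueError(f"{attr} must be positive")

    @property
    def doubling_times(self) -> dict[str, float]:
        return {"t_pot": self.t_pot, "t_div": self.t_div, "t_vol": self.t_vol}


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_parameters`."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    #: coarse multi-start grid per free parameter
    start_grid: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "delta": (0.01, 0.08, 0.18),
            "p": (0.05, 0.3, 0.7),
            "sf_u": (0.93, 0.99),
            "t_h": (0.5, 4.0),
        }
    )
    xatol: float = 1e-6
    fatol: float = 1e-10
    max_iter: int = 2000
    #: square the deviations instead of taking absolute values (a true RMS
    #: objective); non-default variant, kept for comparison only
    rms_objective: bool = False
    polish: bool = True
    seed: int = 0
    convention: str = "ode"


@dataclass(frozen=True)
class FitResult:
    """Estimated parameters with objective value and error statistics."""

    delta: float
    p: float
    sf_u: float
    sf_v: float
    t_h: float
    doubling_time: float
    preset: HistologyPreset
    r: float
    percent_error_mean: float
    percent_error_sd: float
    n_obs: int
    diagnostics: dict = field(default_factory=dict, repr=False)

    @property
    def params(self) -> KineticParameters:
        return KineticParameters.with_shared_doubling_time(
            delta=self.delta,
            p=self.p,
            sf_u=self.sf_u,
            sf_v=self.sf_v,
            t_h=self.t_h,
            doubling_time=self.doubling_time,
        )

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "p": self.p,
            "sf_u": self.sf_u,
            "sf_v": self.sf_v,
            "t_h": self.t_h,
            "doubling_time": self.doubling_time,
            "preset": self.preset.name,
            "r": self.r,
            "percent_error_mean": self.percent_error_mean,
            "percent_error_sd": self.percent_error_sd,
            "n_obs": self.n_obs,
        }


def _aligned_model_values(
    params: KineticParameters,
    course: TreatmentCourse,
    volumes: VolumeSeries,
    convention: str,
) -> np.ndarray:
    """Modelled ``G_i/G_0`` at the measurement dates."""
    index_by_date = {d: i for i, d in enumerate(course.dates)}
    try:
        idx = [index_by_date[d] for d in volumes.dates]
    except KeyError as err:
        raise ValueError(f"measurement date {err.args[0]} not in course") from None
    trajectory = simulate_course(params, course, convention=convention)
    return trajectory[idx]


def objective_R(
    params: KineticParameters,
    course: TreatmentCourse,
    volumes: VolumeSeries,
    convention: str = "ode",
    rms: bool = False,
) -> float:
    """Root-mean absolute deviation between measured and modelled series.

    Both series are normalized to the first measurement day, whose term is
    identically zero; ``n`` counts the remaining measurement days.  With
    ``rms=True`` deviations are squared instead (conventional RMS), a
    non-default variant.
    """
    if len(volumes) < 2:
        raise ValueError("objective needs at least two measurements")
    model = _aligned_model_values(params, course, volumes, convention)
    measured = volumes.normalized()
    dev = np.abs(measured[1:] - model[1:] / model[0])
    if rms:
        return float(math.sqrt(np.mean(dev**2)))
    return float(math.sqrt(np.mean(dev)))


def percent_error_stats(
    model_values: Sequence[float], measured_values: Sequence[float]
) -> tuple[float, float]:
    """Per-day percent deviations ``100*|M_i/M_0 - G_i/G_0|``: (mean, sample SD).

    Both inputs are normalized series aligned day-by-day; the SD uses the
    n-1 sample convention.
    """
    model = np.asarray(model_values, dtype=float)
    measured = np.asarray(measured_values, dtype=float)
    if model.shape != measured.shape:
        raise ValueError("series lengths differ")
    errors = 100.0 * np.abs(measured - model)
    sd = float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0
    return float(np.mean(errors)), sd


def _make_objective(
    course: TreatmentCourse,
    volumes: VolumeSeries,
    preset: HistologyPreset,
    doubling_time: float,
    config: FitConfig,
):
    """Objective over the free vector (delta, p, sf_u, t_h).

    Candidates whose tied SF_v leaves (0, 1] receive a penalty that grows
    with the violation, steering the simplex back into the feasible region.
    """

    def fun(theta: np.ndarray) -> float:
        delta, p, sf_u, t_h = theta
        try:
            sf_v = solve_sf_v(preset.sf_t, p, sf_u)
        except InfeasibleSurvivingFractionError:
            implied = (preset.sf_t - p * sf_u) / (1.0 - p)
            violation = max(-implied, implied - 1.0, 0.0)
            return _INFEASIBLE_PENALTY + violation
        except ValueError:
            return _INFEASIBLE_PENALTY
        params = KineticParameters.with_shared_doubling_time(
            delta=delta, p=p, sf_u=sf_u, sf_v=sf_v, t_h=t_h,
            doubling_time=doubling_time,
        )
        return objective_R(
            params, course, volumes,
            convention=config.convention, rms=config.rms_objective,
        )

    return fun


def fit_parameters(
    course: TreatmentCourse,
    volumes: VolumeSeries,
    preset: HistologyPreset,
    config: FitConfig | None = None,
    doubling_time: float | None = None,
) -> FitResult:
    """Estimate (delta, p, SF_u, T_h) by bounded multi-start Nelder-Mead.

    ``doubling_time`` overrides the growth time shared by T_u, T_v and T_a
    (default: the preset's potential doubling time).  Returns the best
    feasible optimum across all starts; per-start optima are kept in
    ``diagnostics['local_optima']`` for stability inspection.
    """
    config = config or FitConfig()
    if len(volumes) < 5:
        raise ValueError("need at least 5 volume measurements to fit")
    t_growth = preset.t_pot if doubling_time is None else doubling_time
    fun = _make_objective(course, volumes, preset, t_growth, config)
    names = ("delta", "p", "sf_u", "t_h")
    bounds = [config.bounds[n] for n in names]

    starts = [
        theta
        for theta in itertools.product(*(config.start_grid[n] for n in names))
        if fun(np.array(theta)) < _INFEASIBLE_PENALTY
    ]
    if not starts:
        raise FittingError(
            "no feasible starting point: every grid candidate implies an "
            "SF_v outside (0, 1] for this preset"
        )

    local_optima: list[dict] = []
    best = None
    for theta0 in starts:
        res = optimize.minimize(
            fun,
            np.array(theta0, dtype=float),
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "xatol": config.xatol,
                "fatol": config.fatol,
                "maxiter": config.max_iter,
            },
        )
        local_optima.append(
            {"start": tuple(theta0), "x": res.x.tolist(), "r": float(res.fun),
             "converged": bool(res.success)}
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= _INFEASIBLE_PENALTY:
        raise FittingError("optimizer failed to reach a feasible point")
    if config.polish:
        res = optimize.minimize(
            fun, best.x, method="Nelder-Mead", bounds=bounds,
            options={"xatol": config.xatol * 1e-2, "fatol": config.fatol * 1e-2,
                     "maxiter": config.max_iter},
        )
        if res.fun <= best.fun:
            best = res

    delta, p, sf_u, t_h = best.x
    sf_v = solve_sf_v(preset.sf_t, p, sf_u)
    params = KineticParameters.with_shared_doubling_time(
        delta=delta, p=p, sf_u=sf_u, sf_v=sf_v, t_h=t_h, doubling_time=t_growth
    )
    model = _aligned_model_values(params, course, volumes, config.convention)
    measured = volumes.normalized()
    mean_err, sd_err = percent_error_stats(model[1:] / model[0], measured[1:])
    n_converged = sum(o["converged"] for o in local_optima)
    return FitResult(
        delta=float(delta),
        p=float(p),
        sf_u=float(sf_u),
        sf_v=float(sf_v),
        t_h=float(t_h),
        doubling_time=t_growth,
        preset=preset,
        r=float(best.fun),
        percent_error_mean=mean_err,
        percent_error_sd=sd_err,
        n_obs=len(volumes),
        diagnostics={
            "n_starts": len(starts),
            "n_converged": n_converged,
            "local_optima": local_optima,
            "seed": config.seed,
            "convention": config.convention,
            "objective": "rms" if config.rms_objective else "root-mean-absolute",
        },
    )


def doubling_time_comparison(
    course: TreatmentCourse,
    volumes: VolumeSeries,
    preset: HistologyPreset,
    config: FitConfig | None = None,
) -> dict[str, float]:
    """Optimized residue R for each growth-time candidate.

    Refits the free parameters three times with T_u = T_v = T_a set to the
    preset's potential doubling time, cell division time and volume doubling
    time in turn; a well-specified growth time yields the smallest residue.
    """
    return {
        key: fit_parameters(
            course, volumes, preset, config=config, doubling_time=t
        ).r
        for key, t in preset.doubling_times.items()
    }


#: documented scan ranges for each scannable parameter
SCAN_RANGES: dict[str, tuple[float, float]] = {
    "p": (1e-3, 1.0),
    "delta": (0.001, 0.2),
    "sf_u": (0.001, 1.0),
    "sf_v": (0.001, 1.0),
}


def stability_scan(
    parameter: str,
    grid: Sequence[float],
    fitted: FitResult,
    course: TreatmentCourse,
    volumes: VolumeSeries,
) -> list[tuple[float, float]]:
    """One-dimensional slice of R through the fitted point.

    The named parameter sweeps the grid while every other parameter stays at
    its fitted value.  This is a pure slice: scanning ``p`` or ``sf_u`` does
    NOT re-tie ``sf_v`` through the mixing relation, so the slice isolates
    one coordinate exactly as in a stability plot.  A sharp, unique minimum
    at the fitted value indicates the parameter is well determined by the
    series.
    """
    if parameter not in SCAN_RANGES:
        raise ValueError(
            f"unknown scan parameter {parameter!r}; choose from {sorted(SCAN_RANGES)}"
        )
    lo, hi = SCAN_RANGES[parameter]
    base = {
        "delta": fitted.delta,
        "p": fitted.p,
        "sf_u": fitted.sf_u,
        "sf_v": fitted.sf_v,
        "t_h": fitted.t_h,
    }
    out: list[tuple[float, float]] = []
    for value in grid:
        if not (lo <= value <= hi):
            raise ValueError(
                f"scan value {value!r} outside documented range [{lo}, {hi}] "
                f"for {parameter}"
            )
        trial = dict(base)
        trial[parameter] = float(value)
        params = KineticParameters.with_shared_doubling_time(
            doubling_time=fitted.doubling_time, **trial
        )
        out.append((float(value), objective_R(params, course, volumes)))
    return out


def write_fit_report(
    result: FitResult,
    course: TreatmentCourse,
    volumes: VolumeSeries,
    json_path: str | Path,
    trajectory_path: str | Path | None = None,
) -> None:
    """Write the fit as JSON and, optionally, the aligned trajectory as CSV."""
    import json

    Path(json_path).write_text(
        json.dumps(
            {**result.to_dict(), "diagnostics": {
                k: v for k, v in result.diagnostics.items() if k != "local_optima"
            }},
            indent=1,
        )
    )
    if trajectory_path is not None:
        model = _aligned_model_values(
            result.params, course, volumes, result.diagnostics.get("convention", "ode")
        )
        measured = volumes.normalized()
        modelled = model / model[0]
        pd.DataFrame(
            {
                "date": [d.isoformat() for d in volumes.dates],
                "measured_norm": measured,
                "modelled_norm": modelled,
                "abs_diff": np.abs(measured - modelled),
            }
        ).to_csv(trajectory_path, index=False)
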