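"""Cell-count growth assay: exponential fits, SF2 and division time.

A clonogenic-style verification experiment: parallel cultures are seeded
with the same number of cells, one arm receives a single 2 Gy fraction after
plating, and both are counted on several later days.  Each arm is fitted
with ``N(t) = N0 * exp(k t)``; the surviving fraction after 2 Gy (SF2) is
the ratio of the extrapolated day-0 counts, and the division time is
``ln 2 / k`` of the unirradiated arm.  Extrapolating back to day 0 removes
the confound of post-irradiation repopulation, which otherwise drives the
raw irradiated/control count ratio steadily downward over time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "CellCountSeries",
    "GrowthFit",
    "count_ratios",
    "fit_exponential",
    "surviving_fraction",
    "division_time",
    "read_assay_csv",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class CellCountSeries:
    """Mean cell counts (millions) by day for one experimental arm.

    ``seed_count`` is the number of cells plated at day 0 (millions), kept
    separate from the counted days because its inclusion in the fit is a
    modelling choice.  Replicate-level input should be averaged per day
    before construction.
    """

    days: tuple[float, ...]
    counts: tuple[float, ...]
    irradiated: bool
    seed_count: float | None = None

    def __post_init__(self) -> None:
        if len(self.days) != len(self.counts):
            raise ValueError("days and counts must have equal length")
        if len(self.days) < 2:
            raise ValueError("need at least two count days")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(c <= 0 for c in self.counts):
            raise ValueError("counts must be positive")
        if self.seed_count is not None and self.seed_count <= 0:
            raise ValueError("seed_count must be positive")

    def points(self, include_seed: bool) -> tuple[np.ndarray, np.ndarray]:
        days = list(self.days)
        counts = list(self.counts)
        if include_seed and self.seed_count is not None:
            days = [0.0] + days
            counts = [self.seed_count] + counts
        return np.asarray(days, dtype=float), np.asarray(counts, dtype=float)


@dataclass(frozen=True)
class GrowthFit:
    """Exponential growth fit ``N(t) = N0 * exp(k t)``."""

    n0: float
    k: float
    #: residual 2-norm of the fit on the count scale
    goodness: float

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.n0 * np.exp(self.k * np.asarray(t, dtype=float))


def count_ratios(
    irradiated: CellCountSeries,
    control: CellCountSeries,
    ndigits: int | None = 2,
) -> list[tuple[float, float]]:
    """Irradiated/control count ratio on every day present in both arms.

    Rounding (default 2 decimals) matches the usual reporting convention;
    pass ``ndigits=None`` for raw ratios.
    """
    ctrl = dict(zip(control.days, control.counts))
    shared = [(d, n2) for d, n2 in zip(irradiated.days, irradiated.counts) if d in ctrl]
    if not shared:
        raise ValueError("the two series share no count days")
    out = []
    for day, n2 in shared:
        ratio = n2 / ctrl[day]
        out.append((day, round(ratio, ndigits) if ndigits is not None else ratio))
    return out


def fit_exponential(
    series: CellCountSeries,
    include_seed: bool = True,
    objective: str = "log",
) -> GrowthFit:
    """Least-squares fit of ``N0 * exp(k t)`` to the counts.

    ``objective="log"`` (default) regresses ``log N`` on ``t``, giving every
    count day equal relative weight — the convention that reproduces the
    day-0 extrapolation behaviour of growth-assay practice.
    ``objective="counts"`` runs nonlinear least squares on the count scale
    instead, which lets the late, large counts dominate.  With
    ``include_seed`` the plated day-0 count joins the data.  Both fits
    coincide exactly when the data lie on a single exponential.
    Deterministic given the inputs.
    """
    days, counts = series.points(include_seed)
    slope, intercept = np.polyfit(days, np.log(counts), 1)
    if objective == "log":
        n0, k = math.exp(intercept), slope
    elif objective == "counts":
        try:
            with warnings.catch_warnings():
                # exact-exponential data makes the covariance singular; we
                # only use the point estimate
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    lambda t, n0, k: n0 * np.exp(k * t),
                    days, counts, p0=(math.exp(intercept), slope), maxfev=10_000,
                )
        except RuntimeError as err:  # pragma: no cover - defensive
            raise RuntimeError(
                f"exponential fit did not converge ({err}); the log-linear "
                f"estimate was N0={math.exp(intercept):.4g}, k={slope:.4g}"
            ) from err
        n0, k = popt
    else:
        raise ValueError(f"unknown objective {objective!r}; use 'log' or 'counts'")
    resid = counts - n0 * np.exp(k * days)
    return GrowthFit(n0=float(n0), k=float(k), goodness=float(np.linalg.norm(resid)))


def surviving_fraction(irr_fit: GrowthFit, ctrl_fit: GrowthFit) -> float:
    """SF2: ratio of the extrapolated day-0 counts, irradiated over control."""
    if ctrl_fit.n0 <= 0:
        raise ValueError("control day-0 count must be positive")
    return irr_fit.n0 / ctrl_fit.n0


def division_time(k: float) -> tuple[float, float]:
    """Cell division time from a growth rate: ``ln2/k`` as (days, hours)."""
    if k <= 0:
        raise ValueError(f"growth rate must be positive, got {k!r}")
    days = LN2 / k
    return days, days * 24.0


def read_assay_csv(
    path: str | Path, seed_millions: float | None = None
) -> tuple[CellCountSeries, CellCountSeries]:
    """Read an assay table ``day,count_millions,irradiated`` -> (control, irradiated).

    Replicate rows (same day and arm) are averaged before the series are
    built.  ``seed_millions`` attaches the plated day-0 count to both arms.
    """
    frame = pd.read_csv(path)
    missing = {"day", "count_millions", "irradiated"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    series = []
    for flag in (0, 1):
        sub = (
            frame[frame["irradiated"] == flag]
            .groupby("day", sort=True)["count_millions"]
            .mean()
        )
        if sub.empty:
            raise ValueError(f"{path}: no rows with irradiated={flag}")
        series.append(
            CellCountSeries(
                days=tuple(float(d) for d in sub.index),
                counts=tuple(float(c) for c in sub.values),
                irradiated=bool(flag),
                seed_count=seed_millions,
            )
        )
    return series[0], series[1]
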