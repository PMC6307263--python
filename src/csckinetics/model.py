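"""Model/Results interface tying the calendar, kinetics and fitting together.

``TumorRegressionModel`` binds a treatment course, its measured volume
series and a histology preset; ``fit()`` runs the constrained least-squares
estimation and returns a ``TumorRegressionResults`` carrying the estimates,
the objective value, per-day error statistics and diagnostics, with
``summary()``, ``predict()``, stability scans and plotting attached.

Example
-------
>>> from csckinetics import TumorRegressionModel, datasets, synthetic
>>> course, series, truth = synthetic.patient_like_suite(seed=1)["S1"]
>>> model = TumorRegressionModel(course, series, datasets.SQUAMOUS)
>>> res = model.fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import fitting
from .fitting import FitConfig, FitResult, HistologyPreset, VolumeSeries
from .params import KineticParameters
from .schedule import TreatmentCourse, read_course, simulate_course

__all__ = ["TumorRegressionModel", "TumorRegressionResults"]


class TumorRegressionModel:
    """Three-compartment tumor-regression model bound to one patient's data.

    Parameters
    ----------
    course : TreatmentCourse
        Daily treatment calendar spanning first to last fraction.
    volumes : VolumeSeries, optional
        Measured volumes; when omitted they are taken from the course's
        imaging days.
    preset : HistologyPreset
        Histology constants (SF_T and the doubling-time candidates).
    convention : str
        Step-coefficient convention, ``"ode"`` (default) or ``"printed"``.
    """

    def __init__(
        self,
        course: TreatmentCourse,
        volumes: VolumeSeries | None = None,
        preset: HistologyPreset | None = None,
        convention: str = "ode",
    ) -> None:
        if preset is None:
            raise ValueError("a histology preset is required")
        self.course = course
        self.volumes = volumes if volumes is not None else VolumeSeries.from_course(course)
        self.preset = preset
        self.convention = convention

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, preset: HistologyPreset, **kwargs
    ) -> "TumorRegressionModel":
        """Build from a ``date,fraction,volume_cm3`` frame (the file dialect)."""
        from .schedule import _course_from_records

        course = _course_from_records(frame.to_dict("records"))
        return cls(course, preset=preset, **kwargs)

    @classmethod
    def from_csv(
        cls, path: str | Path, preset: HistologyPreset, **kwargs
    ) -> "TumorRegressionModel":
        return cls(read_course(path), preset=preset, **kwargs)

    def simulate(self, params: KineticParameters) -> np.ndarray:
        """Normalized model trajectory ``G_i/G_0`` over the whole course."""
        return simulate_course(params, self.course, convention=self.convention)

    def objective(self, params: KineticParameters) -> float:
        """The objective R at a given parameter point."""
        return fitting.objective_R(
            params, self.course, self.volumes, convention=self.convention
        )

    def fit(self, config: FitConfig | None = None, **kwargs) -> "TumorRegressionResults":
        """Estimate (delta, p, SF_u, T_h); keyword arguments update FitConfig."""
        if config is None:
            config = FitConfig(convention=self.convention, **kwargs)
        result = fitting.fit_parameters(self.course, self.volumes, self.preset, config)
        return TumorRegressionResults(self, result)


class TumorRegressionResults:
    """Fit results wrapper with prediction, scanning and reporting."""

    def __init__(self, model: TumorRegressionModel, fit_result: FitResult) -> None:
        self.model = model
        self.fit_result = fit_result

    # -- estimates ---------------------------------------------------------

    @property
    def params(self) -> pd.Series:
        """Estimates as a named series (delta, p, sf_u, sf_v, t_h)."""
        f = self.fit_result
        return pd.Series(
            {"delta": f.delta, "p": f.p, "sf_u": f.sf_u, "sf_v": f.sf_v, "t_h": f.t_h}
        )

    @property
    def kinetic_params(self) -> KineticParameters:
        return self.fit_result.params

    @property
    def objective_r(self) -> float:
        return self.fit_result.r

    # -- predictions -------------------------------------------------------

    def predict(self) -> pd.DataFrame:
        """Measured vs modelled normalized volumes on the imaging days."""
        f = self.fit_result
        model_values = fitting._aligned_model_values(
            f.params, self.model.course, self.model.volumes, self.model.convention
        )
        modelled = model_values / model_values[0]
        measured = self.model.volumes.normalized()
        return pd.DataFrame(
            {
                "date": [d.isoformat() for d in self.model.volumes.dates],
                "measured_norm": measured,
                "modelled_norm": modelled,
                "abs_diff": np.abs(measured - modelled),
            }
        )

    def trajectory(self) -> pd.DataFrame:
        """Daily modelled burden over the full calendar (all days)."""
        values = self.model.simulate(self.fit_result.params)
        return pd.DataFrame(
            {
                "date": [d.isoformat() for d in self.model.course.dates],
                "fraction": [int(f) for f in self.model.course.treated_flags],
                "modelled_norm": values,
            }
        )

    # -- stability ---------------------------------------------------------

    def stability_scan(
        self, parameter: str, grid: Sequence[float]
    ) -> list[tuple[float, float]]:
        """Slice of R along one parameter, others held at the estimates."""
        return fitting.stability_scan(
            parameter, grid, self.fit_result, self.model.course, self.model.volumes
        )

    def compare_doubling_times(self, config: FitConfig | None = None) -> dict[str, float]:
        """Optimized R with T_pot, T_div and T_vol as the growth time."""
        return fitting.doubling_time_comparison(
            self.model.course, self.model.volumes, self.model.preset, config
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit report."""
        f = self.fit_result
        d = f.diagnostics
        lines = [
            "        Tumor Regression Kinetic Model Fit",
            "=" * 56,
            f"Histology preset:      {f.preset.name} (SF_T = {f.preset.sf_t})",
            f"Doubling time T_u=T_v=T_a: {f.doubling_time:.3g} d",
            f"Observations:          {f.n_obs} imaging days",
            f"Objective:             {d.get('objective', 'root-mean-absolute')}",
            f"Starts (converged):    {d.get('n_starts', '?')} ({d.get('n_converged', '?')})",
            "-" * 56,
            f"{'parameter':<28}{'estimate':>12}",
            f"{'delta (CSC self-renewal)':<28}{f.delta:>12.4f}",
            f"{'p (CSC proportion)':<28}{f.p:>12.4f}",
            f"{'SF_u (CSC survival/2 Gy)':<28}{f.sf_u:>12.4f}",
            f"{'SF_v (TC survival/2 Gy)':<28}{f.sf_v:>12.4f}",
            f"{'T_h (clearance, days)':<28}{f.t_h:>12.4f}",
            "-" * 56,
            f"Objective R:           {f.r:.4f}",
            f"Fit error:             {f.percent_error_mean:.2f} ± "
            f"{f.percent_error_sd:.2f} %  (per-day, mean ± SD)",
            "=" * 56,
        ]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return self.fit_result.to_dict()

    def plot_fit(self, ax=None):
        """Plot measured vs modelled normalized volumes (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        traj = self.trajectory()
        pred = self.predict()
        days = [dt.date.fromisoformat(d) for d in traj["date"]]
        ax.plot(days, traj["modelled_norm"], label="model", lw=1.5)
        mdays = [dt.date.fromisoformat(d) for d in pred["date"]]
        ax.plot(mdays, pred["measured_norm"], "o", ms=3, label="measured")
        ax.set_xlabel("date")
        ax.set_ylabel("relative tumor volume")
        ax.legend()
        return ax
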