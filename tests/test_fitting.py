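"""Objective R, parameter estimation, scans and error statistics."""

import datetime as dt

import numpy as np
import pytest

from csckinetics import datasets
from csckinetics.fitting import (
    FitConfig,
    FittingError,
    VolumeSeries,
    fit_parameters,
    objective_R,
    percent_error_stats,
    stability_scan,
)
from csckinetics.params import KineticParameters, solve_sf_v
from csckinetics.schedule import simulate_course, standard_course
from csckinetics.synthetic import SyntheticSpec, generate_volumes

MONDAY = dt.date(2017, 1, 2)


class TestObjectiveR:
    def test_zero_when_model_equals_measurement(self, noiseless_synth, squamous_truth):
        course, series = noiseless_synth
        assert objective_R(squamous_truth, course, series) < 1e-6

    def test_single_deviation_square_root(self, squamous_truth):
        # one post-baseline measurement off by 0.04 in normalized volume:
        # R = sqrt(0.04) = 0.2
        course = standard_course(MONDAY, 2)
        traj = simulate_course(squamous_truth, course)
        volumes = VolumeSeries(
            dates=tuple(course.dates),
            volumes=np.array([100.0, 100.0 * (traj[1] + 0.04)]),
        )
        assert objective_R(squamous_truth, course, volumes) == pytest.approx(0.2)

    def test_invariant_to_volume_rescaling(self, squamous_truth):
        spec = SyntheticSpec(
            truth=squamous_truth, preset=datasets.SQUAMOUS, noise_sd=0.05, seed=2
        )
        course, series = generate_volumes(spec)
        scaled = VolumeSeries(dates=series.dates, volumes=series.volumes * 3.21)
        assert objective_R(squamous_truth, course, scaled) == pytest.approx(
            objective_R(squamous_truth, course, series), rel=1e-9
        )

    def test_date_outside_course_rejected(self, squamous_truth):
        course = standard_course(MONDAY, 5)
        volumes = VolumeSeries(
            dates=(MONDAY, MONDAY + dt.timedelta(days=365)),
            volumes=np.array([100.0, 90.0]),
        )
        with pytest.raises(ValueError):
            objective_R(squamous_truth, course, volumes)

    def test_rms_variant_differs_and_is_smaller_for_small_deviations(
        self, squamous_truth
    ):
        course = standard_course(MONDAY, 2)
        traj = simulate_course(squamous_truth, course)
        volumes = VolumeSeries(
            dates=tuple(course.dates),
            volumes=np.array([100.0, 100.0 * (traj[1] + 0.04)]),
        )
        rms = objective_R(squamous_truth, course, volumes, rms=True)
        assert rms == pytest.approx(0.04)


class TestPercentErrorStats:
    def test_identical_series_zero(self):
        mean, sd = percent_error_stats([1.0, 0.9, 0.8], [1.0, 0.9, 0.8])
        assert mean == 0.0 and sd == 0.0

    def test_two_day_mean_and_sample_sd(self):
        mean, sd = percent_error_stats([0.90, 0.80], [0.92, 0.84])
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(np.std([2.0, 4.0], ddof=1))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            percent_error_stats([1.0], [1.0, 2.0])


class TestFitParameters:
    def test_noiseless_recovery(self, noiseless_synth, quick_fit_config):
        course, series = noiseless_synth
        fit = fit_parameters(course, series, datasets.SQUAMOUS, quick_fit_config)
        assert abs(fit.delta - 0.03) <= 0.005
        assert abs(fit.p - 0.25) <= 0.02
        assert abs(fit.sf_u - 0.98) <= 0.005
        assert abs(fit.t_h - 1.0) <= 0.3
        assert fit.r < 1e-4
        assert fit.percent_error_mean < 0.1

    def test_sf_v_tied_through_mixing_relation(self, noiseless_synth,
                                               quick_fit_config):
        course, series = noiseless_synth
        fit = fit_parameters(course, series, datasets.SQUAMOUS, quick_fit_config)
        implied = solve_sf_v(datasets.SQUAMOUS.sf_t, fit.p, fit.sf_u)
        assert abs(fit.sf_v - implied) < 1e-9

    def test_optimum_beats_random_feasible_points(self, noiseless_synth,
                                                  quick_fit_config):
        course, series = noiseless_synth
        fit = fit_parameters(course, series, datasets.SQUAMOUS, quick_fit_config)
        rng = np.random.default_rng(11)
        tried = 0
        while tried < 200:
            delta = rng.uniform(0.001, 0.2)
            p = rng.uniform(0.001, 0.99)
            sf_u = rng.uniform(0.5, 1.0)
            t_h = rng.uniform(0.1, 20)
            try:
                sf_v = solve_sf_v(datasets.SQUAMOUS.sf_t, p, sf_u)
            except ValueError:
                continue
            tried += 1
            params = KineticParameters.with_shared_doubling_time(
                delta=delta, p=p, sf_u=sf_u, sf_v=sf_v, t_h=t_h,
                doubling_time=datasets.SQUAMOUS.t_pot,
            )
            assert objective_R(params, course, series) >= fit.r - 1e-12

    def test_too_few_measurements_rejected(self, squamous_truth):
        course = standard_course(MONDAY, 3)
        traj = simulate_course(squamous_truth, course)
        volumes = VolumeSeries(
            dates=tuple(course.dates), volumes=100.0 * traj
        )
        with pytest.raises(ValueError):
            fit_parameters(course, volumes, datasets.SQUAMOUS)

    def test_infeasible_preset_raises(self, noiseless_synth):
        course, series = noiseless_synth
        # SF_T so low that no grid start yields SF_v in (0, 1]
        bad = datasets.HistologyPreset(
            name="impossible", sf_t=0.02, t_pot=6.2, t_div=2.5, t_vol=115.2
        )
        config = FitConfig(start_grid={
            "delta": (0.05,), "p": (0.9,), "sf_u": (0.99,), "t_h": (1.0,),
        })
        with pytest.raises(FittingError):
            fit_parameters(course, series, bad, config)


@pytest.fixture(scope="module")
def fitted(noiseless_synth, quick_fit_config):
    course, series = noiseless_synth
    fit = fit_parameters(course, series, datasets.SQUAMOUS, quick_fit_config)
    return course, series, fit


class TestStabilityScan:
    def test_scan_contains_fit_objective_at_optimum(self, fitted):
        course, series, fit = fitted
        pairs = stability_scan("p", [fit.p], fit, course, series)
        assert pairs[0][1] == pytest.approx(fit.r, abs=1e-9)

    def test_unique_minimum_at_generating_p(self, fitted):
        course, series, fit = fitted
        grid = np.linspace(0.001, 1.0, 81)
        pairs = stability_scan("p", grid, fit, course, series)
        values = np.array([r for _, r in pairs])
        argmin = int(np.argmin(values))
        assert grid[argmin] == pytest.approx(0.25, abs=0.02)
        # single local minimum on the grid: R decreases to it, then increases
        assert np.all(np.diff(values[: argmin + 1]) <= 1e-12)
        assert np.all(np.diff(values[argmin:]) >= -1e-12)

    def test_objective_sensitive_to_self_renewal_rate(self, fitted):
        # R climbs steeply and monotonically as delta leaves the optimum,
        # even though delta's documented range is only a fifth of p's: the
        # self-renewal probability is a well-identified, sensitive parameter
        course, series, fit = fitted
        grid = np.linspace(fit.delta, 0.2, 20)
        values = np.array(
            [r for _, r in stability_scan("delta", grid, fit, course, series)]
        )
        assert np.all(np.diff(values) > 0)
        assert values[-1] > 50 * max(fit.r, 1e-3)

    def test_unknown_parameter_and_out_of_range_grid_rejected(self, fitted):
        course, series, fit = fitted
        with pytest.raises(ValueError):
            stability_scan("t_u", [6.2], fit, course, series)
        with pytest.raises(ValueError):
            stability_scan("delta", [0.5], fit, course, series)


class TestRealisticResidues:
    def test_noisy_fit_residues_in_reported_range(self, squamous_truth,
                                                  quick_fit_config):
        # with contouring-level (3%) noise the optimized residues should land
        # in the same order of magnitude as reported patient fits (0.027-0.082)
        spec = SyntheticSpec(
            truth=squamous_truth, preset=datasets.SQUAMOUS,
            noise_sd=0.03, seed=5,
        )
        course, series = generate_volumes(spec)
        fit = fit_parameters(course, series, datasets.SQUAMOUS, quick_fit_config)
        assert 0.005 < fit.r < 0.3
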