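import datetime as dt

import pytest

from csckinetics import (
    FitConfig,
    KineticParameters,
    SyntheticSpec,
    generate_volumes,
    solve_sf_v,
    standard_course,
)
from csckinetics import datasets

MONDAY = dt.date(2017, 1, 2)


@pytest.fixture(scope="session")
def reference_table():
    return datasets.reference_fits()


@pytest.fixture(scope="session")
def course33():
    """Uninterrupted 33-fraction weekday course starting on a Monday."""
    return standard_course(MONDAY, 33)


def params_for_patient(patient: str) -> KineticParameters:
    """Published estimates as an exactly feasible parameter set."""
    row = datasets.reference_fits().loc[patient]
    preset = datasets.PRESETS[row["histology"]]
    return KineticParameters.with_shared_doubling_time(
        delta=row["delta"],
        p=row["p"],
        sf_u=row["sf_u"],
        sf_v=solve_sf_v(preset.sf_t, row["p"], row["sf_u"]),
        t_h=row["t_h"],
        doubling_time=preset.t_pot,
    )


@pytest.fixture(scope="session")
def s1_params():
    return params_for_patient("S1")


@pytest.fixture(scope="session")
def squamous_truth():
    """A mid-range squamous ground truth used across recovery tests."""
    return KineticParameters.with_shared_doubling_time(
        delta=0.03,
        p=0.25,
        sf_u=0.98,
        sf_v=solve_sf_v(0.90, 0.25, 0.98),
        t_h=1.0,
        doubling_time=datasets.SQUAMOUS.t_pot,
    )


@pytest.fixture(scope="session")
def noiseless_synth(squamous_truth):
    """(course, volumes) generated without noise from the squamous truth."""
    spec = SyntheticSpec(
        truth=squamous_truth, preset=datasets.SQUAMOUS, noise_sd=0.0, seed=7
    )
    return generate_volumes(spec)


@pytest.fixture(scope="session")
def quick_fit_config():
    """Reduced multi-start grid for unit tests where speed matters."""
    return FitConfig(
        start_grid={
            "delta": (0.02, 0.1),
            "p": (0.1, 0.4),
            "sf_u": (0.95, 0.99),
            "t_h": (0.7, 3.0),
        }
    )
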