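"""Packaged reference constants: histology presets, published per-patient
fits, and the NCI-H2170 cell-count assay table.

The five-patient table collects the fitted radiobiological parameters
reported for a published stage-III NSCLC cohort (two adenocarcinoma, three
squamous); it serves as ground truth for the synthetic-data generator and
for internal-consistency checks, not as an optimization target — the
underlying CBCT volume series were never deposited.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .assay import CellCountSeries
from .fitting import HistologyPreset

__all__ = [
    "SQUAMOUS",
    "ADENOCARCINOMA",
    "PRESETS",
    "OVERALL_T_VOL_DAYS",
    "reference_fits",
    "nci_h2170_assay",
]

#: squamous cell carcinoma: SF_T per 2 Gy, potential doubling time,
#: in-vitro division time (60 h), clinical volume doubling time — days
SQUAMOUS = HistologyPreset(
    name="squamous", sf_t=0.90, t_pot=6.2, t_div=2.5, t_vol=115.2
)

#: adenocarcinoma (A549-type): division time 22 h -> 0.92 d
ADENOCARCINOMA = HistologyPreset(
    name="adenocarcinoma", sf_t=0.62, t_pot=7.1, t_div=0.92, t_vol=221.6
)

PRESETS: dict[str, HistologyPreset] = {
    "squamous": SQUAMOUS,
    "adenocarcinoma": ADENOCARCINOMA,
}

#: cohort-average clinical volume doubling time (237 patients), metadata only
OVERALL_T_VOL_DAYS = 166.3

#: per-patient fitted parameters (delta, p, SF_u, SF_v, T_h, residue R) and
#: baseline gross tumor volume, by patient label
_REFERENCE_ROWS = [
    # patient, histology, gtv_cm3, delta, p, sf_u, sf_v, t_h, r
    ("A1", "adenocarcinoma", 162.5, 0.018, 0.416, 0.950, 0.385, 1.5, 0.035),
    ("A2", "adenocarcinoma", 177.1, 0.162, 0.400, 0.942, 0.406, 8.1, 0.027),
    ("S1", "squamous", 115.9, 0.024, 0.242, 0.980, 0.874, 1.1, 0.041),
    ("S2", "squamous", 77.6, 0.048, 0.235, 0.978, 0.876, 0.5, 0.067),
    ("S3", "squamous", 91.8, 0.037, 0.211, 0.986, 0.877, 0.5, 0.082),
]


def reference_fits() -> pd.DataFrame:
    """Published per-patient parameter estimates, indexed by patient label."""
    frame = pd.DataFrame(
        _REFERENCE_ROWS,
        columns=["patient", "histology", "gtv_cm3", "delta", "p", "sf_u",
                 "sf_v", "t_h", "r"],
    )
    return frame.set_index("patient")


def nci_h2170_assay() -> tuple[CellCountSeries, CellCountSeries]:
    """The packaged squamous-cell-line count table: (control, irradiated).

    Mean counts (millions, 3 samples per day) for unirradiated cultures and
    cultures given a single 2 Gy fraction after plating; both seeded with
    1.6 million cells on day 0.
    """
    with resources.files("csckinetics.data").joinpath(
        "nci_h2170_counts.csv"
    ).open() as handle:
        frame = pd.read_csv(handle)
    series = []
    for irradiated in (False, True):
        sub = frame[frame["irradiated"] == int(irradiated)]
        series.append(
            CellCountSeries(
                days=tuple(sub["day"]),
                counts=tuple(sub["count_millions"]),
                irradiated=irradiated,
                seed_count=1.6,
            )
        )
    return series[0], series[1]
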