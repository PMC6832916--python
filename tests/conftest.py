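import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lans_ecg.grid import build_grid
from lans_ecg.simulate import SimConfig, plant_source, simulate_square

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: Coarse-stage squares of the front-torso case study (3x3 alternating layout).
COARSE_SQUARES = tuple(("front", i) for i in (1, 3, 5, 11, 13, 15, 21, 23, 25))
#: Fine-stage squares: the ROI (front 13) and its eight neighbors.
FINE_SQUARES = tuple(("front", i) for i in (7, 8, 9, 12, 13, 14, 17, 18, 19))
ALL_STUDY_SQUARES = tuple(sorted(set(COARSE_SQUARES) | set(FINE_SQUARES), key=lambda k: k[1]))

#: The printed fine-stage comparison of channel 5 across the nine squares:
#: (square, electrode pair, mean SNR dB, SNR SD, mean QRS mV, QRS SD, CV).
TABLE4 = (
    (7, "8/15", 16.82, 4.75, 0.42, 0.17, 0.400),
    (8, "9/16", 22.64, 3.67, 1.10, 0.53, 0.485),
    (9, "10/17", 23.17, 2.25, 1.05, 0.45, 0.428),
    (12, "20/27", 19.20, 5.28, 0.56, 0.42, 0.745),
    (13, "21/28", 21.66, 3.09, 0.82, 0.38, 0.468),
    (14, "22/29", 21.93, 5.47, 1.08, 0.71, 0.653),
    (17, "26/33", 15.39, 4.11, 0.29, 0.20, 0.706),
    (18, "27/34", 15.91, 3.28, 0.37, 0.16, 0.432),
    (19, "28/35", 13.18, 6.01, 0.27, 0.14, 0.508),
)


def table4_aggregated() -> pd.DataFrame:
    """The printed table as an across-subject aggregated metrics table."""
    return pd.DataFrame(
        [
            {
                "side": "front",
                "square": sq,
                "channel": 5,
                "pair": pair,
                "snr_mean": snr,
                "snr_sd": snr_sd,
                "qrs_mean": qrs,
                "qrs_sd": qrs_sd,
                "cv": cv,
                "n_subjects": 19,
            }
            for sq, pair, snr, snr_sd, qrs, qrs_sd, cv in TABLE4
        ]
    )


@pytest.fixture(scope="session")
def grid():
    return build_grid()


@pytest.fixture(scope="session")
def source(grid):
    """Dipole planted under front square 13, axis along its principal diagonal."""
    return plant_source(grid, "front", 13)


@pytest.fixture(scope="session")
def sim_record(grid, source):
    """One default-noise 60 s record of the planted square, with ground truth."""
    return simulate_square(grid, "front", 13, source, rng=0)


@pytest.fixture(scope="session")
def short_config():
    """A short record configuration for structure-level tests."""
    return SimConfig(duration=10.0)


def match_r_peaks(detected: np.ndarray, truth: np.ndarray, fs: float, tol_s: float = 0.05):
    """(true positives, false negatives, false positives) within a time tolerance."""
    tol = int(round(tol_s * fs))
    tp = sum(1 for t in truth if np.any(np.abs(detected - t) <= tol))
    fp = sum(1 for d in detected if not np.any(np.abs(truth - d) <= tol))
    return tp, len(truth) - tp, fp
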