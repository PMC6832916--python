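"""Lead-quality metrics: SNR, mean QRS amplitude, and its coefficient of variation.

SNR (dB) is ``10 log10(signal power / noise power)``; in practice the powers
are estimated from the preprocessing decomposition of a record into a clean
component and a removed (noise) component.  The CV — standard deviation of
the QRS amplitude divided by its mean — compares leads across subjects
independently of the overall signal strength an individual produces.
Reported CVs are fractions (sample standard deviation, n-1).

The per-subject metrics of a study are collected in a flat table (one row
per subject x square x channel) and aggregated across subjects per lead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import TorsoGrid, pair_label
from .preprocess import CleanRecord, FilterSpec, WaveletSpec, preprocess
from .qrs import BeatSet, DetectorSpec, annotate
from .simulate import ECGRecord

__all__ = [
    "ChannelMetrics",
    "snr_db",
    "estimate_snr",
    "cv",
    "evaluate_record",
    "aggregate",
]

#: Columns identifying one lead in metrics tables.
LEAD_KEY = ["side", "square", "channel"]


@dataclass(frozen=True)
class ChannelMetrics:
    """Summary metrics of one lead at one aggregation level."""

    snr_db: float
    qrs_mean: float
    qrs_sd: float
    cv: float
    n_beats: int
    n_subjects: int = 1


def snr_db(signal_power: float, noise_power: float) -> float:
    """``10 log10(signal power / noise power)``; infinities flag degenerate input."""
    if signal_power < 0 or noise_power < 0:
        raise ValueError("powers must be >= 0")
    if noise_power == 0:
        return math.inf
    if signal_power == 0:
        return -math.inf
    return 10.0 * math.log10(signal_power / noise_power)


def estimate_snr(raw: np.ndarray, clean: np.ndarray) -> float:
    """SNR estimate from a raw trace and its cleaned version.

    Signal power is the mean square of the clean trace, noise power the mean
    square of the removed component ``raw - clean``.
    """
    raw = np.asarray(raw, dtype=float)
    clean = np.asarray(clean, dtype=float)
    if raw.shape != clean.shape:
        raise ValueError("raw and clean traces must have the same shape")
    return snr_db(float(np.mean(clean**2)), float(np.mean((raw - clean) ** 2)))


def cv(amplitudes) -> float:
    """Sample coefficient of variation (SD / mean) of a sequence of amplitudes.

    Returns NaN (undefined) when the mean is not positive.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = float(a.mean())
    if mean <= 0:
        return math.nan
    return float(a.std(ddof=1)) / mean


def evaluate_record(
    record: ECGRecord,
    grid: TorsoGrid,
    filter_spec: FilterSpec = FilterSpec(),
    wavelet_spec: WaveletSpec = WaveletSpec(),
    detector_spec: DetectorSpec = DetectorSpec(),
    clean: CleanRecord | None = None,
) -> pd.DataFrame:
    """Per-channel metrics of one record: preprocess, annotate, measure.

    Returns one row per channel with the subject-level SNR estimate and QRS
    amplitude statistics.  Low-quality channels (too few beats) keep their
    row but are marked, with NaN amplitude statistics.
    """
    if clean is None:
        clean = preprocess(record, filter_spec, wavelet_spec)
    beat_sets = annotate(clean, spec=detector_spec)
    channels = grid.channels_of_square(record.side, record.square)
    rows = []
    for c, (ch, beats) in enumerate(zip(channels, beat_sets)):
        amps = beats.amplitude
        ok = not beats.low_quality
        rows.append(
            {
                "subject": record.subject,
                "side": record.side,
                "square": record.square,
                "channel": ch.channel_index,
                "pair": pair_label(ch.electrode_pair),
                "orientation": ch.orientation,
                "snr_db": estimate_snr(record.data[:, c], clean.clean[:, c]),
                "qrs_mean": float(np.mean(amps)) if ok else math.nan,
                "qrs_sd": float(np.std(amps, ddof=1)) if ok and amps.size > 1 else (0.0 if ok else math.nan),
                "cv": cv(amps) if ok and amps.size > 1 else math.nan,
                "n_beats": beats.n_beats,
                "low_quality": beats.low_quality,
            }
        )
    return pd.DataFrame(rows)


def aggregate(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Across-subject aggregation of a per-subject metrics table.

    Per lead: mean and SD across subjects of the per-subject SNR and of the
    per-subject mean QRS amplitude; CV = across-subject SD / mean of the QRS
    amplitude.  Medians are carried along for robust ranking.  Low-quality
    subject rows are excluded; leads with no valid subject at all are
    dropped.  With a single subject the SD fields (and hence the CV) are 0.
    """
    df = per_subject[~per_subject["low_quality"]]
    if df.empty:
        raise ValueError("no valid (non-low-quality) rows to aggregate")

    def _agg(group: pd.DataFrame) -> pd.Series:
        qrs = group["qrs_mean"].to_numpy()
        snr = group["snr_db"].to_numpy()
        n = len(group)
        qrs_mean = float(qrs.mean())
        qrs_sd = float(qrs.std(ddof=1)) if n > 1 else 0.0
        return pd.Series(
            {
                "pair": group["pair"].iloc[0],
                "orientation": group["orientation"].iloc[0],
                "snr_mean": float(snr.mean()),
                "snr_sd": float(snr.std(ddof=1)) if n > 1 else 0.0,
                "snr_median": float(np.median(snr)),
                "qrs_mean": qrs_mean,
                "qrs_sd": qrs_sd,
                "qrs_median": float(np.median(qrs)),
                "cv": (qrs_sd / qrs_mean) if qrs_mean > 0 else math.nan,
                "n_beats": int(group["n_beats"].sum()),
                "n_subjects": n,
            }
        )

    out = df.groupby(LEAD_KEY, sort=True).apply(_agg, include_groups=False).reset_index()
    return out
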