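"""Record readers/writers, report formatting, and study configuration.

Records travel as plain columnar text: a header line ``time  ch1 .. ch6``
followed by one row per sample (time in seconds, voltages in mV), with a
JSON sidecar (``<record>.meta.json``) carrying side, square, subject, seed
and sampling rate.  Reports round the way result tables are printed: SNR
and amplitudes to 2 decimals, CV to 3 decimals, and CVs are fractions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import GridSpec, pair_label
from .preprocess import FilterSpec, WaveletSpec
from .protocol import LANSResult, SelectionConfig
from .qrs import DetectorSpec
from .simulate import ECGRecord, NoiseModel, SimConfig

__all__ = [
    "RecordFormatError",
    "read_record",
    "write_record",
    "write_report",
    "format_metrics_table",
    "StudyConfig",
]

N_CHANNELS = 6
_TIME_TOL = 1e-6  # tolerated jitter of the time column, seconds


class RecordFormatError(ValueError):
    """Raised when a record file violates the columnar format."""


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_record(record: ECGRecord, path: str | Path) -> Path:
    """Write a record as tab-separated text plus its metadata sidecar."""
    path = Path(path)
    cols = ["time"] + [f"ch{i}" for i in range(1, N_CHANNELS + 1)]
    df = pd.DataFrame(
        np.column_stack([record.time, record.data]), columns=cols
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    meta = {
        "side": record.side,
        "square": record.square,
        "subject": record.subject,
        "fs": record.fs,
        **{k: v for k, v in record.meta.items() if _json_safe(v)},
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_record(path: str | Path) -> ECGRecord:
    """Read a record written by :func:`write_record`, validating the format."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    expected = ["time"] + [f"ch{i}" for i in range(1, N_CHANNELS + 1)]
    if list(df.columns) != expected:
        raise RecordFormatError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    arr = df.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(arr))
    if bad.size:
        raise RecordFormatError(f"{path}: non-finite sample at row {int(bad[0][0]) + 1}")
    t = arr[:, 0]
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 2
        raise RecordFormatError(f"{path}: non-monotone time column at row {row}")
    fs = 1.0 / float(np.median(dt))
    if np.any(np.abs(dt - 1.0 / fs) > _TIME_TOL):
        row = int(np.argmax(np.abs(dt - 1.0 / fs) > _TIME_TOL)) + 2
        raise RecordFormatError(f"{path}: irregular sampling near row {row}")
    meta_file = _meta_path(path)
    if not meta_file.exists():
        raise RecordFormatError(f"{path}: missing metadata sidecar {meta_file.name}")
    meta = json.loads(meta_file.read_text())
    if "fs" in meta and abs(meta["fs"] - fs) > 0.01 * meta["fs"]:
        raise RecordFormatError(
            f"{path}: sampling rate {fs:.3f} Hz from the time column does not "
            f"match the declared {meta['fs']} Hz"
        )
    return ECGRecord(
        data=arr[:, 1:],
        fs=float(meta.get("fs", fs)),
        side=meta["side"],
        square=int(meta["square"]),
        subject=meta.get("subject"),
        meta={k: v for k, v in meta.items() if k not in ("side", "square", "subject", "fs")},
    )


def format_metrics_table(agg: pd.DataFrame) -> str:
    """Render an aggregated metrics table with report rounding.

    Columns mirror the printed result-table layout: location, electrode
    pair, SNR mean +/- SD (2 decimals), QRS amplitude mean +/- SD (2
    decimals), CV as a 3-decimal fraction.
    """
    lines = ["location\tchannel\tpair\tsnr_db\tqrs_mv\tcv"]
    for r in agg.itertuples(index=False):
        lines.append(
            f"{r.side} square {r.square}\t{r.channel}\t{r.pair}\t"
            f"{r.snr_mean:.2f} ± {r.snr_sd:.2f}\t"
            f"{r.qrs_mean:.2f} ± {r.qrs_sd:.2f}\t{r.cv:.3f}"
        )
    return "\n".join(lines)


def write_report(result: LANSResult, path: str | Path) -> Path:
    """Write the human-readable outcome of a search.

    Includes the fine-stage metrics table, the three candidate lists, the
    vote tally, and the winner with the quality thresholds it passed.
    """
    if not result.winners:
        raise ValueError("cannot report an empty result")
    path = Path(path)
    cfg = result.config or SelectionConfig()
    lines: list[str] = []
    if result.roi is not None:
        lines.append(f"ROI: {result.roi[0]} square {result.roi[1]}")
    if result.best_channel is not None:
        lines.append(f"best channel: {result.best_channel}")
    lines.append("")
    if result.fine_agg is not None:
        pool = result.fine_agg
        if result.best_channel is not None and cfg.voting_mode == "per_best_channel":
            pool = pool[pool["channel"] == result.best_channel]
        lines.append(format_metrics_table(pool))
        lines.append("")
    by_lead = {c.lead: c for c in result.candidates}

    def name(lead) -> str:
        return by_lead[lead].pair if lead in by_lead else pair_label(lead[1:])

    lines.append("candidates:")
    lines.append("  top SNR:      " + ", ".join(name(l) for l in result.top_snr))
    lines.append("  top QRS:      " + ", ".join(name(l) for l in result.top_qrs))
    lines.append("  lowest CV:    " + ", ".join(name(l) for l in result.low_cv))
    lines.append("votes:")
    for cand in result.candidates:
        marks = " [good]" if cand.good else ""
        lines.append(
            f"  {cand.pair}: {cand.votes} vote(s), SNR {cand.snr:.2f} dB, "
            f"QRS {cand.qrs:.2f} mV, CV {cand.cv:.3f}{marks}"
        )
    lines.append(
        f"winner: {', '.join(result.winner_pairs)} "
        f"(thresholds: SNR > {cfg.snr_good_db} dB, QRS > {cfg.qrs_good_mv} mV)"
    )
    if result.runner_up is not None:
        lines.append(f"runner-up: {name(result.runner_up)}")
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclasses.dataclass
class StudyConfig:
    """Everything a reproducible end-to-end run needs, loadable from YAML."""

    grid: GridSpec = dataclasses.field(default_factory=GridSpec)
    coarse_squares: tuple[tuple[str, int], ...] = tuple(
        ("front", i) for i in (1, 3, 5, 11, 13, 15, 21, 23, 25)
    )
    n_modules: int = 1
    n_subjects: int = 19
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    noise: NoiseModel = dataclasses.field(default_factory=NoiseModel)
    filter: FilterSpec = dataclasses.field(default_factory=FilterSpec)
    wavelet: WaveletSpec = dataclasses.field(default_factory=WaveletSpec)
    detector: DetectorSpec = dataclasses.field(default_factory=DetectorSpec)
    selection: SelectionConfig = dataclasses.field(default_factory=SelectionConfig)
    planted_square: tuple[str, int] = ("front", 13)
    planted_channel: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        nested = {
            "grid": GridSpec,
            "sim": SimConfig,
            "noise": NoiseModel,
            "filter": FilterSpec,
            "wavelet": WaveletSpec,
            "detector": DetectorSpec,
            "selection": SelectionConfig,
        }
        for key, value in raw.items():
            if key in nested:
                value = {
                    k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
                    if isinstance(v, list)
                    else v
                    for k, v in value.items()
                }
                kwargs[key] = nested[key](**value)
            elif key == "coarse_squares":
                kwargs[key] = tuple((s, int(i)) for s, i in value)
            elif key == "planted_square":
                kwargs[key] = (value[0], int(value[1]))
            else:
                kwargs[key] = value
        return cls(**kwargs)
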