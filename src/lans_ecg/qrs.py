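"""Slope-threshold QRS detection and per-beat amplitude measurement.

The R peak carries the steepest slope in the ECG, so detection works on a
smoothed, rectified derivative: candidate peaks of that feature must exceed
an adaptive threshold (a fraction of the running feature maximum) as well as
a noise floor (a multiple of the global median feature — without the floor a
signal-free channel would satisfy the adaptive threshold everywhere).  Each
accepted candidate is refined to the local maximum of the trace and a
refractory period suppresses double detections.

Q and S are the nearest local minima scanned backwards/forwards from R
within a physiological window; the QRS amplitude is the R value minus the
smaller of the Q and S values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d

from .simulate import ECGRecord
from .preprocess import CleanRecord

__all__ = [
    "DetectorSpec",
    "BeatSet",
    "QSPoints",
    "normalize_polarity",
    "detect_r_peaks",
    "locate_qs",
    "qrs_amplitude",
    "annotate",
]


@dataclass(frozen=True)
class DetectorSpec:
    """Detector tuning.  All windows in seconds unless noted."""

    smooth_window: float = 0.15         # moving average on the rectified slope
    threshold_factor: float = 0.5       # fraction of the running feature max
    running_max_window: float = 2.0     # span of the adaptive maximum
    noise_floor_mult: float = 2.5       # feature must exceed this x its median
    refractory: float = 0.2             # minimum R-R separation
    qs_window: float = 0.1              # Q/S search span each side of R
    normalize_polarity: bool = True

    def __post_init__(self) -> None:
        if self.refractory <= 0 or self.qs_window <= 0 or self.smooth_window <= 0:
            raise ValueError("detector windows must be > 0")
        if not 0 < self.threshold_factor <= 1:
            raise ValueError("threshold_factor must be in (0, 1]")


@dataclass
class QSPoints:
    """Q/S localization for one beat; ``*_clipped`` marks window-edge fallback."""

    q: int
    s: int
    q_clipped: bool = False
    s_clipped: bool = False
    boundary: bool = False


@dataclass
class BeatSet:
    """Per-channel beat annotations (sample indices into the trace)."""

    r: np.ndarray
    q: np.ndarray
    s: np.ndarray
    amplitude: np.ndarray        # mV, per beat
    polarity: int = 1            # +1 upright, -1 the trace was sign-flipped
    low_quality: bool = False

    @property
    def n_beats(self) -> int:
        return int(self.r.size)


def normalize_polarity(trace: np.ndarray) -> tuple[np.ndarray, int]:
    """Flip the trace when its extreme deviation from the median is negative.

    Leads whose orientation opposes the electrical axis show an inverted QRS;
    flipping makes the R peak the maximum so the amplitude definition applies
    uniformly.  Returns ``(possibly flipped trace, polarity sign)``.
    """
    med = np.median(trace)
    if med - trace.min() > trace.max() - med:
        return -trace, -1
    return trace, 1


def _slope_feature(trace: np.ndarray, fs: float, spec: DetectorSpec) -> np.ndarray:
    # 5-point central derivative, rectified, moving-average smoothed
    kernel = np.array([-1.0, 8.0, 0.0, -8.0, 1.0]) / 12.0
    deriv = np.convolve(trace, kernel[::-1], mode="same") * fs
    win = max(1, int(round(spec.smooth_window * fs)))
    return np.convolve(np.abs(deriv), np.ones(win) / win, mode="same")


def detect_r_peaks(
    trace: np.ndarray, fs: float, spec: DetectorSpec = DetectorSpec()
) -> np.ndarray:
    """Detected R-peak sample indices, sorted, refractory enforced."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 10:
        return np.array([], dtype=int)
    if spec.normalize_polarity:
        trace, _ = normalize_polarity(trace)
    feature = _slope_feature(trace, fs, spec)
    run_max = maximum_filter1d(feature, size=max(1, int(round(spec.running_max_window * fs))))
    floor = spec.noise_floor_mult * float(np.median(feature))
    height = np.maximum(spec.threshold_factor * run_max, floor)
    dist = max(1, int(round(spec.refractory * fs)))
    cand, _ = signal.find_peaks(feature, distance=dist)
    cand = cand[feature[cand] >= height[cand]]
    if cand.size == 0:
        return np.array([], dtype=int)
    # refine each candidate to the trace maximum near the slope burst
    half = max(1, int(round(0.075 * fs)))
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(trace.size, c + half + 1)
        refined.append(lo + int(np.argmax(trace[lo:hi])))
    refined = np.unique(refined)
    # refractory: left-to-right scan, keeping the taller peak on conflict
    kept: list[int] = []
    for idx in refined:
        if kept and idx - kept[-1] < dist:
            if trace[idx] > trace[kept[-1]]:
                kept[-1] = int(idx)
        else:
            kept.append(int(idx))
    return np.array(kept, dtype=int)


def locate_qs(
    trace: np.ndarray, r_index: int, fs: float, spec: DetectorSpec = DetectorSpec()
) -> QSPoints:
    """Nearest local minima backwards (Q) and forwards (S) from the R peak."""
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    w = max(1, int(round(spec.qs_window * fs)))
    boundary = r_index - w < 0 or r_index + w >= n

    def scan(direction: int) -> tuple[int, bool]:
        if direction < 0:
            idxs = np.arange(max(1, r_index - w), r_index)
        else:
            idxs = np.arange(r_index + 1, min(n - 1, r_index + w + 1))
        if idxs.size:
            seg = trace[idxs]
            is_min = (seg <= trace[idxs - 1]) & (seg <= trace[idxs + 1])
            cand = idxs[is_min]
            if cand.size:  # nearest interior minimum in scan direction
                return int(cand[-1] if direction < 0 else cand[0]), False
        # no interior minimum: fall back to the window edge
        return int(np.clip(r_index + direction * w, 0, n - 1)), True

    q, q_clip = scan(-1)
    s, s_clip = scan(+1)
    return QSPoints(q=q, s=s, q_clipped=q_clip, s_clipped=s_clip, boundary=boundary)


def qrs_amplitude(trace: np.ndarray, q: int, r: int, s: int) -> float:
    """R value minus the smaller of the Q and S values (mV)."""
    if not q < r < s:
        raise ValueError("expected Q < R < S sample order")
    return float(trace[r] - min(trace[q], trace[s]))


def annotate(
    source: ECGRecord | CleanRecord | np.ndarray,
    fs: float | None = None,
    spec: DetectorSpec = DetectorSpec(),
    min_beats: int = 3,
) -> list[BeatSet]:
    """Detect and measure beats on every channel of a (preprocessed) record.

    Channels with fewer than ``min_beats`` detected beats are flagged
    low-quality.  Beats whose Q/S windows touch the trace boundary are
    dropped from the amplitude arrays.
    """
    if isinstance(source, CleanRecord):
        data, fs = source.clean, source.fs
    elif isinstance(source, ECGRecord):
        data, fs = source.data, source.fs
    else:
        data = np.asarray(source, dtype=float)
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
    out: list[BeatSet] = []
    for c in range(data.shape[1]):
        trace = data[:, c]
        polarity = 1
        if spec.normalize_polarity:
            trace, polarity = normalize_polarity(trace)
        inner = replace(spec, normalize_polarity=False)
        r_idx = detect_r_peaks(trace, fs, inner)
        rs, qs, ss, amps = [], [], [], []
        for r in r_idx:
            pts = locate_qs(trace, int(r), fs, inner)
            if pts.boundary:
                continue
            rs.append(int(r))
            qs.append(pts.q)
            ss.append(pts.s)
            amps.append(qrs_amplitude(trace, pts.q, int(r), pts.s))
        beats = BeatSet(
            r=np.array(rs, dtype=int),
            q=np.array(qs, dtype=int),
            s=np.array(ss, dtype=int),
            amplitude=np.array(amps, dtype=float),
            polarity=polarity,
            low_quality=len(rs) < min_beats,
        )
        out.append(beats)
    return out
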