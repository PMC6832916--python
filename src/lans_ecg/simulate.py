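"""Synthetic six-channel body-surface ECG with analytic ground truth.

The cardiac source is modelled as a single current dipole of fixed position
and orientation inside an infinite homogeneous volume conductor.  The
surface potential at a point ``r`` is

    phi(r, t) = k * m(t) * (axis . (r - origin)) / ||r - origin||^3

where ``m(t)`` is a dimensionless beat waveform (a sum of Gaussians, one per
P/Q/R/S/T component) and ``k`` scales the dipole moment.  Because the dipole
direction is fixed over the cardiac cycle, every bipolar lead sees the same
waveform ``m(t)`` scaled by a time-independent *lead gain*
``g = k * (geom(a) - geom(b))``: the QRS amplitude of a lead depends only on
its geometry — distance from the source and alignment of the electrode pair
with the electrical axis — which is exactly the effect the placement search
has to recover.

Records are contaminated with baseline wander (slow sinusoids), powerline
interference, and white noise, each generated separately so the emitted
trace decomposes exactly into clean signal plus noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np

from .grid import PRINCIPAL_DIAGONAL, TorsoGrid

__all__ = [
    "WaveComponent",
    "DipoleSource",
    "NoiseModel",
    "SimConfig",
    "SubjectVariation",
    "ECGRecord",
    "GroundTruth",
    "StudyResult",
    "beat_waveform",
    "lead_gain",
    "lead_voltage",
    "plant_source",
    "planted_best_lead",
    "square_lead_gains",
    "template_qrs_span",
    "simulate_square",
    "simulate_study",
    "DEFAULT_TEMPLATE",
    "DEFAULT_NOISE",
]


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian component of the beat: label, amplitude factor, center (s), width (s)."""

    label: str
    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"{self.label} wave width must be > 0")


#: Beat template with typical adult morphology at 60-80 bpm: amplitudes are
#: relative to the R wave, centers relative to the R peak.
DEFAULT_TEMPLATE: tuple[WaveComponent, ...] = (
    WaveComponent("P", 0.15, -0.20, 0.025),
    WaveComponent("Q", -0.12, -0.035, 0.010),
    WaveComponent("R", 1.00, 0.000, 0.012),
    WaveComponent("S", -0.20, 0.035, 0.012),
    WaveComponent("T", 0.35, 0.240, 0.045),
)

#: Half-width of the beat support used when rendering (covers P through T).
_BEAT_HALF_SPAN = 0.45
#: Offset of the first R peak from the start of the record.
_FIRST_BEAT_OFFSET = 0.35


@dataclass(frozen=True)
class DipoleSource:
    """Fixed cardiac dipole: origin (cm, behind the front plane), unit axis,
    moment scale (mV cm^2 equivalent), and the beat template."""

    origin: tuple[float, float, float]
    axis: tuple[float, float, float]
    moment_scale: float = 1.0
    beat_template: tuple[WaveComponent, ...] = DEFAULT_TEMPLATE

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float)
        if not math.isclose(float(np.linalg.norm(a)), 1.0, rel_tol=1e-6):
            raise ValueError("axis must have unit norm")
        r = [w for w in self.beat_template if w.label == "R"]
        if not r or r[0].amplitude <= 0:
            raise ValueError("beat template needs an R component with amplitude > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Additive contamination: baseline sinusoids, white noise, powerline tone.

    ``baseline`` entries are (amplitude mV, frequency Hz); baseline
    frequencies must stay below 0.5 Hz (respiratory / movement drift).
    Amplitudes in mV, chosen to emulate the post-hardware-filter regime of a
    wearable chest sensor (lead SNR in the low-20 dB range on a good lead).
    """

    baseline: tuple[tuple[float, float], ...] = ((0.012, 0.25), (0.008, 0.12))
    white_sd: float = 0.008
    powerline_amp: float = 0.006
    powerline_freq: float = 50.0

    def __post_init__(self) -> None:
        for amp, freq in self.baseline:
            if amp < 0:
                raise ValueError("baseline amplitude must be >= 0")
            if not (0 < freq < 0.5):
                raise ValueError("baseline frequencies must lie in (0, 0.5) Hz")
        if self.white_sd < 0 or self.powerline_amp < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @property
    def silent(self) -> bool:
        return (
            self.white_sd == 0
            and self.powerline_amp == 0
            and all(a == 0 for a, _ in self.baseline)
        )


DEFAULT_NOISE = NoiseModel()


@dataclass(frozen=True)
class SimConfig:
    """Acquisition settings: 200 Hz sampling, 1-minute records by default."""

    fs: float = 200.0
    duration: float = 60.0
    heart_rate: float = 75.0
    rr_jitter: float = 0.03  # fractional SD of the beat interval

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0 or self.heart_rate <= 0:
            raise ValueError("fs, duration and heart_rate must be > 0")
        beat = 60.0 / self.heart_rate
        if self.duration < 2 * beat:
            raise ValueError("duration must cover at least two beat intervals")
        if not 0 <= self.rr_jitter < 0.5:
            raise ValueError("rr_jitter must be in [0, 0.5)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass(frozen=True)
class SubjectVariation:
    """Across-subject variability: log-normal dipole strength (sigma of log),
    and uniform positional jitter of at most ``position_jitter`` cm per axis."""

    moment_sigma: float = 0.35
    position_jitter: float = 1.0


@dataclass
class ECGRecord:
    """A six-channel voltage trace (mV) tied to one measurement square."""

    data: np.ndarray  # (n_samples, 6)
    fs: float
    side: str
    square: int
    subject: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class GroundTruth:
    """Simulator-side truth for one record."""

    r_indices: np.ndarray            # true R-peak samples (same on all channels)
    clean: np.ndarray                # (n, 6) noise-free traces
    noise: np.ndarray                # (n, 6); clean + noise == record.data exactly
    lead_gain: np.ndarray            # (6,) signed geometric gains
    qrs_amplitude: np.ndarray        # (6,) true per-channel QRS amplitude, mV


@dataclass
class StudyResult:
    """Everything :func:`simulate_study` produced."""

    records: dict[tuple[int, str, int], ECGRecord]
    truths: dict[tuple[int, str, int], GroundTruth]
    planted_best: tuple[str, int, int]          # (side, square, channel) of the
                                                # largest base-source QRS amplitude
    planted_pair: tuple[int, int]
    subject_scales: np.ndarray
    subject_offsets: np.ndarray


# ---------------------------------------------------------------------------
# waveform and field evaluation


def beat_waveform(t: np.ndarray | float, template: Sequence[WaveComponent] = DEFAULT_TEMPLATE) -> np.ndarray:
    """Dimensionless beat magnitude m(t), t in seconds relative to the R peak."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for w in template:
        out += w.amplitude * np.exp(-((t - w.center) ** 2) / (2.0 * w.width**2))
    return out


def _geom_potential(source: DipoleSource, point: Sequence[float]) -> float:
    """Unit-moment dipole potential factor at a point (time-independent part)."""
    r = np.asarray(point, dtype=float) - np.asarray(source.origin, dtype=float)
    dist = float(np.linalg.norm(r))
    if dist < 1e-9:
        raise ValueError("electrode coincides with the dipole origin")
    return float(np.dot(np.asarray(source.axis, dtype=float), r)) / dist**3


def lead_gain(source: DipoleSource, pos_a: Sequence[float], pos_b: Sequence[float]) -> float:
    """Signed, time-independent gain of the bipolar lead a-b (mV per unit m(t))."""
    return source.moment_scale * (
        _geom_potential(source, pos_a) - _geom_potential(source, pos_b)
    )


def lead_voltage(
    source: DipoleSource,
    pos_a: Sequence[float],
    pos_b: Sequence[float],
    t: np.ndarray | float,
) -> np.ndarray:
    """Clean lead voltage (mV) of a single beat centered at t = 0."""
    return lead_gain(source, pos_a, pos_b) * beat_waveform(t, source.beat_template)


@lru_cache(maxsize=32)
def template_qrs_span(
    template: tuple[WaveComponent, ...] = DEFAULT_TEMPLATE,
    fs: float = 200.0,
    qs_window: float = 0.1,
) -> float:
    """QRS amplitude of the unit template: m at the R peak minus the smaller of
    the Q- and S-side minima within ``qs_window`` seconds of it."""
    t = np.arange(-_BEAT_HALF_SPAN, _BEAT_HALF_SPAN, 1.0 / fs)
    m = beat_waveform(t, template)
    r = int(np.argmax(m))
    w = int(round(qs_window * fs))
    q = m[max(0, r - w) : r].min()
    s = m[r + 1 : r + 1 + w].min()
    return float(m[r] - min(q, s))


# ---------------------------------------------------------------------------
# beat schedule and record synthesis


def _beat_times(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """R-peak times: first at ``_FIRST_BEAT_OFFSET``, last T wave inside the record."""
    interval = 60.0 / config.heart_rate
    times = []
    t = _FIRST_BEAT_OFFSET
    while t + _BEAT_HALF_SPAN <= config.duration:
        times.append(t)
        step = interval
        if config.rr_jitter > 0:
            step *= max(0.5, 1.0 + config.rr_jitter * rng.standard_normal())
        t += step
    return np.asarray(times)


def _render_beats(n: int, fs: float, beat_times: np.ndarray, template: Sequence[WaveComponent]) -> np.ndarray:
    """m(t) over a full record, evaluating each beat only on its support."""
    out = np.zeros(n)
    half = int(round(_BEAT_HALF_SPAN * fs))
    for bt in beat_times:
        c = int(round(bt * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        t = (np.arange(lo, hi) / fs) - bt
        out[lo:hi] += beat_waveform(t, template)
    return out


def square_lead_gains(grid: TorsoGrid, side: str, index: int, source: DipoleSource) -> np.ndarray:
    """Signed lead gains of the six channels of a square, channel order 1..6."""
    gains = []
    for ch in grid.channels_of_square(side, index):
        a = grid.electrode(ch.electrode_pair[0]).position
        b = grid.electrode(ch.electrode_pair[1]).position
        gains.append(lead_gain(source, a, b))
    return np.asarray(gains)


def _generate_noise(
    n: int, fs: float, noise: NoiseModel, rng: np.random.Generator, n_channels: int = 6
) -> np.ndarray:
    t = np.arange(n) / fs
    out = np.zeros((n, n_channels))
    tones = [(a, f) for a, f in noise.baseline if a > 0]
    if noise.powerline_amp > 0:
        tones.append((noise.powerline_amp, noise.powerline_freq))
    for amp, freq in tones:
        # independent random phase per channel; expand via angle addition so
        # only two length-n trig evaluations are needed per tone
        phase = rng.uniform(0, 2 * np.pi, n_channels)
        wt = 2 * np.pi * freq * t
        out += amp * (
            np.sin(wt)[:, None] * np.cos(phase)[None, :]
            + np.cos(wt)[:, None] * np.sin(phase)[None, :]
        )
    if noise.white_sd > 0:
        out += noise.white_sd * rng.standard_normal((n, n_channels))
    return out


def simulate_square(
    grid: TorsoGrid,
    side: str,
    index: int,
    source: DipoleSource,
    noise: NoiseModel = DEFAULT_NOISE,
    config: SimConfig = SimConfig(),
    rng: np.random.Generator | int | None = None,
    subject: int | None = None,
) -> tuple[ECGRecord, GroundTruth]:
    """Simulate one six-channel record for a measurement square."""
    rng = np.random.default_rng(rng)
    n = config.n_samples
    beat_times = _beat_times(config, rng)
    m = _render_beats(n, config.fs, beat_times, source.beat_template)
    # AC-coupled front end: the emitted clean projection is zero-mean, as a
    # real chest sensor cannot pass the DC component of the beat train.
    m = m - m.mean()
    gains = square_lead_gains(grid, side, index, source)
    clean = m[:, None] * gains[None, :]
    noise_arr = _generate_noise(n, config.fs, noise, rng)
    data = clean + noise_arr
    span = template_qrs_span(source.beat_template, config.fs)
    truth = GroundTruth(
        r_indices=np.round(beat_times * config.fs).astype(int),
        clean=clean,
        noise=noise_arr,
        lead_gain=gains,
        qrs_amplitude=np.abs(gains) * span,
    )
    record = ECGRecord(
        data=data,
        fs=config.fs,
        side=side,
        square=index,
        subject=subject,
        meta={"source_origin": tuple(source.origin), "heart_rate": config.heart_rate},
    )
    return record, truth


# ---------------------------------------------------------------------------
# source placement and multi-subject studies


def _square_center(grid: TorsoGrid, side: str, index: int) -> np.ndarray:
    corners = grid.electrodes_of_square(side, index)
    pts = np.array([grid.electrode(e).position for e in corners])
    return pts.mean(axis=0)


def _channel_direction(grid: TorsoGrid, side: str, index: int, channel: int) -> np.ndarray:
    ch = grid.channels_of_square(side, index)[channel - 1]
    a = np.array(grid.electrode(ch.electrode_pair[0]).position)
    b = np.array(grid.electrode(ch.electrode_pair[1]).position)
    d = b - a
    return d / np.linalg.norm(d)


def plant_source(
    grid: TorsoGrid,
    side: str,
    index: int,
    channel: int = 5,
    depth: float = 6.0,
    target_qrs_mv: float = 1.0,
    template: Sequence[WaveComponent] = DEFAULT_TEMPLATE,
) -> DipoleSource:
    """Place a dipole under the center of a square, axis along one of its
    channels, scaled so that channel's true QRS amplitude is ``target_qrs_mv``.

    ``depth`` is measured from the square's electrode plane into the torso.
    The planted channel is then the globally strongest lead, giving the
    recovery tests an unambiguous ground truth.
    """
    center = _square_center(grid, side, index)
    sign = 1.0 if side == "front" else -1.0
    origin = (center[0], center[1], center[2] + sign * depth)
    axis = tuple(_channel_direction(grid, side, index, channel))
    probe = DipoleSource(origin=origin, axis=axis, moment_scale=1.0, beat_template=tuple(template))
    g = square_lead_gains(grid, side, index, probe)[channel - 1]
    span = template_qrs_span(tuple(template))
    if abs(g) * span == 0:
        raise ValueError("degenerate geometry: planted channel has zero gain")
    return replace(probe, moment_scale=target_qrs_mv / (abs(g) * span))


def planted_best_lead(
    grid: TorsoGrid,
    squares: Sequence[tuple[str, int]],
    source: DipoleSource,
) -> tuple[str, int, int]:
    """(side, square, channel) with the largest true QRS amplitude under ``source``."""
    span = template_qrs_span(source.beat_template)
    best, best_amp = None, -np.inf
    for side, index in squares:
        amps = np.abs(square_lead_gains(grid, side, index, source)) * span
        ch = int(np.argmax(amps)) + 1
        if amps[ch - 1] > best_amp:
            best_amp = float(amps[ch - 1])
            best = (side, index, ch)
    assert best is not None
    return best


def _subject_rng(seed: int, subject: int, extra: tuple[int, ...] = ()) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject, *extra)))


def simulate_study(
    grid: TorsoGrid,
    squares: Sequence[tuple[str, int]],
    n_subjects: int,
    source: DipoleSource,
    variation: SubjectVariation = SubjectVariation(),
    noise: NoiseModel = DEFAULT_NOISE,
    config: SimConfig = SimConfig(),
    seed: int = 0,
) -> StudyResult:
    """Simulate a multi-subject study: one record per (subject, square).

    Each subject gets a multiplicative log-normal dipole strength and a small
    positional offset, drawn from per-subject seed streams so results do not
    depend on the order squares or subjects are simulated in.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    squares = list(squares)
    records: dict[tuple[int, str, int], ECGRecord] = {}
    truths: dict[tuple[int, str, int], GroundTruth] = {}
    scales = np.empty(n_subjects)
    offsets = np.empty((n_subjects, 2))
    side_code = {"front": 0, "back": 1}
    for subj in range(n_subjects):
        prng = _subject_rng(seed, subj)
        scales[subj] = math.exp(variation.moment_sigma * prng.standard_normal())
        offsets[subj] = prng.uniform(-variation.position_jitter, variation.position_jitter, 2)
        origin = (
            source.origin[0] + offsets[subj, 0],
            source.origin[1] + offsets[subj, 1],
            source.origin[2],
        )
        subj_source = replace(
            source, origin=origin, moment_scale=source.moment_scale * scales[subj]
        )
        for side, index in squares:
            rng = _subject_rng(seed, subj, (side_code[side], index))
            rec, truth = simulate_square(
                grid, side, index, subj_source, noise, config, rng, subject=subj
            )
            records[(subj, side, index)] = rec
            truths[(subj, side, index)] = truth
    best = planted_best_lead(grid, squares, source)
    pair = grid.channels_of_square(best[0], best[1])[best[2] - 1].electrode_pair
    return StudyResult(
        records=records,
        truths=truths,
        planted_best=best,
        planted_pair=pair,
        subject_scales=scales,
        subject_offsets=offsets,
    )
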