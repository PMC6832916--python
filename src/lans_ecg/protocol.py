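"""The layered (A, N) square-based (LANS) electrode-placement search.

The search runs in two stages.  In the *coarse* stage, A pairwise
non-adjacent squares chosen for the application are measured with N sensor
modules in ceil(A/N) rounds, and the square with the best signal quality —
SNR first, QRS amplitude as the secondary metric — becomes the region of
interest (ROI).  In the *fine* stage the 8 squares surrounding the ROI are
measured in ceil(8/N) further rounds, and the optimal electrode pair is
chosen by voting: the top three leads by SNR, the top three by mean QRS
amplitude, and the three with the lowest CV of QRS amplitude each cast one
vote, and the lead with the most votes wins.

Testing (A + 8) x 6 leads in ceil(A/N) + ceil(8/N) rounds compares with
6 x (number of squares) leads for exhaustively measuring the whole grid
(330 on the default torso grid, versus a worst case of 168 for the layered
search at A = 20).
"""

from __future__ import annotations

import math
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field, replace

import pandas as pd

from .grid import A_MAX, TorsoGrid
from .metrics import LEAD_KEY, aggregate, evaluate_record
from .preprocess import FilterSpec, WaveletSpec
from .qrs import DetectorSpec
from .simulate import ECGRecord

__all__ = [
    "LANSPlan",
    "SelectionConfig",
    "LANSResult",
    "testing_lead_count",
    "direct_lead_count",
    "measurement_rounds",
    "make_plan",
    "select_roi",
    "select_best_channel",
    "select_optimal_pairs",
    "run_lans",
]

#: Lead identity as it appears in votes and candidate lists.
LeadKey = tuple[str, int, int]  # (side, square, channel)

#: Squares evaluated in the fine stage besides the ROI itself.
FINE_NEIGHBOR_COUNT = 8


class ProtocolError(ValueError):
    """Raised for invalid plans or incomplete metric tables."""


def testing_lead_count(A: int) -> int:
    """Total single-lead channels tested by the layered search: (A + 8) x 6."""
    if not 1 <= A <= A_MAX:
        raise ProtocolError(f"A must be in 1..{A_MAX}, got {A}")
    return (A + FINE_NEIGHBOR_COUNT) * 6


def direct_lead_count(grid: TorsoGrid) -> int:
    """Channels needed to test every square of the grid directly."""
    return grid.n_squares() * 6


def measurement_rounds(
    A: int, N: int, roi_neighbor_count: int = FINE_NEIGHBOR_COUNT
) -> tuple[int, int, int]:
    """(coarse rounds, fine rounds, total) for A squares and N modules."""
    if N < 1:
        raise ProtocolError("N must be >= 1")
    if A < 1:
        raise ProtocolError("A must be >= 1")
    coarse = math.ceil(A / N)
    fine = math.ceil(roi_neighbor_count / N)
    return coarse, fine, coarse + fine


@dataclass(frozen=True)
class LANSPlan:
    """A validated study plan: coarse squares, module count, round batches."""

    coarse_squares: tuple[tuple[str, int], ...]
    N: int

    @property
    def A(self) -> int:
        return len(self.coarse_squares)

    @property
    def coarse_rounds(self) -> list[list[tuple[str, int]]]:
        sq = list(self.coarse_squares)
        return [sq[i : i + self.N] for i in range(0, len(sq), self.N)]

    def fine_rounds(self, fine_squares: Sequence[tuple[str, int]]) -> list[list[tuple[str, int]]]:
        sq = list(fine_squares)
        return [sq[i : i + self.N] for i in range(0, len(sq), self.N)]


def make_plan(grid: TorsoGrid, coarse_squares: Sequence[tuple[str, int]], N: int) -> LANSPlan:
    """Build a plan, enforcing pairwise non-adjacency of the coarse squares."""
    if N < 1:
        raise ProtocolError("N must be >= 1")
    coarse = tuple(coarse_squares)
    if not 1 <= len(coarse) <= A_MAX:
        raise ProtocolError(f"number of coarse squares must be in 1..{A_MAX}")
    violations = grid.validate_coarse_set(coarse)
    if violations:
        raise ProtocolError(f"coarse squares are not pairwise non-adjacent: {violations}")
    return LANSPlan(coarse_squares=coarse, N=N)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds and voting settings for the final selection.

    A lead is "good" when its mean SNR exceeds ``snr_good_db`` and its mean
    QRS amplitude exceeds ``qrs_good_mv``; the fine-stage marking thresholds
    annotate per-lead plots/reports.  ``voting_mode`` chooses the candidate
    pool: ``per_best_channel`` restricts it to the best channel's lead in
    each fine-stage square (the narrowed procedure), ``global`` votes over
    all fine-stage leads.
    """

    snr_good_db: float = 21.0
    qrs_good_mv: float = 1.0
    mark_snr_db: float = 22.0
    mark_qrs_mv: float = 0.9
    top_k: int = 3
    voting_mode: str = "per_best_channel"
    #: Leads measurable in fewer than this fraction of the study's subjects
    #: are excluded from the candidate pool (guards the CV ranking against
    #: tiny-sample artifacts on barely-detectable leads).
    min_subject_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ProtocolError("top_k must be >= 1")
        if not 0 <= self.min_subject_fraction <= 1:
            raise ProtocolError("min_subject_fraction must be in [0, 1]")
        if self.voting_mode not in ("per_best_channel", "global"):
            raise ProtocolError("voting_mode must be 'per_best_channel' or 'global'")


@dataclass
class Candidate:
    """One pooled lead with its metric values and vote count."""

    lead: LeadKey
    pair: str
    snr: float
    qrs: float
    cv: float
    votes: int = 0
    good: bool = False


@dataclass
class LANSResult:
    """Outcome of a selection (and, from :func:`run_lans`, the whole search)."""

    top_snr: list[LeadKey]
    top_qrs: list[LeadKey]
    low_cv: list[LeadKey]
    votes: dict[LeadKey, int]
    winners: list[LeadKey]
    winner_pairs: list[str]
    runner_up: LeadKey | None
    candidates: list[Candidate]
    roi: tuple[str, int] | None = None
    best_channel: int | None = None
    coarse_table: pd.DataFrame | None = None
    fine_table: pd.DataFrame | None = None
    coarse_agg: pd.DataFrame | None = None
    fine_agg: pd.DataFrame | None = None
    rounds_log: list[dict] = field(default_factory=list)
    config: SelectionConfig | None = None


def _lead_key(row: pd.Series) -> LeadKey:
    return (row["side"], int(row["square"]), int(row["channel"]))


def _square_order(side: str, index: int) -> tuple[int, int]:
    return (0 if side == "front" else 1, index)


def select_roi(coarse_table: pd.DataFrame) -> tuple[str, int]:
    """Pick the ROI from per-subject coarse-stage metrics.

    The ROI is the square with the highest median SNR pooled over its six
    channels and all subjects; ties break by median QRS amplitude, then by
    lowest square index.  SNR is the primary metric throughout.
    """
    if coarse_table.empty:
        raise ProtocolError("empty coarse metrics table")
    df = coarse_table[~coarse_table["low_quality"]]
    scores = []
    for (side, square), group in df.groupby(["side", "square"], sort=False):
        scores.append(
            (
                -group["snr_db"].median(),
                -group["qrs_mean"].median(),
                _square_order(side, int(square)),
                (side, int(square)),
            )
        )
    if not scores:
        raise ProtocolError("all coarse-stage leads were low-quality")
    scores.sort()
    return scores[0][3]


def select_best_channel(fine_table: pd.DataFrame) -> int:
    """Channel index with the best fine-stage SNR distribution.

    Ranks the six channel indices by median SNR pooled over the fine-stage
    squares and subjects; ties break by median QRS amplitude, then by the
    lower channel index.
    """
    df = fine_table[~fine_table["low_quality"]]
    if df.empty:
        raise ProtocolError("empty fine metrics table")
    scores = []
    for channel, group in df.groupby("channel", sort=True):
        scores.append(
            (-group["snr_db"].median(), -group["qrs_mean"].median(), int(channel))
        )
    scores.sort()
    return scores[0][2]


def select_optimal_pairs(
    fine_agg: pd.DataFrame,
    config: SelectionConfig = SelectionConfig(),
    best_channel: int | None = None,
) -> LANSResult:
    """Candidate voting over the fine-stage aggregated metrics table.

    Expects across-subject rows with columns ``side, square, channel, pair,
    snr_mean, qrs_mean, cv``.  Builds the three candidate lists (top-k SNR,
    top-k QRS amplitude, lowest-k CV), counts votes, and declares the
    winner(s); ties break by SNR rank, then QRS amplitude, then square and
    channel index.
    """
    pool = fine_agg
    if config.voting_mode == "per_best_channel":
        if best_channel is None:
            raise ProtocolError("per_best_channel voting needs best_channel")
        pool = fine_agg[fine_agg["channel"] == best_channel]
    pool = pool.dropna(subset=["snr_mean", "qrs_mean", "cv"])
    if "n_subjects" in pool.columns and len(pool):
        min_n = config.min_subject_fraction * pool["n_subjects"].max()
        pool = pool[pool["n_subjects"] >= min_n]
    if len(pool) < config.top_k:
        raise ProtocolError(
            f"candidate pool ({len(pool)} leads) smaller than top_k={config.top_k}"
        )

    def ranked(col: str, ascending: bool) -> list[LeadKey]:
        sgn = 1 if ascending else -1
        rows = sorted(
            pool.itertuples(index=False),
            key=lambda r: (
                sgn * getattr(r, col),
                -r.snr_mean,
                -r.qrs_mean,
                _square_order(r.side, int(r.square)),
                int(r.channel),
            ),
        )
        return [(r.side, int(r.square), int(r.channel)) for r in rows]

    snr_rank = ranked("snr_mean", ascending=False)
    top_snr = snr_rank[: config.top_k]
    top_qrs = ranked("qrs_mean", ascending=False)[: config.top_k]
    low_cv = ranked("cv", ascending=True)[: config.top_k]

    votes: dict[LeadKey, int] = {}
    for lst in (top_snr, top_qrs, low_cv):
        for lead in lst:
            votes[lead] = votes.get(lead, 0) + 1

    # max votes wins; ties resolved by SNR rank (which is itself unique after
    # its own QRS/index tie-breaks), so the winner is deterministic and single
    snr_pos = {lead: i for i, lead in enumerate(snr_rank)}
    order = sorted(votes, key=lambda l: (-votes[l], snr_pos[l]))
    winners = [order[0]]
    runner_up = order[1] if len(order) > 1 else None

    by_key = {(r.side, int(r.square), int(r.channel)): r for r in pool.itertuples(index=False)}
    candidates = []
    for lead in order:
        r = by_key[lead]
        candidates.append(
            Candidate(
                lead=lead,
                pair=r.pair,
                snr=float(r.snr_mean),
                qrs=float(r.qrs_mean),
                cv=float(r.cv),
                votes=votes[lead],
                good=r.snr_mean > config.snr_good_db and r.qrs_mean > config.qrs_good_mv,
            )
        )
    return LANSResult(
        top_snr=top_snr,
        top_qrs=top_qrs,
        low_cv=low_cv,
        votes=votes,
        winners=winners,
        winner_pairs=[by_key[l].pair for l in winners],
        runner_up=runner_up,
        candidates=candidates,
        best_channel=best_channel,
        config=config,
    )


RecordProvider = Callable[[int, str, int], ECGRecord]


def run_lans(
    provider: RecordProvider,
    grid: TorsoGrid,
    plan: LANSPlan,
    subjects: Sequence[int],
    filter_spec: FilterSpec = FilterSpec(),
    wavelet_spec: WaveletSpec = WaveletSpec(),
    detector_spec: DetectorSpec = DetectorSpec(),
    selection: SelectionConfig = SelectionConfig(),
) -> LANSResult:
    """Execute the full two-stage search.

    ``provider(subject, side, index)`` yields the record for one subject on
    one square; both measured stages are scheduled in batches of at most
    ``plan.N`` squares per round.  The ROI's coarse-stage records are reused
    in the fine stage (its metrics are part of the fine pool), so only the
    8 (fewer on the grid boundary) surrounding squares are newly measured.
    """
    subjects = list(subjects)
    if not subjects:
        raise ProtocolError("need at least one subject")
    rounds_log: list[dict] = []

    def measure(stage: str, batches: list[list[tuple[str, int]]]) -> pd.DataFrame:
        frames = []
        for i, batch in enumerate(batches, start=1):
            rounds_log.append({"stage": stage, "round": i, "squares": list(batch)})
            for side, index in batch:
                for subj in subjects:
                    rec = provider(subj, side, index)
                    frames.append(
                        evaluate_record(rec, grid, filter_spec, wavelet_spec, detector_spec)
                    )
        return pd.concat(frames, ignore_index=True)

    coarse_table = measure("coarse", plan.coarse_rounds)
    roi = select_roi(coarse_table)

    fine_new = sorted(grid.neighbors_of_square(*roi))
    fine_table_new = measure("fine", plan.fine_rounds([(roi[0], i) for i in fine_new]))
    roi_rows = coarse_table[
        (coarse_table["side"] == roi[0]) & (coarse_table["square"] == roi[1])
    ]
    fine_table = pd.concat([roi_rows, fine_table_new], ignore_index=True)

    best_channel = select_best_channel(fine_table)
    fine_agg = aggregate(fine_table)
    result = select_optimal_pairs(fine_agg, selection, best_channel=best_channel)
    result.roi = roi
    result.coarse_table = coarse_table
    result.fine_table = fine_table
    result.coarse_agg = aggregate(coarse_table)
    result.fine_agg = fine_agg
    result.rounds_log = rounds_log
    return result
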