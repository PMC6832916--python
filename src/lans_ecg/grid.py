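"""Torso electrode grid: numbering, measurement squares, lead channels, adjacency.

The torso is covered by two planar arrays of electrodes, one on the front and
one on the back of the chest, each laid out as ``rows_per_side`` rows of
``columns_per_side`` electrodes at a fixed spacing (5 cm by default).
Electrodes are numbered row-major: the front side first (ids 1..42 on the
default grid), then the back side (43..84).

Every four mutually adjacent electrodes bound a *measurement square* to which
a four-electrode sensor module can be attached.  Because the front of the
chest is not planar, one physical row of squares (between electrode rows 3
and 4 by default) is absent on the front side, leaving 25 front squares and
30 back squares on the default grid.  The front squares are nevertheless
indexed on a logically contiguous 5x5 grid, so square neighborhoods behave
uniformly on both sides.

Each square supports six bipolar lead channels — two horizontal, two
vertical, and the two diagonals.  Channel 5 is the principal diagonal
(top-left to bottom-right), channel 6 the counter diagonal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

FRONT = "front"
BACK = "back"
SIDES = (FRONT, BACK)

HORIZONTAL = "horizontal"
VERTICAL = "vertical"
PRINCIPAL_DIAGONAL = "principal_diagonal"
COUNTER_DIAGONAL = "counter_diagonal"
ORIENTATIONS = (HORIZONTAL, VERTICAL, PRINCIPAL_DIAGONAL, COUNTER_DIAGONAL)

#: Channel index -> (orientation, (corner of positive electrode, corner of
#: reference electrode)).  Corners are "tl", "tr", "bl", "br".  Channels 5/6
#: (the diagonals) are pinned by convention; 1-4 follow a fixed assignment:
#: 1 = top horizontal, 2 = bottom horizontal, 3 = left vertical,
#: 4 = right vertical.
CHANNEL_LAYOUT: dict[int, tuple[str, tuple[str, str]]] = {
    1: (HORIZONTAL, ("tl", "tr")),
    2: (HORIZONTAL, ("bl", "br")),
    3: (VERTICAL, ("tl", "bl")),
    4: (VERTICAL, ("tr", "br")),
    5: (PRINCIPAL_DIAGONAL, ("tl", "br")),
    6: (COUNTER_DIAGONAL, ("tr", "bl")),
}

#: Maximum number of coarse-stage squares such that a pairwise non-adjacent
#: placement still exists on the default grid (reported study constant, not
#: derived here; the validator checks only pairwise non-adjacency).
A_MAX = 20


class GridConfigError(ValueError):
    """Raised for dimensionally invalid grid specifications."""


class GridLookupError(KeyError):
    """Raised for out-of-range electrode/square lookups."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the two-sided electrode array.

    Parameters
    ----------
    electrode_spacing : float
        Distance between neighboring electrodes, cm.
    columns_per_side, rows_per_side : int
        Electrode columns and rows on each side.
    front_skipped_square_row : int or None
        Ordinal of the physical square row absent on the front side
        (between electrode rows ``k`` and ``k+1``); ``None`` for no gap.
    torso_depth : float
        Separation between the front and back electrode planes, cm
        (used only to place electrodes in 3-D for the simulator).
    """

    electrode_spacing: float = 5.0
    columns_per_side: int = 6
    rows_per_side: int = 7
    front_skipped_square_row: int | None = 3
    torso_depth: float = 20.0

    def __post_init__(self) -> None:
        if self.electrode_spacing <= 0:
            raise GridConfigError("electrode_spacing must be > 0")
        if self.columns_per_side < 2 or self.rows_per_side < 2:
            raise GridConfigError("need at least 2 columns and 2 rows of electrodes")
        if self.torso_depth <= 0:
            raise GridConfigError("torso_depth must be > 0")
        skip = self.front_skipped_square_row
        if skip is not None and not (1 <= skip <= self.rows_per_side - 1):
            raise GridConfigError(
                f"front_skipped_square_row {skip} outside 1..{self.rows_per_side - 1}"
            )

    @property
    def electrodes_per_side(self) -> int:
        return self.columns_per_side * self.rows_per_side

    @property
    def squares_per_row(self) -> int:
        return self.columns_per_side - 1


@dataclass(frozen=True)
class ElectrodeRef:
    """One electrode: global 1-based id, side, 1-based row/col, 3-D position (cm)."""

    id: int
    side: str
    row: int
    col: int
    position: tuple[float, float, float]


@dataclass(frozen=True)
class SquareRef:
    """One measurement square with its corner electrode ids (TL, TR, BL, BR)."""

    side: str
    index: int
    square_row: int
    square_col: int
    corners: tuple[int, int, int, int]

    @property
    def corner_map(self) -> dict[str, int]:
        tl, tr, bl, br = self.corners
        return {"tl": tl, "tr": tr, "bl": bl, "br": br}


@dataclass(frozen=True)
class LeadChannel:
    """A bipolar lead of a square: channel index 1-6, orientation, electrode pair.

    ``electrode_pair`` is (positive electrode id, reference electrode id).
    """

    channel_index: int
    orientation: str
    electrode_pair: tuple[int, int]


class TorsoGrid:
    """The built electrode/square/channel model.  Construct via :func:`build_grid`."""

    def __init__(self, spec: GridSpec):
        self.spec = spec
        self._electrodes: dict[int, ElectrodeRef] = {}
        self._by_loc: dict[tuple[str, int, int], int] = {}
        self._squares: dict[tuple[str, int], SquareRef] = {}
        self._square_grid_shape: dict[str, tuple[int, int]] = {}
        self._build()

    # -- construction -----------------------------------------------------

    def _build(self) -> None:
        s = self.spec
        for side_i, side in enumerate(SIDES):
            offset = side_i * s.electrodes_per_side
            for row in range(1, s.rows_per_side + 1):
                for col in range(1, s.columns_per_side + 1):
                    eid = offset + (row - 1) * s.columns_per_side + col
                    self._electrodes[eid] = ElectrodeRef(
                        id=eid,
                        side=side,
                        row=row,
                        col=col,
                        position=self._position(side, row, col),
                    )
                    self._by_loc[(side, row, col)] = eid

        for side in SIDES:
            top_rows = self._square_top_rows(side)
            n_cols = s.squares_per_row
            self._square_grid_shape[side] = (len(top_rows), n_cols)
            for sq_row, top in enumerate(top_rows, start=1):
                for sq_col in range(1, n_cols + 1):
                    index = (sq_row - 1) * n_cols + sq_col
                    tl = self._by_loc[(side, top, sq_col)]
                    tr = self._by_loc[(side, top, sq_col + 1)]
                    bl = self._by_loc[(side, top + 1, sq_col)]
                    br = self._by_loc[(side, top + 1, sq_col + 1)]
                    self._squares[(side, index)] = SquareRef(
                        side=side,
                        index=index,
                        square_row=sq_row,
                        square_col=sq_col,
                        corners=(tl, tr, bl, br),
                    )

    def _square_top_rows(self, side: str) -> list[int]:
        """Electrode row of the top edge of each square row, in square-row order."""
        s = self.spec
        rows = list(range(1, s.rows_per_side))
        if side == FRONT and s.front_skipped_square_row is not None:
            rows = [r for r in rows if r != s.front_skipped_square_row]
        return rows

    def _position(self, side: str, row: int, col: int) -> tuple[float, float, float]:
        s = self.spec
        y = (row - 1) * s.electrode_spacing  # increases downward along the torso
        if side == FRONT:
            return ((col - 1) * s.electrode_spacing, y, 0.0)
        # Back electrodes mirror the columns when both sides are viewed from
        # the front, so front/back squares stack geometrically.
        x = (s.columns_per_side - col) * s.electrode_spacing
        return (x, y, s.torso_depth)

    # -- lookups ----------------------------------------------------------

    @property
    def electrodes(self) -> Sequence[ElectrodeRef]:
        return tuple(self._electrodes.values())

    def electrode(self, eid: int) -> ElectrodeRef:
        try:
            return self._electrodes[eid]
        except KeyError:
            raise GridLookupError(f"no electrode with id {eid}") from None

    def electrode_id(self, side: str, row: int, col: int) -> int:
        try:
            return self._by_loc[(side, row, col)]
        except KeyError:
            raise GridLookupError(f"no electrode at {(side, row, col)}") from None

    def squares(self, side: str | None = None) -> list[SquareRef]:
        if side is None:
            return list(self._squares.values())
        return [sq for (s, _), sq in self._squares.items() if s == side]

    def n_squares(self, side: str | None = None) -> int:
        return len(self.squares(side))

    def square(self, side: str, index: int) -> SquareRef:
        if side not in SIDES:
            raise GridLookupError(f"unknown side {side!r}")
        try:
            return self._squares[(side, index)]
        except KeyError:
            raise GridLookupError(f"no square {index} on the {side} side") from None

    def electrodes_of_square(self, side: str, index: int) -> tuple[int, int, int, int]:
        """Corner electrode ids of a square as (TL, TR, BL, BR)."""
        return self.square(side, index).corners

    def channels_of_square(self, side: str, index: int) -> list[LeadChannel]:
        """The six lead channels of a square, in channel-index order."""
        corner_map = self.square(side, index).corner_map
        return [
            LeadChannel(ch, orient, (corner_map[pos], corner_map[ref]))
            for ch, (orient, (pos, ref)) in sorted(CHANNEL_LAYOUT.items())
        ]

    def neighbors_of_square(self, side: str, index: int) -> set[int]:
        """8-neighborhood of a square in the logical square grid of its side."""
        sq = self.square(side, index)
        n_rows, n_cols = self._square_grid_shape[side]
        out: set[int] = set()
        for dr, dc in itertools.product((-1, 0, 1), repeat=2):
            if dr == dc == 0:
                continue
            r, c = sq.square_row + dr, sq.square_col + dc
            if 1 <= r <= n_rows and 1 <= c <= n_cols:
                out.add((r - 1) * n_cols + c)
        return out

    # -- protocol helpers -------------------------------------------------

    def validate_coarse_set(
        self, squares: Iterable[tuple[str, int]]
    ) -> list[tuple[tuple[str, int], tuple[str, int], str]]:
        """Check that a coarse-stage square set is pairwise non-adjacent.

        Two squares are adjacent when they share an electrode.  Returns a list
        of ``(square_a, square_b, reason)`` violations; empty means the set is
        valid.  Duplicate entries are reported as violations.
        """
        squares = list(squares)
        if not squares:
            raise ValueError("coarse square set must be non-empty")
        violations: list[tuple[tuple[str, int], tuple[str, int], str]] = []
        seen: set[tuple[str, int]] = set()
        for key in squares:
            if key in seen:
                violations.append((key, key, "duplicate"))
            seen.add(key)
        for a, b in itertools.combinations(sorted(set(squares)), 2):
            ca = set(self.square(*a).corners)
            cb = set(self.square(*b).corners)
            if ca & cb:
                violations.append((a, b, "shared electrodes"))
        return violations

    def classify_orientations(
        self, squares: Iterable[tuple[str, int]]
    ) -> dict[str, int]:
        """Count lead channels by orientation over a set of squares."""
        counts = {o: 0 for o in ORIENTATIONS}
        for side, index in squares:
            for ch in self.channels_of_square(side, index):
                counts[ch.orientation] += 1
        return counts

    # -- export -----------------------------------------------------------

    def to_table(self) -> pd.DataFrame:
        """All lead channels as a flat table (one row per square x channel)."""
        rows = []
        for (side, index), sq in sorted(
            self._squares.items(), key=lambda kv: (kv[0][0] != FRONT, kv[0][1])
        ):
            for ch in self.channels_of_square(side, index):
                pos, ref = ch.electrode_pair
                epos = self.electrode(pos).position
                eref = self.electrode(ref).position
                rows.append(
                    {
                        "side": side,
                        "square": index,
                        "square_row": sq.square_row,
                        "square_col": sq.square_col,
                        "channel": ch.channel_index,
                        "orientation": ch.orientation,
                        "electrode_pos": pos,
                        "electrode_ref": ref,
                        "pos_x": epos[0],
                        "pos_y": epos[1],
                        "pos_z": epos[2],
                        "ref_x": eref[0],
                        "ref_y": eref[1],
                        "ref_z": eref[2],
                    }
                )
        return pd.DataFrame(rows)


def build_grid(spec: GridSpec | None = None) -> TorsoGrid:
    """Build the torso grid from a :class:`GridSpec` (defaults to the study grid)."""
    return TorsoGrid(spec or GridSpec())


def pair_label(pair: tuple[int, int]) -> str:
    """Format an electrode pair the way reports print it, e.g. ``'10/17'``."""
    return f"{pair[0]}/{pair[1]}"
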