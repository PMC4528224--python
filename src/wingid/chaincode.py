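"""Freeman 8-directional chain coding of closed pixel outlines.

A closed contour is encoded as a starting pixel plus a sequence of direction
codes 0-7, where code ``k`` points along the angle ``k * pi/4`` measured
counterclockwise from the +x axis.  Even codes are axis-parallel unit steps
(length 1), odd codes are diagonal steps (length sqrt(2)).  The cumulative
step lengths give the arc-length parameter ``t_p`` of every contour point,
which is what the elliptic Fourier transform integrates over.

Coordinate convention (stated once, used by everything downstream): image
pixels are ``(row, col)`` with row 0 at the top; mathematical coordinates are
``x = col``, ``y = (height - 1) - row`` so that y increases upward.  All chain
codes produced by :func:`trace` run counterclockwise in these y-up
coordinates, which keeps the sign of the first-harmonic area term stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ChainCodeError

SQRT2 = float(np.sqrt(2.0))

#: (dx, dy) of each of the 8 direction codes, in y-up mathematical coordinates.
CODE_STEPS = np.array(
    [[1, 0], [1, 1], [0, 1], [-1, 1], [-1, 0], [-1, -1], [0, -1], [1, -1]],
    dtype=np.int64,
)

#: Segment length of each code: 1 for even (axis) codes, sqrt(2) for odd (diagonal).
STEP_LENGTH = np.where(np.arange(8) % 2 == 0, 1.0, SQRT2)

_STEP_TO_CODE = {(int(dx), int(dy)): code for code, (dx, dy) in enumerate(CODE_STEPS)}


@dataclass(frozen=True)
class ChainCode:
    """A closed outline as a start pixel plus 8-directional codes.

    Attributes
    ----------
    start : tuple of int
        ``(x0, y0)`` of the starting pixel in mathematical coordinates.
    codes : ndarray of int
        Direction codes, one per step; the final step returns to ``start``
        for a closed chain.
    """

    start: tuple
    codes: np.ndarray

    @property
    def delta_t(self) -> np.ndarray:
        """Per-step segment lengths, 1 or sqrt(2)."""
        return STEP_LENGTH[self.codes]

    @property
    def cum_t(self) -> np.ndarray:
        """Cumulative arc length t_p after each step (strictly increasing)."""
        return np.cumsum(self.delta_t)

    @property
    def total_T(self) -> float:
        """Total perimeter length T."""
        return float(self.cum_t[-1]) if len(self.codes) else 0.0

    def __len__(self) -> int:
        return len(self.codes)

    def is_closed(self) -> bool:
        """True when the vector sum of all steps is (0, 0)."""
        return bool(np.all(CODE_STEPS[self.codes].sum(axis=0) == 0))


def trace(outline) -> ChainCode:
    """Encode a traversed :class:`~wingid.outline.BinaryOutline` as a chain code.

    The outline's pixel sequence is converted to y-up coordinates, oriented
    counterclockwise (reversing if needed), and rotated so the traversal
    starts at the topmost-then-leftmost pixel; the starting-point choice is
    arbitrary but deterministic, and the elliptic Fourier normalization later
    removes any residual starting-point dependence.

    Raises
    ------
    ChainCodeError
        If consecutive pixels are not 8-neighbours, a pixel is visited twice,
        or the path is too short to close.
    """
    pixels = np.asarray(outline.pixels, dtype=np.int64)
    if pixels.ndim != 2 or pixels.shape[1] != 2:
        raise ChainCodeError("outline pixels must be an (n, 2) array of (row, col)")
    height = int(outline.image_shape[0])
    xy = np.column_stack([pixels[:, 1], height - 1 - pixels[:, 0]])
    if len(xy) > 1 and np.array_equal(xy[0], xy[-1]):
        xy = xy[:-1]
    if len(xy) < 4:
        raise ChainCodeError(f"outline of {len(xy)} pixels cannot form a closed 8-connected loop")
    seen = set(map(tuple, xy.tolist()))
    if len(seen) != len(xy):
        raise ChainCodeError("outline visits a pixel more than once (branching or 1-px-wide spur)")

    # counterclockwise orientation in y-up coordinates (positive signed area)
    x, y = xy[:, 0], xy[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 == 0:
        raise ChainCodeError("outline encloses zero area")
    if area2 < 0:
        xy = xy[::-1]

    # start at topmost-then-leftmost pixel (max y, then min x, in y-up terms)
    start_idx = int(np.lexsort((xy[:, 0], -xy[:, 1]))[0])
    xy = np.roll(xy, -start_idx, axis=0)

    deltas = np.roll(xy, -1, axis=0) - xy
    codes = np.empty(len(xy), dtype=np.int64)
    for i, (dx, dy) in enumerate(deltas):
        code = _STEP_TO_CODE.get((int(dx), int(dy)))
        if code is None:
            r, c = int(height - 1 - xy[i, 1]), int(xy[i, 0])
            raise ChainCodeError(
                f"pixels at (row={r}, col={c}) and the next outline pixel are not 8-neighbours"
            )
        codes[i] = code
    return ChainCode(start=(int(xy[0, 0]), int(xy[0, 1])), codes=codes)


def to_coordinates(cc: ChainCode) -> np.ndarray:
    """Integrate a chain code into arc-length-parameterized coordinates.

    Returns an ``(n_steps + 1, 3)`` array of rows ``(t_p, x_p, y_p)`` starting
    at ``(0, x0, y0)``; for a closed chain the last point coincides with the
    first and ``t`` ends at the perimeter ``T``.
    """
    steps = CODE_STEPS[cc.codes]
    x = cc.start[0] + np.concatenate([[0], np.cumsum(steps[:, 0])])
    y = cc.start[1] + np.concatenate([[0], np.cumsum(steps[:, 1])])
    t = np.concatenate([[0.0], cc.cum_t])
    return np.column_stack([t, x.astype(float), y.astype(float)])
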