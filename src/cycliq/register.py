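"""Translation-only registration of staining cycles to the first cycle.

Cyclic imaging acquires each cycle after the stage returns to a stored
position, which leaves a small rigid offset between cycles.  Because cells
are fixed and channels within one cycle are imaged without moving the
stage, a single integer (dy, dx) per cycle suffices.  The shift is found by
exhaustively scoring every candidate displacement within ``max_shift`` with
zero-normalised cross-correlation (ZNCC) on the overlapping pixels of the
two nuclear-stain reference images and taking the argmax.

The exhaustive ZNCC surface is evaluated in closed form: the cross term
for all shifts comes from one FFT cross-correlation, and the per-shift
window sums/variances come from 2-D prefix sums.  This is algebraically the
same as a per-shift loop (a literal loop oracle is used in the tests) but
runs in O(HW log HW) instead of O(HW * shifts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .stack import Cycle, CycleStack, MarkerChannel

__all__ = ["ShiftVector", "translate", "estimate_shift", "align_cycles"]

log = logging.getLogger(__name__)

#: relative epsilon below the best score within which shifts count as tied
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class ShiftVector:
    """Displacement of a moving image relative to the reference.

    ``moving ~ translate(reference, dy, dx)``; to align the moving image
    apply ``translate(moving, -dy, -dx)``.  ``similarity`` is the ZNCC score
    in [-1, 1] at that displacement.
    """

    dy: int
    dx: int
    similarity: float


def translate(image: np.ndarray, dy: int, dx: int, fill: float = 0.0) -> np.ndarray:
    """Shift an image by integer (dy, dx) with constant fill.

    ``translate(img, dy, dx)[r, c] == img[r - dy, c - dx]`` where defined.
    """
    out = np.full_like(image, fill)
    h, w = image.shape
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ysrc = slice(max(-dy, 0), h + min(-dy, 0))
    xsrc = slice(max(-dx, 0), w + min(-dx, 0))
    if ys.start < ys.stop and xs.start < xs.stop:
        out[ys, xs] = image[ysrc, xsrc]
    return out


def _prefix(a: np.ndarray) -> np.ndarray:
    s = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    s[1:, 1:] = a.cumsum(0).cumsum(1)
    return s


def _window_sums(prefix: np.ndarray, r0: np.ndarray, r1: np.ndarray,
                 c0: np.ndarray, c1: np.ndarray) -> np.ndarray:
    """Rectangle sums for every (row-window, col-window) combination."""
    return (
        prefix[np.ix_(r1, c1)]
        - prefix[np.ix_(r0, c1)]
        - prefix[np.ix_(r1, c0)]
        + prefix[np.ix_(r0, c0)]
    )


def zncc_surface(reference: np.ndarray, moving: np.ndarray, max_shift: int) -> np.ndarray:
    """ZNCC score for every integer shift in [-max_shift, max_shift]^2.

    Entry [i, j] scores displacement (dy, dx) = (i - max_shift, j - max_shift),
    comparing ``reference[r, c]`` against ``moving[r + dy, c + dx]`` over the
    overlap; out-of-frame pixels are excluded.  Shifts whose overlap is empty
    or constant get -inf.
    """
    if reference.shape != moving.shape:
        raise ValueError("reference and moving images must share a shape")
    h, w = reference.shape
    ref = reference.astype(float)
    mov = moving.astype(float)

    m = int(max_shift)
    dys = np.arange(-m, m + 1)
    dxs = np.arange(-m, m + 1)

    # cross[dy, dx] = sum_r ref[r, c] * mov[r + dy, c + dx]
    full = fftconvolve(mov, ref[::-1, ::-1], mode="full")
    cross = full[h - 1 - m : h - 1 + m + 1, w - 1 - m : w - 1 + m + 1]

    pr, pr2 = _prefix(ref), _prefix(ref**2)
    pm, pm2 = _prefix(mov), _prefix(mov**2)

    # valid ref rows for displacement dy: [max(0, -dy), h - max(0, dy))
    r0 = np.maximum(0, -dys)
    r1 = h - np.maximum(0, dys)
    c0 = np.maximum(0, -dxs)
    c1 = w - np.maximum(0, dxs)
    # corresponding mov rows are offset by +dy
    r0m, r1m = r0 + dys, r1 + dys
    c0m, c1m = c0 + dxs, c1 + dxs

    n = np.outer(r1 - r0, c1 - c0).astype(float)
    sr = _window_sums(pr, r0, r1, c0, c1)
    sr2 = _window_sums(pr2, r0, r1, c0, c1)
    sm = _window_sums(pm, r0m, r1m, c0m, c1m)
    sm2 = _window_sums(pm2, r0m, r1m, c0m, c1m)

    with np.errstate(invalid="ignore", divide="ignore"):
        num = cross - sr * sm / n
        var_r = sr2 - sr**2 / n
        var_m = sm2 - sm**2 / n
        score = num / np.sqrt(var_r * var_m)
    bad = (n <= 0) | (var_r <= 1e-12 * np.maximum(n, 1)) | (
        var_m <= 1e-12 * np.maximum(n, 1)
    )
    score[bad] = -np.inf
    return score


def estimate_shift(reference: np.ndarray, moving: np.ndarray, max_shift: int) -> ShiftVector:
    """Best integer displacement of ``moving`` relative to ``reference``.

    Exhaustive ZNCC argmax over [-max_shift, max_shift]^2 with a
    deterministic tie-break: smallest ``|dy| + |dx|`` first, then
    lexicographic (dy, dx).

    Raises ``ValueError`` for constant images, whose similarity is undefined.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        raise ValueError("similarity is undefined for constant images")
    score = zncc_surface(reference, moving, max_shift)
    best = score.max()
    if not np.isfinite(best):
        raise ValueError("no shift with a defined similarity within max_shift")
    eps = _TIE_EPS * max(1.0, abs(best))
    cand = np.argwhere(score >= best - eps)
    m = int(max_shift)
    shifts = cand - m
    order = sorted(
        range(len(shifts)),
        key=lambda i: (abs(shifts[i][0]) + abs(shifts[i][1]), shifts[i][0], shifts[i][1]),
    )
    dy, dx = (int(v) for v in shifts[order[0]])
    return ShiftVector(dy, dx, float(score[dy + m, dx + m]))


def align_cycles(
    stack: CycleStack,
    max_shift: int = 20,
    similarity_floor: float = 0.2,
) -> tuple[CycleStack, list[ShiftVector]]:
    """Align every cycle of a stack to cycle 1 via its reference channel.

    Every channel of cycle c (reference, stained, erased) is translated by
    the negated shift estimated between cycle c's reference and cycle 1's
    reference, so within-cycle channels share one shift.  A cycle whose best
    similarity falls below ``similarity_floor`` is still aligned but logged
    as a warning (likely drift beyond the search bound).
    """
    ref0 = stack.cycles[0].reference
    shifts: list[ShiftVector] = []
    cycles: list[Cycle] = []
    for c, cyc in enumerate(stack.cycles):
        if c == 0:
            sv = ShiftVector(0, 0, 1.0)
            cycles.append(Cycle(cyc.index, cyc.reference.copy(),
                                [MarkerChannel(ch.name, ch.stained.copy(),
                                               None if ch.erased is None else ch.erased.copy())
                                 for ch in cyc.channels]))
        else:
            sv = estimate_shift(ref0, cyc.reference, max_shift)
            if sv.similarity < similarity_floor:
                log.warning(
                    "cycle %d: best similarity %.3f below floor %.3f "
                    "(drift may exceed max_shift=%d)",
                    cyc.index, sv.similarity, similarity_floor, max_shift,
                )
            back = lambda img: translate(img, -sv.dy, -sv.dx)  # noqa: E731
            cycles.append(
                Cycle(
                    cyc.index,
                    back(cyc.reference),
                    [
                        MarkerChannel(ch.name, back(ch.stained),
                                      None if ch.erased is None else back(ch.erased))
                        for ch in cyc.channels
                    ],
                )
            )
        shifts.append(sv)
    return CycleStack(cycles), shifts
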