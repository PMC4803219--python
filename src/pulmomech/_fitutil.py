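"""Small shared fitting helpers (hinge/breakpoint regression)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HingeFit:
    """Two-segment continuous piecewise-linear least-squares fit."""

    break_idx: int          # index of the breakpoint sample within the input
    y_break: float          # fitted value at the breakpoint
    slope_pre: float
    slope_post: float
    rss: float
    coef: tuple[float, float, float]  # intercept, slope, hinge slope increment


def hinge_fit(t: np.ndarray, y: np.ndarray, candidates: np.ndarray | None = None,
              min_seg: int = 2) -> HingeFit:
    """Fit ``y(t) = a + b*t + c*max(t - t_j, 0)`` over candidate breakpoints.

    The breakpoint ``t_j`` minimizing the residual sum of squares over the
    candidate sample positions is returned.  Both segments share the value at
    the breakpoint (continuity is built into the hinge basis).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = t.size
    if n < 2 * min_seg + 1:
        raise ValueError("too few samples for a two-segment fit")
    if candidates is None:
        candidates = np.arange(min_seg, n - min_seg)
    best = None
    t0 = t[0]
    ts = t - t0
    for j in candidates:
        X = np.column_stack([np.ones(n), ts, np.maximum(ts - ts[j], 0.0)])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((X @ coef - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, int(j), coef)
    rss, j, coef = best
    y_break = float(coef[0] + coef[1] * ts[j])
    return HingeFit(break_idx=j, y_break=y_break, slope_pre=float(coef[1]),
                    slope_post=float(coef[1] + coef[2]), rss=rss,
                    coef=(float(coef[0]), float(coef[1]), float(coef[2])))
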