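"""Eight-way expression-velocity trend classification of quadratic fits.

A gated gene's fitted curve ``f(t) = A t^2 + B t + C`` over the study
window is labeled by (i) overall direction (increasing/decreasing of the
fitted endpoints), and (ii) the behaviour of the expression velocity
``|f'(t)|`` (constant when the quadratic term is not significant,
otherwise accelerating or decelerating), with interior extrema detected
from the observed per-day means (Maxima/Minima) taking precedence.
"""

from __future__ import annotations

from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TrendLabel", "classify_trend", "classify_trend_closed_form", "velocity_profile"]


class TrendLabel(str, Enum):
    INC_CONST = "INC_CONST"
    INC_ACCEL = "INC_ACCEL"
    INC_DECEL = "INC_DECEL"
    DEC_CONST = "DEC_CONST"
    DEC_ACCEL = "DEC_ACCEL"
    DEC_DECEL = "DEC_DECEL"
    MAXIMA = "MAXIMA"
    MINIMA = "MINIMA"

    @property
    def display(self) -> str:
        """Human-facing label used in report columns."""
        return _DISPLAY[self]


_DISPLAY = {
    TrendLabel.INC_CONST: "Increasing, constant",
    TrendLabel.INC_ACCEL: "Increasing, ↑ velocity",
    TrendLabel.INC_DECEL: "Increasing, ↓ velocity",
    TrendLabel.DEC_CONST: "Decreasing, constant",
    TrendLabel.DEC_ACCEL: "Decreasing, ↑ velocity",
    TrendLabel.DEC_DECEL: "Decreasing, ↓ velocity",
    TrendLabel.MAXIMA: "Maxima",
    TrendLabel.MINIMA: "Minima",
}


def _poly(A: float, B: float, C: float):
    return lambda t: A * t * t + B * t + C


def classify_trend(
    A: float,
    B: float,
    C: float,
    p_quadratic: float,
    window: tuple[float, float],
    day_means: Sequence[float] | None = None,
    alpha: float = 0.05,
) -> TrendLabel:
    """Assign one of the eight velocity-trend labels.

    Decision procedure:

    1. If the first and last observed day means are both strictly below
       every interior day mean -> ``MAXIMA``; both strictly above ->
       ``MINIMA``.  Ties fall through.
    2. Direction from the fitted endpoints: increasing iff
       ``f(t_max) > f(t_min)`` (exact tie: sign of the derivative at the
       window midpoint).
    3. ``p_quadratic >= alpha`` -> velocity constant (``*_CONST``).
    4. Otherwise locate the vertex ``t* = -B / (2A)``: at or beyond the
       right edge the speed ``|f'|`` shrinks over the window
       (``*_DECEL``); at or before the left edge it grows (``*_ACCEL``);
       strictly interior (and not caught by rule 1) the larger endpoint
       speed decides.
    """
    t_min, t_max = float(window[0]), float(window[1])
    if t_max <= t_min:
        raise ValueError(f"window must satisfy t_min < t_max, got {window}")
    f = _poly(A, B, C)

    if day_means is not None and len(day_means) >= 3:
        m = np.asarray(day_means, dtype=float)
        first, last, interior = m[0], m[-1], m[1:-1]
        if first < interior.min() and last < interior.min():
            return TrendLabel.MAXIMA
        if first > interior.max() and last > interior.max():
            return TrendLabel.MINIMA

    lo, hi = f(t_min), f(t_max)
    if hi > lo:
        increasing = True
    elif hi < lo:
        increasing = False
    else:
        increasing = (2 * A * (t_min + t_max) / 2 + B) > 0

    if p_quadratic >= alpha or A == 0:
        if A == 0 and p_quadratic < alpha:
            raise RuntimeError("A == 0 with significant quadratic term: inconsistent fit")
        return TrendLabel.INC_CONST if increasing else TrendLabel.DEC_CONST

    vertex = -B / (2.0 * A)
    if vertex >= t_max:
        decel = True
    elif vertex <= t_min:
        decel = False
    else:
        speed_start = abs(2 * A * t_min + B)
        speed_end = abs(2 * A * t_max + B)
        decel = speed_start >= speed_end
    if increasing:
        return TrendLabel.INC_DECEL if decel else TrendLabel.INC_ACCEL
    return TrendLabel.DEC_DECEL if decel else TrendLabel.DEC_ACCEL


def classify_trend_closed_form(
    A: float, B: float, C: float, window: tuple[float, float], days: Sequence[float]
) -> TrendLabel:
    """Label an exact quadratic (no fit uncertainty) on a day grid.

    Used to validate planted trajectories: the quadratic term counts as
    significant iff ``A != 0`` and the Maxima/Minima rule is evaluated on
    the noiseless curve values at ``days``.
    """
    means = [_poly(A, B, C)(t) for t in days]
    return classify_trend(A, B, C, 1.0 if A == 0 else 0.0, window, means)


def velocity_profile(
    A: float, B: float, C: float, window: tuple[float, float], n_points: int = 50
) -> pd.DataFrame:
    """Tabulate fitted values and derivative on an even grid over the window."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    t = np.linspace(window[0], window[1], n_points)
    return pd.DataFrame(
        {"t": t, "fitted": A * t**2 + B * t + C, "derivative": 2 * A * t + B}
    )
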