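"""Patlak-Gjedde linear graphic analysis of irreversible tracer uptake.

For a tracer trapped irreversibly in tissue, the apparent tissue
distribution volume y(t) = C_T(t)/Ca(t) becomes linear in the normalized
arterial time x(t) = int_0^t Ca ds / Ca(t) (theta, minutes) once the
reversible compartments equilibrate:

    C_T(t)/Ca(t) = Ki * theta(t) + V_D

The slope Ki (mL g^-1 min^-1) is the net blood-brain influx constant; the
ordinate intercept V_D (mL g^-1) approximates the distribution volume of
free tracer, K1/k2 in the two-tissue compartment model. The full analysis
regresses all frames from 12 min onward; the two-point variant draws a line
through a fixed population intercept (0, V_D) and one late-time point,
which is what every simplified single-time-point method reduces to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .input_kinetics import LATE_WINDOW, auc_trapezoid, detect_first_appearance
from .tac import TimeActivityCurve

#: Default start of the linear (equilibrated) Patlak window, minutes.
DEFAULT_T_LO = 12.0

#: Population mean gray-matter ordinate intercept (mL/g), used to constrain
#: every two-point analysis at both scanning sites.
DEFAULT_VD = 0.55


@dataclass(frozen=True)
class PatlakResult:
    """Outcome of a Patlak fit."""

    ki: float
    vd: float
    r: float
    n_frames: int
    window: tuple[float, float]
    mode: str  # "full" | "two_point"

    def to_dict(self) -> dict:
        return {
            "ki": self.ki,
            "vd": self.vd,
            "r": self.r,
            "n_frames": self.n_frames,
            "window": list(self.window),
            "mode": self.mode,
        }


def patlak_full(
    idif: TimeActivityCurve,
    tissue: TimeActivityCurve,
    t_lo: float = DEFAULT_T_LO,
    t_appear: float | None = None,
) -> PatlakResult:
    """Multi-frame Patlak regression over frames with mid-time >= t_lo.

    The abscissa of frame j is the running trapezoidal plasma integral to
    its mid-time divided by the frame blood concentration; the ordinate is
    the tissue-to-blood concentration ratio. Unweighted OLS gives Ki
    (slope) and V_D (intercept).
    """
    if not tissue.schedule.approx_equal(idif.schedule):
        raise ValidationError("blood and tissue TACs must share one frame schedule")
    if t_appear is None:
        t_appear = detect_first_appearance(idif)
    mid = idif.mid
    mask = mid >= t_lo
    if int(mask.sum()) < 3:
        raise InsufficientDataError("full Patlak needs >= 3 frames past t_lo")
    if np.any(idif.value[mask] <= 0):
        raise ValidationError("non-positive blood concentration in the Patlak window")
    x = np.array(
        [auc_trapezoid(idif, t_appear, tm, t_anchor=t_appear) for tm in mid[mask]]
    ) / idif.value[mask]
    y = tissue.value[mask] / idif.value[mask]
    fit = stats.linregress(x, y)
    return PatlakResult(
        ki=float(fit.slope),
        vd=float(fit.intercept),
        r=float(fit.rvalue),
        n_frames=int(mask.sum()),
        window=(float(t_lo), float(idif.schedule.end[-1])),
        mode="full",
    )


def distribution_volume_late(
    tissue: TimeActivityCurve,
    idif: TimeActivityCurve,
    window: tuple[float, float] = LATE_WINDOW,
) -> float:
    """Apparent late distribution volume V_T: mean tissue / mean blood.

    Both means are taken over the frames whose mid-times fall in the
    terminal window (the final three 5-min frames of the harmonized
    protocol).
    """
    mask = tissue.schedule.window_mask(*window)
    if not mask.any() or not idif.schedule.window_mask(*window).any():
        raise InsufficientDataError("no frames in the late window")
    blood = float(np.mean(idif.value[idif.schedule.window_mask(*window)]))
    if blood <= 0:
        raise ValidationError("non-positive late blood concentration")
    return float(np.mean(tissue.value[mask])) / blood


def patlak_two_point(
    v_t_late: float,
    theta_late: float,
    v_d: float = DEFAULT_VD,
) -> float:
    """Ki from the line through (0, v_d) and one late point (theta, V_T)."""
    if theta_late <= 0:
        raise ValidationError("theta must be positive")
    return (v_t_late - v_d) / theta_late
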