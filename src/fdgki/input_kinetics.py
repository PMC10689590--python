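"""Pharmacokinetics of the image-derived input function (IDIF).

After an intravenous FDG bolus, the arterial concentration declines in
three roughly exponential phases: rapid mixing of the bolus in the blood
pool, partitioning of plasma FDG into bodily tissues, and renal elimination
of FDG. The whole input function is therefore modelled as

    Ca(t) = A e^(-lambda1 t) + B e^(-lambda2 t) + C e^(-lambda3 t)

for t >= t_appear (time of first appearance of radioactivity in blood),
with the time origin at injection. The decomposition uses the classical
method of residuals (exponential peeling): fit the slowest phase on the
late-window semi-log plot, subtract its extrapolate, refit the residuals
for the intermediate phase, and once more for the fast phase.

From the measured curve and its decomposition the module derives the
late-recording summary metrics used by the simplified Ki estimators:

* ``auc_0_67``   — trapezoidal plasma integral to the end of the recording,
* ``ca_52_67``   — mean blood concentration during the final 52-67 min window,
* ``theta_52_67``— the normalized arterial input, AUC / Ca (minutes),
* AUC recovery percentages of the mono-, bi- and tri-exponential models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DecompositionError,
    DegenerateInputError,
    InsufficientDataError,
    ValidationError,
)
from .tac import TRUNCATION_MIN, TimeActivityCurve

#: Default semi-log fitting window for the terminal elimination phase
#: (minutes). The lower bound is exposed because some protocols start the
#: tail window at 30 min instead of 35 min.
DEFAULT_TAIL_WINDOW = (35.0, 67.0)

#: Window bracketing the intermediate tissue-partitioning phase (minutes).
DEFAULT_INTERMEDIATE_WINDOW = (2.0, 20.0)

#: Upper bound of the fast bolus-mixing phase window (minutes); the lower
#: bound is the time of peak blood radioactivity.
DEFAULT_FAST_UPPER = 2.0

#: Window of the terminal "single frame": the final three 5-min frames of
#: the harmonized 67-min protocol.
LATE_WINDOW = (52.0, 67.0)

#: Fraction of the curve maximum that defines first appearance.
APPEARANCE_FRACTION = 0.05


@dataclass(frozen=True)
class TriExpParams:
    """Tri-exponential input-function parameters, time origin at injection.

    ``A, B, C`` are ordinate intercepts (concentration units) of the fast,
    intermediate and terminal phases; ``lambda1 > lambda2 > lambda3`` are
    the corresponding fractional rate constants (1/min). ``flags`` records
    degraded peeling stages (e.g. ``"no_fast_phase"`` when fewer than three
    positive residuals were available and A was set to zero).
    """

    A: float
    B: float
    C: float
    lambda1: float
    lambda2: float
    lambda3: float
    t_appear: float = 0.0
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.C > 0 and self.lambda3 > 0):
            raise ValidationError("terminal phase requires C > 0 and lambda3 > 0")
        if self.A < 0 or self.B < 0:
            raise ValidationError("amplitudes A, B must be non-negative")
        if not (self.lambda1 > self.lambda2 > self.lambda3):
            raise ValidationError("rate ordering lambda1 > lambda2 > lambda3 violated")
        if self.t_appear < 0:
            raise ValidationError("t_appear must be non-negative")

    @property
    def terms(self) -> tuple[tuple[float, float], ...]:
        """(amplitude, rate) pairs, fast to slow."""
        return (
            (self.A, self.lambda1),
            (self.B, self.lambda2),
            (self.C, self.lambda3),
        )

    def to_dict(self) -> dict:
        return {
            "A": self.A,
            "B": self.B,
            "C": self.C,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "lambda3": self.lambda3,
            "t_appear": self.t_appear,
            "flags": list(self.flags),
        }


@dataclass(frozen=True)
class InputMetrics:
    """Summary pharmacokinetic metrics of one measured IDIF."""

    auc_0_67: float
    ca_52_67: float
    theta_52_67: float
    lambda3_tail: float
    c_tail: float
    recovery_mono: float
    recovery_bi: float
    recovery_tri: float

    def to_dict(self) -> dict:
        return {
            "auc_0_67": self.auc_0_67,
            "ca_52_67": self.ca_52_67,
            "theta_52_67": self.theta_52_67,
            "lambda3_tail": self.lambda3_tail,
            "c_tail": self.c_tail,
            "recovery_mono": self.recovery_mono,
            "recovery_bi": self.recovery_bi,
            "recovery_tri": self.recovery_tri,
        }


def detect_first_appearance(idif: TimeActivityCurve) -> float:
    """Mid-time of the first frame exceeding 5% of the curve maximum."""
    vmax = float(np.max(idif.value))
    if vmax <= 0:
        raise DegenerateInputError("all-zero IDIF: no radioactivity appearance")
    idx = int(np.argmax(idif.value > APPEARANCE_FRACTION * vmax))
    return float(idif.mid[idx])


def time_to_peak(idif: TimeActivityCurve) -> float:
    """Mid-time of the frame with maximum blood radioactivity."""
    if float(np.max(idif.value)) <= 0:
        raise DegenerateInputError("all-zero IDIF has no peak")
    return float(idif.mid[int(np.argmax(idif.value))])


def _loglinear(t: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """OLS of ln(v) on t; returns (intercept back-transformed, -slope)."""
    fit = stats.linregress(t, np.log(v))
    return float(np.exp(fit.intercept)), float(-fit.slope)


def fit_loglinear_tail(
    idif: TimeActivityCurve, window: tuple[float, float] = DEFAULT_TAIL_WINDOW
) -> tuple[float, float]:
    """Fit the terminal mono-exponential C e^(-lambda t) on a semi-log plot.

    Returns ``(c_tail, lam)`` with the intercept back-transformed to the
    concentration at t = 0 (injection) and the negated slope in 1/min.
    """
    mask = idif.schedule.window_mask(*window)
    if int(mask.sum()) < 3:
        raise InsufficientDataError(
            f"need >= 3 frames with mid-time in [{window[0]}, {window[1]}] min"
        )
    v = idif.value[mask]
    if np.any(v <= 0):
        raise ValidationError("non-positive IDIF value in the tail window")
    return _loglinear(idif.mid[mask], v)


def _peel_stage(
    t: np.ndarray, residual: np.ndarray, mask: np.ndarray, scale: float
) -> tuple[float, float] | None:
    """One peeling stage: log-linear fit on positive residuals in a window.

    Residuals below 1e-8 of the curve maximum are float noise left over
    from a perfectly-explained slower phase and are excluded, so a purely
    mono- or bi-exponential curve degrades cleanly instead of fitting
    numerical debris.
    """
    use = mask & (residual > 1e-8 * scale)
    if int(use.sum()) < 3:
        return None
    return _loglinear(t[use], residual[use])


def decompose_triexp(
    idif: TimeActivityCurve,
    tail_window: tuple[float, float] = DEFAULT_TAIL_WINDOW,
    intermediate_window: tuple[float, float] = DEFAULT_INTERMEDIATE_WINDOW,
    fast_upper: float = DEFAULT_FAST_UPPER,
) -> TriExpParams:
    """Decompose an IDIF into three exponentials by the method of residuals.

    Stage 1 fits the terminal phase (C, lambda3) on ``tail_window``; its
    extrapolate is subtracted from the whole series and the intermediate
    phase (B, lambda2) fitted on the positive residuals within
    ``intermediate_window``; a second subtraction isolates the fast phase
    (A, lambda1) between the time of peak radioactivity and ``fast_upper``.
    A stage with fewer than three positive residuals degrades to zero
    amplitude and is flagged instead of failing, so noisy clinical curves
    still yield a usable (bi- or mono-exponential) model.
    """
    t = idif.mid
    c_tail, lam3 = fit_loglinear_tail(idif, tail_window)
    if lam3 <= 0:
        raise DecompositionError("non-decaying tail: lambda3 <= 0")
    flags: list[str] = []

    resid1 = idif.value - c_tail * np.exp(-lam3 * t)
    mid_mask = idif.schedule.window_mask(*intermediate_window)
    scale = float(np.max(idif.value))
    stage2 = _peel_stage(t, resid1, mid_mask, scale)
    if stage2 is None:
        b, lam2 = 0.0, 10.0 * lam3
        flags.append("no_intermediate_phase")
    else:
        b, lam2 = stage2
        if lam2 <= lam3:
            raise DecompositionError(
                f"rate ordering violated: lambda2 ({lam2:.4g}) <= lambda3 ({lam3:.4g})"
            )

    resid2 = resid1 - b * np.exp(-lam2 * t)
    t_peak = time_to_peak(idif)
    fast_mask = (t > t_peak) & (t <= fast_upper)
    stage3 = _peel_stage(t, resid2, fast_mask, scale)
    if stage3 is None:
        a, lam1 = 0.0, 10.0 * lam2
        flags.append("no_fast_phase")
    else:
        a, lam1 = stage3
        if lam1 <= lam2:
            raise DecompositionError(
                f"rate ordering violated: lambda1 ({lam1:.4g}) <= lambda2 ({lam2:.4g})"
            )

    return TriExpParams(
        A=a,
        B=b,
        C=c_tail,
        lambda1=lam1,
        lambda2=lam2,
        lambda3=lam3,
        t_appear=detect_first_appearance(idif),
        flags=tuple(flags),
    )


def eval_triexp(p: TriExpParams, t) -> np.ndarray | float:
    """Model concentration at time(s) t; zero before the appearance time."""
    t_arr = np.asarray(t, dtype=float)
    out = np.zeros_like(t_arr)
    live = t_arr >= p.t_appear
    for amp, lam in p.terms:
        if amp > 0:
            out = out + np.where(live, amp * np.exp(-lam * t_arr), 0.0)
    if np.isscalar(t):
        return float(out)
    return out


def auc_trapezoid(
    tac: TimeActivityCurve,
    t_start: float,
    t_end: float,
    t_anchor: float | None = None,
) -> float:
    """Trapezoidal integral of the measured curve between two times.

    Samples are the (mid-time, value) pairs; when ``t_start`` precedes the
    first mid-time and ``t_anchor`` is given, a zero-valued anchor point at
    the appearance time is prepended. Window edges are linearly
    interpolated on the sample polyline.
    """
    if t_start > t_end:
        raise ValidationError("t_start must not exceed t_end")
    if t_end > tac.schedule.end[-1] + 1e-9:
        raise ValidationError("t_end exceeds the last frame end")
    if t_start == t_end:
        return 0.0
    times = tac.mid
    values = tac.value
    if t_anchor is not None and t_anchor < times[0]:
        times = np.concatenate([[t_anchor], times])
        values = np.concatenate([[0.0], values])
    # A frame value is the frame mean, so the curve is extended flat from
    # the last mid-time to the frame end; this preserves the measured
    # integral of the final frame instead of discarding its second half.
    last_end = float(tac.schedule.end[-1])
    if last_end > times[-1]:
        times = np.concatenate([times, [last_end]])
        values = np.concatenate([values, [values[-1]]])
    lo = max(t_start, float(times[0]))
    hi = min(t_end, float(times[-1]))
    if hi <= lo:
        raise ValidationError("empty integration window")
    inner = times[(times > lo) & (times < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    vals = np.interp(grid, times, values)
    return float(np.trapezoid(vals, grid))


def auc_analytic(
    p: TriExpParams,
    t_start: float,
    t_end: float,
    n_terms: int = 3,
) -> float:
    """Closed-form integral of the (1-, 2- or 3-term) model.

    ``n_terms`` counts terms from the slow end: 1 keeps only the terminal
    C e^(-lambda3 t) phase, 2 adds the intermediate, 3 the full model.
    Integration never extends before the appearance time.
    """
    if not 1 <= n_terms <= 3:
        raise ValidationError("n_terms must be 1, 2 or 3")
    lo = max(t_start, p.t_appear)
    hi = t_end
    if hi <= lo:
        return 0.0
    used = p.terms[3 - n_terms :]
    total = 0.0
    for amp, lam in used:
        if amp > 0:
            total += (amp / lam) * (np.exp(-lam * lo) - np.exp(-lam * hi))
    return float(total)


def compute_metrics(
    idif: TimeActivityCurve,
    p: TriExpParams,
    late_window: tuple[float, float] = LATE_WINDOW,
) -> InputMetrics:
    """Derive the late-recording summary metrics from a decomposed IDIF.

    ``ca_52_67`` is the unweighted mean of frames with mid-time inside the
    late window; ``auc_0_67`` the trapezoidal integral from the appearance
    time to the end of the recording; ``theta_52_67`` their ratio; the
    recovery percentages compare the analytic AUC of the 1-, 2- and 3-term
    models against the measured integral.
    """
    mask = idif.schedule.window_mask(*late_window)
    if not mask.any():
        raise InsufficientDataError(
            f"no frames with mid-time in [{late_window[0]}, {late_window[1]}] min"
        )
    ca = float(np.mean(idif.value[mask]))
    if ca <= 0:
        raise ValidationError("non-positive terminal blood concentration")
    t_end = min(TRUNCATION_MIN, float(idif.schedule.end[-1]))
    auc = auc_trapezoid(idif, p.t_appear, t_end, t_anchor=p.t_appear)
    recov = [100.0 * auc_analytic(p, p.t_appear, t_end, n) / auc for n in (1, 2, 3)]
    return InputMetrics(
        auc_0_67=auc,
        ca_52_67=ca,
        theta_52_67=auc / ca,
        lambda3_tail=p.lambda3,
        c_tail=p.C,
        recovery_mono=recov[0],
        recovery_bi=recov[1],
        recovery_tri=recov[2],
    )
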