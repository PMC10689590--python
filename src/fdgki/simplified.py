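"""Single-time-point Ki estimators and their evaluation vs the full IDIF.

All four simplified methods share the same core: estimate the normalized
arterial input theta(52-67 min) from a late or single-frame measurement,
then obtain Ki as a two-point Patlak line through the population ordinate
intercept (0, V_D) and the late point (theta, V_T). They differ only in
how theta is estimated:

* Method 1 — semi-log fit of the late blood curve (35-67 min) gives the
  terminal phase C e^(-lambda3 t); its analytic AUC, scaled by the
  population mean fraction of the total AUC carried by that phase
  (~85%), estimates the full plasma integral, hence theta = AUC / Ca.
* Method 2 — site regression of AUC(0-67) on the terminal blood
  concentration Ca(52-67) estimates the AUC from a single late frame.
* Method 3 — site regression of theta on the individual lambda3.
* Method 4 — site regression of theta on subject age: no blood kinetics
  needed at all, one late PET frame suffices.

Accuracy is summarized as the percentage error of each method's Ki
relative to the full-IDIF multi-frame Patlak estimate,
100 * (method - reference) / reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import CalibrationDomainError, CalibrationUnitsError, ValidationError
from .input_kinetics import (
    DEFAULT_TAIL_WINDOW,
    LATE_WINDOW,
    TriExpParams,
    auc_analytic,
    fit_loglinear_tail,
)
from .patlak import distribution_volume_late, patlak_full, patlak_two_point
from .tac import SubjectRecord, TimeActivityCurve

#: Assumed appearance time (minutes) when extrapolating the terminal phase
#: in protocols with no measured early frames (Method 1).
DEFAULT_T_APPEAR = 0.5

METHOD_NAMES = ("full", "m1", "m2", "m3", "m4")


@dataclass(frozen=True)
class LinearModel:
    """A fitted simple regression y = slope * x + intercept."""

    slope: float
    intercept: float

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept}

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(slope=float(d["slope"]), intercept=float(d["intercept"]))


@dataclass(frozen=True)
class SiteCalibration:
    """Population calibration for one scanning site.

    Carries the population ordinate intercept ``v_d`` (mL/g), the mean
    fraction ``recovery_late`` of the total plasma integral recovered by
    the terminal exponential phase, and four simple regressions relating
    late-recording observables to the full-recording AUC and theta.
    ``units_note`` binds the AUC-vs-Ca regression (whose coefficients are
    not scale-free) to the concentration scale it was fitted on.
    """

    site: str
    v_d: float
    recovery_late: float
    auc_vs_ca: LinearModel
    theta_vs_lambda3: LinearModel
    theta_vs_age: LinearModel
    lambda3_vs_age: LinearModel
    units_note: str = ""
    fit_stats: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not 0 < self.recovery_late < 1:
            raise ValidationError("recovery_late must be a fraction in (0, 1)")
        if not self.v_d > 0:
            raise ValidationError("v_d must be positive")
        for age in (18.0, 95.0):
            if self.theta_vs_age.predict(age) <= 0:
                raise ValidationError("theta-vs-age line non-positive in adult range")
        for lam in (0.004, 0.02):
            if self.theta_vs_lambda3.predict(lam) <= 0:
                raise ValidationError(
                    "theta-vs-lambda3 line non-positive in physiological range"
                )

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "v_d": self.v_d,
            "recovery_late": self.recovery_late,
            "auc_vs_ca": self.auc_vs_ca.to_dict(),
            "theta_vs_lambda3": self.theta_vs_lambda3.to_dict(),
            "theta_vs_age": self.theta_vs_age.to_dict(),
            "lambda3_vs_age": self.lambda3_vs_age.to_dict(),
            "units_note": self.units_note,
            "fit_stats": self.fit_stats,
            "schema_version": 1,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SiteCalibration":
        return cls(
            site=str(d["site"]),
            v_d=float(d["v_d"]),
            recovery_late=float(d["recovery_late"]),
            auc_vs_ca=LinearModel.from_dict(d["auc_vs_ca"]),
            theta_vs_lambda3=LinearModel.from_dict(d["theta_vs_lambda3"]),
            theta_vs_age=LinearModel.from_dict(d["theta_vs_age"]),
            lambda3_vs_age=LinearModel.from_dict(d["lambda3_vs_age"]),
            units_note=str(d.get("units_note", "")),
            fit_stats=dict(d.get("fit_stats", {})),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "SiteCalibration":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def load_site_calibration(site: str) -> SiteCalibration:
    """Load a shipped default calibration (``"aarhus"`` or ``"bern"``)."""
    name = site.strip().lower()
    if name not in ("aarhus", "bern"):
        raise ValidationError(f"no shipped calibration for site {site!r}")
    payload = resources.files("fdgki.data").joinpath(f"{name}.json").read_text()
    return SiteCalibration.from_dict(json.loads(payload))


@dataclass(frozen=True)
class MethodResult:
    """A single Ki estimate with its provenance."""

    method: str  # full | m1 | m2 | m3 | m4
    region: str  # GM | WM
    ki: float
    theta_used: float
    inputs_used: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.ki):
            raise ValidationError("non-finite ki")
        if not self.theta_used > 0:
            raise ValidationError("theta_used must be positive")


def method1(
    idif_late: TimeActivityCurve,
    ca_late: float,
    v_t_late: float,
    cal: SiteCalibration,
    *,
    region: str = "GM",
    tail_window: tuple[float, float] = DEFAULT_TAIL_WINDOW,
    t_appear: float = DEFAULT_T_APPEAR,
    t_end: float = 67.0,
) -> MethodResult:
    """Ki from the late blood curve via the terminal-phase AUC fraction.

    The semi-log tail fit gives C e^(-lambda3 t); its analytic integral
    from the (assumed) appearance time to the end of the recording, divided
    by the population recovery fraction, estimates the full plasma
    integral.
    """
    if ca_late <= 0:
        raise ValidationError("ca_late must be positive")
    c_tail, lam3 = fit_loglinear_tail(idif_late, tail_window)
    mono = TriExpParams(
        A=0.0, B=0.0, C=c_tail,
        lambda1=100.0 * lam3, lambda2=10.0 * lam3, lambda3=lam3,
        t_appear=t_appear,
    )
    auc_tail = auc_analytic(mono, t_appear, t_end, n_terms=1)
    auc_full = auc_tail / cal.recovery_late
    theta = auc_full / ca_late
    ki = patlak_two_point(v_t_late, theta, cal.v_d)
    return MethodResult(
        method="m1",
        region=region,
        ki=ki,
        theta_used=theta,
        inputs_used={
            "c_tail": c_tail,
            "lambda3": lam3,
            "auc_tail": auc_tail,
            "recovery_late": cal.recovery_late,
            "ca_late": ca_late,
            "v_t_late": v_t_late,
            "v_d": cal.v_d,
        },
    )


def method2(
    ca_late: float,
    v_t_late: float,
    cal: SiteCalibration,
    *,
    region: str = "GM",
) -> MethodResult:
    """Ki from the single-frame blood concentration via the AUC-vs-Ca line."""
    if ca_late <= 0:
        raise ValidationError("ca_late must be positive")
    auc_est = cal.auc_vs_ca.predict(ca_late)
    if auc_est <= 0:
        raise CalibrationDomainError("AUC-vs-Ca regression predicts non-positive AUC")
    theta = auc_est / ca_late
    ki = patlak_two_point(v_t_late, theta, cal.v_d)
    return MethodResult(
        method="m2",
        region=region,
        ki=ki,
        theta_used=theta,
        inputs_used={"ca_late": ca_late, "auc_est": auc_est,
                     "v_t_late": v_t_late, "v_d": cal.v_d},
    )


def method3(
    lambda3: float,
    v_t_late: float,
    cal: SiteCalibration,
    *,
    region: str = "GM",
) -> MethodResult:
    """Ki from the individual terminal elimination rate via theta-vs-lambda3."""
    if lambda3 <= 0:
        raise ValidationError("lambda3 must be positive")
    theta = cal.theta_vs_lambda3.predict(lambda3)
    if theta <= 0:
        raise CalibrationDomainError("theta-vs-lambda3 regression predicts theta <= 0")
    ki = patlak_two_point(v_t_late, theta, cal.v_d)
    return MethodResult(
        method="m3",
        region=region,
        ki=ki,
        theta_used=theta,
        inputs_used={"lambda3": lambda3, "v_t_late": v_t_late, "v_d": cal.v_d},
    )


def method4(
    age: float,
    v_t_late: float,
    cal: SiteCalibration,
    *,
    region: str = "GM",
) -> MethodResult:
    """Ki from subject age alone via the theta-vs-age site regression."""
    if age <= 0:
        raise ValidationError("age must be positive")
    theta = cal.theta_vs_age.predict(age)
    if theta <= 0:
        raise CalibrationDomainError("theta-vs-age regression predicts theta <= 0")
    ki = patlak_two_point(v_t_late, theta, cal.v_d)
    return MethodResult(
        method="m4",
        region=region,
        ki=ki,
        theta_used=theta,
        inputs_used={"age": age, "v_t_late": v_t_late, "v_d": cal.v_d},
    )


def percent_error(method_ki: float, reference_ki: float) -> float:
    """Percentage error of a simplified estimate vs the full-IDIF reference."""
    if reference_ki == 0:
        raise ValidationError("reference ki must be non-zero")
    return 100.0 * (method_ki - reference_ki) / reference_ki


def _check_units(cal: SiteCalibration, tac: TimeActivityCurve) -> None:
    if cal.units_note and tac.units and cal.units_note != tac.units:
        raise CalibrationUnitsError(
            f"calibration is unit-bound to {cal.units_note!r} but the TAC carries "
            f"{tac.units!r}; the AUC-vs-Ca coefficients are not scale-free"
        )


def quantify_subject(
    subject: SubjectRecord,
    cal: SiteCalibration,
    methods: tuple[str, ...] = METHOD_NAMES,
    *,
    tail_window: tuple[float, float] = DEFAULT_TAIL_WINDOW,
    late_window: tuple[float, float] = LATE_WINDOW,
    t_lo_full: float = 12.0,
) -> pd.DataFrame:
    """Run the requested estimators on both brain regions of one subject.

    Returns one row per region x method with columns ``subject_id, region,
    method, ki, theta_used, pct_error_vs_full`` (the last is NaN when the
    full reference was not requested).
    """
    unknown = set(methods) - set(METHOD_NAMES)
    if unknown:
        raise ValidationError(f"unknown methods: {sorted(unknown)}")
    idif = subject.idif
    ca_mask = idif.schedule.window_mask(*late_window)
    ca_late = float(np.mean(idif.value[ca_mask]))
    lam3 = None
    if "m1" in methods or "m3" in methods:
        _, lam3 = fit_loglinear_tail(idif, tail_window)
    rows = []
    for region, tissue in (("GM", subject.gm), ("WM", subject.wm)):
        v_t = distribution_volume_late(tissue, idif, late_window)
        full_ki = np.nan
        if "full" in methods:
            full = patlak_full(idif, tissue, t_lo=t_lo_full)
            full_ki = full.ki
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "region": region,
                    "method": "full",
                    "ki": full.ki,
                    "vd": full.vd,
                    "theta_used": np.nan,
                    "pct_error_vs_full": 0.0,
                }
            )
        for m in methods:
            if m == "full":
                continue
            if m == "m1":
                res = method1(idif, ca_late, v_t, cal, region=region,
                              tail_window=tail_window)
            elif m == "m2":
                _check_units(cal, idif)
                res = method2(ca_late, v_t, cal, region=region)
            elif m == "m3":
                res = method3(lam3, v_t, cal, region=region)
            else:
                res = method4(subject.age, v_t, cal, region=region)
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "region": region,
                    "method": m,
                    "ki": res.ki,
                    "vd": cal.v_d,
                    "theta_used": res.theta_used,
                    "pct_error_vs_full": (
                        percent_error(res.ki, full_ki) if np.isfinite(full_ki) else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def quantify_cohort(
    subjects: list[SubjectRecord],
    cal: SiteCalibration,
    methods: tuple[str, ...] = METHOD_NAMES,
    **kwargs,
) -> pd.DataFrame:
    """Concatenate :func:`quantify_subject` over a cohort."""
    frames = [quantify_subject(s, cal, methods, **kwargs) for s in subjects]
    return pd.concat(frames, ignore_index=True)
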