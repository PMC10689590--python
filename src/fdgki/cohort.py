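"""Synthetic cohorts: virtual subjects with known ground-truth kinetics.

No patient data ship with this package. Instead, virtual subjects are
generated from the same models the analysis assumes, plus realistic frame
schedules and multiplicative measurement noise:

* the arterial input is a tri-exponential with an appearance delay; the
  terminal elimination rate lambda3 follows a site-specific linear
  age-dependence with Gaussian scatter;
* gray- and white-matter curves follow the irreversible two-tissue
  compartment model, C_T = Ca (*) h with impulse response
  h(t) = K1/(k2+k3) * [k3 + k2 e^(-(k2+k3) t)], whose closed-form
  net influx Ki = K1*k3/(k2+k3) and free distribution volume V_D = K1/k2
  form the truth table against which every estimator is judged;
* frame values are analytic frame averages (as PET reconstructs them),
  multiplied by lognormal noise of fixed coefficient of variation; the
  analysis side deliberately keeps its mid-time convention, mirroring the
  mismatch present in real framed acquisitions.

Default population parameters target terminal-phase behaviour typical of
adult oncology cohorts: mean lambda3 near 0.012 (Aarhus-like ages) or
0.0095 per min (Bern-like), terminal-window theta near 110 / 103 min, and
a terminal-phase AUC share in the mid-80s of percent. Amplitudes and the
two fast rate constants are not identifiable from published summary
statistics; their defaults are stated assumptions (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .input_kinetics import LATE_WINDOW, TriExpParams, auc_analytic
from .schedules import SITE_SCHEDULES
from .simplified import SiteCalibration
from .tac import FrameSchedule, SubjectRecord, TimeActivityCurve

_MAX_REJECTION_TRIES = 1000

#: Physiological lower bound on the terminal elimination rate (1/min).
LAMBDA3_FLOOR = 0.002


@dataclass(frozen=True)
class TwoTCParams:
    """Irreversible two-tissue compartment parameters for one region."""

    K1: float  # mL/g/min, unidirectional blood-brain clearance
    k2: float  # 1/min, efflux from the free compartment
    k3: float  # 1/min, phosphorylation (trapping) rate
    region: str = "GM"

    def __post_init__(self) -> None:
        if min(self.K1, self.k2) <= 0 or self.k3 < 0:
            raise ValidationError("K1, k2 must be positive and k3 non-negative")
        if self.k3 > 0 and not 0.005 <= self.ki_true <= 0.06:
            raise ValidationError(f"implied Ki {self.ki_true:.4g} outside [0.005, 0.06]")
        if not 0.3 <= self.vd_true <= 0.8:
            raise ValidationError(f"implied V_D {self.vd_true:.3g} outside [0.3, 0.8]")

    @property
    def ki_true(self) -> float:
        """Closed-form net influx K1*k3/(k2+k3)."""
        return self.K1 * self.k3 / (self.k2 + self.k3)

    @property
    def vd_true(self) -> float:
        """Free distribution volume K1/k2."""
        return self.K1 / self.k2


@dataclass(frozen=True)
class LognormalSpec:
    """A lognormal draw specified by its mean and coefficient of variation."""

    mean: float
    cv: float

    def draw(self, rng: np.random.Generator) -> float:
        if self.cv == 0:
            return self.mean
        sigma = float(np.sqrt(np.log1p(self.cv**2)))
        return float(self.mean * np.exp(rng.normal(-0.5 * sigma**2, sigma)))


@dataclass
class CohortGenParams:
    """Population distributions for one simulated site."""

    n_subjects: int
    site: str
    seed: int
    age_mean: float
    age_sd: float
    lambda3_slope: float  # per min per year
    lambda3_intercept: float  # per min
    lambda3_scatter_sd: float  # per min, residual scatter around the age line
    t_appear_mean: float  # min
    t_appear_sd: float
    amp_a: LognormalSpec
    rate1: LognormalSpec
    amp_b: LognormalSpec
    rate2: LognormalSpec
    amp_c: LognormalSpec
    gm: dict = field(default_factory=dict)  # K1/k2/k3 -> LognormalSpec
    wm: dict = field(default_factory=dict)
    noise_cv: float = 0.03
    age_range: tuple[float, float] = (18.0, 95.0)

    @classmethod
    def aarhus(cls, n_subjects: int = 52, seed: int = 0, noise_cv: float = 0.03):
        return cls(
            n_subjects=n_subjects,
            site="Aarhus",
            seed=seed,
            age_mean=56.5,
            age_sd=14.1,
            lambda3_slope=-9.36e-05,
            lambda3_intercept=0.0174,
            lambda3_scatter_sd=0.00224,
            t_appear_mean=0.24,
            t_appear_sd=0.05,
            amp_a=LognormalSpec(75.0, 0.30),
            rate1=LognormalSpec(3.5, 0.25),
            amp_b=LognormalSpec(5.0, 0.25),
            rate2=LognormalSpec(0.15, 0.20),
            amp_c=LognormalSpec(5.0, 0.15),
            gm={
                "K1": LognormalSpec(0.10, 0.20),
                "k2": LognormalSpec(0.18, 0.15),
                "k3": LognormalSpec(0.097, 0.25),
            },
            wm={
                "K1": LognormalSpec(0.050, 0.20),
                "k2": LognormalSpec(0.098, 0.15),
                "k3": LognormalSpec(0.039, 0.25),
            },
            noise_cv=noise_cv,
        )

    @classmethod
    def bern(cls, n_subjects: int = 24, seed: int = 0, noise_cv: float = 0.03):
        return cls(
            n_subjects=n_subjects,
            site="Bern",
            seed=seed,
            age_mean=59.7,
            age_sd=15.2,
            lambda3_slope=0.0,
            lambda3_intercept=0.00946,
            lambda3_scatter_sd=0.0019,
            t_appear_mean=0.51,
            t_appear_sd=0.11,
            amp_a=LognormalSpec(120.0, 0.30),
            rate1=LognormalSpec(4.0, 0.25),
            amp_b=LognormalSpec(7.2, 0.25),
            rate2=LognormalSpec(0.15, 0.20),
            amp_c=LognormalSpec(5.0, 0.15),
            gm={
                "K1": LognormalSpec(0.10, 0.20),
                "k2": LognormalSpec(0.18, 0.15),
                "k3": LognormalSpec(0.097, 0.25),
            },
            wm={
                "K1": LognormalSpec(0.050, 0.20),
                "k2": LognormalSpec(0.098, 0.15),
                "k3": LognormalSpec(0.039, 0.25),
            },
            noise_cv=noise_cv,
        )

    @classmethod
    def for_site(cls, site: str, **kwargs) -> "CohortGenParams":
        name = site.strip().lower()
        if name == "aarhus":
            return cls.aarhus(**kwargs)
        if name == "bern":
            return cls.bern(**kwargs)
        raise ValidationError(f"unknown site template {site!r}")


def lambda3_of_age(age: float, cal: SiteCalibration, floor: float = LAMBDA3_FLOOR) -> float:
    """Terminal elimination rate predicted from age, floored physiologically."""
    if age <= 0:
        raise ValidationError("age must be positive")
    return max(floor, cal.lambda3_vs_age.predict(age))


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _noise(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Unit-mean lognormal multiplicative noise with the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))


def input_frame_averages(p: TriExpParams, schedule: FrameSchedule) -> np.ndarray:
    """Analytic frame averages of the tri-exponential input.

    Each frame value is the integral of the model over [start, end] divided
    by the full frame duration; frames wholly before the appearance time
    are zero, frames straddling it integrate only the live part.
    """
    lo = np.maximum(schedule.start, p.t_appear)
    hi = schedule.end
    out = np.zeros(len(schedule))
    live = hi > p.t_appear
    for amp, lam in p.terms:
        if amp > 0:
            seg = (amp / lam) * (np.exp(-lam * lo[live]) - np.exp(-lam * hi[live]))
            out[live] += seg
    return out / schedule.duration


def _tissue_pieces(p: TriExpParams, q: TwoTCParams):
    """Closed-form convolution of the input with the irreversible 2TC kernel.

    In appearance-origin time u = t - t_appear the tissue curve is a sum of
    a constant, the input exponentials, and one e^(-(k2+k3)u) term per
    input exponential. Returns (constant, [(coef, rate), ...]).
    """
    beta = q.k2 + q.k3
    const = 0.0
    expo: list[tuple[float, float]] = []
    for amp, lam in p.terms:
        if amp <= 0:
            continue
        c = amp * np.exp(-lam * p.t_appear)  # appearance-origin amplitude
        denom = beta - lam
        if abs(denom) < 1e-12 * beta:
            lam = lam * (1 + 1e-9)  # nudge off the degenerate resonance
            denom = beta - lam
        const += c * q.K1 * q.k3 / (beta * lam)
        expo.append((c * q.K1 / beta * (q.k2 / denom - q.k3 / lam), lam))
        expo.append((-c * q.K1 * q.k2 / (beta * denom), beta))
    return const, expo


def tissue_frame_averages(
    p: TriExpParams, q: TwoTCParams, schedule: FrameSchedule
) -> np.ndarray:
    """Analytic frame averages of the noiseless 2TC tissue curve."""
    const, expo = _tissue_pieces(p, q)
    lo = np.maximum(schedule.start, p.t_appear) - p.t_appear
    hi = schedule.end - p.t_appear
    out = np.zeros(len(schedule))
    live = hi > 0
    out[live] = const * (hi[live] - lo[live])
    for coef, rate in expo:
        out[live] += (coef / rate) * (np.exp(-rate * lo[live]) - np.exp(-rate * hi[live]))
    return out / schedule.duration


def simulate_idif(
    p: TriExpParams,
    schedule: FrameSchedule,
    noise_cv: float = 0.0,
    seed=0,
    subject_id: str = "",
    units: str = "sim-arb",
) -> TimeActivityCurve:
    """Simulate a framed IDIF: analytic frame averages x lognormal noise."""
    rng = _as_rng(seed)
    values = input_frame_averages(p, schedule) * _noise(rng, len(schedule), noise_cv)
    return TimeActivityCurve(
        schedule=schedule, value=values, label="blood", subject_id=subject_id, units=units
    )


def simulate_tissue(
    p: TriExpParams,
    q: TwoTCParams,
    schedule: FrameSchedule,
    noise_cv: float = 0.0,
    seed=0,
    subject_id: str = "",
    units: str = "sim-arb",
) -> TimeActivityCurve:
    """Simulate a framed tissue curve from the irreversible 2TC model."""
    rng = _as_rng(seed)
    values = tissue_frame_averages(p, q, schedule) * _noise(rng, len(schedule), noise_cv)
    return TimeActivityCurve(
        schedule=schedule, value=values, label=q.region, subject_id=subject_id, units=units
    )


def _draw_2tc(spec: dict, region: str, rng: np.random.Generator) -> TwoTCParams:
    for _ in range(_MAX_REJECTION_TRIES):
        try:
            return TwoTCParams(
                K1=spec["K1"].draw(rng),
                k2=spec["k2"].draw(rng),
                k3=spec["k3"].draw(rng),
                region=region,
            )
        except ValidationError:
            continue
    raise ValidationError(f"2TC rejection sampling exhausted for {region}")


def _draw_triexp(g: CohortGenParams, age: float, rng: np.random.Generator) -> TriExpParams:
    for _ in range(_MAX_REJECTION_TRIES):
        lam3 = max(
            LAMBDA3_FLOOR,
            g.lambda3_slope * age + g.lambda3_intercept
            + rng.normal(0.0, g.lambda3_scatter_sd),
        )
        t_appear = max(0.05, rng.normal(g.t_appear_mean, g.t_appear_sd))
        try:
            return TriExpParams(
                A=g.amp_a.draw(rng),
                B=g.amp_b.draw(rng),
                C=g.amp_c.draw(rng),
                lambda1=g.rate1.draw(rng),
                lambda2=g.rate2.draw(rng),
                lambda3=lam3,
                t_appear=t_appear,
            )
        except ValidationError:
            continue
    raise ValidationError("input-function rejection sampling exhausted")


def generate_cohort(g: CohortGenParams) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate a cohort and its ground-truth table.

    Returns the subject records (noisy framed TACs) and one truth row per
    subject holding the generating parameters and the noiseless late-frame
    quantities: the analytic plasma integral, terminal concentration and
    theta, plus closed-form Ki and V_D per region.
    """
    rng = np.random.default_rng(g.seed)
    schedule = SITE_SCHEDULES[g.site]()
    late_mask = schedule.window_mask(*LATE_WINDOW)
    subjects: list[SubjectRecord] = []
    truth_rows = []
    for i in range(g.n_subjects):
        subject_id = f"{g.site.lower()}-{i + 1:03d}"
        for _ in range(_MAX_REJECTION_TRIES):
            age = rng.normal(g.age_mean, g.age_sd)
            if g.age_range[0] <= age <= g.age_range[1]:
                break
        else:
            raise ValidationError("age rejection sampling exhausted")
        p = _draw_triexp(g, age, rng)
        gm_q = _draw_2tc(g.gm, "GM", rng)
        wm_q = _draw_2tc(g.wm, "WM", rng)
        idif = simulate_idif(p, schedule, g.noise_cv, rng, subject_id)
        gm = simulate_tissue(p, gm_q, schedule, g.noise_cv, rng, subject_id)
        wm = simulate_tissue(p, wm_q, schedule, g.noise_cv, rng, subject_id)
        subjects.append(
            SubjectRecord(subject_id=subject_id, age=float(age), site=g.site,
                          idif=idif, gm=gm, wm=wm)
        )
        clean_idif = input_frame_averages(p, schedule)
        ca_true = float(np.mean(clean_idif[late_mask]))
        auc_true = auc_analytic(p, p.t_appear, float(schedule.end[-1]))
        gm_clean = tissue_frame_averages(p, gm_q, schedule)
        wm_clean = tissue_frame_averages(p, wm_q, schedule)
        truth_rows.append(
            {
                "subject_id": subject_id,
                "age": float(age),
                "site": g.site,
                "t_appear": p.t_appear,
                "A": p.A, "B": p.B, "C": p.C,
                "lambda1": p.lambda1, "lambda2": p.lambda2, "lambda3": p.lambda3,
                "auc_true": auc_true,
                "ca_true": ca_true,
                "theta_true": auc_true / ca_true,
                "ki_gm_true": gm_q.ki_true,
                "vd_gm_true": gm_q.vd_true,
                "ki_wm_true": wm_q.ki_true,
                "vd_wm_true": wm_q.vd_true,
                "vt_gm_true": float(np.mean(gm_clean[late_mask])) / ca_true,
                "vt_wm_true": float(np.mean(wm_clean[late_mask])) / ca_true,
            }
        )
    return subjects, pd.DataFrame(truth_rows)
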