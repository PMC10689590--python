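"""Population calibration: cohort regressions and the correlation matrix.

Given a cohort of decomposed IDIFs, this module fits the simple
regressions that power the simplified Ki estimators (AUC vs Ca, theta vs
lambda3, theta vs age, lambda3 vs age), computes the cohort-mean fraction
of the plasma integral carried by the terminal phase, and tabulates the
Pearson correlation matrix over the pharmacokinetic parameter set
{A, lambda1, B, lambda2, C, lambda3, AUC, Ca, theta, age}.

P-values are two-sided from the t distribution with n-2 df and reported
uncorrected; significance tiers are flagged at 0.05, 0.002, 0.0002 and
1e-5 so users can judge which correlations would survive a correction for
the number of pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .input_kinetics import compute_metrics, decompose_triexp
from .simplified import LinearModel, SiteCalibration
from .tac import SubjectRecord

#: Required columns of a cohort parameter table.
TABLE_COLUMNS = (
    "subject_id",
    "age",
    "A",
    "B",
    "C",
    "lambda1",
    "lambda2",
    "lambda3",
    "auc_0_67",
    "ca_52_67",
    "theta_52_67",
    "recovery_mono",
    "recovery_bi",
    "recovery_tri",
)

#: Variables entering the correlation matrix, in display order.
CORRELATION_VARS = (
    "A",
    "lambda1",
    "B",
    "lambda2",
    "C",
    "lambda3",
    "auc_0_67",
    "ca_52_67",
    "theta_52_67",
    "age",
)

#: Uncorrected significance tiers and their star flags.
SIGNIFICANCE_TIERS = ((1e-5, "#"), (2e-4, "***"), (2e-3, "**"), (0.05, "*"))


def cohort_parameter_table(subjects: list[SubjectRecord], **decompose_kwargs) -> pd.DataFrame:
    """Decompose every subject's IDIF and tabulate the kinetic parameters."""
    rows = []
    for s in subjects:
        p = decompose_triexp(s.idif, **decompose_kwargs)
        m = compute_metrics(s.idif, p)
        rows.append(
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "A": p.A,
                "B": p.B,
                "C": p.C,
                "lambda1": p.lambda1,
                "lambda2": p.lambda2,
                "lambda3": p.lambda3,
                **m.to_dict(),
            }
        )
    df = pd.DataFrame(rows)
    return df[[c for c in TABLE_COLUMNS if c in df.columns]
              + [c for c in df.columns if c not in TABLE_COLUMNS]]


def _validate_table(table: pd.DataFrame, n_min: int) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns {missing}")
    if len(table) < n_min:
        raise InsufficientDataError(f"need at least {n_min} subjects, got {len(table)}")
    core = table[[c for c in TABLE_COLUMNS if c != "subject_id"]]
    if core.isna().any().any():
        raise ValidationError("cohort table contains missing values")


def _regress(table: pd.DataFrame, x: str, y: str) -> tuple[LinearModel, dict]:
    xv = table[x].to_numpy(dtype=float)
    yv = table[y].to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise ValidationError(f"degenerate predictor variance in {y} ~ {x}")
    fit = stats.linregress(xv, yv)
    model = LinearModel(slope=float(fit.slope), intercept=float(fit.intercept))
    return model, {"r": float(fit.rvalue), "p": float(fit.pvalue), "n": int(len(xv))}


def fit_site_calibration(
    table: pd.DataFrame,
    v_d: float = 0.55,
    site: str = "custom",
    units_note: str = "",
) -> SiteCalibration:
    """Fit the four site regressions and the terminal AUC recovery fraction.

    Per-regression Pearson r and two-sided p land in
    ``SiteCalibration.fit_stats``.
    """
    _validate_table(table, n_min=3)
    stats_out: dict[str, dict] = {}
    auc_vs_ca, stats_out["auc_vs_ca"] = _regress(table, "ca_52_67", "auc_0_67")
    theta_vs_lam3, stats_out["theta_vs_lambda3"] = _regress(table, "lambda3", "theta_52_67")
    theta_vs_age, stats_out["theta_vs_age"] = _regress(table, "age", "theta_52_67")
    lam3_vs_age, stats_out["lambda3_vs_age"] = _regress(table, "age", "lambda3")
    return SiteCalibration(
        site=site,
        v_d=v_d,
        recovery_late=float(table["recovery_mono"].mean()) / 100.0,
        auc_vs_ca=auc_vs_ca,
        theta_vs_lambda3=theta_vs_lam3,
        theta_vs_age=theta_vs_age,
        lambda3_vs_age=lam3_vs_age,
        units_note=units_note,
        fit_stats=stats_out,
    )


def significance_flag(p: float) -> str:
    """Star flag for an uncorrected two-sided p-value."""
    if not np.isfinite(p):
        return ""
    for threshold, flag in SIGNIFICANCE_TIERS:
        if p < threshold:
            return flag
    return ""


def correlation_matrix(
    table: pd.DataFrame,
    variables: tuple[str, ...] = CORRELATION_VARS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of the pharmacokinetic parameters.

    Returns ``(r, p, flags)`` DataFrames indexed by variable. A constant
    column yields NaN r/p (correlation undefined) for its pairs.
    """
    if len(table) < 4:
        raise InsufficientDataError("correlation matrix needs n >= 4")
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValidationError(f"table missing variables {missing}")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi = table[variables[i]].to_numpy(dtype=float)
            xj = table[variables[j]].to_numpy(dtype=float)
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = list(variables)
    r_df = pd.DataFrame(r, index=idx, columns=idx)
    p_df = pd.DataFrame(p, index=idx, columns=idx)
    flags = p_df.map(significance_flag)
    np.fill_diagonal(flags.values, "")
    return r_df, p_df, flags
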