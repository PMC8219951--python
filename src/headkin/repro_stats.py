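"""Reproducibility and transfer statistics.

Implements the study's statistics layer: coefficient of variation with the
industry reproducibility bands (good < 5%, acceptable 5-10%, marginal
10-20%), percent transfer / percent change headline metrics, paired t-tests
with change-score effect sizes, single-case ("one-vs-many") t-tests, Pearson
correlations, and the ordinary-least-squares regressions of histology
outcomes on kinematics.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateGroupError,
    InsufficientDataError,
    InvalidSpecError,
    UndefinedStatError,
)
from .kinmetrics import KinematicSummary

log = logging.getLogger(__name__)

GRADES = ("good", "acceptable", "marginal", "poor")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the tabulated-report convention).

    numpy/python round() rounds half to even; printed tables round half up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def cov(mean_or_sample, sd: float | None = None) -> float:
    """Coefficient of variation, percent: 100 x SD / mean.

    Accepts either ``(mean, sd)`` or a raw sample (SD computed with n-1
    denominator).  Undefined for non-positive means.
    """
    if sd is None:
        sample = np.asarray(mean_or_sample, dtype=float)
        if sample.size < 2:
            raise InsufficientDataError("need at least two observations for a COV")
        m = float(np.mean(sample))
        s = float(np.std(sample, ddof=1))
    else:
        m, s = float(mean_or_sample), float(sd)
    if s < 0:
        raise InvalidSpecError("sd must be non-negative")
    if m <= 0:
        raise UndefinedStatError("COV undefined for mean <= 0")
    return 100.0 * s / m


def grade_cov(cov_pct: float) -> str:
    """Reproducibility band for a COV: good, acceptable, marginal, or poor.

    The published scale stops at 20%; larger values get an explicit
    out-of-band ``poor`` label rather than a forced ``marginal``.
    """
    if cov_pct < 0:
        raise InvalidSpecError("COV cannot be negative")
    if cov_pct < 5:
        return "good"
    if cov_pct <= 10:
        return "acceptable"
    if cov_pct <= 20:
        return "marginal"
    log.info("COV %.1f%% exceeds the published 20%% band edge; labelling 'poor'", cov_pct)
    return "poor"


def percent_transfer(numerator_mean: float, denominator_mean: float) -> float:
    """100 x a / b (full precision; round for headline parity)."""
    if denominator_mean == 0:
        raise UndefinedStatError("percent transfer undefined for zero denominator")
    return 100.0 * numerator_mean / denominator_mean


def percent_change(later: float, earlier: float) -> float:
    """100 x (a - b) / b (full precision; round for headline parity)."""
    if earlier == 0:
        raise UndefinedStatError("percent change undefined for zero baseline")
    return 100.0 * (later - earlier) / earlier


@dataclass
class ComparisonResult:
    t: float
    df: int
    p: float
    effect_size: float
    effect_size_method: str
    mean_pct_difference: float
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def paired_t(x, y) -> ComparisonResult:
    """Two-sided paired t-test on per-animal differences ``x - y``.

    Effect sizes: ``d_z`` (mean difference over SD of differences) always,
    plus the independent-groups conversion ``d_z * sqrt(2 (1 - r))`` using
    the measured cross-condition correlation r (reported in ``extra``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidSpecError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise InsufficientDataError("paired t needs n >= 2")
    d = x - y
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    df = n - 1
    if sd_d == 0:
        t_stat = 0.0 if mean_d == 0 else np.inf * np.sign(mean_d)
    else:
        t_stat = mean_d / (sd_d / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t_stat), df)) if np.isfinite(t_stat) else 0.0
    d_z = mean_d / sd_d if sd_d > 0 else 0.0
    extra = {}
    if n >= 3 and np.std(x) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(x, y)[0, 1])
        extra["cross_condition_r"] = r
        extra["d_independent_groups"] = d_z * float(np.sqrt(max(0.0, 2.0 * (1.0 - r))))
    mean_pct = percent_change(float(np.mean(x)), float(np.mean(y))) if np.mean(y) != 0 else np.nan
    return ComparisonResult(float(t_stat), df, p, float(d_z), "d_z = mean_diff/sd_diff",
                            float(mean_pct), extra)


def one_vs_many_t(x_star: float, group) -> ComparisonResult:
    """Single-case comparison of one value against a control sample.

    ``t = (x* - mean) / (sd * sqrt(1 + 1/n))`` with ``df = n - 1`` and an
    uncorrected two-sided p (the liberal convention for declaring
    single-subject replication).
    """
    g = np.asarray(group, dtype=float)
    if g.size < 2:
        raise InsufficientDataError("control sample needs n >= 2")
    m = float(np.mean(g))
    s = float(np.std(g, ddof=1))
    if s == 0:
        raise DegenerateGroupError("control sample has zero variance")
    n = g.size
    t_stat = (float(x_star) - m) / (s * np.sqrt(1.0 + 1.0 / n))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t_stat), df))
    eff = (float(x_star) - m) / s
    mean_pct = percent_change(float(x_star), m) if m != 0 else np.nan
    return ComparisonResult(float(t_stat), df, p, float(eff),
                            "(x* - mean)/sd", float(mean_pct))


def one_vs_many_t_vectorized(x_star: np.ndarray, mean: float, sd: float, n: int):
    """Array-valued single-case t and p against fixed control summaries."""
    if sd <= 0:
        raise DegenerateGroupError("control sample has zero variance")
    t_stat = (np.asarray(x_star, dtype=float) - mean) / (sd * np.sqrt(1.0 + 1.0 / n))
    p = 2.0 * sps.t.sf(np.abs(t_stat), n - 1)
    return t_stat, p


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with the t-based two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("pearson needs paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class RegressionResult:
    f: float
    p: float
    r_squared: float
    n: int
    df_model: int
    df_resid: int
    params: dict


def kinematics_pathology_regression(peaks, fwhms, outcome) -> RegressionResult:
    """OLS of a histology outcome on peak angular velocity and FWHM.

    Two predictors plus intercept; reports the omnibus F on (2, n-3) degrees
    of freedom.  Collinear predictors trigger a rank-deficiency warning and a
    pseudo-inverse fit (statsmodels' default behaviour).
    """
    import statsmodels.api as sm

    peaks = np.asarray(peaks, dtype=float)
    fwhms = np.asarray(fwhms, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    n = outcome.size
    if peaks.size != n or fwhms.size != n:
        raise InvalidSpecError("predictors and outcome must have equal length")
    if n <= 3:
        raise InsufficientDataError("regression needs n > 3 (two predictors + intercept)")
    X = sm.add_constant(np.column_stack([peaks, fwhms]), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("collinear predictors: falling back to a pseudo-inverse fit",
                      RuntimeWarning, stacklevel=2)
    fit = sm.OLS(outcome, X).fit()
    return RegressionResult(
        f=float(fit.fvalue), p=float(fit.f_pvalue), r_squared=float(fit.rsquared),
        n=n, df_model=int(fit.df_model), df_resid=int(fit.df_resid),
        params={"intercept": float(fit.params[0]), "peak": float(fit.params[1]),
                "fwhm": float(fit.params[2])},
    )


@dataclass
class CohortStats:
    metric_name: str
    n: int
    mean: float
    sd: float
    cov: float
    grade: str

    def cell(self, decimals: int = 2) -> str:
        """Human-readable table cell: 'mean ± SD, COV%'."""
        return (f"{round_half_up(self.mean, decimals):.{decimals}f} ± "
                f"{round_half_up(self.sd, decimals):.{decimals}f}, "
                f"{round_half_up(self.cov, 1):.1f}%")


METRIC_COLUMNS = {
    "peak_angular_velocity": "Peak angular velocity (rad/s)",
    "fwhm_ms": "FWHM (ms)",
    "time_to_peak_ms": "Time to peak (ms)",
}
SENSOR_ORDER = ("machine", "skull_resultant", "skull_coronal")


def summaries_to_frame(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(s.to_dict() if isinstance(s, KinematicSummary) else dict(s))
    return pd.DataFrame(rows)


def cohort_table(summaries, by: str | dict | None = None) -> pd.DataFrame:
    """Mean ± SD and COV per metric x sensor (x experiment) in table layout.

    ``summaries`` is a collection of per-animal kinematic summaries (or an
    equivalent DataFrame); ``by`` optionally maps animal_id -> experiment
    label, or is a single label for the whole collection.  Cells with no
    observations are omitted with a warning.
    """
    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_to_frame(summaries)
    if df.empty:
        raise InsufficientDataError("no summaries supplied")
    if by is None:
        df = df.assign(experiment="all")
    elif isinstance(by, str):
        df = df.assign(experiment=by)
    else:
        df = df.assign(experiment=df["animal_id"].map(by))
    rows = []
    for (exp, sensor), sub in df.groupby(["experiment", "sensor"], sort=False):
        for metric, label in METRIC_COLUMNS.items():
            vals = sub[metric].dropna().to_numpy()
            if vals.size == 0:
                log.warning("empty cell: %s / %s / %s", exp, sensor, metric)
                continue
            m = float(np.mean(vals))
            s = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            c = cov(m, s)
            rows.append(
                {
                    "experiment": exp,
                    "sensor": sensor,
                    "metric": label,
                    "n": int(vals.size),
                    "mean": m,
                    "sd": s,
                    "cov_pct": round_half_up(c, 1),
                    "grade": grade_cov(c),
                }
            )
    out = pd.DataFrame(rows)
    sensor_rank = {s: i for i, s in enumerate(SENSOR_ORDER)}
    out = out.sort_values(
        ["experiment", "sensor", "metric"],
        key=lambda col: col.map(sensor_rank).fillna(0) if col.name == "sensor" else col,
        kind="stable",
    ).reset_index(drop=True)
    return out


def render_table(table: pd.DataFrame) -> str:
    """Human-readable rendering of the cohort table."""
    lines = []
    for exp, sub in table.groupby("experiment", sort=False):
        lines.append(f"Experiment {exp} (n = {int(sub['n'].max())})")
        pivot = sub.pivot_table(index="metric", columns="sensor",
                                values=["mean", "sd", "cov_pct"], aggfunc="first")
        for metric in sub["metric"].unique():
            cells = []
            for sensor in [s for s in SENSOR_ORDER if s in sub["sensor"].unique()]:
                m = pivot.loc[metric, ("mean", sensor)]
                s = pivot.loc[metric, ("sd", sensor)]
                c = pivot.loc[metric, ("cov_pct", sensor)]
                cells.append(f"{sensor}: {m:.2f} ± {s:.2f} ({c:.1f}%)")
            lines.append(f"  {metric:<32s} " + " | ".join(cells))
    return "\n".join(lines)
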