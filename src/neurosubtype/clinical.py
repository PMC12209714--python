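"""Clinical comparison statistics between patient subtypes.

Two-sample t-tests from raw scores or from published summary statistics
(mean/SD/n, or mean with a 95% confidence interval from which the SD is
recovered by inverting the CI formula), plus covariate-adjusted partial
correlations between regional volumes and clinical scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Published per-subtype summary statistics (mean, SD) of the reference
#: fibromyalgia cohort, n = 38 (subtype 1) vs n = 37 (subtype 2); used only
#: for consistency checks of the summary-based tests, never as machine
#: truth.
REFERENCE_SUBTYPE_SUMMARIES = {
    "age": ((43.3, 10.5, 38), (48.4, 10.1, 37)),
    "symptom_duration": ((79.7, 69.5, 38), (51.9, 48.9, 37)),
    "education_years": ((14.3, 3.1, 38), (13.5, 3.1, 37)),
    "pain_vas": ((6.1, 1.3, 38), (6.2, 1.8, 37)),
    "wpi": ((11.1, 3.9, 38), (11.3, 3.6, 37)),
    "mfi20": ((69.5, 12.9, 38), (65.6, 16.0, 37)),
    "psqi": ((11.9, 2.9, 38), (11.0, 3.7, 37)),
    "bdi2": ((9.6, 6.8, 38), (7.9, 7.1, 37)),
    "pss": ((30.7, 9.0, 38), (25.0, 9.3, 37)),
    "fiqr": ((43.4, 17.2, 38), (35.2, 20.1, 37)),
}


def ttest_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from per-group mean/SD/n; returns (t, df, p).

    Identical to the raw-data test on any samples having these summaries.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("SDs must be positive")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n_a + n_b - 2)
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return float(res.statistic), df, float(res.pvalue)


def sd_from_ci(mean: float, lo: float, hi: float, n: int, level: float = 0.95) -> float:
    """Recover a sample SD from a t-based confidence interval of the mean."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (lo <= mean <= hi):
        raise ValueError(f"CI [{lo}, {hi}] does not bracket its mean {mean}")
    half = (hi - lo) / 2.0
    tq = stats.t.ppf(0.5 + level / 2.0, n - 1)
    se = half / tq
    return se * np.sqrt(n)


def ttest_from_ci(
    mean_a: float, lo_a: float, hi_a: float, n_a: int,
    mean_b: float, lo_b: float, hi_b: float, n_b: int,
    variant: str = "pooled",
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Two-sample t-test from per-group mean and confidence interval.

    The per-group SE is the CI half-width divided by the t quantile at
    n-1 df; SD = SE * sqrt(n); then the summary-based test applies.  With
    published (rounded) CIs the result is approximate by construction.
    """
    sd_a = sd_from_ci(mean_a, lo_a, hi_a, n_a, level)
    sd_b = sd_from_ci(mean_b, lo_b, hi_b, n_b, level)
    return ttest_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b, variant=variant)


@dataclass
class PartialCorrelationResult:
    r: float
    n: int
    n_covariates: int
    p: float

    @property
    def df(self) -> int:
        return self.n - 2 - self.n_covariates


def partial_correlation(x, y, covariates=None) -> PartialCorrelationResult:
    """Pearson correlation of x and y after regressing out covariates.

    Both variables are residualized on the covariate set (with intercept)
    by least squares; p comes from t = r*sqrt(df/(1-r^2)) with
    df = n - 2 - n_covariates.  With an empty covariate set this is the
    plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = len(x)
    if covariates is None or (np.size(covariates) == 0):
        Z = np.ones((n, 1))
        n_cov = 0
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
        if Z.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
        n_cov = Z.shape[1]
        if any(np.std(Z[:, j]) == 0 for j in range(n_cov)):
            raise ValueError("constant covariate")
        if np.linalg.matrix_rank(Z) < n_cov:
            raise ValueError("perfectly collinear covariates")
        Z = np.column_stack([np.ones(n), Z])
    df = n - 2 - n_cov
    if df < 1:
        raise ValueError(f"insufficient degrees of freedom: n={n}, covariates={n_cov}")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(r=r, n=n, n_covariates=n_cov, p=p)


def compare_subtypes(
    scores: pd.DataFrame,
    subtype_labels: pd.DataFrame,
    measures: list[str] | None = None,
    variant: str = "pooled",
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-measure subtype comparison from raw clinical scores.

    ``scores`` has one row per patient (``subject_id`` plus measure
    columns); ``subtype_labels`` maps ``subject_id`` to an integer
    ``subtype``.  Returns one row per measure with group means/SDs/ns, the
    two-sample test, and the between-group difference with its confidence
    interval.
    """
    merged = scores.merge(subtype_labels, on="subject_id", how="inner")
    if measures is None:
        measures = [c for c in scores.columns if c != "subject_id"]
    unknown = [m for m in measures if m not in merged.columns]
    if unknown:
        raise ValueError(f"unknown measure(s): {unknown}")
    g1 = merged[merged["subtype"] == 1]
    g2 = merged[merged["subtype"] == 2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both subtypes need at least two patients with scores")
    rows = []
    for m in measures:
        a = g1[m].to_numpy(dtype=float)
        b = g2[m].to_numpy(dtype=float)
        t, df, p = (
            ttest_from_summary(
                a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b),
                variant=variant,
            )
            if a.std(ddof=1) > 0 and b.std(ddof=1) > 0
            else (0.0, float(len(a) + len(b) - 2), 1.0)
        )
        diff = a.mean() - b.mean()
        sp = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        se = sp * np.sqrt(1 / len(a) + 1 / len(b))
        tq = stats.t.ppf(0.5 + ci_level / 2.0, len(a) + len(b) - 2)
        rows.append(
            {
                "measure": m,
                "mean_1": a.mean(), "sd_1": a.std(ddof=1), "n_1": len(a),
                "mean_2": b.mean(), "sd_2": b.std(ddof=1), "n_2": len(b),
                "t": t, "df": df, "p": p,
                "difference": diff,
                "ci_low": diff - tq * se,
                "ci_high": diff + tq * se,
            }
        )
    return pd.DataFrame(rows)
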