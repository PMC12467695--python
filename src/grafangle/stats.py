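"""Agreement and reliability statistics for validating angle measurements.

Bland-Altman agreement against a known reference, mean absolute error and
success rate, intraclass correlation (two-way random effects, absolute
agreement) with F-based confidence intervals, and one-way ANOVA with
eta-squared, Cohen's f, and post-hoc power from the noncentral F
distribution. Angles are reported to one decimal and dimensionless
quantities to two, rounding half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .geometry import round_reported


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary of value-minus-reference differences."""

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int
    z: float = 1.96

    def rounded(self) -> dict[str, float]:
        return {
            "bias": round_reported(self.bias),
            "sd_diff": round_reported(self.sd_diff),
            "loa_lower": round_reported(self.loa_lower),
            "loa_upper": round_reported(self.loa_upper),
        }


def bland_altman_vs_reference(values, reference, z: float = 1.96) -> AgreementStats:
    """Bland-Altman agreement of measurements against a reference.

    ``reference`` may be a scalar (known phantom truth) or per-measurement
    array. Bias is the mean difference, sd the sample SD (n-1 denominator),
    and the 95% limits of agreement are bias +/- z*sd. Rounding is applied
    only at reporting, via :meth:`AgreementStats.rounded`.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("Bland-Altman needs n >= 2 (SD undefined otherwise)")
    if z <= 0:
        raise ValueError("z must be > 0")
    diff = values - np.asarray(reference, dtype=float)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = loa_from_bias_sd(bias, sd, z)
    return AgreementStats(bias=bias, sd_diff=sd, loa_lower=lo, loa_upper=hi, n=values.size, z=z)


def loa_from_bias_sd(bias: float, sd: float, z: float = 1.96) -> tuple[float, float]:
    """Limits of agreement (bias - z*sd, bias + z*sd)."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return (bias - z * sd, bias + z * sd)


def mean_absolute_error(values, reference) -> float:
    """Mean of |value - reference| (scalar or per-measurement reference)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mean_absolute_error needs at least one value")
    return float(np.abs(values - np.asarray(reference, dtype=float)).mean())


def success_rate(outcomes) -> tuple[float, str]:
    """Fraction of successes plus a human-readable "k/n" count string."""
    outcomes = np.asarray(outcomes, dtype=bool)
    if outcomes.size == 0:
        raise ValueError("success_rate needs at least one outcome")
    k = int(outcomes.sum())
    return k / outcomes.size, f"{k}/{outcomes.size}"


# ---------------------------------------------------------------------------
# intraclass correlation


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_lower: float
    ci_upper: float
    model: str
    n_subjects: int
    n_raters: int


def _two_way_mean_squares(matrix: np.ndarray) -> tuple[float, float, float, int, int]:
    """Row (subject), column (rater), and residual mean squares of a
    complete two-way layout with one observation per cell."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("ICC needs a complete matrix with >= 2 subjects and >= 2 raters")
    if np.isnan(m).any():
        raise ValueError("ICC matrix must have no missing cells")
    n, k = m.shape
    grand = m.mean()
    ss_rows = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_two_way_single(matrix, confidence: float = 0.95) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way ANOVA mean squares with the F-based
    confidence interval of McGraw & Wong. Raises on zero total variance
    (reliability undefined).
    """
    msr, msc, mse, n, k = _two_way_mean_squares(matrix)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr == 0 and msc == 0 and mse == 0:
        raise ValueError("ICC undefined: zero total variance")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse == 0 and msc == 0:
        lo = hi = icc
    else:
        a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if np.isinf(a) or np.isinf(b):
            lo = hi = 1.0
        elif (a * msc) ** 2 + (b * mse) ** 2 == 0:
            lo = hi = icc  # degenerate: no rater or residual variability
        else:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
    return ICCResult(
        icc=float(icc),
        ci_lower=float(min(lo, icc)),
        ci_upper=float(max(hi, icc)),
        model="two-way random, absolute agreement, single measurement (ICC 2,1)",
        n_subjects=n,
        n_raters=k,
    )


def icc_two_way_average(matrix, confidence: float = 0.95) -> ICCResult:
    """ICC(2,k): as ICC(2,1) but for the mean of the k raters."""
    single = icc_two_way_single(matrix, confidence)
    k = single.n_raters

    def up(r: float) -> float:
        return k * r / (1.0 + (k - 1.0) * r) if r < 1.0 else 1.0

    return ICCResult(
        icc=up(single.icc),
        ci_lower=up(single.ci_lower),
        ci_upper=up(single.ci_upper),
        model="two-way random, absolute agreement, average of k measurements (ICC 2,k)",
        n_subjects=single.n_subjects,
        n_raters=k,
    )


# ---------------------------------------------------------------------------
# one-way ANOVA with effect sizes and post-hoc power


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float
    eta2: float
    cohens_f: float
    power: float
    group_ns: tuple[int, ...]


def oneway_anova(groups, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with eta-squared, Cohen's f, and post-hoc power.

    eta2 = SS_between / SS_total; f = sqrt(eta2 / (1 - eta2)); power is
    evaluated from the noncentral F distribution at the observed effect
    size with noncentrality lambda = f^2 * N.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs >= 2 observations")
    ns = tuple(len(g) for g in arrays)
    n_total = sum(ns)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    ss_total = ss_between + ss_within
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f_stat = 0.0 if ms_b == 0 else np.inf
        p = 1.0 if ms_b == 0 else 0.0
    else:
        f_stat = ms_b / ms_w
        p = float(sps.f.sf(f_stat, df_b, df_w))
    eta2 = float(ss_between / ss_total) if ss_total > 0 else 0.0
    f_effect = cohens_f_from_eta2(eta2) if eta2 < 1.0 else np.inf
    power = _posthoc_power(f_effect, df_b, df_w, n_total, alpha)
    return AnovaResult(
        f_stat=float(f_stat),
        p_value=p,
        eta2=eta2,
        cohens_f=float(f_effect),
        power=power,
        group_ns=ns,
    )


def _posthoc_power(f_effect: float, df_b: int, df_w: int, n_total: int, alpha: float) -> float:
    if not np.isfinite(f_effect):
        return 1.0
    if f_effect == 0:
        return alpha
    nc = f_effect**2 * n_total
    crit = sps.f.ppf(1 - alpha, df_b, df_w)
    return float(sps.ncf.sf(crit, df_b, df_w, nc))


def cohens_f_from_eta2(eta2: float) -> float:
    """Cohen's f = sqrt(eta2 / (1 - eta2))."""
    if not 0.0 <= eta2 < 1.0:
        raise ValueError(f"eta2 must lie in [0, 1), got {eta2}")
    return float(np.sqrt(eta2 / (1.0 - eta2)))
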