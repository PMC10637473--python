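"""Disproportionality statistics: information component, ROR and PRR.

The information component (IC) is the Bayesian shrinkage estimate of the
log2 observed-to-expected reporting ratio for a drug-reaction pair,

    IC = log2( (n_observed + 0.5) / (n_expected + 0.5) ),

the point summary of the BCPNN (Bayesian Confidence Propagation Neural
Network) measure.  The +0.5 shrinkage terms pull small-count pairs toward
IC = 0 and make the estimate usable at the very low expected frequencies
typical of large spontaneous-reporting databases.

Credibility bounds treat the relative reporting rate lambda as having a
Gamma posterior with shape n_observed + 0.5 and rate n_expected + 0.5
(whose mean reproduces the point IC on the log2 scale); IC025 and IC975
are log2 of the exact 2.5% and 97.5% gamma quantiles.  A normal
approximation on the log scale (digamma mean, trigamma variance) is
available for comparison.  The conventional signal criterion is IC025 > 0.

The frequentist comparators ROR (reporting odds ratio) and PRR
(proportional reporting ratio) are computed from the same 2x2 table with
log-normal Wald intervals and a Haldane-Anscombe +0.5 correction on
degenerate tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .contingency import (
    STRATA,
    StratumCounts,
    count_stratum,
    expected_count,
    pair_counts,
)
from .errors import UndefinedStratumError
from .icsr_model import Dataset

_LN2 = np.log(2.0)


def _check_level(level: float) -> None:
    if not 0.0 < level < 1.0:
        raise ValueError(f"credibility level must be in (0, 1), got {level}")


# ---------------------------------------------------------------------------
# array-level primitives (used by the vectorised table path)


def ic_point(n_observed, n_expected):
    """log2((n_observed + 0.5) / (n_expected + 0.5)); array-safe."""
    n_observed = np.asarray(n_observed, dtype=float)
    n_expected = np.asarray(n_expected, dtype=float)
    out = np.log2((n_observed + 0.5) / (n_expected + 0.5))
    return out if out.ndim else float(out)


def ic_interval(n_observed, n_expected, level: float = 0.95, method: str = "gamma"):
    """Credibility bounds of the IC; returns (low, high), array-safe.

    ``gamma``: exact quantiles of Gamma(shape=n_obs+0.5, rate=n_exp+0.5),
    log2-transformed.  ``normal``: normal approximation of log lambda with
    mean digamma(shape) - log(rate) and variance trigamma(shape).
    """
    _check_level(level)
    shape = np.asarray(n_observed, dtype=float) + 0.5
    rate = np.asarray(n_expected, dtype=float) + 0.5
    alpha = (1.0 - level) / 2.0
    if method == "gamma":
        lo = np.log2(stats.gamma.ppf(alpha, a=shape, scale=1.0 / rate))
        hi = np.log2(stats.gamma.ppf(1.0 - alpha, a=shape, scale=1.0 / rate))
    elif method == "normal":
        z = stats.norm.ppf(1.0 - alpha)
        mu = digamma(shape) - np.log(rate)
        sd = np.sqrt(polygamma(1, shape))
        lo = (mu - z * sd) / _LN2
        hi = (mu + z * sd) / _LN2
    else:
        raise ValueError(f"unknown interval method {method!r}")
    if np.ndim(lo) == 0:
        return float(lo), float(hi)
    return lo, hi


# ---------------------------------------------------------------------------
# scalar API on StratumCounts


def information_component(counts: StratumCounts) -> float:
    """Point IC for one pair in one stratum."""
    return ic_point(counts.n_observed, expected_count(counts))


def ic_credible_interval(
    counts: StratumCounts, level: float = 0.95, method: str = "gamma"
) -> tuple[float, float]:
    """(IC025, IC975)-style bounds at the requested credibility level."""
    return ic_interval(counts.n_observed, expected_count(counts), level, method)


class RatioEstimate(NamedTuple):
    value: float
    ci_low: float
    ci_high: float
    corrected: bool


def reporting_odds_ratio(counts: StratumCounts, level: float = 0.95) -> RatioEstimate:
    """ROR = (a*d)/(b*c) with a log-normal Wald interval.

    Any zero cell triggers the Haldane-Anscombe correction (+0.5 on all four
    cells), flagged in the result.
    """
    _check_level(level)
    a, b, c, d = (float(x) for x in counts.cells())
    corrected = min(a, b, c, d) == 0.0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RatioEstimate(
        ror, float(ror * np.exp(-z * se)), float(ror * np.exp(z * se)), corrected
    )


def proportional_reporting_ratio(
    counts: StratumCounts, level: float = 0.95
) -> RatioEstimate:
    """PRR = (a/n_drug) / (c/(n_total - n_drug)) with a log-normal interval.

    Zero a or c triggers the +0.5 correction on all four cells (margins
    recomputed), flagged.  Undefined when the drug accounts for the whole
    stratum (no comparator population).
    """
    _check_level(level)
    a, b, c, d = (float(x) for x in counts.cells())
    if c + d == 0.0:
        raise UndefinedStratumError(
            "PRR undefined: no reports without the drug in this stratum"
        )
    corrected = a == 0.0 or c == 0.0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n_drug = a + b
    n_other = c + d
    prr = (a / n_drug) / (c / n_other)
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    se = np.sqrt(max(1 / a - 1 / n_drug + 1 / c - 1 / n_other, 0.0))
    return RatioEstimate(
        prr, float(prr * np.exp(-z * se)), float(prr * np.exp(z * se)), corrected
    )


# ---------------------------------------------------------------------------
# composed result


@dataclass(frozen=True)
class DisproportionalityResult:
    """All statistics for one drug-reaction pair in one stratum.

    ``is_na`` marks strata with zero observed reports: the IC fields are NaN
    and render as NA downstream, mirroring the convention of publication
    tables where a pair never reported in one sex shows a whole-row NA.
    """

    ic: float
    ic025: float
    ic975: float
    ror: float
    ror_ci: tuple[float, float]
    ror_corrected: bool
    prr: float | None
    prr_ci: tuple[float, float] | None
    prr_corrected: bool
    counts: StratumCounts | None
    is_signal: bool
    is_na: bool

    @classmethod
    def from_interval(
        cls, ic: float, ic025: float, ic975: float
    ) -> "DisproportionalityResult":
        """Build a result from published (IC, IC025, IC975) values only.

        Useful for classifying sex patterns of externally reported rows for
        which the underlying counts are not available.
        """
        is_na = any(np.isnan(v) for v in (ic, ic025, ic975))
        return cls(
            ic=ic,
            ic025=ic025,
            ic975=ic975,
            ror=np.nan,
            ror_ci=(np.nan, np.nan),
            ror_corrected=False,
            prr=None,
            prr_ci=None,
            prr_corrected=False,
            counts=None,
            is_signal=(not is_na) and ic025 > 0,
            is_na=is_na,
        )

    @classmethod
    def na(cls, counts: StratumCounts | None = None) -> "DisproportionalityResult":
        res = cls.from_interval(np.nan, np.nan, np.nan)
        return replace(res, counts=counts)


def evaluate_pair(
    dataset: Dataset,
    drug: str,
    reaction_pt: str,
    stratum: str,
    level: float = 0.95,
    interval_method: str = "gamma",
) -> DisproportionalityResult:
    """Count one pair in one stratum and compute IC, ROR and PRR.

    The dataset must be deduplicated.  Raises UndefinedStratumError for an
    empty stratum; a pair with zero observed reports returns an ``is_na``
    result with NaN IC fields.
    """
    counts = count_stratum(dataset, drug, reaction_pt, stratum)
    n_exp = expected_count(counts)  # raises on empty stratum

    ror = reporting_odds_ratio(counts, level)
    try:
        prr = proportional_reporting_ratio(counts, level)
    except UndefinedStratumError:
        prr = None

    if counts.n_observed == 0:
        ic = ic025 = ic975 = float("nan")
        is_na = True
        is_signal = False
    else:
        ic = ic_point(counts.n_observed, n_exp)
        ic025, ic975 = ic_interval(counts.n_observed, n_exp, level, interval_method)
        is_na = False
        is_signal = ic025 > 0
    return DisproportionalityResult(
        ic=ic,
        ic025=ic025,
        ic975=ic975,
        ror=ror.value,
        ror_ci=(ror.ci_low, ror.ci_high),
        ror_corrected=ror.corrected,
        prr=prr.value if prr else None,
        prr_ci=(prr.ci_low, prr.ci_high) if prr else None,
        prr_corrected=prr.corrected if prr else False,
        counts=counts,
        is_signal=is_signal,
        is_na=is_na,
    )


# ---------------------------------------------------------------------------
# vectorised table


def analyze_pairs(
    dataset: Dataset,
    drugs: Sequence[str] | None = None,
    reaction_pts: Sequence[str] | None = None,
    strata: Sequence[str] = STRATA,
    level: float = 0.95,
    interval_method: str = "gamma",
) -> pd.DataFrame:
    """Disproportionality table for many pairs at once.

    One row per (drug, reaction_pt, stratum) with counts, n_expected, IC and
    bounds, ROR/PRR with intervals and correction flags, is_signal and
    is_na.  IC columns are NaN where is_na (zero observed) or the stratum is
    empty.
    """
    _check_level(level)
    df = pair_counts(dataset, drugs=drugs, reaction_pts=reaction_pts, strata=strata)
    n_obs = df["n_observed"].to_numpy(dtype=float)
    n_exp = df["n_expected"].to_numpy(dtype=float)
    defined = np.isfinite(n_exp)

    ic = np.full(len(df), np.nan)
    lo = np.full(len(df), np.nan)
    hi = np.full(len(df), np.nan)
    live = defined & (n_obs > 0)
    if live.any():
        ic[live] = ic_point(n_obs[live], n_exp[live])
        lo[live], hi[live] = ic_interval(
            n_obs[live], n_exp[live], level, interval_method
        )
    df["ic"] = ic
    df["ic025"] = lo
    df["ic975"] = hi
    df["is_na"] = ~live
    df["is_signal"] = live & (lo > 0)

    # 2x2 cells
    a = n_obs
    b = df["n_drug"].to_numpy(dtype=float) - a
    c = df["n_reaction"].to_numpy(dtype=float) - a
    d = df["n_total"].to_numpy(dtype=float) - df["n_drug"].to_numpy(
        dtype=float
    ) - df["n_reaction"].to_numpy(dtype=float) + a
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)

    ror_corr = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0) & defined
    aa, bb, cc, dd = (x + np.where(ror_corr, 0.5, 0.0) for x in (a, b, c, d))
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = np.where(defined, (aa * dd) / (bb * cc), np.nan)
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    df["ror"] = ror
    df["ror_low"] = ror * np.exp(-z * se)
    df["ror_high"] = ror * np.exp(z * se)
    df["ror_corrected"] = ror_corr

    prr_def = defined & ((c + d) > 0)
    prr_corr = ((a == 0) | (c == 0)) & prr_def
    aa, bb, cc, dd = (x + np.where(prr_corr, 0.5, 0.0) for x in (a, b, c, d))
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = np.where(prr_def, (aa / (aa + bb)) / (cc / (cc + dd)), np.nan)
        se = np.sqrt(
            np.maximum(1 / aa - 1 / (aa + bb) + 1 / cc - 1 / (cc + dd), 0.0)
        )
    df["prr"] = prr
    df["prr_low"] = prr * np.exp(-z * se)
    df["prr_high"] = prr * np.exp(z * se)
    df["prr_corrected"] = prr_corr
    return df
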