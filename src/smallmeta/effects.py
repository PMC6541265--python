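"""Standardized effect sizes from reported summary statistics.

Primary intervention studies report their results heterogeneously: post-test
means and SDs, ANOVA F values, t statistics, p values, ready-made Cohen's d,
or pre-post change scores.  This module converts each of those to a
standardized mean difference d and onward to a correlation r and Fisher z,
following the conventional two-group formulas.  The preference order used by
the batch converter is: post means/SDs, F, reported d, p, change scores.

Sign convention: positive effects always mean the intervention helped, so
symptom scales (e.g. depression inventories) must be sign-flipped upstream.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SummaryStats",
    "DegenerateInputError",
    "d_from_post_means",
    "d_from_change_scores",
    "d_from_F",
    "d_from_t",
    "d_from_p",
    "d_ppc2",
    "var_d_ppc2",
    "hedges_correction",
    "r_from_d",
    "d_from_r",
    "z_from_r",
    "r_from_z",
    "var_z",
    "effect_size_from_stats",
    "PREFERENCE_ORDER",
]

PREFERENCE_ORDER = ("post_means", "F", "d_reported", "p", "change_scores")


class DegenerateInputError(ValueError):
    """Inputs admit no meaningful effect size (e.g. zero pooled SD)."""


@dataclass
class SummaryStats:
    """Reported statistics for one outcome of one comparison.

    Only the fields consistent with the study's reporting should be set.
    ``rho_prepost`` is the pre-post correlation within condition, required by
    the pre-post-controlled effect size and almost never reported.
    """

    design: str = "post_only"  # or "prepost"
    m_t: float | None = None
    m_c: float | None = None
    sd_t: float | None = None
    sd_c: float | None = None
    n_t: int | None = None
    n_c: int | None = None
    F: float | None = None
    t: float | None = None
    p: float | None = None
    sign: int = 1
    d_reported: float | None = None
    m_pre_t: float | None = None
    m_pre_c: float | None = None
    sd_pre_t: float | None = None
    sd_pre_c: float | None = None
    m_post_t: float | None = None
    m_post_c: float | None = None
    diff_m_t: float | None = None
    diff_m_c: float | None = None
    diff_sd_t: float | None = None
    diff_sd_c: float | None = None
    rho_prepost: float | None = None


def _pooled_sd(sd_t: float, sd_c: float, n_t: int, n_c: int) -> float:
    if sd_t < 0 or sd_c < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_t < 2 or n_c < 2:
        raise ValueError("need at least two observations per group")
    s2 = ((n_t - 1) * sd_t**2 + (n_c - 1) * sd_c**2) / (n_t + n_c - 2)
    if s2 <= 0:
        raise DegenerateInputError("zero pooled standard deviation")
    return math.sqrt(s2)


def d_from_post_means(m_t, m_c, sd_t, sd_c, n_t, n_c) -> float:
    """Cohen's d from post-test means and SDs, pooled-SD denominator."""
    return (m_t - m_c) / _pooled_sd(sd_t, sd_c, n_t, n_c)


def d_from_change_scores(diff_m_t, diff_m_c, diff_sd_t, diff_sd_c, n_t, n_c) -> float:
    """Standardized mean difference of pre-post change scores."""
    return (diff_m_t - diff_m_c) / _pooled_sd(diff_sd_t, diff_sd_c, n_t, n_c)


def d_from_t(t, n_t, n_c) -> float:
    """d from a two-sample t statistic: d = t * sqrt(1/n_t + 1/n_c)."""
    if n_t < 1 or n_c < 1:
        raise ValueError("group sizes must be positive")
    return t * math.sqrt(1.0 / n_t + 1.0 / n_c)


def d_from_F(F, n_t, n_c, sign: int = 1) -> float:
    """d from a one-way two-group ANOVA F, using t = sqrt(F).

    The direction is not recoverable from F; ``sign`` must come from the
    reported means or narrative.
    """
    if F < 0:
        raise ValueError("F must be non-negative")
    if sign not in (-1, 1):
        raise ValueError("sign must be +1 or -1")
    return sign * d_from_t(math.sqrt(F), n_t, n_c)


def d_from_p(p, n_t, n_c, sign: int = 1) -> float:
    """d from a two-sided p value, inverting the central t CDF at df = n-2."""
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if sign not in (-1, 1):
        raise ValueError("sign must be +1 or -1")
    df = n_t + n_c - 2
    t = stats.t.isf(p / 2.0, df)
    return sign * d_from_t(t, n_t, n_c)


def hedges_correction(n_t, n_c) -> float:
    """Small-sample bias correction 1 - 3/(4(n_t+n_c-2) - 1)."""
    df = n_t + n_c - 2
    if df < 1:
        raise ValueError("need n_t + n_c >= 3")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def d_ppc2(m_pre_t, m_post_t, m_pre_c, m_post_c, sd_pre_t, sd_pre_c,
           n_t, n_c, rho_prepost=None) -> float:
    """Pre-post-controlled standardized effect (Morris's second variant).

    The group change scores are standardized by the pooled *pre-test* SD and
    bias-corrected by the Hedges factor.  ``rho_prepost`` does not enter the
    point estimate, only its variance (:func:`var_d_ppc2`); it is required
    here so callers cannot silently ignore that the variance needs it.
    """
    if rho_prepost is None:
        raise ValueError(
            "pre-post correlation not supplied; impute one explicitly or use "
            "a post-only effect size"
        )
    if not -1 < rho_prepost < 1:
        raise ValueError("rho_prepost must be in (-1, 1)")
    sd_pre = _pooled_sd(sd_pre_t, sd_pre_c, n_t, n_c)
    cp = hedges_correction(n_t, n_c)
    return cp * ((m_post_t - m_pre_t) - (m_post_c - m_pre_c)) / sd_pre


def var_d_ppc2(d, n_t, n_c, rho_prepost) -> float:
    """Sampling variance of the pre-post-controlled d (Morris 2008)."""
    cp = hedges_correction(n_t, n_c)
    n = n_t + n_c
    if n < 5:
        raise ValueError("need n_t + n_c >= 5")
    a = 2.0 * (1.0 - rho_prepost) * n / (n_t * n_c)
    return cp**2 * a * ((n - 2.0) / (n - 4.0)) * (1.0 + d**2 / a) - d**2


def r_from_d(d, n_t, n_c) -> float:
    """Point-biserial-style conversion d -> r with a = (n_t+n_c)^2/(n_t*n_c).

    Unequal group sizes shrink r for a given d; with n_t = n_c this reduces to
    the familiar a = 4.
    """
    a = (n_t + n_c) ** 2 / (n_t * n_c)
    return d / math.sqrt(d**2 + a)


def d_from_r(r) -> float:
    """Equal-n inverse conversion r -> d = 2r / sqrt(1 - r^2)."""
    if not -1 < r < 1:
        raise ValueError("|r| must be < 1")
    return 2.0 * r / math.sqrt(1.0 - r**2)


def z_from_r(r):
    """Fisher's variance-stabilizing transform z = atanh(r)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def r_from_z(z):
    """Inverse Fisher transform r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def var_z(n):
    """Large-sample variance of Fisher z: 1/(n - 3)."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 4):
        raise ValueError("need n >= 4")
    out = 1.0 / (n - 3.0)
    return float(out) if out.ndim == 0 else out


def effect_size_from_stats(s: SummaryStats, hedges: bool = False) -> float:
    """Compute d from a :class:`SummaryStats`, walking the preference order.

    Post-test means and SDs are used when available, then F, then a reported
    d, then p, then pre-post change scores.  With ``hedges=True``, the
    small-sample correction is applied to the returned d.
    """
    d = None
    if None not in (s.m_t, s.m_c, s.sd_t, s.sd_c, s.n_t, s.n_c):
        d = d_from_post_means(s.m_t, s.m_c, s.sd_t, s.sd_c, s.n_t, s.n_c)
    elif s.F is not None and None not in (s.n_t, s.n_c):
        d = d_from_F(s.F, s.n_t, s.n_c, s.sign)
    elif s.d_reported is not None:
        d = s.d_reported
    elif s.t is not None and None not in (s.n_t, s.n_c):
        d = d_from_t(s.t, s.n_t, s.n_c)
    elif s.p is not None and None not in (s.n_t, s.n_c):
        d = d_from_p(s.p, s.n_t, s.n_c, s.sign)
    elif None not in (s.diff_m_t, s.diff_m_c, s.diff_sd_t, s.diff_sd_c, s.n_t, s.n_c):
        d = d_from_change_scores(s.diff_m_t, s.diff_m_c, s.diff_sd_t,
                                 s.diff_sd_c, s.n_t, s.n_c)
    if d is None:
        raise ValueError("insufficient statistics to compute an effect size")
    if hedges and None not in (s.n_t, s.n_c):
        d *= hedges_correction(s.n_t, s.n_c)
    return d


def effect_table_from_stats(stats_list: Sequence[SummaryStats], hedges: bool = False):
    """Batch conversion: list of SummaryStats -> DataFrame with d, r, z."""
    import pandas as pd

    rows = []
    for s in stats_list:
        d = effect_size_from_stats(s, hedges=hedges)
        r = r_from_d(d, s.n_t, s.n_c) if None not in (s.n_t, s.n_c) else np.nan
        rows.append({"d": d, "r": r, "z": np.arctanh(r) if np.isfinite(r) else np.nan,
                     "n_t": s.n_t, "n_c": s.n_c})
    return pd.DataFrame(rows)
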