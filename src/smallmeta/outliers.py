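"""Outlier identification among study effects and sensitivity re-analysis.

Two screens are provided: the boxplot (1.5 x IQR) rule on the study-level
correlations, and externally studentized deleted residuals from leave-one-out
random-effects fits.  ``sensitivity_rerun`` repeats the full analysis with
and without the flagged studies so both rows can be reported side by side.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pooling import MetaAnalysis

__all__ = [
    "detect_outliers_iqr",
    "detect_outliers_deleted_residuals",
    "sensitivity_rerun",
    "SensitivityPair",
]


def detect_outliers_iqr(values, study_ids: Sequence[str], whis: float = 1.5) -> list[str]:
    """Flag effects beyond ``whis`` interquartile ranges outside the quartiles.

    Quartiles follow the linear-interpolation convention (numpy default,
    R type 7).  Flags are invariant to study order.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("IQR screen needs at least four studies")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - whis * iqr, q3 + whis * iqr
    return [sid for sid, v in zip(study_ids, values) if v < lo or v > hi]


def detect_outliers_deleted_residuals(z, var_z, study_ids: Sequence[str],
                                      crit: float = 1.96,
                                      method: str = "DL") -> list[str]:
    """Flag studies whose externally studentized deleted residual exceeds crit.

    For each study the model is refit without it; the residual of the held-out
    effect against the leave-one-out pooled estimate is standardized by
    sqrt(v_i + tau^2_(-i) + se(mu_(-i))^2).
    """
    z = np.asarray(z, dtype=float)
    v = np.asarray(var_z, dtype=float)
    k = z.size
    if k < 4:
        raise ValueError("deleted-residual screen needs at least four studies")
    flagged = []
    for i in range(k):
        mask = np.arange(k) != i
        res = MetaAnalysis(z[mask], v[mask]).fit(method=method)
        denom = np.sqrt(v[i] + res.tau2 + res.se_z**2)
        t_i = (z[i] - res.mu_z) / denom
        if abs(t_i) > crit:
            flagged.append(study_ids[i])
    return flagged


@dataclass
class SensitivityPair:
    """Full-sample and outlier-excluded analyses of one study set."""

    excluded: list[str]
    full: dict
    without: dict

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(self.full, sample="all"),
                dict(self.without, sample="w/o outliers")]
        return pd.DataFrame(rows)


def sensitivity_rerun(studies: pd.DataFrame, excluded: Sequence[str],
                      method: str = "DL") -> SensitivityPair:
    """Re-run pooling and every bias method with and without ``excluded``.

    ``studies`` is an aggregated study table (study_id, z, var_z, ...).
    Excluding every study is an error; excluding none returns two identical
    analyses.
    """
    from .bias import egger_test, limit_meta, top_precision, trim_and_fill

    excluded = list(excluded)
    keep = studies[~studies["study_id"].isin(excluded)]
    if keep.empty:
        raise ValueError("cannot exclude every study")

    def analyse(tbl: pd.DataFrame) -> dict:
        res = MetaAnalysis.from_dataframe(tbl).fit(method=method)
        egger = egger_test(tbl["z"].to_numpy(), tbl["var_z"].to_numpy())
        lim = limit_meta(tbl["z"].to_numpy(), tbl["var_z"].to_numpy(), method=method)
        tf = trim_and_fill(tbl["z"].to_numpy(), tbl["var_z"].to_numpy(),
                           study_ids=tbl["study_id"].tolist(), method=method)
        top = top_precision(tbl["z"].to_numpy(), tbl["var_z"].to_numpy(),
                            study_ids=tbl["study_id"].tolist())
        lo, hi = res.conf_int()
        return {
            "k": res.k,
            "r_pooled": res.r_pooled,
            "ci_low": lo,
            "ci_high": hi,
            "I2": res.I2,
            "tau2": res.tau2,
            "egger_t": egger.t_stat,
            "egger_p": egger.p,
            "limit_r": lim.r_limit,
            "limit_ci_low": lim.ci_low,
            "limit_ci_high": lim.ci_high,
            "limit_d": lim.d_limit,
            "trimfill_k0": tf.k0,
            "trimfill_r": tf.r_adjusted,
            "top10_r": top.r_pooled,
        }

    return SensitivityPair(excluded=excluded, full=analyse(studies), without=analyse(keep))
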