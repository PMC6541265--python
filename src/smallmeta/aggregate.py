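"""Within-study aggregation of correlated outcomes into one effect per study.

A study that administers m outcome measures to the same participants yields m
correlated effect sizes.  Two composites are provided, both assuming a common
within-study outcome correlation rho (default .50, the conventional
imputation when primary articles do not report it):

``method="mean"``
    the average correlation, i.e. the effect of the intervention on the mean
    of the m standardized outcomes, with the variance of a mean of correlated
    estimates.  The composite equals the arithmetic mean of the inputs.

``method="composite"``
    the Schmidt-Hunter composite correlation: the correlation of treatment
    with the *sum* (composite scale) of the m standardized outcomes,

        r_composite = rbar * m / sqrt(m + m(m-1) rho) = rbar * sqrt(m / (1+(m-1) rho)).

    Because averaging outcomes cancels measure-specific error, the composite
    correlation exceeds the average correlation whenever rho < 1; at rho = 1
    the two coincide.  This is the default used by the replication pipeline.

Study-level weighting uses the mean per-comparison sample size nbar of the
contributing rows, with Fisher-z variance 1/(nbar - 3).
"""
from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .data import StudyEffect

logger = logging.getLogger(__name__)

__all__ = [
    "composite_correlation",
    "composite_variance",
    "aggregate_outcomes",
    "aggregate_interventions",
    "aggregate_dataset",
    "to_study_effects",
]


def composite_correlation(rs: Sequence[float], within_r: float = 0.5) -> float:
    """Schmidt-Hunter composite correlation of treatment with the outcome sum."""
    rs = np.asarray(rs, dtype=float)
    m = rs.size
    if m == 0:
        raise ValueError("no effects to aggregate")
    if not 0 <= within_r <= 1:
        raise ValueError("within_r must be in [0, 1]")
    out = rs.mean() * math.sqrt(m / (1.0 + (m - 1) * within_r))
    if abs(out) >= 1.0:
        raise ValueError(
            f"composite correlation {out:.3f} outside (-1, 1); "
            "inputs are inconsistent with the assumed within-study correlation"
        )
    return float(out)


def composite_variance(variances: Sequence[float], within_r: float = 0.5) -> float:
    """Variance of the mean of m estimates with pairwise correlation within_r."""
    v = np.asarray(variances, dtype=float)
    m = v.size
    if m == 0:
        raise ValueError("no variances to aggregate")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    s = np.sqrt(v)
    total = v.sum() + within_r * (s.sum() ** 2 - v.sum())
    return float(total / m**2)


def aggregate_outcomes(effects: Sequence[tuple[float, float]],
                       within_r: float = 0.5,
                       method: str = "mean") -> tuple[float, float]:
    """Collapse m (r, n) outcome effects sharing one sample into (r, var_r).

    With ``method="mean"`` the point estimate is the arithmetic mean and the
    variance is that of a mean of correlated estimates (so the composite's
    precision grows with m, but sublinearly).  With ``method="composite"`` the
    Schmidt-Hunter composite correlation is returned instead, with the
    variance evaluated at the composite's own sample size.
    """
    if len(effects) == 0:
        raise ValueError("no effects to aggregate")
    rs = np.array([e[0] for e in effects], dtype=float)
    ns = np.array([e[1] for e in effects], dtype=float)
    if len(set(ns.tolist())) > 1:
        logger.warning("aggregating outcomes with mixed sample sizes: %s", ns.tolist())
    var_r = (1.0 - rs**2) ** 2 / (ns - 1.0)
    if method == "mean":
        return float(rs.mean()), composite_variance(var_r, within_r)
    if method == "composite":
        rc = composite_correlation(rs, within_r)
        nbar = ns.mean()
        return rc, float((1.0 - rc**2) ** 2 / (nbar - 1.0))
    raise ValueError(f"unknown aggregation method {method!r}")


def aggregate_interventions(arm_effects: Sequence[tuple[float, float]],
                            control_n: float,
                            study_id: str = "study",
                            within_r: float = 0.5,
                            method: str = "mean") -> StudyEffect:
    """Collapse per-arm composites sharing one control into a StudyEffect.

    ``arm_effects`` holds (r, n_t) per intervention arm; the shared control
    sample is counted once in the study's effective N.
    """
    if len(arm_effects) == 0:
        raise ValueError("no arms to aggregate")
    rs = np.array([a[0] for a in arm_effects], dtype=float)
    if method == "composite":
        r = composite_correlation(rs, within_r)
    else:
        r = float(rs.mean())
    n_eff = float(sum(a[1] for a in arm_effects) + control_n)
    return StudyEffect(study_id=study_id, r=r, z=math.atanh(r),
                       var_z=1.0 / (n_eff - 3.0), n_eff=n_eff,
                       n_rows=len(arm_effects))


def aggregate_dataset(df: pd.DataFrame,
                      within_r: float = 0.5,
                      method: str = "composite",
                      n_mode: str = "mean") -> pd.DataFrame:
    """Aggregate a coded effect table to one row per study.

    All of a study's rows (outcomes x interventions, plus rows of merged
    sibling articles) enter one composite with the imputed correlation
    ``within_r``.  The study's effective sample size is the mean (``n_mode=
    "mean"``, default) or sum over distinct arms plus control (``n_mode=
    "arms"``) of per-comparison totals.  Returns columns: study_id, r, r_mean,
    z, var_z, n_eff, n_rows.  ``r_mean`` is the pre-composite average
    correlation, retained for the outlier screen.
    """
    df = df.dropna(subset=["r"])
    if df.empty:
        raise ValueError("no usable rows to aggregate")
    source_col = "source_id" if "source_id" in df.columns else "study_id"
    records = []
    for sid, g in df.groupby("study_id", sort=False):
        rs = g["r"].to_numpy(dtype=float)
        r_mean = float(rs.mean())
        if method == "composite":
            r = composite_correlation(rs, within_r)
        elif method == "mean":
            r = r_mean
        else:
            raise ValueError(f"unknown aggregation method {method!r}")
        if n_mode == "mean":
            n_eff = float(g["n_total"].astype(float).mean())
        elif n_mode == "arms":
            n_eff = float(
                sum(ga["n_t"].astype(float).mean()
                    for _, ga in g.groupby([source_col, "intervention"], sort=False))
                + sum(gs["n_c"].astype(float).mean()
                      for _, gs in g.groupby(source_col, sort=False))
            )
        else:
            raise ValueError(f"unknown n_mode {n_mode!r}")
        records.append(
            {
                "study_id": sid,
                "r": r,
                "r_mean": r_mean,
                "z": math.atanh(r),
                "var_z": 1.0 / (n_eff - 3.0),
                "n_eff": n_eff,
                "n_rows": len(g),
            }
        )
    return pd.DataFrame.from_records(records)


def to_study_effects(studies: pd.DataFrame) -> list[StudyEffect]:
    """Convert an aggregated study table into typed StudyEffect records."""
    return [
        StudyEffect(study_id=row.study_id, r=row.r, z=row.z, var_z=row.var_z,
                    n_eff=row.n_eff, n_rows=int(row.n_rows))
        for row in studies.itertuples(index=False)
    ]
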