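"""Small-study-effect diagnostics and bias-adjusted pooled estimates.

When less precise studies systematically report larger effects (publication
selection being the usual culprit), the funnel plot of effects against
standard errors is asymmetric and the ordinary pooled estimate is inflated.
This module implements the standard detection and adjustment toolkit on the
Fisher-z scale:

* :func:`egger_test` - regression test of funnel asymmetry,
* :func:`trim_and_fill` - rank-based imputation of mirrored studies,
* :func:`cumulative_meta` - pooled estimate as studies are added most
  precise first,
* :func:`top_precision` - fixed-effect estimate from the most precise decile,
* :func:`limit_meta` - the extended random-effects (limit meta-analysis)
  model whose adjusted estimate is the model's expectation as study precision
  tends to infinity.

All adjusted estimates are back-transformed to the correlation scale.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pooling import MetaAnalysis, MetaAnalysisResults

__all__ = [
    "EggerResult",
    "TrimFillResult",
    "LimitMetaResult",
    "egger_test",
    "trim_and_fill",
    "cumulative_meta",
    "top_precision",
    "top10",
    "limit_meta",
]


# ---------------------------------------------------------------------------
# Egger regression test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EggerResult:
    """Classical Egger regression test of funnel-plot asymmetry.

    The standardized effect z_i/se_i is regressed on precision 1/se_i by
    ordinary least squares; a nonzero intercept indicates asymmetry and is
    tested with k-2 degrees of freedom.
    """

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    t_stat: float
    df: int
    p: float

    def __str__(self) -> str:
        return (f"Egger regression test: intercept={self.intercept:.3f} "
                f"(SE {self.se_intercept:.3f}), t({self.df})={self.t_stat:.2f}, "
                f"p={self.p:.4f}")


def egger_test(z, var_z, weighted: bool = False) -> EggerResult:
    """Test funnel asymmetry by regressing standardized effect on precision.

    With ``weighted=True`` the meta-regression variant is used instead:
    weighted least squares of z on se with weights 1/var_z (identical t
    statistic to the classical form, kept for completeness).
    """
    z = np.asarray(z, dtype=float)
    v = np.asarray(var_z, dtype=float)
    k = z.size
    if k < 3:
        raise ValueError("Egger test needs at least three studies")
    se = np.sqrt(v)
    if weighted:
        # WLS: z = b0 + b1*se, weights 1/v; intercept tested is b1's partner
        X = np.column_stack([np.ones(k), se])
        W = 1.0 / v
        XtWX = X.T @ (W[:, None] * X)
        beta = np.linalg.solve(XtWX, X.T @ (W * z))
        resid = z - X @ beta
        s2 = float(np.sum(W * resid**2) / (k - 2))
        cov = s2 * np.linalg.inv(XtWX)
        # small-study term is the slope on se in this parameterization
        inter, slope = float(beta[1]), float(beta[0])
        se_i, se_s = math.sqrt(cov[1, 1]), math.sqrt(cov[0, 0])
    else:
        y = z / se
        x = 1.0 / se
        X = np.column_stack([np.ones(k), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = float(resid @ resid / (k - 2))
        cov = s2 * np.linalg.inv(X.T @ X)
        inter, slope = float(beta[0]), float(beta[1])
        se_i, se_s = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    t = inter / se_i
    p = float(2 * stats.t.sf(abs(t), k - 2))
    return EggerResult(intercept=inter, slope=slope, se_intercept=se_i,
                       se_slope=se_s, t_stat=float(t), df=k - 2, p=p)


# ---------------------------------------------------------------------------
# Duval-Tweedie trim and fill
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrimFillResult:
    """Trim-and-fill adjusted estimate with the imputed mirror studies."""

    k0: int
    side: str
    results: MetaAnalysisResults
    filled: pd.DataFrame = field(repr=False)

    @property
    def r_adjusted(self) -> float:
        return self.results.r_pooled

    @property
    def conf_int(self) -> tuple[float, float]:
        return self.results.conf_int()


def _l0_estimate(y: np.ndarray, center: float) -> int:
    """L0 estimator of the number of suppressed studies on the right side."""
    n = y.size
    dev = y - center
    ranks = stats.rankdata(np.abs(dev))
    t_n = float(ranks[dev > 0].sum())
    l0 = (4.0 * t_n - n * (n + 1.0)) / (2.0 * n - 1.0)
    return max(0, int(round(l0)))


def _r0_estimate(y: np.ndarray, center: float) -> int:
    """R0 estimator: length of the run of rightmost ranks minus one."""
    n = y.size
    dev = y - center
    order = np.argsort(np.abs(dev))
    signs = np.sign(dev)[order]
    run = 0
    for s in signs[::-1]:
        if s > 0:
            run += 1
        else:
            break
    return max(0, run - 1)


def trim_and_fill(z, var_z, study_ids=None, side: str = "auto",
                  estimator: str = "L0", method: str = "DL",
                  max_iter: int = 50) -> TrimFillResult:
    """Duval-Tweedie trim and fill on the Fisher-z scale.

    Iteratively trims the k0 most extreme effects on the asymmetric side
    (chosen from the Egger slope sign when ``side="auto"``), re-estimates the
    center by fixed effect, and on convergence imputes mirror-image studies;
    the adjusted estimate pools observed plus imputed studies with the given
    tau^2 estimator.  Observed studies are never removed from the final pool.
    """
    z = np.asarray(z, dtype=float)
    v = np.asarray(var_z, dtype=float)
    k = z.size
    if k < 3:
        raise ValueError("trim and fill needs at least three studies")
    if study_ids is None:
        study_ids = [f"study_{i + 1}" for i in range(k)]
    if side == "auto":
        side = "right" if egger_test(z, v).intercept >= 0 else "left"
    if side not in ("left", "right"):
        raise ValueError("side must be 'left', 'right' or 'auto'")
    flip = -1.0 if side == "left" else 1.0
    y = flip * z
    est = {"L0": _l0_estimate, "R0": _r0_estimate}.get(estimator.upper())
    if est is None:
        raise ValueError("estimator must be 'L0' or 'R0'")

    k0 = 0
    trace = []
    for _ in range(max_iter):
        keep = np.argsort(y)[: k - k0] if k0 else np.arange(k)
        w = 1.0 / v[keep]
        center = float(np.sum(w * y[keep]) / np.sum(w))
        new_k0 = min(est(y, center), k - 2)
        trace.append(new_k0)
        if new_k0 == k0:
            break
        k0 = new_k0
    else:
        raise RuntimeError(f"trim and fill did not converge; k0 trace: {trace}")

    order = np.argsort(y)
    fill_idx = order[k - k0:] if k0 else np.array([], dtype=int)
    filled_y = 2.0 * center - y[fill_idx]
    all_z = np.concatenate([z, flip * filled_y])
    all_v = np.concatenate([v, v[fill_idx]])
    ids = list(study_ids) + [f"filled_{study_ids[i]}" for i in fill_idx]
    res = MetaAnalysis(all_z, all_v, ids).fit(method=method)
    filled = pd.DataFrame(
        {
            "study_id": ids,
            "z": all_z,
            "se": np.sqrt(all_v),
            "filled": [False] * k + [True] * k0,
        }
    )
    return TrimFillResult(k0=k0, side=side, results=res, filled=filled)


# ---------------------------------------------------------------------------
# Cumulative meta-analysis and TOP10
# ---------------------------------------------------------------------------

def cumulative_meta(z, var_z, study_ids=None, method: str = "DL") -> pd.DataFrame:
    """Pooled estimate over nested prefixes, most precise study first.

    Shows how much adding progressively smaller studies moves the estimate;
    the last row equals the full pooled analysis.  The first prefix of size
    one reports the study's own effect.
    """
    z = np.asarray(z, dtype=float)
    v = np.asarray(var_z, dtype=float)
    if z.size < 2:
        raise ValueError("cumulative meta-analysis needs at least two studies")
    if study_ids is None:
        study_ids = [f"study_{i + 1}" for i in range(z.size)]
    order = np.argsort(v, kind="stable")
    rows = []
    for j in range(1, z.size + 1):
        idx = order[:j]
        if j == 1:
            r = float(np.tanh(z[idx[0]]))
            se = math.sqrt(v[idx[0]])
            lo, hi = np.tanh(z[idx[0]] - 1.96 * se), np.tanh(z[idx[0]] + 1.96 * se)
            rows.append({"k": 1, "added": study_ids[idx[0]], "r_pooled": r,
                         "ci_low": float(lo), "ci_high": float(hi)})
            continue
        res = MetaAnalysis(z[idx], v[idx]).fit(method=method)
        lo, hi = res.conf_int()
        rows.append({"k": j, "added": study_ids[order[j - 1]],
                     "r_pooled": res.r_pooled, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def top_precision(z, var_z, study_ids=None, frac: float = 0.10) -> MetaAnalysisResults:
    """Fixed-effect pooling of the ceil(frac*k) most precise studies.

    A simple, surprisingly robust estimate under small-study bias: the most
    precise studies are the least affected by selection.  Ties in precision
    are broken by study id order (deterministic).  With fewer than 10 studies
    the single most precise study is used (with a warning).
    """
    import warnings

    z = np.asarray(z, dtype=float)
    v = np.asarray(var_z, dtype=float)
    k = z.size
    if study_ids is None:
        study_ids = [f"study_{i + 1}" for i in range(k)]
    if k < 10:
        warnings.warn("fewer than 10 studies; TOP10 uses the single most precise")
    m = max(1, math.ceil(frac * k))
    order = sorted(range(k), key=lambda i: (v[i], str(study_ids[i])))
    idx = order[:m]
    if m == 1:
        i = idx[0]
        # degenerate one-study pool: report the study itself
        model = MetaAnalysis([z[i], z[i]], [v[i], v[i]], [study_ids[i]] * 2)
        res = model.fit_fixed()
        res.k = 1
        res.df = 0
        res.Q, res.I2, res.p_Q = 0.0, 0.0, 1.0
        res.se_z = math.sqrt(v[i])
        return res
    return MetaAnalysis(z[idx], v[idx], [study_ids[i] for i in idx]).fit_fixed()


#: Alias under the conventional name.
top10 = top_precision


# ---------------------------------------------------------------------------
# Limit meta-analysis (extended random-effects model)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LimitMetaResult:
    """Limit meta-analysis: bias-adjusted estimate and small-study test.

    The extended random-effects model allows the expected effect to drift
    with total study variance, E[z_i] = beta + alpha*sqrt(v_i + tau^2).  Its
    expectation in the limit of infinite precision, beta + alpha*tau, is the
    bias-adjusted pooled effect (the "expectation" adjustment).  Q_small =
    Q - Q' (df 1) tests for small-study effects; Q' (df k-2) is the residual
    heterogeneity of the extended model.  G holds the per-study shrinkage
    factors sqrt(tau^2/(v_i + tau^2)).
    """

    r_limit: float
    ci_low: float
    ci_high: float
    z_limit: float
    se_limit: float
    alpha: float
    beta: float
    tau2: float
    Q: float
    Q_small: float
    Q_resid: float
    df_resid: int
    p_small: float
    p_resid: float
    G: np.ndarray = field(repr=False)
    shrunken_z: np.ndarray = field(repr=False)
    note: str = ""

    @property
    def d_limit(self) -> float:
        """Adjusted estimate on the standardized-mean-difference scale."""
        return 2.0 * self.r_limit / math.sqrt(1.0 - self.r_limit**2)

    def __str__(self) -> str:
        return (f"Limit meta-analysis: r={self.r_limit:.3f} "
                f"[{self.ci_low:.3f}, {self.ci_high:.3f}]; "
                f"Q-Q'(1)={self.Q_small:.2f}, p={self.p_small:.4f}; "
                f"Q'({self.df_resid})={self.Q_resid:.2f}, p={self.p_resid:.4f}")


def limit_meta(z, var_z, method: str = "DL", adjust: str = "beta0") -> LimitMetaResult:
    """Fit the limit meta-analysis model on the Fisher-z scale.

    The generalized radial regression z_i*sqrt(w_i) = alpha + beta*sqrt(w_i)
    with random-effects weights w_i = 1/(v_i + tau^2) estimates the limit
    effect beta and small-study coefficient alpha.  Adjustments:

    * ``"beta0"`` (default): beta + alpha*tau, the model expectation at
      infinite precision;
    * ``"betalim"``: beta alone (discards the entire small-study component);
    * ``"mulim"``: random-effects pool of the shrunken estimates.

    The Q decomposition uses fixed-effect weights so that Q = Q_small + Q'
    exactly.  When tau^2 = 0 the shrinkage factors are all zero and the
    adjustment reduces to the regression limit beta (noted on the result).
    """
    z = np.asarray(z, dtype=float)
    v = np.asarray(var_z, dtype=float)
    k = z.size
    if k < 3:
        raise ValueError("limit meta-analysis needs at least three studies")
    fit = MetaAnalysis(z, v).fit(method=method)
    tau2 = fit.tau2
    tau = math.sqrt(tau2)
    Q = fit.Q

    note = ""
    if tau2 == 0.0:
        note = "tau^2 = 0: shrinkage factors are all zero; adjustment is the regression limit"

    w = 1.0 / (v + tau2)
    sw = np.sqrt(w)
    X = np.column_stack([np.ones(k), sw])
    yv = z * sw
    coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
    alpha_c, beta_c = float(coef[0]), float(coef[1])
    resid = yv - X @ coef
    s2 = float(resid @ resid / (k - 2))
    cov = s2 * np.linalg.inv(X.T @ X)

    # shrunken estimates: pulled toward the adjusted center, retaining the
    # between-study component of each study's deviation
    G = np.sqrt(tau2 / (v + tau2))
    shrunken = beta_c + alpha_c * tau + G * (z - fit.mu_z)

    if adjust == "beta0":
        z_adj = beta_c + alpha_c * tau
        var_adj = cov[1, 1] + tau2 * cov[0, 0] + 2.0 * tau * cov[0, 1]
    elif adjust == "betalim":
        z_adj = beta_c
        var_adj = cov[1, 1]
    elif adjust == "mulim":
        mu_fit = MetaAnalysis(shrunken, v).fit(method=method)
        z_adj = mu_fit.mu_z
        var_adj = mu_fit.se_z**2
    else:
        raise ValueError("adjust must be 'beta0', 'betalim' or 'mulim'")
    se_adj = math.sqrt(max(var_adj, 0.0))

    # Q decomposition from the fixed-weight Egger regression (exact split)
    wf = 1.0 / v
    swf = np.sqrt(wf)
    Xf = np.column_stack([np.ones(k), swf])
    coef_f, *_ = np.linalg.lstsq(Xf, z * swf, rcond=None)
    fitted_f = coef_f[1] + coef_f[0] / swf
    Q_resid = float(np.sum(wf * (z - fitted_f) ** 2))
    Q_small = max(0.0, Q - Q_resid)

    lo, hi = z_adj - 1.96 * se_adj, z_adj + 1.96 * se_adj
    return LimitMetaResult(
        r_limit=float(np.tanh(z_adj)),
        ci_low=float(np.tanh(lo)),
        ci_high=float(np.tanh(hi)),
        z_limit=float(z_adj),
        se_limit=se_adj,
        alpha=alpha_c,
        beta=beta_c,
        tau2=tau2,
        Q=Q,
        Q_small=Q_small,
        Q_resid=Q_resid,
        df_resid=k - 2,
        p_small=float(stats.chi2.sf(Q_small, 1)),
        p_resid=float(stats.chi2.sf(Q_resid, k - 2)),
        G=G,
        shrunken_z=shrunken,
        note=note,
    )
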