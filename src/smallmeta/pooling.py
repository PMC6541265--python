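"""Random-effects pooling of study-level correlations (Model/Results style).

The model is the standard two-level normal meta-analysis on the Fisher-z
scale: observed study effects z_i ~ N(theta_i, v_i) with true effects
theta_i ~ N(mu, tau^2).  :class:`MetaAnalysis` holds the data; ``fit``
estimates tau^2 (DerSimonian-Laird by default; Paule-Mandel and REML
available) and returns a :class:`MetaAnalysisResults` carrying the pooled
effect with its Wald confidence interval (back-transformed to r), Cochran's Q
and I^2, and accessors for all small-study-bias diagnostics.
"""
from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import StudyEffect

__all__ = [
    "MetaAnalysis",
    "MetaAnalysisResults",
    "PooledResult",
    "pool_random_effects",
    "pool_fixed_effects",
]


class MetaAnalysis:
    """Meta-analysis model for study effects on the Fisher-z scale.

    Parameters
    ----------
    z, var_z : array-like
        Study effects and their sampling variances on the z scale.
    study_ids : sequence of str, optional
        Labels; defaults to ``study_1 .. study_k``.
    """

    def __init__(self, z, var_z, study_ids: Sequence[str] | None = None):
        self.z = np.asarray(z, dtype=float)
        self.var_z = np.asarray(var_z, dtype=float)
        if self.z.shape != self.var_z.shape or self.z.ndim != 1:
            raise ValueError("z and var_z must be 1-d arrays of equal length")
        if np.any(~np.isfinite(self.z)) or np.any(~np.isfinite(self.var_z)):
            raise ValueError("z and var_z must be finite")
        if np.any(self.var_z <= 0):
            raise ValueError("all sampling variances must be positive")
        if study_ids is None:
            study_ids = [f"study_{i + 1}" for i in range(self.z.size)]
        if len(study_ids) != self.z.size:
            raise ValueError("study_ids length mismatch")
        self.study_ids = list(study_ids)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_study_effects(cls, studies: Sequence[StudyEffect]) -> "MetaAnalysis":
        return cls(
            [s.z for s in studies],
            [s.var_z for s in studies],
            [s.study_id for s in studies],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, effect_col: str = "z",
                       var_col: str = "var_z", id_col: str = "study_id") -> "MetaAnalysis":
        return cls(df[effect_col].to_numpy(), df[var_col].to_numpy(),
                   df[id_col].tolist())

    @classmethod
    def from_correlations(cls, r, n, study_ids=None) -> "MetaAnalysis":
        r = np.asarray(r, dtype=float)
        n = np.asarray(n, dtype=float)
        return cls(np.arctanh(r), 1.0 / (n - 3.0), study_ids)

    # -- tau^2 estimators ---------------------------------------------------

    @property
    def k(self) -> int:
        return self.z.size

    def _q_fixed(self):
        w = 1.0 / self.var_z
        mu_f = np.sum(w * self.z) / np.sum(w)
        return float(np.sum(w * (self.z - mu_f) ** 2)), w

    def _tau2_dl(self) -> float:
        Q, w = self._q_fixed()
        C = np.sum(w) - np.sum(w**2) / np.sum(w)
        return max(0.0, (Q - (self.k - 1)) / C)

    def _tau2_pm(self, tol=1e-10, max_iter=200) -> float:
        # Paule-Mandel: solve Q_gen(tau2) = k - 1 by bisection
        def qgen(t2):
            w = 1.0 / (self.var_z + t2)
            mu = np.sum(w * self.z) / np.sum(w)
            return np.sum(w * (self.z - mu) ** 2)

        if qgen(0.0) <= self.k - 1:
            return 0.0
        lo, hi = 0.0, 1.0
        while qgen(hi) > self.k - 1 and hi < 1e4:
            hi *= 10
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            if qgen(mid) > self.k - 1:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return 0.5 * (lo + hi)

    def _tau2_reml(self, tol=1e-10, max_iter=200) -> float:
        t2 = self._tau2_dl()
        for _ in range(max_iter):
            w = 1.0 / (self.var_z + t2)
            mu = np.sum(w * self.z) / np.sum(w)
            new = max(0.0, float(np.sum(w**2 * ((self.z - mu) ** 2 - self.var_z))
                                 / np.sum(w**2) + 1.0 / np.sum(w)))
            if abs(new - t2) < tol:
                t2 = new
                break
            t2 = new
        return t2

    # -- fitting ------------------------------------------------------------

    def fit(self, method: str = "DL", alpha: float = 0.05) -> "MetaAnalysisResults":
        """Fit the random-effects model; ``method`` in {"DL", "PM", "REML", "FE"}."""
        if self.k < 2:
            raise ValueError("need at least two studies to pool")
        method = method.upper()
        if method == "DL":
            tau2 = self._tau2_dl()
        elif method == "PM":
            tau2 = self._tau2_pm()
        elif method == "REML":
            tau2 = self._tau2_reml()
        elif method == "FE":
            tau2 = 0.0
        else:
            raise ValueError(f"unknown estimator {method!r}")
        return MetaAnalysisResults(self, method=method, tau2=tau2, alpha=alpha)

    def fit_fixed(self, alpha: float = 0.05) -> "MetaAnalysisResults":
        """Inverse-variance fixed-effect fit (tau^2 forced to zero)."""
        return self.fit(method="FE", alpha=alpha)


class MetaAnalysisResults:
    """Fitted pooled effect with heterogeneity statistics and diagnostics.

    Attributes mirror the quantities a meta-analyst reports: ``r_pooled`` with
    ``ci_low``/``ci_high`` (back-transformed Wald interval), ``tau2``, ``Q``,
    ``df`` and ``I2`` (percent).  Small-study-bias methods are exposed as
    methods returning their own result objects.
    """

    def __init__(self, model: MetaAnalysis, method: str, tau2: float, alpha: float = 0.05):
        self.model = model
        self.method = method
        self.tau2 = float(tau2)
        self.alpha = alpha
        self.k = model.k
        self.weights = 1.0 / (model.var_z + self.tau2)
        self.mu_z = float(np.sum(self.weights * model.z) / np.sum(self.weights))
        self.se_z = float(math.sqrt(1.0 / np.sum(self.weights)))
        self.Q, _ = model._q_fixed()
        self.df = self.k - 1
        self.I2 = max(0.0, (self.Q - self.df) / self.Q) * 100.0 if self.Q > 0 else 0.0
        self.p_Q = float(stats.chi2.sf(self.Q, self.df))

    # -- scalar summaries ---------------------------------------------------

    @property
    def r_pooled(self) -> float:
        return float(np.tanh(self.mu_z))

    def conf_int_z(self, alpha: float | None = None) -> tuple[float, float]:
        a = self.alpha if alpha is None else alpha
        q = stats.norm.ppf(1 - a / 2)
        return self.mu_z - q * self.se_z, self.mu_z + q * self.se_z

    def conf_int(self, alpha: float | None = None) -> tuple[float, float]:
        lo, hi = self.conf_int_z(alpha)
        return float(np.tanh(lo)), float(np.tanh(hi))

    @property
    def ci_low(self) -> float:
        return self.conf_int()[0]

    @property
    def ci_high(self) -> float:
        return self.conf_int()[1]

    @property
    def zvalue(self) -> float:
        return self.mu_z / self.se_z

    @property
    def pvalue(self) -> float:
        return float(2 * stats.norm.sf(abs(self.zvalue)))

    # -- diagnostics --------------------------------------------------------

    def egger_test(self, **kwargs):
        from .bias import egger_test

        return egger_test(self.model.z, self.model.var_z, **kwargs)

    def trim_and_fill(self, **kwargs):
        from .bias import trim_and_fill

        return trim_and_fill(self.model.z, self.model.var_z,
                             study_ids=self.model.study_ids,
                             method=self.method, **kwargs)

    def cumulative(self, **kwargs):
        from .bias import cumulative_meta

        return cumulative_meta(self.model.z, self.model.var_z,
                               study_ids=self.model.study_ids,
                               method=self.method, **kwargs)

    def top_precision(self, frac: float = 0.10):
        from .bias import top_precision

        return top_precision(self.model.z, self.model.var_z,
                             study_ids=self.model.study_ids, frac=frac)

    def limit_meta(self, **kwargs):
        from .bias import limit_meta

        return limit_meta(self.model.z, self.model.var_z, **kwargs)

    def leave_one_out(self) -> pd.DataFrame:
        """Refit without each study in turn; one row per omitted study."""
        rows = []
        for i in range(self.k):
            mask = np.arange(self.k) != i
            res = MetaAnalysis(self.model.z[mask], self.model.var_z[mask]).fit(self.method)
            rows.append({"omitted": self.model.study_ids[i],
                         "r_pooled": res.r_pooled, "tau2": res.tau2, "I2": res.I2})
        return pd.DataFrame(rows)

    # -- plot-ready data ----------------------------------------------------

    def forest_data(self) -> pd.DataFrame:
        se = np.sqrt(self.model.var_z)
        q = stats.norm.ppf(1 - self.alpha / 2)
        return pd.DataFrame(
            {
                "study_id": self.model.study_ids,
                "r": np.tanh(self.model.z),
                "ci_low": np.tanh(self.model.z - q * se),
                "ci_high": np.tanh(self.model.z + q * se),
                "weight_pct": 100 * self.weights / self.weights.sum(),
            }
        )

    def funnel_data(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study_id": self.model.study_ids,
                "z": self.model.z,
                "se": np.sqrt(self.model.var_z),
            }
        )

    def plot_forest(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * self.k + 1.5))
        fd = self.forest_data().iloc[::-1]
        y = np.arange(len(fd))
        ax.errorbar(fd["r"], y, xerr=[fd["r"] - fd["ci_low"], fd["ci_high"] - fd["r"]],
                    fmt="s", color="k", ecolor="gray", ms=4)
        ax.axvline(self.r_pooled, color="C0", ls="--", lw=1)
        ax.set_yticks(y, fd["study_id"])
        ax.set_xlabel("correlation r")
        return ax

    def plot_funnel(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fd = self.funnel_data()
        ax.scatter(fd["z"], fd["se"], s=18, color="k")
        ax.axvline(self.mu_z, color="C0", ls="--", lw=1)
        ax.invert_yaxis()
        ax.set_xlabel("Fisher z")
        ax.set_ylabel("standard error")
        return ax

    # -- reporting ----------------------------------------------------------

    def to_dict(self) -> dict:
        lo, hi = self.conf_int()
        return {
            "k": self.k,
            "estimator": self.method,
            "scale": "fisher-z",
            "r_pooled": self.r_pooled,
            "ci_low": lo,
            "ci_high": hi,
            "tau2": self.tau2,
            "Q": self.Q,
            "df": self.df,
            "p_Q": self.p_Q,
            "I2": self.I2,
        }

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Random-effects meta-analysis" if self.method != "FE" else "Fixed-effect meta-analysis",
            "=" * 46,
            f"studies (k)          {self.k:>10d}",
            f"estimator            {self.method:>10s}",
            f"pooled r             {self.r_pooled:>10.4f}",
            f"95% CI               [{lo:.4f}, {hi:.4f}]",
            f"z, p                 {self.zvalue:>10.3f}  {self.pvalue:.4f}",
            f"tau^2 (z scale)      {self.tau2:>10.5f}",
            f"Q (df={self.df:3d})           {self.Q:>10.3f}  p={self.p_Q:.4f}",
            f"I^2                  {self.I2:>9.1f}%",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<MetaAnalysisResults k={self.k} {self.method} "
                f"r={self.r_pooled:.3f} I2={self.I2:.1f}%>")


#: The pooled-summary type is the results class itself.
PooledResult = MetaAnalysisResults


def _as_model(studies) -> MetaAnalysis:
    if isinstance(studies, MetaAnalysis):
        return studies
    if isinstance(studies, pd.DataFrame):
        return MetaAnalysis.from_dataframe(studies)
    return MetaAnalysis.from_study_effects(list(studies))


def pool_random_effects(studies, method: str = "DL") -> MetaAnalysisResults:
    """Random-effects pooling of StudyEffects / study table / model."""
    return _as_model(studies).fit(method=method)


def pool_fixed_effects(studies) -> MetaAnalysisResults:
    """Inverse-variance fixed-effect pooling."""
    return _as_model(studies).fit_fixed()
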