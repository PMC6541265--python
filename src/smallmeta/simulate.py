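"""Synthetic meta-analytic datasets with the structure the pipeline assumes.

The generator emulates an intervention literature: k studies whose true
effects (Fisher-z scale) vary around a mean with between-study SD tau; group
sizes drawn from a skewed log-normal (many small studies, a few large ones);
one or more intervention arms per study; several correlated outcome measures
per arm; and, optionally, selection for significance - studies whose pooled
effect is not significantly positive are redrawn with a given probability,
which induces funnel asymmetry while keeping k fixed (a truncation mode that
simply discards such studies is also provided).

Output uses the same row schema as the packaged tables, so synthetic data
flows through the identical pipeline.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy import stats

__all__ = ["SyntheticConfig", "generate"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Defaults mirror a small-sample intervention literature: 40 studies, a
    small true benefit (z = 0.10), moderate heterogeneity (tau = 0.15), a
    median group size of 20 with substantial spread, three outcomes per study
    correlated at .50, one arm, and no selection.
    """

    k: int = 40
    mu_z: float = 0.10
    tau: float = 0.15
    n_median: float = 20.0
    n_sigma: float = 0.6
    n_min: int = 5
    m_outcomes: int = 3
    within_r: float = 0.5
    n_arms: int = 1
    selection: float = 0.0
    selection_mode: str = "redraw"  # or "truncate"
    alpha: float = 0.05
    seed: int = 0
    max_redraws: int = field(default=5000, repr=False)

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not 0 <= self.selection <= 1:
            raise ValueError("selection must be in [0, 1]")
        if not -1 < self.within_r < 1:
            raise ValueError("within_r must be in (-1, 1)")
        if self.m_outcomes >= 2 and self.within_r < -1.0 / (self.m_outcomes - 1):
            raise ValueError("within_r makes the outcome correlation matrix infeasible")
        if self.selection_mode not in ("redraw", "truncate"):
            raise ValueError("selection_mode must be 'redraw' or 'truncate'")


def _draw_group_size(rng: np.random.Generator, cfg: SyntheticConfig) -> int:
    n = rng.lognormal(mean=math.log(cfg.n_median), sigma=cfg.n_sigma)
    return max(cfg.n_min, int(round(n)))


def _draw_study(rng: np.random.Generator, cfg: SyntheticConfig, sid: str,
                chol: np.ndarray) -> tuple[list[dict], float, float]:
    """One study's rows plus its pooled (z, var) used for the selection rule."""
    theta = rng.normal(cfg.mu_z, cfg.tau)
    n_c = _draw_group_size(rng, cfg)
    rows = []
    zs, n_totals = [], []
    for a in range(cfg.n_arms):
        n_t = _draw_group_size(rng, cfg)
        n_total = n_t + n_c
        v = 1.0 / (n_total - 3.0)
        eps = chol @ rng.standard_normal(cfg.m_outcomes)
        z_hat = theta + math.sqrt(v) * eps
        r_hat = np.tanh(z_hat)
        for j in range(cfg.m_outcomes):
            rows.append(
                {
                    "study_id": sid,
                    "available_data": "post-msds",
                    "measure": f"outcome_{j + 1}",
                    "intervention": f"arm_{a + 1}",
                    "n_t": n_t,
                    "n_c": n_c,
                    "n_total": n_total,
                    "r": float(r_hat[j]),
                }
            )
            zs.append(float(z_hat[j]))
            n_totals.append(n_total)
    z_bar = float(np.mean(zs))
    v_bar = 1.0 / (float(np.mean(n_totals)) - 3.0)
    return rows, z_bar, v_bar


def generate(config: SyntheticConfig) -> pd.DataFrame:
    """Generate an effect table (EffectRow schema) from a config.

    Reproducible: the same config (including seed) yields a bit-identical
    table.  Under ``selection_mode="redraw"`` each selected-for-significance
    study is redrawn until its pooled effect is significantly positive, so k
    stays fixed; under ``"truncate"`` non-significant selected studies are
    dropped and k may shrink.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.m_outcomes
    corr = np.full((m, m), config.within_r)
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("infeasible outcome correlation matrix") from exc
    z_crit = stats.norm.ppf(1.0 - config.alpha / 2.0)

    all_rows: list[dict] = []
    for i in range(config.k):
        sid = f"Synth.{i + 1:03d}"
        rows, z_bar, v_bar = _draw_study(rng, config, sid, chol)
        selected = config.selection > 0 and rng.random() < config.selection
        if selected:
            significant = z_bar / math.sqrt(v_bar) > z_crit
            if config.selection_mode == "truncate":
                if not significant:
                    continue
            else:
                redraws = 0
                while not significant:
                    redraws += 1
                    if redraws > config.max_redraws:
                        raise RuntimeError(
                            "selection redraw limit exceeded; significance is "
                            "essentially unreachable under this configuration"
                        )
                    rows, z_bar, v_bar = _draw_study(rng, config, sid, chol)
                    significant = z_bar / math.sqrt(v_bar) > z_crit
        all_rows.extend(rows)
    df = pd.DataFrame(all_rows)
    for col in ("n_t", "n_c", "n_total"):
        df[col] = df[col].astype("Int64")
    return df
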