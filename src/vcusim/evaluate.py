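"""Across-run aggregation of simulation results.

For each dataset variant the variance-component and trend estimates are
averaged across simulation runs with normal-approximation 95% confidence
intervals (mean +/- 1.96 sd/sqrt(runs)).  Prediction quality of the genotype
deviations H_i is measured per run by the mean squared error and the
Spearman rank correlation between BLUPs and simulated true values over all
genotypes (checks included) tested in at least three distinct years; per-run
MSEs are pooled by a fixed-effect meta-analysis with inverse-squared-SE
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reml import ModelFit, blup_H

__all__ = [
    "RunSummary",
    "summarize",
    "mse_H",
    "pooled_mse",
    "rank_corr_H",
    "eligible_genotypes",
]

Z95 = 1.959963984540054


def eligible_genotypes(data: pd.DataFrame, min_years: int = 3) -> list[str]:
    """Genotypes (candidates and checks) observed in >= min_years distinct
    calendar years of the analysed dataset."""
    ny = data.groupby("genotype")["year"].nunique()
    return sorted(ny[ny >= min_years].index)


def _ci(values: np.ndarray) -> tuple[float, float, float]:
    m = float(np.mean(values))
    half = Z95 * float(np.std(values, ddof=1)) / np.sqrt(len(values))
    return m, m - half, m + half


def mse_H(fit: ModelFit, truth: pd.Series, eligible) -> tuple[float, float, int]:
    """Mean squared difference between predicted and true genotype deviations
    over the eligible genotypes, with its standard error (sd/sqrt(n))."""
    eligible = list(eligible)
    if not eligible:
        raise ValueError("no eligible genotypes")
    pred = blup_H(fit).reindex(eligible)
    if pred.isna().any():
        missing = pred.index[pred.isna()].tolist()[:5]
        raise KeyError(f"fit lacks BLUPs for eligible genotypes, e.g. {missing}")
    sq = (pred.to_numpy() - truth.reindex(eligible).to_numpy()) ** 2
    n = len(sq)
    se = float(np.std(sq, ddof=1)) / np.sqrt(n) if n > 1 else np.inf
    return float(np.mean(sq)), se, n


def rank_corr_H(fit: ModelFit, truth: pd.Series, eligible) -> float:
    """Spearman correlation of predicted vs true genotype deviations."""
    eligible = list(eligible)
    pred = blup_H(fit).reindex(eligible).to_numpy()
    true = truth.reindex(eligible).to_numpy()
    rho = stats.spearmanr(pred, true).statistic
    return float(rho)


def pooled_mse(
    mses: "list[tuple[float, float]]", zero_se_weight: float = 1e12
) -> tuple[float, float, float]:
    """Fixed-effect meta-analytic pool of per-run MSEs.

    Weights are inverse squared standard errors; the pooled CI follows from
    the total weight, half-width 1.96/sqrt(sum of weights).  A run with zero
    SE (e.g. a single eligible genotype pair) is capped at a large weight.
    """
    if len(mses) < 2:
        raise ValueError("need at least two runs to pool")
    est = np.array([m for m, _ in mses], dtype=float)
    se = np.array([s for _, s in mses], dtype=float)
    w = np.where(se > 0, 1.0 / np.maximum(se, 1e-300) ** 2, zero_se_weight)
    w = np.minimum(w, zero_se_weight)
    pooled = float(np.sum(w * est) / np.sum(w))
    half = Z95 / np.sqrt(float(np.sum(w)))
    return pooled, pooled - half, pooled + half


#: rows of the parameter table, in reporting order
PARAM_ORDER = [
    "year",
    "location",
    "year_location",
    "trial",
    "genotype",
    "genotype_location",
    "genotype_year",
    "genotype_year_location",
    "residual",
    "genetic_trend",
    "nongenetic_trend",
]


@dataclass
class RunSummary:
    """Across-run summary for one dataset variant."""

    variant: str
    n_runs: int
    n_failed: int
    params: pd.DataFrame  # index parameter, columns mean/lo/hi
    mse: tuple[float, float, float] | None = None
    mean_rank_corr: float | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.params.copy()
        out.insert(0, "variant", self.variant)
        if self.mse is not None:
            out.loc["mse_H"] = [self.variant, *self.mse]
        if self.mean_rank_corr is not None:
            out.loc["rank_corr_H"] = [self.variant, self.mean_rank_corr, np.nan, np.nan]
        return out


def summarize(
    fits: "list[ModelFit]",
    variant: str = "",
    mses: "list[tuple[float, float]] | None" = None,
    rank_corrs: "list[float] | None" = None,
    n_failed: int = 0,
) -> RunSummary:
    """Aggregate converged fits of one variant across simulation runs."""
    if len(fits) < 2:
        raise ValueError("need at least two converged fits to summarize")
    rows = {}
    for name in PARAM_ORDER:
        if name == "genetic_trend":
            vals = np.array([f.beta_hat for f in fits])
        elif name == "nongenetic_trend":
            vals = np.array([f.gamma_hat for f in fits])
        elif name in fits[0].vc:
            vals = np.array([f.vc[name] for f in fits])
        else:
            continue
        if np.isnan(vals).all():
            continue
        rows[name] = _ci(vals)
    params = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean", "lo", "hi"]
    )
    mse = pooled_mse(mses) if mses else None
    rc = float(np.mean(rank_corrs)) if rank_corrs else None
    return RunSummary(
        variant=variant,
        n_runs=len(fits),
        n_failed=n_failed,
        params=params,
        mse=mse,
        mean_rank_corr=rc,
    )
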