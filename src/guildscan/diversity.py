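"""Alpha diversity: richness, Chao1, Shannon, Simpson, rarefaction curves.

Conventions follow the QIIME-1 defaults: Shannon entropy in bits (log base
2) and Simpson as ``1 - sum(p_i^2)``, the probability that two random reads
come from different OTUs.  Chao1 is the bias-corrected form
``S_obs + F1*(F1-1) / (2*(F2+1))`` with F1/F2 the singleton and doubleton
counts; it equals observed richness when there are no singletons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlphaResult",
    "alpha_diversity",
    "alpha_diversity_table",
    "rarefaction_curve",
    "compare_alpha_paired",
]

METRICS = ("observed_otus", "chao1", "shannon", "simpson")


@dataclass
class AlphaResult:
    """Per-sample values of one alpha metric, with the depth/seed provenance."""

    metric: str
    values: pd.Series
    depth: int | None = None
    seed: int | None = None


def _check_row(counts_row: np.ndarray) -> np.ndarray:
    row = np.asarray(counts_row)
    if row.ndim != 1 or (row < 0).any():
        raise ValueError("counts must be a nonnegative 1-D vector")
    if row.sum() == 0:
        raise ValueError("zero-sum count vector has undefined diversity")
    return row


def alpha_diversity(counts_row, metric: str, shannon_base: float = 2.0) -> float:
    """Alpha diversity of one sample's count vector."""
    row = _check_row(counts_row)
    if metric == "observed_otus":
        return float(np.count_nonzero(row))
    if metric == "chao1":
        s_obs = np.count_nonzero(row)
        f1 = int(np.sum(row == 1))
        f2 = int(np.sum(row == 2))
        return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))
    p = row[row > 0] / row.sum()
    if metric == "shannon":
        return float(-np.sum(p * np.log(p) / np.log(shannon_base)))
    if metric == "simpson":
        return float(1.0 - np.sum(p**2))
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def alpha_diversity_table(table, metrics=METRICS, depth=None, seed=None) -> pd.DataFrame:
    """All requested metrics for every sample of an OtuTable."""
    rows = {
        sid: {m: alpha_diversity(table.counts.loc[sid].to_numpy(), m) for m in metrics}
        for sid in table.sample_ids
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def rarefaction_curve(counts_row, depths, n_reps: int = 10, seed: int = 0) -> pd.Series:
    """Mean observed OTU count over random subsamples at each depth.

    Depths exceeding the row total are skipped (with a warning entry of NaN
    rather than extrapolation).
    """
    row = _check_row(np.asarray(counts_row, dtype=int))
    total = int(row.sum())
    rng = np.random.default_rng(seed)
    out = {}
    for depth in depths:
        if depth > total:
            out[depth] = np.nan
            continue
        obs = [
            np.count_nonzero(rng.multivariate_hypergeometric(row, int(depth)))
            for _ in range(n_reps)
        ]
        out[depth] = float(np.mean(obs))
    return pd.Series(out, name="observed_otus")


def compare_alpha_paired(before: AlphaResult, after: AlphaResult) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank on per-subject differences (after - before).

    Zero differences are dropped (Wilcoxon's original rule); fewer than two
    nonzero differences leave no test to run and raise.
    """
    if not before.values.index.equals(after.values.index):
        raise ValueError("before/after must cover the same subjects in order")
    diffs = (after.values - before.values).to_numpy(dtype=float)
    nonzero = diffs[diffs != 0]
    if nonzero.size < 2:
        raise ValueError("fewer than 2 nonzero paired differences")
    res = stats.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
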