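"""Clinical endpoints and their association with co-abundance groups.

Covers the trial-side statistics: HOMA insulin-resistance / beta-cell
indices (Matthews forms, glucose in mmol/L, insulin in uIU/mL),
last-observation-carried-forward imputation for missed visits, paired
two-tailed t tests within arm, between-arm ANCOVA with the baseline value
as covariate, and the CAG x clinical Spearman association grid computed on
per-subject week12 - week0 deltas.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationGrid",
    "homa_indices",
    "locf_impute",
    "paired_endpoint_test",
    "ancova_between_arms",
    "cag_clinical_association",
]

#: canonical clinical variables with units
CLINICAL_UNITS = {
    "FBG": "mmol/L",
    "PBG2h": "mmol/L",
    "HbA1c": "%",
    "insulin": "uIU/mL",
    "TC": "mmol/L",
    "TG": "mmol/L",
    "LDLc": "mmol/L",
    "HDLc": "mmol/L",
    "weight": "kg",
    "BMI": "kg/m2",
    "waist": "cm",
    "hip": "cm",
    "SBP": "mmHg",
    "DBP": "mmHg",
}


@dataclass
class AssociationGrid:
    """Spearman R and p for every (CAG, clinical variable) pair."""

    r: pd.DataFrame
    p: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.p < alpha


def homa_indices(fbg: float, insulin: float) -> tuple[float, float]:
    """Homeostasis-model indices from fasting glucose and insulin.

    HOMA-IR = FBG * insulin / 22.5 and HOMA-beta = 20 * insulin /
    (FBG - 3.5); the latter is undefined (NaN, with a warning) when fasting
    glucose is at or below 3.5 mmol/L.
    """
    if insulin < 0:
        raise ValueError("insulin must be nonnegative")
    homa_ir = fbg * insulin / 22.5
    if fbg <= 3.5:
        logger.warning("FBG %.2f <= 3.5 mmol/L: HOMA-beta undefined", fbg)
        return float(homa_ir), float("nan")
    return float(homa_ir), float(20.0 * insulin / (fbg - 3.5))


def locf_impute(series: Sequence[float]) -> list[float]:
    """Last observation carried forward over an ordered visit series.

    Missing values (None/NaN) are replaced by the most recent observed
    value; a missing baseline is an error (the subject is excluded
    upstream).  Observed values are never altered.
    """
    out: list[float] = []
    last: Optional[float] = None
    for i, v in enumerate(series):
        missing = v is None or (isinstance(v, float) and np.isnan(v))
        if missing:
            if last is None:
                raise ValueError("baseline visit is missing; subject must be excluded")
            out.append(last)
        else:
            last = float(v)
            out.append(last)
    return out


def paired_endpoint_test(week0: Sequence[float], week12: Sequence[float]) -> tuple[float, float]:
    """Two-tailed paired t test on week12 - week0 within one arm."""
    a = np.asarray(week12, dtype=float)
    b = np.asarray(week0, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 paired observations")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences; t test undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def ancova_between_arms(
    endpoint: Sequence[float],
    baseline: Sequence[float],
    arm: Sequence[str],
) -> tuple[float, float]:
    """Between-arm comparison of a week-12 endpoint adjusting for baseline.

    Fits ``endpoint ~ 1 + baseline + arm`` by OLS; returns the arm
    coefficient (second arm minus first, arms in sorted order) and its
    t-based two-sided p.  A constant baseline is collinear with the
    intercept and is dropped with a warning.
    """
    import statsmodels.api as sm

    y = np.asarray(endpoint, dtype=float)
    base = np.asarray(baseline, dtype=float)
    arm = pd.Series(list(arm))
    arms = sorted(arm.unique())
    if len(arms) != 2:
        raise ValueError("exactly two arms required")
    indicator = (arm == arms[1]).astype(float).to_numpy()
    if np.allclose(base.std(), 0.0):
        warnings.warn("baseline is constant; dropping covariate", stacklevel=2)
        X = np.column_stack([np.ones_like(y), indicator])
        idx = 1
    else:
        X = np.column_stack([np.ones_like(y), base, indicator])
        idx = 2
    fit = sm.OLS(y, X).fit()
    return float(fit.params[idx]), float(fit.pvalues[idx])


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with exact-enumeration p below n=11, t approximation above."""
    n = x.size
    if n <= 10:
        res = stats.spearmanr(x, y)
        # exact permutation p over all orderings at tiny n
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        from itertools import permutations

        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) >= obs - 1e-12:
                count += 1
        return float(res.statistic), count / total
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def cag_clinical_association(
    cag_deltas: pd.DataFrame,
    clinical_deltas: pd.DataFrame,
    key_cags: Optional[Sequence[str]] = None,
) -> AssociationGrid:
    """Spearman grid between CAG abundance deltas and clinical deltas.

    Both inputs are indexed by subject (week12 - week0 per subject).  A
    constant column has an undefined rank correlation and is masked as NaN.
    """
    subjects = cag_deltas.index.intersection(clinical_deltas.index)
    if len(subjects) < 3:
        raise ValueError("fewer than 3 aligned subjects")
    cags = list(key_cags) if key_cags is not None else list(cag_deltas.columns)
    r = pd.DataFrame(index=cags, columns=clinical_deltas.columns, dtype=float)
    p = pd.DataFrame(index=cags, columns=clinical_deltas.columns, dtype=float)
    for cag in cags:
        x = cag_deltas.loc[subjects, cag].to_numpy(dtype=float)
        for var in clinical_deltas.columns:
            y = clinical_deltas.loc[subjects, var].to_numpy(dtype=float)
            if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
                r.loc[cag, var] = np.nan
                p.loc[cag, var] = np.nan
                continue
            rho, pval = _spearman(x, y)
            r.loc[cag, var] = rho
            p.loc[cag, var] = pval
    return AssociationGrid(r, p)
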