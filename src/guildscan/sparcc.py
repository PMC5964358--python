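"""SparCC: sparse correlation inference for compositional count data.

Read counts only carry relative information: closing counts to fractions
induces spurious negative correlation (about -1/(D-1) between D otherwise
independent taxa).  SparCC works from log-ratio variances, which are
invariant to the closure:

    t_ij = Var_samples[ log(x_i / x_j) ] = w_i + w_j - 2 rho_ij sqrt(w_i w_j)

with w_i the latent (basis) log-abundance variance of OTU i.  Under the
sparsity assumption that most correlations vanish, summing over j gives a
linear system for the basis variances,

    t_i. = (D - 2) w_i + T_w,    T_w = sum_i t_i. / (2 (D - 1)),

from which rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)).  Strongly
correlated pairs violate the sparsity assumption, so the estimator
iteratively excludes the currently most-correlated pair from the sums and
re-solves.  Count uncertainty is handled by averaging (median) over
Dirichlet posterior draws of the fractions, and significance by a bootstrap
over samples that re-runs the whole estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["SparccResult", "estimate_fractions", "basis_correlations", "sparcc"]


@dataclass
class SparccResult:
    """Basis correlation matrix with bootstrap pseudo-p-values."""

    otu_ids: list[str]
    rho: np.ndarray
    pvals: Optional[np.ndarray]
    n_draws: int
    n_bootstrap: int
    excluded_pairs: list[tuple[int, int]] = field(default_factory=list)

    def rho_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rho, index=self.otu_ids, columns=self.otu_ids)

    def pval_frame(self):
        import pandas as pd

        if self.pvals is None:
            raise ValueError("no bootstrap was run")
        return pd.DataFrame(self.pvals, index=self.otu_ids, columns=self.otu_ids)


def estimate_fractions(counts: np.ndarray, n_draws: int, seed: int) -> np.ndarray:
    """Posterior fraction draws: per sample, Dirichlet(counts + 1).

    Returns an array of shape (n_draws, n_samples, n_otus) with strictly
    positive rows summing to 1; a zero count still yields a positive
    fraction through the unit pseudocount.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(seed)
    n, d = counts.shape
    draws = np.empty((n_draws, n, d))
    alpha = counts + 1.0
    for k in range(n_draws):
        g = rng.standard_gamma(alpha)
        draws[k] = g / g.sum(axis=1, keepdims=True)
    return draws


def _logratio_variances(fractions: np.ndarray) -> np.ndarray:
    """t_ij = Var over samples of log(x_i/x_j), computed via the log covariance."""
    L = np.log(fractions)
    C = np.cov(L, rowvar=False)
    v = np.diag(C)
    return v[:, None] + v[None, :] - 2.0 * C


def basis_correlations(
    fractions: np.ndarray,
    exclusion_threshold: float = 0.1,
    max_exclusions: Optional[int] = None,
    _collect_excluded: Optional[list] = None,
) -> np.ndarray:
    """One SparCC pass on a single fraction matrix (samples x OTUs).

    Solves the sparsity-approximation linear system for basis variances,
    forms correlations, and iteratively excludes the most-correlated
    remaining pair with |rho| > ``exclusion_threshold``, re-solving after
    each exclusion.  By default the iteration runs until no eligible pair
    exceeds the threshold (``max_exclusions`` caps the rounds); a pair is
    never excluded when either OTU would drop below 3 included partners,
    which keeps the linear system nonsingular.  OTUs whose solved basis
    variance turns nonpositive -- a small-D degeneracy of the linear
    system -- get their correlations zeroed, with a warning.
    """
    fractions = np.asarray(fractions, dtype=float)
    d = fractions.shape[1]
    if d < 4:
        raise ValueError("SparCC needs at least 4 OTUs (D - 2 > 1)")
    t = _logratio_variances(fractions)

    # M encodes which t_ij participate in each row sum; starts fully coupled.
    M = np.ones((d, d)) + np.diag(np.full(d, d - 2.0))
    include = np.ones((d, d), dtype=bool)
    np.fill_diagonal(include, False)
    excluded: list[tuple[int, int]] = []

    def solve() -> np.ndarray:
        t_sum = np.where(include, t, 0.0).sum(axis=1)
        omega = np.linalg.solve(M, t_sum)
        bad = omega <= 0
        if bad.any():
            logger.warning(
                "nonpositive basis variance for OTU index %s; correlations zeroed",
                np.flatnonzero(bad).tolist(),
            )
        om = np.where(bad, np.nan, omega)
        denom = 2.0 * np.sqrt(np.outer(om, om))
        rho = (om[:, None] + om[None, :] - t) / denom
        rho = np.clip(np.nan_to_num(rho, nan=0.0), -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        return rho

    rho = solve()
    limit = max_exclusions if max_exclusions is not None else d * (d - 1) // 2
    for _ in range(limit):
        off = np.abs(rho).copy()
        np.fill_diagonal(off, 0.0)
        off[~include] = 0.0
        degree = include.sum(axis=1)
        off[degree <= 3, :] = 0.0
        off[:, degree <= 3] = 0.0
        i, j = np.unravel_index(np.argmax(off), off.shape)
        if off[i, j] <= exclusion_threshold:
            break
        include[i, j] = include[j, i] = False
        M[i, j] -= 1.0
        M[j, i] -= 1.0
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        excluded.append((min(i, j), max(i, j)))
        rho = solve()
    if _collect_excluded is not None:
        _collect_excluded.extend(excluded)
    return rho


def _rho_from_counts(
    counts: np.ndarray,
    n_draws: int,
    exclusion_threshold: float,
    max_exclusions: Optional[int],
    seed: int,
    collect=None,
) -> np.ndarray:
    draws = estimate_fractions(counts, n_draws, seed)
    rhos = np.stack(
        [
            basis_correlations(
                draws[k], exclusion_threshold, max_exclusions, _collect_excluded=collect
            )
            for k in range(n_draws)
        ]
    )
    return np.median(rhos, axis=0)


def sparcc(
    counts,
    n_draws: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusions: Optional[int] = None,
    n_bootstrap: int = 100,
    seed: int = 0,
    otu_ids: Optional[list[str]] = None,
) -> SparccResult:
    """Full SparCC estimate on a core-OTU count table.

    ``counts`` is samples x OTUs (ndarray or DataFrame).  The point estimate
    is the element-wise median of ``basis_correlations`` over ``n_draws``
    Dirichlet fraction draws.  Significance: ``n_bootstrap`` null datasets
    are built by independently permuting each OTU's counts across samples
    (which preserves every OTU's abundance distribution while destroying
    inter-OTU association), the full estimator is re-run on each, and the
    two-sided pseudo-p is
    ``(1 + #{|rho_null| >= |rho_obs|}) / (1 + n_bootstrap)``; pass
    ``n_bootstrap=0`` to skip.  The (undefined) diagonal p is set to the
    smallest attainable value and should be masked downstream.

    Deterministic given ``seed``; all draw / bootstrap seeds are spawned
    from it.
    """
    try:
        import pandas as pd

        if isinstance(counts, pd.DataFrame):
            otu_ids = otu_ids or list(counts.columns)
            counts = counts.to_numpy()
    except ImportError:  # pragma: no cover
        pass
    counts = np.asarray(counts)
    n, d = counts.shape
    if otu_ids is None:
        otu_ids = [f"OTU{i + 1}" for i in range(d)]
    if n < 8:
        logger.warning("only %d samples; SparCC estimates will be unstable", n)

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(1 + n_bootstrap)
    excluded: list[tuple[int, int]] = []
    rho = _rho_from_counts(
        counts,
        n_draws,
        exclusion_threshold,
        max_exclusions,
        int(child[0].generate_state(1)[0] % (2**31)),
        collect=excluded,
    )

    pvals = None
    if n_bootstrap > 0:
        exceed = np.zeros((d, d))
        abs_obs = np.abs(rho)
        for b in range(n_bootstrap):
            bseed = int(child[1 + b].generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(bseed)
            null = np.column_stack([rng.permutation(counts[:, j]) for j in range(d)])
            rho_b = _rho_from_counts(
                null,
                n_draws,
                exclusion_threshold,
                max_exclusions,
                bseed,
            )
            exceed += np.abs(rho_b) >= abs_obs
        pvals = (1.0 + exceed) / (1.0 + n_bootstrap)
        np.fill_diagonal(pvals, 1.0 / (1.0 + n_bootstrap))

    return SparccResult(
        otu_ids=list(otu_ids),
        rho=rho,
        pvals=pvals,
        n_draws=n_draws,
        n_bootstrap=n_bootstrap,
        excluded_pairs=sorted(set(excluded)),
    )
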