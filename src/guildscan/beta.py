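"""Beta diversity, ordination and permutation tests.

Five bounded [0, 1] distances between communities: Bray-Curtis, binary and
weighted Jaccard, and unweighted / (normalised) weighted UniFrac.  PCA runs
on the log10-normalised table, PCoA on any distance matrix via Gower
double-centering.  Group structure is tested with one-way MANOVA on
ordination scores (Wilks' lambda) and with PERMANOVA: the pseudo-F of
Anderson (2001),

    F = (SS_among / (a - 1)) / (SS_within / (N - a)),

where the sums of squares come from pairwise distances, and the p-value is
``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` over seeded label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "distance_matrix",
    "pca",
    "pcoa",
    "manova_on_scores",
    "permanova",
    "paired_shift_comparison",
    "BETA_METRICS",
]

BETA_METRICS = (
    "bray_curtis",
    "jaccard_binary",
    "jaccard_weighted",
    "unifrac_unweighted",
    "unifrac_weighted",
)


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    ids: list[str]
    data: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.ids = list(self.ids)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if np.abs(self.data - self.data.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(self.data)).max(initial=0.0) != 0.0:
            raise ValueError("diagonal must be exactly zero")
        if (self.data < 0).any():
            raise ValueError("distances must be nonnegative")

    def between(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.data[i, j])

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(k) for k in keep]
        return DistanceMatrix(list(keep), self.data[np.ix_(idx, idx)], self.metric)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.data, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.data, ids=self.ids)


@dataclass
class OrdinationResult:
    """Sample scores with the eigenvalue / explained-variance spectrum."""

    scores: pd.DataFrame  # samples x components
    eigenvalues: np.ndarray
    method: str
    explained: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.explained is None:
            pos = np.clip(self.eigenvalues, 0, None)
            self.explained = pos / pos.sum() if pos.sum() > 0 else pos


def _bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    denom = np.sum(x + y)
    return float(np.sum(np.abs(x - y)) / denom) if denom else 0.0


def _jaccard_binary(x: np.ndarray, y: np.ndarray) -> float:
    a, b = x > 0, y > 0
    union = np.count_nonzero(a | b)
    return 1.0 - np.count_nonzero(a & b) / union if union else 0.0


def _jaccard_weighted(x: np.ndarray, y: np.ndarray) -> float:
    mx = np.sum(np.maximum(x, y))
    return 1.0 - float(np.sum(np.minimum(x, y)) / mx) if mx else 0.0


def distance_matrix(table, metric: str, tree=None) -> DistanceMatrix:
    """Pairwise sample distances for one of the five supported metrics.

    Abundance metrics are computed on relative abundances; the UniFrac pair
    requires a tree (newick path, string, or skbio TreeNode) whose leaves
    cover every OTU in the table.  Weighted UniFrac uses the normalised,
    [0, 1]-bounded variant.
    """
    from .otus import relative_abundance

    ids = table.sample_ids
    if metric in ("unifrac_unweighted", "unifrac_weighted"):
        if tree is None:
            raise ValueError(f"{metric} requires a phylogenetic tree")
        import io as _io

        import skbio
        from skbio.diversity import beta_diversity

        if isinstance(tree, str) and "(" in tree:
            tree = skbio.TreeNode.read(_io.StringIO(tree))
        elif not isinstance(tree, skbio.TreeNode):
            tree = skbio.TreeNode.read(str(tree))
        if len(tree.children) > 2:
            # multifurcating root (e.g. a star tree): insert zero-length
            # internal branches, which leaves every UniFrac value unchanged
            tree = tree.copy()
            tree.bifurcate()
            for node in tree.traverse(include_self=False):
                if node.length is None:
                    node.length = 0.0
        leaves = {t.name for t in tree.tips()}
        missing = [o for o in table.otu_ids if o not in leaves]
        if missing:
            raise ValueError(f"tree is missing OTU leaves: {missing}")
        kw = dict(ids=ids, taxa=table.otu_ids, tree=tree, validate=True)
        if metric == "unifrac_unweighted":
            dm = beta_diversity("unweighted_unifrac", table.counts.to_numpy(), **kw)
        else:
            dm = beta_diversity(
                "weighted_unifrac", table.counts.to_numpy(), normalized=True, **kw
            )
        data = dm.data.copy()
        np.fill_diagonal(data, 0.0)
        return DistanceMatrix(ids, (data + data.T) / 2.0, metric)

    fun = {
        "bray_curtis": _bray_curtis,
        "jaccard_binary": _jaccard_binary,
        "jaccard_weighted": _jaccard_weighted,
    }.get(metric)
    if fun is None:
        raise ValueError(f"unknown metric {metric!r}")
    rel = relative_abundance(table).to_numpy()
    n = len(ids)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            data[i, j] = data[j, i] = fun(rel[i], rel[j])
    return DistanceMatrix(ids, data, metric)


def pca(normalized_table: pd.DataFrame) -> OrdinationResult:
    """Column-centered (unscaled) principal-component analysis."""
    X = np.asarray(normalized_table, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("rank-0 input: all samples identical")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (X.shape[0] - 1)
    scores = pd.DataFrame(
        u * s,
        index=normalized_table.index,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return OrdinationResult(scores, eig, "PCA")


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal-coordinate analysis by Gower double-centering.

    Negative eigenvalues (non-Euclidean distances) are retained in the
    spectrum for transparency; coordinates are built from the positive
    eigenvalues only, with no Cailliez/Lingoes correction.
    """
    D2 = dm.data**2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    scores = pd.DataFrame(
        coords, index=dm.ids, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
    )
    return OrdinationResult(scores, eigvals, "PCoA")


def manova_on_scores(
    scores: pd.DataFrame, group_labels: Sequence, n_components: int = 2
) -> tuple[float, float]:
    """One-way MANOVA (Wilks' lambda F approximation) on leading score columns."""
    from statsmodels.multivariate.manova import MANOVA

    labels = pd.Series(list(group_labels), index=scores.index, name="group")
    if labels.nunique() < 2:
        raise ValueError("MANOVA needs at least two groups")
    k = min(n_components, scores.shape[1])
    if k > len(scores) - labels.nunique():
        raise ValueError("too many components for the sample size")
    Y = scores.iloc[:, :k]
    X = pd.get_dummies(labels, drop_first=True, dtype=float)
    X.insert(0, "Intercept", 1.0)
    try:
        mv = MANOVA(endog=Y.to_numpy(), exog=X.to_numpy())
        res = mv.mv_test(
            hypotheses=[
                (
                    "group",
                    np.hstack(
                        [np.zeros((X.shape[1] - 1, 1)), np.eye(X.shape[1] - 1)]
                    ),
                )
            ]
        )
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("singular within-group covariance; try fewer components") from exc
    tab = res.results["group"]["stat"]
    row = tab.loc["Wilks' lambda"]
    return float(row["F Value"]), float(row["Pr > F"])


def _permanova_ss(D2: np.ndarray, labels: np.ndarray) -> tuple[float, float, int]:
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within, len(groups)


def permanova(
    dm: DistanceMatrix,
    labels: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutational multivariate ANOVA: seeded pseudo-F permutation test."""
    labels = np.asarray(list(labels))
    if len(labels) != len(dm.ids):
        raise ValueError("one label per sample required")
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two members")
    D2 = dm.data**2
    n = len(labels)

    ss_total, ss_within, a = _permanova_ss(D2, labels)

    def f_stat(ss_w: float) -> float:
        return ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))

    f_obs = f_stat(ss_within)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _, ss_w, _ = _permanova_ss(D2, perm)
        if f_stat(ss_w) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return float(f_obs), float(p)


def paired_shift_comparison(
    dms: Mapping[str, DistanceMatrix],
    sample_meta: pd.DataFrame,
    arms: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Compare per-subject week0 -> week12 microbiota shifts between arms.

    For each metric the shift of a subject is the distance between their two
    timepoint samples; arms are compared with a two-sided Mann-Whitney U
    test.  Subjects missing a timepoint are skipped.  Returns one row per
    metric with per-arm median shifts, U and p.
    """
    meta = sample_meta
    if arms is None:
        arms = sorted(meta["arm"].unique())
    if len(arms) != 2:
        raise ValueError("exactly two arms required")
    rows = {}
    for metric, dm in dms.items():
        shifts: dict[str, list[float]] = {a: [] for a in arms}
        for subj, grp in meta.groupby("subject"):
            tps = grp.set_index("timepoint")
            if "week0" not in tps.index or "week12" not in tps.index:
                continue
            s0 = grp.index[grp["timepoint"] == "week0"][0]
            s1 = grp.index[grp["timepoint"] == "week12"][0]
            arm = grp["arm"].iloc[0]
            if arm in shifts:
                shifts[arm].append(dm.between(s0, s1))
        u, p = stats.mannwhitneyu(shifts[arms[0]], shifts[arms[1]], alternative="two-sided")
        rows[metric] = {
            f"median_shift_{arms[0]}": float(np.median(shifts[arms[0]])),
            f"median_shift_{arms[1]}": float(np.median(shifts[arms[1]])),
            "U": float(u),
            "p": float(p),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
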