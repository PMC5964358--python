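"""Co-abundance groups (CAGs): guild structure from the SparCC matrix.

Core OTUs are clustered by Ward linkage on the correlation distance
``d = 1 - rho``.  The dendrogram is then validated top-down: at each node a
PERMANOVA (on the correlation distance restricted to the node's OTUs, with
the two Ward children as groups) decides whether the split is real; a split
is accepted only when p < alpha and both children contain at least two
OTUs.  Leaves of the accepted-split tree are the CAGs.  A CAG's abundance
in a sample is the sum of the relative abundances of its member OTUs, so
the CAG table conserves the core-OTU total per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

from .beta import DistanceMatrix, permanova

__all__ = [
    "CagPartition",
    "CagAbundanceTable",
    "correlation_distance",
    "ward_tree",
    "partition_by_permanova",
    "cag_abundance",
    "compare_cag_paired",
    "export_network",
]


@dataclass
class CagPartition:
    """OTU -> CAG assignment plus the dendrogram and per-split p-values."""

    assignment: dict[str, str]  # otu id -> cag id
    linkage: np.ndarray
    otu_ids: list[str]
    split_pvalues: list[tuple[int, float, bool]]  # (node size, p, accepted)
    alpha: float

    @property
    def n_cags(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for otu, cag in self.assignment.items():
            out.setdefault(cag, []).append(otu)
        return {k: sorted(v) for k, v in sorted(out.items())}

    def labels(self, otu_order: list[str]) -> np.ndarray:
        return np.array([self.assignment[o] for o in otu_order])


@dataclass
class CagAbundanceTable:
    """Samples x CAGs relative-abundance sums with member provenance."""

    abundance: pd.DataFrame
    members: dict[str, list[str]] = field(default_factory=dict)


def correlation_distance(rho: pd.DataFrame) -> DistanceMatrix:
    """d_ij = 1 - rho_ij on OTUs; zero diagonal, range [0, 2]."""
    mat = np.asarray(rho, dtype=float)
    if np.abs(mat - mat.T).max(initial=0.0) > 1e-10:
        raise ValueError("correlation matrix is not symmetric")
    ids = list(rho.index) if isinstance(rho, pd.DataFrame) else [
        f"OTU{i + 1}" for i in range(mat.shape[0])
    ]
    d = 1.0 - (mat + mat.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d, "sparcc_correlation")


def ward_tree(dm: DistanceMatrix) -> np.ndarray:
    """Ward linkage (Lance-Williams update) on the correlation distance.

    OTUs are ordered by sorted label before linkage so that the result is
    invariant to the input order of the distance matrix.
    """
    if len(dm.ids) < 2:
        raise ValueError("need at least 2 OTUs")
    order = sorted(dm.ids)
    d = dm.submatrix(order)
    return hierarchy.linkage(squareform(d.data, checks=False), method="ward")


def partition_by_permanova(
    linkage: np.ndarray,
    dm: DistanceMatrix,
    alpha: float = 0.001,
    n_perm: int = 999,
    seed: int = 0,
) -> CagPartition:
    """Cut the Ward dendrogram where PERMANOVA supports the split.

    Top-down traversal from the root: the two Ward children of a node
    define group labels for a PERMANOVA on the node's sub-distance-matrix;
    the split is accepted iff p <= alpha and both children hold >= 2 OTUs
    (a node whose best split isolates a single OTU is kept whole).  The
    permutation p carries the +1 correction, so its floor at 999
    permutations is exactly 0.001: acceptance is therefore on p <= alpha,
    which makes the conventional alpha = 0.001 attainable.
    Accepted children are recursed into; the final leaves are numbered
    CAG1..CAGk in dendrogram order.
    """
    order = sorted(dm.ids)
    dms = dm.submatrix(order)
    tree = hierarchy.to_tree(linkage)
    ss = np.random.SeedSequence(seed)
    split_log: list[tuple[int, float, bool]] = []
    groups: list[list[str]] = []

    def leaves(node) -> list[str]:
        return [order[i] for i in node.pre_order(lambda x: x.id)]

    def visit(node) -> None:
        if node.is_leaf():
            groups.append([order[node.id]])
            return
        left, right = leaves(node.left), leaves(node.right)
        if len(left) < 2 or len(right) < 2:
            groups.append(left + right)
            return
        members = left + right
        sub = dms.submatrix(members)
        labels = ["L"] * len(left) + ["R"] * len(right)
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        _, p = permanova(sub, labels, n_perm=n_perm, seed=sub_seed)
        accepted = p <= alpha
        split_log.append((len(members), float(p), bool(accepted)))
        if accepted:
            visit(node.left)
            visit(node.right)
        else:
            groups.append(members)

    visit(tree)
    assignment = {
        otu: f"CAG{k + 1}" for k, group in enumerate(groups) for otu in group
    }
    return CagPartition(assignment, linkage, order, split_log, alpha)


def cag_abundance(rel_table: pd.DataFrame, partition: CagPartition) -> CagAbundanceTable:
    """Per-sample CAG abundance: sum of member-OTU relative abundances."""
    members = partition.members()
    missing = [o for g in members.values() for o in g if o not in rel_table.columns]
    if missing:
        raise KeyError(f"relative-abundance table lacks OTUs: {missing}")
    cols = {cag: rel_table[otus].sum(axis=1) for cag, otus in members.items()}
    return CagAbundanceTable(pd.DataFrame(cols), members)


def compare_cag_paired(
    cag_table: CagAbundanceTable,
    sample_meta: pd.DataFrame,
    arm: str,
) -> pd.DataFrame:
    """Per-CAG two-sided Wilcoxon signed-rank, week12 vs week0, within one arm.

    Returns a frame with the median paired difference, the test statistic
    and p per CAG; subjects lacking either timepoint are skipped.
    """
    meta = sample_meta[sample_meta["arm"] == arm]
    pairs: list[tuple[str, str]] = []
    for _, grp in meta.groupby("subject"):
        t0 = grp.index[grp["timepoint"] == "week0"]
        t1 = grp.index[grp["timepoint"] == "week12"]
        if len(t0) == 1 and len(t1) == 1:
            pairs.append((t0[0], t1[0]))
    if not pairs:
        raise ValueError(f"no complete pairs in arm {arm!r}")
    s0 = [p[0] for p in pairs]
    s1 = [p[1] for p in pairs]
    rows = {}
    for cag in cag_table.abundance.columns:
        diff = (
            cag_table.abundance.loc[s1, cag].to_numpy()
            - cag_table.abundance.loc[s0, cag].to_numpy()
        )
        nonzero = diff[diff != 0]
        if nonzero.size < 2:
            raise ValueError(f"{cag}: fewer than 2 nonzero paired differences")
        res = stats.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided")
        rows[cag] = {
            "median_delta": float(np.median(diff)),
            "W": float(res.statistic),
            "p": float(res.pvalue),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def export_network(
    rho: pd.DataFrame,
    partition: CagPartition,
    mean_abundance: Mapping[str, float],
    edge_threshold: float = 0.4,
    use_absolute: bool = False,
    edge_path=None,
    node_path=None,
    graphml_path=None,
):
    """Build the Cytoscape-ready co-abundance network.

    Edges connect OTU pairs with rho above ``edge_threshold`` (positive
    correlations only unless ``use_absolute``); nodes carry their CAG id
    and mean relative abundance.  CAGs none of whose OTUs reach a
    qualifying edge are flagged ``excluded_from_display``.  Returns the
    networkx graph plus node/edge DataFrames; writes TSV/GraphML when paths
    are given.
    """
    import networkx as nx

    otus = list(rho.index)
    g = nx.Graph()
    for otu in otus:
        g.add_node(
            otu,
            cag=partition.assignment[otu],
            mean_abundance=float(mean_abundance.get(otu, 0.0)),
        )
    edges = []
    mat = rho.to_numpy()
    for i in range(len(otus)):
        for j in range(i + 1, len(otus)):
            r = mat[i, j]
            score = abs(r) if use_absolute else r
            if score > edge_threshold:
                g.add_edge(otus[i], otus[j], weight=float(r))
                edges.append({"source": otus[i], "target": otus[j], "rho": float(r)})
    connected_cags = {partition.assignment[n] for n, deg in g.degree() if deg > 0}
    nodes = pd.DataFrame(
        [
            {
                "otu": n,
                "cag": d["cag"],
                "mean_abundance": d["mean_abundance"],
                "excluded_from_display": d["cag"] not in connected_cags,
            }
            for n, d in g.nodes(data=True)
        ]
    )
    edges = pd.DataFrame(edges, columns=["source", "target", "rho"])
    if edge_path is not None:
        edges.to_csv(edge_path, sep="\t", index=False)
    if node_path is not None:
        nodes.to_csv(node_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    return g, nodes, edges
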