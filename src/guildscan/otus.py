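"""OTU clustering and the sample x OTU count table.

Quality-filtered amplicons are clustered into operational taxonomic units
(OTUs) by greedy centroid clustering at 97% identity; counts are organised
in an :class:`OtuTable` which the rest of the pipeline consumes.  The table
supports rarefaction to a common depth, relative abundance, a core-OTU
prevalence filter and the log10 normalisation used for PCA.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "OtuAssignment",
    "cluster_otus",
    "build_table",
    "rarefy",
    "relative_abundance",
    "core_otus",
    "normalize_log",
]


@dataclass
class OtuTable:
    """Samples x OTUs counts plus per-sample metadata.

    ``counts`` is indexed by sample id with one column per OTU id;
    ``sample_meta`` shares the index and carries subject / arm / timepoint.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    otu_taxonomy: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not self.counts.index.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.counts.index]
        if not np.isfinite(self.counts.to_numpy(dtype=float)).all():
            raise ValueError("counts must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        """Samples as rows; metadata columns prefixed '#' before OTU columns."""
        meta = self.sample_meta.add_prefix("#")
        pd.concat([meta, self.counts], axis=1).to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path) -> "OtuTable":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        meta_cols = [c for c in df.columns if c.startswith("#")]
        meta = df[meta_cols].rename(columns=lambda c: c[1:])
        counts = df.drop(columns=meta_cols).astype(int)
        return cls(counts, meta)


@dataclass
class OtuAssignment:
    """read id -> (otu id, identity) plus the centroid sequences."""

    assignments: dict[str, tuple[str, float]]
    centroids: dict[str, str]

    def otu_of(self, read_id: str) -> str:
        return self.assignments[read_id][0]


def _identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns."""
    res = edlib.align(a, b, mode="NW", task="path")
    cols = sum(int(n) for n in re.findall(r"(\d+)", res["cigar"]))
    return (cols - res["editDistance"]) / cols


def cluster_otus(
    seqs: Mapping[str, tuple[str, int]],
    identity: float = 0.97,
) -> OtuAssignment:
    """Greedy centroid clustering of dereplicated reads.

    ``seqs`` maps read id -> (sequence, abundance).  Unique sequences are
    processed in decreasing abundance (ties broken lexicographically by
    sequence); each joins the first existing centroid whose global-alignment
    identity is >= the threshold, otherwise founds a new OTU.  Deterministic
    given the ordering rule, so permuting the input leaves the centroid set
    unchanged when abundances are distinct.
    """
    order = sorted(seqs.items(), key=lambda kv: (-kv[1][1], kv[1][0]))
    centroids: dict[str, str] = {}
    assignments: dict[str, tuple[str, float]] = {}
    for read_id, (seq, _ab) in order:
        seq = seq.upper()
        hit = None
        for otu_id, cent in centroids.items():
            ident = _identity(seq, cent)
            if ident >= identity:
                hit = (otu_id, ident)
                break
        if hit is None:
            otu_id = f"OTU{len(centroids) + 1}"
            centroids[otu_id] = seq
            assignments[read_id] = (otu_id, 1.0)
        else:
            assignments[read_id] = hit
    return OtuAssignment(assignments, centroids)


def build_table(
    assign: OtuAssignment,
    read_sample_map: Mapping[str, str],
    sample_meta: Optional[pd.DataFrame] = None,
) -> OtuTable:
    """Tabulate assigned reads into counts[sample, otu]; totals are conserved."""
    samples = sorted(set(read_sample_map.values()))
    otus = sorted(assign.centroids, key=lambda o: int(o[3:]))
    counts = pd.DataFrame(0, index=samples, columns=otus, dtype=int)
    for read_id, (otu_id, _) in assign.assignments.items():
        if read_id not in read_sample_map:
            raise KeyError(f"read {read_id!r} has no sample assignment")
        counts.loc[read_sample_map[read_id], otu_id] += 1
    if sample_meta is None:
        sample_meta = pd.DataFrame(index=counts.index)
    return OtuTable(counts, sample_meta)


def rarefy(table: OtuTable, depth: int = 5000, seed: int = 0) -> OtuTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning.  Sampling is multivariate hypergeometric per sample, so every
    retained row sums to ``depth`` exactly.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    rows, kept_ids = [], []
    for sid in table.sample_ids:
        row = table.counts.loc[sid].to_numpy()
        total = int(row.sum())
        if total < depth:
            logger.warning("sample %s has %d < %d reads; dropped", sid, total, depth)
            continue
        rows.append(rng.multivariate_hypergeometric(row, depth))
        kept_ids.append(sid)
    if not rows:
        raise ValueError(f"no sample reaches depth {depth}")
    counts = pd.DataFrame(np.array(rows), index=kept_ids, columns=table.otu_ids)
    return OtuTable(counts, table.sample_meta.loc[kept_ids], table.otu_taxonomy)


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Row-normalise counts; every row sums to 1."""
    totals = table.counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return table.counts.div(totals, axis=0)


def core_otus(table: OtuTable, min_prevalence: float = 0.20) -> OtuTable:
    """Restrict to OTUs present in strictly more than ``min_prevalence`` of samples."""
    if len(table.sample_ids) == 0:
        raise ValueError("empty table")
    prevalence = (table.counts > 0).mean(axis=0)
    keep = prevalence.index[prevalence > min_prevalence]
    tax = table.otu_taxonomy.loc[keep] if table.otu_taxonomy is not None else None
    return OtuTable(table.counts[keep].copy(), table.sample_meta, tax)


def normalize_log(table: OtuTable, pseudocount: float = 1e-6) -> pd.DataFrame:
    """log10(relative abundance + pseudocount); the PCA input."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log10(relative_abundance(table) + pseudocount)
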