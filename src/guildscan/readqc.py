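"""Paired-end amplicon read processing.

Three-rule pipeline applied in fixed order:

1. trim both read ends inward at the first base with Phred quality > 20;
2. merge the pair on the best ungapped overlap of at least 50 bp;
3. keep merged reads longer than 399 bp with expected errors below 0.5.

Expected errors for a quality string ``Q_1..Q_L`` are ``sum(10^(-Q_i/10))``,
the mean number of wrong base calls implied by the Phred scores.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO

import numpy as np

__all__ = [
    "SeqRecord",
    "QcReport",
    "trim_low_quality_ends",
    "merge_pair",
    "expected_errors",
    "filter_reads",
    "qc_pipeline",
    "read_fastq",
    "write_fastq",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A read: DNA string plus per-base Phred scores of equal length."""

    id: str
    bases: str
    quals: np.ndarray

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=int)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"{self.id}: {len(self.bases)} bases but {len(self.quals)} quality scores"
            )
        if len(self.quals) and (self.quals.min() < 0 or self.quals.max() > 60):
            raise ValueError(f"{self.id}: Phred scores must lie in [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class QcReport:
    """Bookkeeping for a QC run; rejection reasons partition the losses."""

    n_input_pairs: int = 0
    n_merged: int = 0
    n_passed: int = 0
    reasons: dict = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.reasons[reason] = self.reasons.get(reason, 0) + 1

    def validate(self) -> None:
        if not (self.n_passed <= self.n_merged <= self.n_input_pairs):
            raise AssertionError("QC counts are inconsistent")
        if sum(self.reasons.values()) != self.n_input_pairs - self.n_passed:
            raise AssertionError("rejection reasons do not partition the losses")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input_pairs": self.n_input_pairs,
                "n_merged": self.n_merged,
                "n_passed": self.n_passed,
                "reasons": self.reasons,
            },
            indent=2,
        )


def trim_low_quality_ends(read: SeqRecord, q_threshold: int = 20) -> SeqRecord:
    """Strip both ends inward until the first and last base have Q > threshold.

    Interior low-quality bases are left untouched; the result may be empty.
    Idempotent: trimming a trimmed read changes nothing.
    """
    q = read.quals
    keep = np.flatnonzero(q > q_threshold)
    if keep.size == 0:
        return SeqRecord(read.id, "", np.empty(0, dtype=int))
    lo, hi = keep[0], keep[-1] + 1
    return SeqRecord(read.id, read.bases[lo:hi], q[lo:hi])


def expected_errors(quals: np.ndarray) -> float:
    """Sum of per-base error probabilities, ``sum(10^(-Q/10))``."""
    quals = np.asarray(quals, dtype=float)
    if quals.size == 0:
        raise ValueError("expected_errors of an empty quality vector")
    return float(np.sum(10.0 ** (-quals / 10.0)))


def merge_pair(
    fwd: SeqRecord,
    rev: SeqRecord,
    min_overlap: int = 50,
    max_mismatch_frac: float = 0.1,
) -> tuple[Optional[SeqRecord], Optional[str]]:
    """Merge a read pair on its best ungapped overlap.

    The reverse read arrives in sequencing orientation and is
    reverse-complemented internally.  Every overlap length from
    ``min_overlap`` up to the shorter read is scored by match count; the
    best (ties to the longest) is accepted when its mismatch fraction is at
    most ``max_mismatch_frac``.  Within the overlap the higher-quality base
    wins and the merged quality is the max of the two.

    Returns ``(merged, None)`` on success or ``(None, reason)`` on failure.
    """
    if len(fwd) < min_overlap or len(rev) < min_overlap:
        return None, "too_short_to_merge"
    rc_bases = reverse_complement(rev.bases)
    rc_quals = rev.quals[::-1]
    f = np.frombuffer(fwd.bases.encode(), dtype=np.uint8)
    r = np.frombuffer(rc_bases.encode(), dtype=np.uint8)
    max_l = min(len(f), len(r))

    best_l, best_matches = -1, -1
    for L in range(min_overlap, max_l + 1):
        matches = int(np.count_nonzero(f[len(f) - L :] == r[:L]))
        if matches >= best_matches:  # >= so ties prefer the longer overlap
            best_matches, best_l = matches, L
    mism = best_l - best_matches
    if mism / best_l > max_mismatch_frac:
        return None, "overlap_mismatch"

    L = best_l
    fo_b, fo_q = fwd.bases[len(f) - L :], fwd.quals[len(f) - L :]
    ro_b, ro_q = rc_bases[:L], rc_quals[:L]
    take_f = fo_q >= ro_q
    consensus = "".join(fb if tf else rb for fb, rb, tf in zip(fo_b, ro_b, take_f))
    cons_q = np.maximum(fo_q, ro_q)
    merged = SeqRecord(
        fwd.id,
        fwd.bases[: len(f) - L] + consensus + rc_bases[L:],
        np.concatenate([fwd.quals[: len(f) - L], cons_q, rc_quals[L:]]),
    )
    return merged, None


def filter_reads(
    merged: Iterable[SeqRecord],
    min_len: int = 400,
    max_ee: float = 0.5,
    report: Optional[QcReport] = None,
) -> tuple[list[SeqRecord], QcReport]:
    """Length and expected-error filter: keep iff len >= min_len and EE < max_ee.

    The default min_len of 400 encodes a strict "longer than 399 bp" rule;
    the expected-error bound is strict as well, so EE exactly 0.5 fails.
    """
    report = report if report is not None else QcReport()
    kept: list[SeqRecord] = []
    for rec in merged:
        if len(rec) < min_len:
            report.reject("too_short")
        elif expected_errors(rec.quals) >= max_ee:
            report.reject("high_expected_error")
        else:
            kept.append(rec)
    report.n_passed += len(kept)
    return kept, report


def qc_pipeline(
    pairs: Iterable[tuple[SeqRecord, SeqRecord]],
    q_threshold: int = 20,
    min_overlap: int = 50,
    max_mismatch_frac: float = 0.1,
    min_len: int = 400,
    max_ee: float = 0.5,
) -> tuple[list[SeqRecord], QcReport]:
    """Run trim -> merge -> filter over read pairs and tally a QcReport."""
    report = QcReport()
    merged_reads: list[SeqRecord] = []
    for fwd, rev in pairs:
        report.n_input_pairs += 1
        fwd = trim_low_quality_ends(fwd, q_threshold)
        rev = trim_low_quality_ends(rev, q_threshold)
        rec, reason = merge_pair(fwd, rev, min_overlap, max_mismatch_frac)
        if rec is None:
            report.reject(reason)
            continue
        report.n_merged += 1
        merged_reads.append(rec)
    kept, report = filter_reads(merged_reads, min_len, max_ee, report)
    report.validate()
    return kept, report


# -- FASTQ I/O (Phred+33, gzip-transparent) ----------------------------------


def _open(path, mode: str = "rt") -> TextIO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[SeqRecord]:
    """Yield SeqRecords from a (possibly gzipped) Phred+33 FASTQ file."""
    from Bio import SeqIO

    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield SeqRecord(
                rec.id,
                str(rec.seq).upper(),
                np.asarray(rec.letter_annotations["phred_quality"], dtype=int),
            )


def write_fastq(records: Iterable[SeqRecord], path) -> int:
    n = 0
    with _open(path, "wt") as fh:
        for rec in records:
            qual = "".join(chr(q + 33) for q in rec.quals)
            fh.write(f"@{rec.id}\n{rec.bases}\n+\n{qual}\n")
            n += 1
    return n
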