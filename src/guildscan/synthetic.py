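"""Synthetic microbiome cohorts with known guild structure.

Every fixture the pipeline needs, generated with ground truth attached:

* guild-structured compositional counts — log basis abundances are
  multivariate normal with an exchangeable block-correlation structure
  (high within a guild, low across), closed to fractions and sampled into
  reads by a multinomial, which is exactly the generative world in which
  basis-correlation inference is well-posed;
* paired week-0 / week-12 two-arm cohorts with arm-specific fold-changes
  planted on chosen guilds and clinical deltas linearly coupled to the
  planted guild deltas plus Gaussian noise;
* paired-end FASTQ reads from templates with a controllable overlap and
  per-position quality profile;
* random binary trees over OTU labels for UniFrac.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .otus import OtuTable
from .readqc import SeqRecord, reverse_complement

__all__ = [
    "GuildSpec",
    "EffectSpec",
    "GuildCounts",
    "CohortDataset",
    "generate_guild_counts",
    "generate_paired_cohort",
    "generate_read_pairs",
    "generate_random_tree",
    "DEFAULT_CLINICAL_BASELINES",
]

#: baseline (mean, sd) per clinical variable for a T2DM-with-hyperlipidemia
#: cohort; units as in clinical.CLINICAL_UNITS
DEFAULT_CLINICAL_BASELINES = {
    "FBG": (7.8, 1.5),
    "PBG2h": (11.5, 2.5),
    "HbA1c": (8.0, 1.0),
    "insulin": (12.0, 4.0),
    "TC": (5.5, 1.0),
    "TG": (2.6, 1.0),
    "LDLc": (3.4, 0.8),
    "HDLc": (1.2, 0.3),
    "weight": (75.0, 10.0),
    "BMI": (26.5, 3.0),
    "waist": (95.0, 8.0),
    "hip": (100.0, 6.0),
    "SBP": (130.0, 12.0),
    "DBP": (80.0, 8.0),
}


@dataclass
class GuildSpec:
    """Block-correlation layout of the latent log basis abundances."""

    n_guilds: int
    otus_per_guild: int
    within_corr: float
    between_corr: float = 0.0
    basis_logmean_sd: float = 1.0
    basis_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_guilds < 1 or self.otus_per_guild < 1:
            raise ValueError("n_guilds and otus_per_guild must be positive")
        if not (0.0 <= self.within_corr <= 1.0) or not (0.0 <= self.between_corr < 1.0):
            raise ValueError("correlations must lie in [0, 1)")
        if self.basis_logmean_sd <= 0 or self.basis_log_sd <= 0:
            raise ValueError("spread parameters must be positive")

    @property
    def n_otus(self) -> int:
        return self.n_guilds * self.otus_per_guild

    def correlation_matrix(self) -> np.ndarray:
        d = self.n_otus
        R = np.full((d, d), self.between_corr)
        for g in range(self.n_guilds):
            sl = slice(g * self.otus_per_guild, (g + 1) * self.otus_per_guild)
            R[sl, sl] = self.within_corr
        np.fill_diagonal(R, 1.0)
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError(
                "guild spec implies a non-positive-semidefinite covariance "
                f"(within={self.within_corr}, between={self.between_corr})"
            )
        return R

    def guild_of(self) -> dict[str, int]:
        return {f"OTU{i + 1}": i // self.otus_per_guild for i in range(self.n_otus)}


@dataclass
class EffectSpec:
    """Planted treatment effect: guild fold-changes plus clinical couplings.

    ``arm`` names the treated arm, or ``"both"`` to treat both arms.
    ``clinical_couplings`` maps a clinical variable to
    (guild index, slope, noise sd): the subject's week12-week0 delta of
    that variable is slope * (guild relative-abundance delta) + noise.
    """

    target_guilds: Sequence[int]
    log2_fold_change: Sequence[float]
    arm: str = "A"
    clinical_couplings: Mapping[str, tuple[int, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.target_guilds) != len(self.log2_fold_change):
            raise ValueError("one fold change per target guild")
        if not np.isfinite(list(self.log2_fold_change)).all():
            raise ValueError("fold changes must be finite")
        for var, (g, slope, sd) in self.clinical_couplings.items():
            if sd <= 0:
                raise ValueError(f"{var}: noise sd must be positive")

    def validate_against(self, spec: GuildSpec) -> None:
        for g in self.target_guilds:
            if not (0 <= g < spec.n_guilds):
                raise ValueError(f"target guild {g} outside 0..{spec.n_guilds - 1}")
        for var, (g, _, _) in self.clinical_couplings.items():
            if not (0 <= g < spec.n_guilds):
                raise ValueError(f"coupling for {var} references unknown guild {g}")


@dataclass
class GuildCounts:
    """Counts plus the ground truth used by recovery tests."""

    table: OtuTable
    guild_of: dict[str, int]
    basis: np.ndarray  # latent log basis abundances, samples x OTUs


@dataclass
class CohortDataset:
    """Paired two-arm cohort with embedded ground truth."""

    table_week0: OtuTable
    table_week12: OtuTable
    clinical: pd.DataFrame  # one row per subject-visit
    truth: dict

    def combined_table(self) -> OtuTable:
        counts = pd.concat([self.table_week0.counts, self.table_week12.counts])
        meta = pd.concat([self.table_week0.sample_meta, self.table_week12.sample_meta])
        return OtuTable(counts, meta)

    def clinical_deltas(self) -> pd.DataFrame:
        vars_ = [c for c in self.clinical.columns if c not in ("subject", "arm", "week")]
        out = {}
        piv = self.clinical.set_index(["subject", "week"])
        for v in vars_:
            out[v] = piv[v].unstack("week")[12] - piv[v].unstack("week")[0]
        return pd.DataFrame(out)

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.table_week0.to_tsv(d / "otu_table_week0.tsv")
        self.table_week12.to_tsv(d / "otu_table_week12.tsv")
        self.clinical.to_csv(d / "clinical.csv", index=False)
        truth = {
            "guild_of": self.truth["guild_of"],
            "target_guilds": list(self.truth["effect"].target_guilds),
            "log2_fold_change": list(self.truth["effect"].log2_fold_change),
            "treated_arm": self.truth["effect"].arm,
        }
        (d / "truth.json").write_text(json.dumps(truth, indent=2))


def _basis_logmeans(spec: GuildSpec, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, spec.basis_logmean_sd, size=spec.n_otus)


def _draw_log_basis(
    n: int, mu: np.ndarray, chol: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    z = rng.standard_normal((n, len(mu)))
    return mu + sd * (z @ chol.T)


def generate_guild_counts(
    n_samples: int,
    spec: GuildSpec,
    library_size: int = 10000,
    seed: int = 0,
) -> GuildCounts:
    """Guild-structured compositional counts with ground truth.

    Log basis abundances are MVN with the spec's block correlation; each
    sample's reads are a multinomial draw of ``library_size`` reads from
    the closed basis fractions, so every row sums exactly to the library
    size.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    rng = np.random.default_rng(seed)
    R = spec.correlation_matrix()
    chol = np.linalg.cholesky(R + 1e-12 * np.eye(spec.n_otus))
    mu = _basis_logmeans(spec, rng)
    log_basis = _draw_log_basis(n_samples, mu, chol, spec.basis_log_sd, rng)
    fractions = np.exp(log_basis)
    fractions /= fractions.sum(axis=1, keepdims=True)
    counts = np.stack([rng.multinomial(library_size, f) for f in fractions])
    otu_ids = [f"OTU{i + 1}" for i in range(spec.n_otus)]
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    table = OtuTable(
        pd.DataFrame(counts, index=sample_ids, columns=otu_ids),
        pd.DataFrame(index=sample_ids),
    )
    return GuildCounts(table, spec.guild_of(), log_basis)


def generate_paired_cohort(
    n_per_arm: int,
    spec: GuildSpec,
    effect: EffectSpec,
    seed: int = 0,
    library_size: int = 10000,
    subject_corr: float = 0.7,
    arm_names: tuple[str, str] = ("A", "B"),
    clinical_baselines: Optional[Mapping[str, tuple[float, float]]] = None,
) -> CohortDataset:
    """Two-arm paired cohort with planted guild and clinical effects.

    Week-0 and week-12 log basis abundances are identically distributed
    guild-structured draws correlated within subject at ``subject_corr``
    (the gut microbiome is strongly individual, so repeat samples of one
    person resemble each other far more than samples of different people);
    under a null effect the two timepoints are exchangeable.  In the
    treated arm the week-12 basis abundance of each target guild is
    multiplied by ``2**log2_fold_change`` before closure.  Clinical deltas
    follow the declared linear couplings on the guild relative-abundance
    deltas; un-coupled variables drift by pure noise.
    """
    if n_per_arm < 3:
        raise ValueError("need at least 3 subjects per arm")
    effect.validate_against(spec)
    if effect.arm not in (*arm_names, "both"):
        raise ValueError(f"treated arm {effect.arm!r} not in {arm_names}")
    baselines = dict(clinical_baselines or DEFAULT_CLINICAL_BASELINES)
    rng = np.random.default_rng(seed)
    R = spec.correlation_matrix()
    chol = np.linalg.cholesky(R + 1e-12 * np.eye(spec.n_otus))
    mu = _basis_logmeans(spec, rng)
    otu_ids = [f"OTU{i + 1}" for i in range(spec.n_otus)]
    guild_of = spec.guild_of()
    guild_cols = {
        g: [i for i, o in enumerate(otu_ids) if guild_of[o] == g]
        for g in range(spec.n_guilds)
    }

    counts0, counts12, meta0, meta12 = [], [], [], []
    clin_rows = []
    for arm in arm_names:
        treated = effect.arm in (arm, "both")
        for k in range(n_per_arm):
            subject = f"{arm}{k + 1:03d}"
            z0 = _draw_log_basis(1, mu, chol, spec.basis_log_sd, rng)[0]
            fresh = _draw_log_basis(1, mu, chol, spec.basis_log_sd, rng)[0]
            # AR(1)-style mixture keeps week-12 marginally identical to week-0
            z1 = mu + subject_corr * (z0 - mu) + np.sqrt(1 - subject_corr**2) * (fresh - mu)
            if treated:
                for g, lfc in zip(effect.target_guilds, effect.log2_fold_change):
                    z1[guild_cols[g]] += lfc * np.log(2.0)
            f0 = np.exp(z0)
            f0 /= f0.sum()
            f1 = np.exp(z1)
            f1 /= f1.sum()
            counts0.append(rng.multinomial(library_size, f0))
            counts12.append(rng.multinomial(library_size, f1))
            meta0.append((f"{subject}_w0", subject, arm, "week0"))
            meta12.append((f"{subject}_w12", subject, arm, "week12"))

            guild_delta = {
                g: f1[cols].sum() - f0[cols].sum() for g, cols in guild_cols.items()
            }
            row0 = {"subject": subject, "arm": arm, "week": 0}
            row12 = {"subject": subject, "arm": arm, "week": 12}
            for var, (mean, sd) in baselines.items():
                base = rng.normal(mean, sd)
                if var in effect.clinical_couplings and treated:
                    g, slope, noise_sd = effect.clinical_couplings[var]
                    delta = slope * guild_delta[g] + rng.normal(0.0, noise_sd)
                else:
                    delta = rng.normal(0.0, 0.05 * sd)
                row0[var] = base
                row12[var] = base + delta
            clin_rows.extend([row0, row12])

    def mk_table(counts, meta):
        ids = [m[0] for m in meta]
        md = pd.DataFrame(
            {"subject": [m[1] for m in meta], "arm": [m[2] for m in meta],
             "timepoint": [m[3] for m in meta]},
            index=ids,
        )
        return OtuTable(pd.DataFrame(np.stack(counts), index=ids, columns=otu_ids), md)

    dataset = CohortDataset(
        table_week0=mk_table(counts0, meta0),
        table_week12=mk_table(counts12, meta12),
        clinical=pd.DataFrame(clin_rows),
        truth={"spec": spec, "effect": effect, "guild_of": guild_of},
    )
    return dataset


def generate_read_pairs(
    templates: Sequence[str],
    n_reads_per_template: int,
    read_len: int,
    overlap_len: int,
    error_profile: Optional[Sequence[float]] = None,
    seed: int = 0,
    qual_sd: float = 0.0,
) -> list[tuple[SeqRecord, SeqRecord]]:
    """Paired-end reads whose forward/reverse members overlap exactly.

    Each template yields ``n_reads_per_template`` pairs covering its first
    ``2*read_len - overlap_len`` bases; the reverse read is emitted
    reverse-complemented, as sequenced.  Per-base qualities are drawn
    around ``error_profile`` (mean Phred per read position, default Q40)
    and substitution errors are injected at the rate the drawn quality
    implies.
    """
    if not templates:
        raise ValueError("templates must be nonempty")
    if overlap_len > read_len:
        raise ValueError("overlap_len cannot exceed read_len")
    span = 2 * read_len - overlap_len
    profile = (
        np.full(read_len, 40.0)
        if error_profile is None
        else np.asarray(error_profile, dtype=float)
    )
    if profile.shape != (read_len,):
        raise ValueError("error_profile must have one mean Phred per read position")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    pairs = []
    for t_idx, template in enumerate(templates):
        template = template.upper()
        if len(template) < span:
            raise ValueError(
                f"template {t_idx} length {len(template)} < 2*read_len - overlap_len = {span}"
            )
        fwd_t = template[:read_len]
        rev_t = template[span - read_len : span]
        for k in range(n_reads_per_template):
            recs = []
            for name, seq in (("1", fwd_t), ("2", rev_t)):
                if qual_sd > 0:
                    q = np.rint(rng.normal(profile, qual_sd)).astype(int)
                else:
                    q = np.rint(profile).astype(int)
                q = np.clip(q, 2, 40)
                p_err = 10.0 ** (-q / 10.0)
                bases = np.array(list(seq))
                err = rng.random(read_len) < p_err
                for pos in np.flatnonzero(err):
                    choices = alphabet[alphabet != bases[pos]]
                    bases[pos] = rng.choice(choices)
                recs.append((bases, q))
            rid = f"T{t_idx}_{k}"
            fwd = SeqRecord(rid, "".join(recs[0][0]), recs[0][1])
            rev_bases = reverse_complement("".join(recs[1][0]))
            rev = SeqRecord(rid, rev_bases, recs[1][1][::-1])
            pairs.append((fwd, rev))
    return pairs


def generate_random_tree(otu_labels: Sequence[str], seed: int = 0) -> str:
    """Random rooted binary tree over the labels, as a newick string.

    Subtrees are joined uniformly at random with exponential branch
    lengths; byte-identical output for a fixed seed.
    """
    labels = list(otu_labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate OTU labels")
    rng = np.random.default_rng(seed)
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b1 = rng.exponential(0.1) + 1e-3
        b2 = rng.exponential(0.1) + 1e-3
        merged = f"({nodes[i]}:{b1:.6f},{nodes[j]}:{b2:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"
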