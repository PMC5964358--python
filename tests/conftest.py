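"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

import guildscan as gs


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def qc_fixture():
    """60 read pairs with a known QC fate.

    20 clean pairs (merge to 400 bp at Q40), 20 pairs whose true overlap is
    49 bp (one short of the merge rule), 10 pairs merging to 399 bp (one
    short of the length rule), and 10 pairs at Q21 whose merged expected
    errors exceed 0.5.  Exactly the 20 clean pairs should pass.
    """
    rng = np.random.default_rng(42)
    pairs = []
    # clean: 250 bp reads, 100 bp overlap -> merged length 400
    pairs += gs.generate_read_pairs(
        [random_dna(400, rng) for _ in range(4)], 5, 250, 100, seed=1
    )
    # true overlap 49 bp < 50 -> unmergeable
    pairs += gs.generate_read_pairs(
        [random_dna(451, rng) for _ in range(4)], 5, 250, 49, seed=2
    )
    # merged length 2*250 - 101 = 399, one short of "longer than 399 bp"
    pairs += gs.generate_read_pairs(
        [random_dna(399, rng) for _ in range(2)], 5, 250, 101, seed=3
    )
    # Q21 survives end-trimming (Q > 20) but EE = 400 * 10^-2.1 ~ 3.2 >= 0.5
    pairs += gs.generate_read_pairs(
        [random_dna(400, rng) for _ in range(2)],
        5,
        250,
        100,
        error_profile=np.full(250, 21.0),
        seed=4,
    )
    return pairs


@pytest.fixture(scope="session")
def planted_guilds():
    """Planted 4-guild dataset (within 0.8, D=40, n=200) plus its SparCC fit."""
    spec = gs.GuildSpec(n_guilds=4, otus_per_guild=10, within_corr=0.8)
    data = gs.generate_guild_counts(200, spec, library_size=10000, seed=3)
    result = gs.sparcc(data.table.counts, n_draws=10, n_bootstrap=0, seed=4)
    return spec, data, result


@pytest.fixture(scope="session")
def planted_cohort():
    """Two-arm paired cohort with a guild enriched in both arms and coupled
    negatively to two clinical deltas."""
    spec = gs.GuildSpec(n_guilds=8, otus_per_guild=5, within_corr=0.8)
    effect = gs.EffectSpec(
        target_guilds=[4],
        log2_fold_change=[1.0],
        arm="both",
        clinical_couplings={"FBG": (4, -1.0, 0.01), "TG": (4, -1.0, 0.01)},
    )
    dataset = gs.generate_paired_cohort(50, spec, effect, seed=11)
    return spec, effect, dataset
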