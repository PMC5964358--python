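"""Cluster reads into OTUs at 97% identity and build the count table.

Thirty dereplicated sequences derived from three 300-bp templates with up
to 1% mutations collapse back to three OTUs; the table then tabulates
per-sample counts, is rarefied to a common depth and prevalence-filtered.
"""

import numpy as np

import guildscan as gs

rng = np.random.default_rng(3)
templates = ["".join(rng.choice(list("ACGT"), 300)) for _ in range(3)]

seqs, read_sample_map = {}, {}
for t, tpl in enumerate(templates):
    for k in range(10):
        bases = list(tpl)
        for pos in rng.choice(300, size=rng.integers(0, 4), replace=False):
            bases[pos] = rng.choice([b for b in "ACGT" if b != bases[pos]])
        rid = f"t{t}_r{k}"
        seqs[rid] = ("".join(bases), int(rng.integers(1, 40)))
        read_sample_map[rid] = f"S{k % 3 + 1}"

assign = gs.cluster_otus(seqs, identity=0.97)
print(f"unique reads  : {len(seqs)}")
print(f"OTUs at 97%   : {len(assign.centroids)}  (one per template)")

table = gs.build_table(assign, read_sample_map)
print(f"table shape   : {table.counts.shape[0]} samples x {table.counts.shape[1]} OTUs")
print(table.counts)

core = gs.core_otus(table, min_prevalence=0.20)
print(f"core OTUs (> 20% prevalence): {core.otu_ids}")
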