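"""Run the three-rule read QC on synthetic paired-end reads.

Rule (i) trims both read ends inward at the first base with Phred > 20,
rule (ii) merges pairs on a best ungapped overlap of at least 50 bp, and
rule (iii) keeps merged reads longer than 399 bp with expected errors
below 0.5.
"""

import numpy as np

import guildscan as gs

rng = np.random.default_rng(0)
templates = ["".join(rng.choice(list("ACGT"), 420)) for _ in range(5)]

# clean pairs plus a batch whose overlap is one base short of rule (ii)
pairs = gs.generate_read_pairs(templates, 20, read_len=250, overlap_len=90, seed=1)
pairs += gs.generate_read_pairs(templates, 5, read_len=230, overlap_len=49, seed=2)

kept, report = gs.qc_pipeline(pairs)
print(f"input pairs : {report.n_input_pairs}")
print(f"merged      : {report.n_merged}  (pairs with a >= 50 bp overlap)")
print(f"passed      : {report.n_passed}  (> 399 bp and expected errors < 0.5)")
print(f"rejections  : {report.reasons}")
print(f"mean merged length: {np.mean([len(r) for r in kept]):.0f} bp")

ee = [gs.expected_errors(r.quals) for r in kept]
print(f"mean expected errors of survivors: {np.mean(ee):.3f}")
print("(expected errors = sum of per-base miscall probabilities 10^(-Q/10))")
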