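"""Simulate a pooled, hashed single-cell experiment with ground truth.

Generates six genetically distinct donors, sparse per-cell allele counts
(AD/DP), HTO counts with 30% staining failure, and the noisy assignment
tables a hashing and a genetic demultiplexer would emit.
"""

import jointdemux as jd

cfg = jd.SimConfig(seed=0)
exp = jd.simulate_experiment(cfg)
jd.write_experiment(exp, "scratch/example_sim")

tf = exp.truth.frame
print(f"cells: {len(tf)}  donors: {cfg.n_donors}")
print(f"true doublets: {tf.IsDoublet.sum()}  unstained cells: {(~tf.Stained).sum()}")
print(f"variants: {len(exp.counts.variants)} "
      f"({cfg.n_private_per_donor} planted privates per donor)")
print(f"hashing verdicts: {exp.hashing_table.counts()}")
print(f"genetic verdicts: {exp.genetic_table.counts()}")
# The hashing tool reports unstained cells as negatives; the genetic tool
# sees every singlet but only as an anonymous donor (hidden map below).
print(f"hidden donor map: {exp.donor_map}")
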