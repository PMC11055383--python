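"""Verify the rescue by re-demultiplexing against reconstructed genotypes.

A binomial-likelihood demultiplexer assigns every cell to a donor using
only the minimal reconstructed genotypes, then the refined assignment is
compared with the rescued one: high concordance means the donor-specific
variants carry real identity signal.
"""

import jointdemux as jd

exp = jd.simulate_experiment(jd.SimConfig(seed=0))
m = jd.match_methods(exp.genetic_table, exp.hashing_table, exp.config.n_donors)
joint = jd.joint_assign(exp.hashing_table, exp.genetic_table, m)
genos = jd.reconstruct_genotypes(exp.counts, joint)

refined = jd.assign_cells(exp.counts, genos)
print("refined verdicts:", refined.counts())

frac, n = jd.concordance(refined, joint.as_assignment_table())
print(f"rescued/refined concordance: {frac:.4f} over {n} shared singlets")
# Fewer variants mean shallower per-cell coverage, so the refined pass
# calls more negatives than the rescue; the cells it does call agree with
# the rescued labels almost everywhere.
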