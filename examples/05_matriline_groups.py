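"""Find matriline (zero-pairwise-difference) groups among consensus genomes.

Five genomes share one mtDNA haplotype (differing only in which sites are
uncalled); five others carry private substitutions.
"""

import numpy as np

from paleomito import compare, simulate

rng = np.random.default_rng(7)
L = 16_569
base = simulate.simulate_reference(L, seed=1).encoded

genomes = {}
for i in range(5):  # one maternal lineage, different coverage gaps
    g = base.copy()
    g[rng.choice(L, size=400, replace=False)] = 4  # N
    genomes[f"specimen_mat{i}"] = "".join("ACGTN"[c] for c in g)
for i in range(5):  # unrelated individuals
    g = base.copy()
    sites = rng.choice(L, size=20, replace=False)
    g[sites] = (g[sites] + 1 + i % 3) % 4
    g[rng.choice(L, size=400, replace=False)] = 4
    genomes[f"specimen_ind{i}"] = "".join("ACGTN"[c] for c in g)

matrix = compare.difference_matrix(genomes)
groups = compare.zero_difference_groups(matrix, min_overlap=1_000)
print("groups (size-sorted):")
for grp in groups:
    print(" ", grp)
# A group of five with zero pairwise differences over the jointly covered
# positions indicates the same individual or maternally related individuals.
# Grouping uses maximal cliques because zero-difference is not transitive
# when coverage differs, and ignores pairs sharing <1,000 called positions.
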