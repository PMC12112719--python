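"""Affinity-maturation bookkeeping on a redesigned-variant pool.

Clusters a pool at 97.5% identity, decomposes the cluster centroids into
single mutations, and combines the most improving singles into consensus
double/triple mutants.
"""

import numpy as np

from ubdesign.constants import AA_ALPHABET, UBIQUITIN_WT
from ubdesign.maturation import (
    MaturationConfig,
    apply_mutant,
    cluster_pool,
    consensus_mutants,
    diff_mutations,
    enumerate_singles,
)

parent = UBIQUITIN_WT
rng = np.random.default_rng(4)
pool = []
for _ in range(30):
    seq = list(parent)
    for pos in rng.choice(len(parent), size=int(rng.integers(2, 5)), replace=False):
        options = [a for a in AA_ALPHABET if a != seq[pos]]
        seq[pos] = options[int(rng.integers(len(options)))]
    pool.append("".join(seq))

cfg = MaturationConfig()
clusters, centroids = cluster_pool(pool, cfg)
print(f"pool of {len(pool)} variants -> {len(clusters)} clusters at "
      f"{cfg.cluster_identity:.1%} identity")

specs = [diff_mutations(parent, pool[c]) for c in centroids]
singles = enumerate_singles(specs)
print(f"{len(singles)} distinct single mutations across the centroids")

# synthetic ddG scores stand in for per-variant MD estimates
scored = {str(s): round(float(rng.normal(-0.5, 1.0)), 2) for s in singles}
improving = {m: g for m, g in scored.items() if g < 0}
print(f"{len(improving)} singles have negative ddG (predicted improvement)")

consensus = consensus_mutants(scored, cfg)
print(f"consensus mutants (top improvers, distinct positions): {len(consensus)}")
for m in consensus[:5]:
    print(f"  {m}  ->  {apply_mutant(parent, m)[:40]}...")
print("Each consensus mutant combines 2-3 improving substitutions that do")
print("not touch the same scaffold position.")
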