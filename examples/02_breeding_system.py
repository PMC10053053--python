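"""Run the three-way DLY crossbreeding system at reduced scale.

The pyramid: a purebred nucleus (GGP) of Duroc, Landrace and Yorkshire is
expanded within breed into GP generations; Landrace boars x Yorkshire sows
give the LY parent generation; Duroc terminal boars x LY sows give the
commercial DLY generation.  The nucleus is replaced twice (all males, half
the females) from GP recruits drawn evenly across dam families.
"""

import numpy as np

from crossgp import (BreedSpec, FounderConfig, desk_scale_config,
                     generate_founders, run_breeding_system)

founders = generate_founders(FounderConfig(
    breeds=(BreedSpec("Duroc", 6, 30), BreedSpec("Landrace", 6, 60),
            BreedSpec("Yorkshire", 12, 300)),
    markers_per_chrom=100, seed=1))
system = run_breeding_system(founders, desk_scale_config(seed=2))

print("generation sizes (GGP2/GGP3 are composed of existing animals):")
for label, idx in system.membership.items():
    print(f"  {label:5s} {idx.size:6d}")
print(f"distinct animals in the system: {system.n_distinct}")

cand = system.candidate_idx
breeds = system.population.roster["breed"].to_numpy()[cand]
print(f"purebred candidates (2 boars + 2 gilts per GGP3 sow): {cand.size}")
print("  breed ratio D:L:Y =",
      ":".join(str((breeds == b).sum()) for b in
               ("Duroc", "Landrace", "Yorkshire")),
      "(the 1:2:10 structure of the full-scale design)")

# Mendelian spot-check: every candidate haplotype is carried by a parent
pop = system.population
r = pop.roster
ids = {i: j for j, i in enumerate(r["id"])}
i = int(cand[0])
si = ids[r.loc[i, "sire"]]
ok = np.all((pop.haplotypes[2 * i] == pop.haplotypes[2 * si])
            | (pop.haplotypes[2 * i] == pop.haplotypes[2 * si + 1]))
print(f"paternal haplotype of first candidate consistent with its sire: {ok}")
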