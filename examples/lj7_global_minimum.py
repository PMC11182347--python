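"""Global optimisation of the 7-atom Lennard-Jones cluster.

Basin-hopping (perturb, minimise, Metropolis-accept on minimised
energies) transforms the rugged cluster landscape into basins and finds
the pentagonal-bipyramid global minimum at E = -16.5054 (reduced units).
"""

import numpy as np

from ktntools import basin_hopping, lowest_k, make_lj_cluster

lj = make_lj_cluster(7)
start = np.random.default_rng(0).normal(scale=1.0, size=lj.dimension)
mset = basin_hopping(lj, start, 2000, temperature=1.0, seed=1)

print(f"distinct minima visited: {len(mset)}")
for rank, m in enumerate(lowest_k(mset, 5)):
    print(f"  rank {rank}: E = {m.energy:.6f}")
# The lowest value, -16.505384, is the known LJ7 global minimum; the
# next isomers (-15.935, -15.593) are the capped-octahedron family.
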