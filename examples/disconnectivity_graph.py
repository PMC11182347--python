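"""Potential- and free-energy disconnectivity graphs of a small landscape.

Builds a bead-peptide database (short basin-hopping run plus pairwise
connections), renders the potential-energy disconnectivity graph with
leaves coloured by helix fraction, regroups the minima into free-energy
groups at 310 K, and renders the free-energy graph.
"""

import numpy as np

from ktntools import (build_tree, color_tree, connectunc_refine,
                      make_bead_peptide, regroup_free_energy, render)
from ktntools.basinhopping import basin_hopping, lowest_k
from ktntools.ktn import KTN
from ktntools.metrics import secondary_structure_fractions
from ktntools.units import KB_KCAL

pep = make_bead_peptide(10, "prot1")
net = KTN()
for seed, start in ((0, pep.helix_configuration()),
                    (1, pep.strand_configuration())):
    mset = basin_hopping(pep, start, 400, temperature=1.0, seed=seed)
    for m in lowest_k(mset, 10):
        net.add_minimum(m)
connectunc_refine(net, pep, distance_tol=np.inf, max_attempts=15)

helix = {}
for i, m in net.minima.items():
    ops = secondary_structure_fractions(pep, m.coordinates)
    helix[i] = ops.helix_fraction

tree = build_tree(net)
color_tree(tree, helix, (0.0, 1.0))
render(tree, "pe_disconnectivity.svg")
print(f"potential-energy graph: {tree.leaf_count} leaves "
      f"-> pe_disconnectivity.svg")

grouped = regroup_free_energy(net, 310.0, KB_KCAL * 310.0)
ftree = build_tree(grouped)
render(ftree, "fe_disconnectivity.svg")
print(f"free-energy graph at 310 K: {ftree.leaf_count} groups "
      f"-> fe_disconnectivity.svg")
# Leaves coloured red have no helical content, green-to-blue leaves are
# increasingly helical; the deep blue funnel holds the global minimum.
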