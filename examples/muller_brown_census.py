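"""Stationary-point census of the Müller-Brown surface.

Basin-hopping finds the three minima of this classic 2-D benchmark;
double-ended DNEB + hybrid eigenvector-following searches then locate
the two index-1 saddles connecting them, giving the complete kinetic
transition network of the surface.
"""

import numpy as np

from ktntools import KTN, basin_hopping, connect_pair, make_muller_brown
from ktntools.basinhopping import CartesianMove

mb = make_muller_brown()
mset = basin_hopping(mb, np.array([0.2, 0.8]), 500, temperature=30.0,
                     move=CartesianMove(0.75), seed=7)
net = KTN()
for m in mset:
    net.add_minimum(m)

ids = sorted(net.minima, key=lambda i: net.minima[i].energy)
result = connect_pair(mb, net.minima[ids[0]], net.minima[ids[1]],
                      max_cycles=10)
for (m_minus, ts, m_plus) in result:
    a = net.add_minimum(m_minus)
    b = net.add_minimum(m_plus)
    net.add_transition_state(ts, minus_id=a, plus_id=b)

print(f"{len(net)} minima, {net.n_ts} transition states")
for i in sorted(net.minima, key=lambda i: net.minima[i].energy):
    m = net.minima[i]
    print(f"  min {i}: E = {m.energy:10.4f} at ({m.coordinates[0]:+.4f}, "
          f"{m.coordinates[1]:+.4f})")
for t in sorted(net.transition_states):
    ts = net.transition_states[t]
    print(f"  ts  {t}: E = {ts.energy:10.4f} connecting minima "
          f"{ts.minus_min_id} and {ts.plus_min_id}")
# The three minima (-146.70, -108.17, -80.77) and two saddles (-40.66,
# -72.25) match the published stationary points of this surface.
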