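"""Shear stress on a junction from its four neighbours' tensions.

A junction between cells a and b carries cortical tension on each side;
continuity at the two end vertices ties the cortical tensions to the four
neighbour junctions, giving tau = |(T1+T3) - (T2+T4)| / (2L).
"""

import numpy as np

from epimech import inference, network, synth
from epimech.shear import compute_shear

cfg = synth.SyntheticConfig(n_cells=200, seed=1)
net, truth = synth.generate_equilibrium_network(cfg)
restricted = network.restrict_threefold(net)
inf = inference.infer_tensions(restricted)

estimates, excluded = compute_shear(restricted, inf)
taus = np.array([e.tau for e in estimates.values()])

print(f"junctions with a shear estimate: {len(estimates)}")
print(f"excluded (with reasons):         {len(excluded)}")
print(f"tau median / mean / max:         "
      f"{np.median(taus):.4f} / {taus.mean():.4f} / {taus.max():.4f}")
one = next(iter(estimates.values()))
print(f"example junction {one.junction}: T1..T4 = "
      f"{tuple(round(float(t), 3) for t in one.tensions)}, "
      f"L = {one.length:.1f} px, tau = {one.tau:.4f}")
# tau has units of tension per pixel; it is the average gradient of
# cortical tension transferred across the junction's adhesion complexes.
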