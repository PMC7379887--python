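"""Steady states and perturbation trajectories of the RNA life cycle.

Builds a gene whose processing rate doubles mid-course and shows how the
premature pool drops while the mature pool is only transiently perturbed.
"""

import numpy as np

from rnakinetics import KineticModel, RateFunction, solve, steady_state

# constant rates: the system sits at P = k1/k2, M = k1/k3
P, M = steady_state(2.0, 1.0, 0.5)
print(f"constant rates k1=2, k2=1, k3=0.5  ->  P={P:g}, M={M:g}")

# now let processing rise 1 -> 3 /h around t=4 h
model = KineticModel(
    RateFunction.constant(2.0),
    RateFunction.sigmoid(h0=1.0, h1=3.0, t1=4.0, beta=1.5),
    RateFunction.constant(0.5),
)
times = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0])
traj = solve(model, times)
print("\n  t[h]   premature   mature")
for t, p, m in zip(traj.times, traj.premature, traj.mature):
    print(f"{t:6.1f}  {p:10.4f}  {m:8.4f}")

print(
    "\nPremature RNA falls toward k1/k2_final = 2/3 because faster processing "
    "drains the pool;\nmature RNA dips only transiently and returns to "
    "k1/k3 = 4: its steady state does not depend on k2."
)
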