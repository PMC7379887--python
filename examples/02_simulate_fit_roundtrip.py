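"""Simulate a noisy time course and recover the generating rates.

Draws a gene whose synthesis rate is sigmoidally up-regulated, simulates a
3-replicate nascent-RNA time course at 5% noise, and fits the true
regulatory class back to the data.
"""

from rnakinetics import (
    KineticModel,
    NoiseModel,
    RateFunction,
    RegulatoryClass,
    fit,
    simulate_profile,
)

truth = KineticModel(
    RateFunction.sigmoid(h0=2.0, h1=6.0, t1=4.0, beta=1.0),  # k1 tripled
    RateFunction.constant(1.0),
    RateFunction.constant(0.5),
)
profile, _ = simulate_profile(
    truth, n_replicates=3, noise=NoiseModel(level=0.05), seed=11, sd_mode="exact"
)

result = fit(profile, RegulatoryClass.from_code("s"), seed=11)
print(f"chi2 = {result.objective:.2f} on dof = {result.dof}")
print(f"two-tailed p = {result.p_value:.3f}, AIC = {result.aic:.1f}, converged = {result.converged}")
print("\nparameter   truth   estimate")
truth_values = {
    "k1.h0": 2.0, "k1.h1": 6.0, "k1.t1": 4.0, "k1.beta": 1.0,
    "k2.h0": 1.0, "k3.h0": 0.5,
}
for name, est in result.parameters.items():
    print(f"{name:9s}  {truth_values[name]:6.2f}  {est:8.3f}")

print(
    "\nA p-value away from 0 and 1 says the class explains the data at the "
    "stated replicate noise;\nestimates land within a few percent of the "
    "generating parameters."
)
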