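"""Profile-likelihood confidence intervals for fitted kinetic rates.

Fits constant rates to a simulated steady-state-like time course and
profiles each parameter: the 95% interval is where re-optimizing the other
parameters keeps chi2 within 3.84 of its minimum.
"""

from rnakinetics import (
    KineticModel,
    NoiseModel,
    RateFunction,
    RegulatoryClass,
    confidence_intervals,
    fit,
    simulate_profile,
)

truth = KineticModel(
    RateFunction.constant(3.0),
    RateFunction.constant(1.2),
    RateFunction.constant(0.4),
)
profile, _ = simulate_profile(truth, noise=NoiseModel(level=0.1), seed=21, sd_mode="exact")
result = fit(profile, RegulatoryClass.from_code("no-reg"), seed=21)
intervals = confidence_intervals(result, profile, level=0.95)

print("parameter   truth   estimate   95% CI")
for name, ci in intervals.items():
    est = result.parameters[name]
    truth_val = {"k1.h0": 3.0, "k2.h0": 1.2, "k3.h0": 0.4}[name]
    print(f"{name:9s}  {truth_val:6.2f}  {est:8.3f}   [{ci.lower:.3f}, {ci.upper:.3f}]")

print(
    "\nEach interval should bracket the generating value roughly 95% of the "
    "time; width reflects\nhow strongly 36 noisy observations constrain that "
    "rate."
)
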