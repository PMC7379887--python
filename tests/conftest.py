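import numpy as np
import pytest

from rnakinetics import (
    ExpressionProfile,
    KineticModel,
    RateFunction,
    steady_state,
)


@pytest.fixture
def const_model() -> KineticModel:
    """k1=2 units/h, k2=1/h, k3=0.5/h: steady state P=2, M=4."""
    return KineticModel(
        RateFunction.constant(2.0),
        RateFunction.constant(1.0),
        RateFunction.constant(0.5),
    )


@pytest.fixture
def grid() -> np.ndarray:
    return np.array([0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0])


def exact_profile(
    model: KineticModel,
    times,
    rel_sd: float = 0.05,
    n_replicates: int = 3,
    include_synthesis: bool = True,
) -> ExpressionProfile:
    """Noise-free profile: means equal the clean trajectory exactly."""
    from rnakinetics import solve

    traj = solve(model, times)
    kwargs = {}
    if include_synthesis:
        kwargs = {
            "synthesis_mean": traj.synthesis,
            "synthesis_sd": rel_sd * np.abs(traj.synthesis),
        }
    return ExpressionProfile(
        times=np.asarray(times, dtype=float),
        premature_mean=traj.premature,
        premature_sd=rel_sd * np.abs(traj.premature),
        mature_mean=traj.mature,
        mature_sd=rel_sd * np.abs(traj.mature),
        n_replicates=n_replicates,
        **kwargs,
    )


def rk4_reference(k1f, k2f, k3f, p0, m0, times, n_sub=400):
    """Brute-force fixed-step RK4 integration, independent of the package solvers."""
    times = np.asarray(times, dtype=float)
    P, M = float(p0), float(m0)
    outP, outM = [P], [M]
    for ta, tb in zip(times[:-1], times[1:]):
        h = (tb - ta) / n_sub
        t = ta
        for _ in range(n_sub):
            def f(tt, p, m):
                return (k1f(tt) - k2f(tt) * p, k2f(tt) * p - k3f(tt) * m)

            d1 = f(t, P, M)
            d2 = f(t + h / 2, P + h / 2 * d1[0], M + h / 2 * d1[1])
            d3 = f(t + h / 2, P + h / 2 * d2[0], M + h / 2 * d2[1])
            d4 = f(t + h, P + h * d3[0], M + h * d3[1])
            P += h / 6 * (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0])
            M += h / 6 * (d1[1] + 2 * d2[1] + 2 * d3[1] + d4[1])
            t += h
        outP.append(P)
        outM.append(M)
    return np.array(outP), np.array(outM)
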