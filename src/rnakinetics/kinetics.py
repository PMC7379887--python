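"""The RNA life-cycle ODE system and its steady state.

The abundance of premature (P) and mature (M) RNA of a gene follows

    dP/dt = k1(t) - k2(t) * P
    dM/dt = k2(t) * P - k3(t) * M

where k1, k2, k3 are the synthesis, processing and degradation rates, each a
:class:`~rnakinetics.rates.RateFunction` of time.  When all three rates are
constant the system sits at the steady state P = k1/k2, M = k1/k3; when any
rate varies the system is integrated numerically, starting (by default) from
the steady state implied by the rate values at the first requested time.
Time is in hours; concentrations in arbitrary expression units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _fastsolve
from .errors import ConfigurationError, DomainError, NumericalError
from .rates import Form, RateFunction

__all__ = [
    "KineticModel",
    "Trajectory",
    "steady_state",
    "initial_conditions",
    "solve",
    "closed_form_constant",
]

RATE_NAMES = ("k1", "k2", "k3")
SPECIES = ("premature", "mature", "synthesis")


def steady_state(k1v: float, k2v: float, k3v: float) -> tuple[float, float]:
    """Steady-state premature and mature abundance for fixed rate values.

    Setting both derivatives to zero gives P = k1/k2 and M = k1/k3 exactly.
    """
    if not (k1v > 0 and k2v > 0 and k3v > 0):
        raise DomainError(
            f"steady state undefined for non-positive rates "
            f"(k1={k1v}, k2={k2v}, k3={k3v})"
        )
    return k1v / k2v, k1v / k3v


@dataclass(frozen=True)
class KineticModel:
    """The (k1, k2, k3) triple of rate functions for one gene."""

    k1: RateFunction
    k2: RateFunction
    k3: RateFunction

    @property
    def rates(self) -> tuple[RateFunction, RateFunction, RateFunction]:
        return (self.k1, self.k2, self.k3)

    @property
    def forms(self) -> tuple[Form, Form, Form]:
        return (self.k1.form, self.k2.form, self.k3.form)

    @property
    def is_constant(self) -> bool:
        return all(r.is_constant for r in self.rates)

    @property
    def n_free_params(self) -> int:
        return sum(r.n_params for r in self.rates)

    def to_dict(self) -> dict:
        return {name: r.to_dict() for name, r in zip(RATE_NAMES, self.rates)}

    @classmethod
    def from_dict(cls, config: Mapping) -> "KineticModel":
        extra = set(config) - set(RATE_NAMES)
        if extra:
            raise ConfigurationError(f"unknown keys in model configuration: {sorted(extra)}")
        missing = set(RATE_NAMES) - set(config)
        if missing:
            raise ConfigurationError(f"model configuration missing rates: {sorted(missing)}")
        return cls(*(RateFunction.from_dict(config[name]) for name in RATE_NAMES))

    def _packed(self) -> tuple[np.ndarray, np.ndarray]:
        """Positional encoding for the numba integrator."""
        codes = np.empty(3, dtype=np.int64)
        params = np.zeros((3, 6), dtype=float)
        for i, r in enumerate(self.rates):
            codes[i] = _fastsolve.FORM_CODES[r.form.value]
            params[i, : r.n_params] = r.params
        return codes, params


@dataclass(frozen=True)
class Trajectory:
    """P(t), M(t) and k1(t) sampled on an increasing time grid."""

    times: np.ndarray
    premature: np.ndarray
    mature: np.ndarray
    synthesis: np.ndarray

    def __post_init__(self):
        for name in ("times", "premature", "mature", "synthesis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.times.shape[0]
        for name in ("premature", "mature", "synthesis"):
            if getattr(self, name).shape != (n,):
                raise DomainError(f"trajectory field {name} must match times length {n}")

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table with columns time, species, value."""
        frames = [
            pd.DataFrame({"time": self.times, "species": sp, "value": vals})
            for sp, vals in zip(SPECIES, (self.premature, self.mature, self.synthesis))
        ]
        return pd.concat(frames, ignore_index=True)

    def to_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, sep="\t", comment="#")
        cols = {}
        for sp in SPECIES:
            sub = df[df["species"] == sp].sort_values("time")
            cols[sp] = sub["value"].to_numpy()
        times = np.sort(df["time"].unique())
        return cls(times, cols["premature"], cols["mature"], cols["synthesis"])


def initial_conditions(model: KineticModel, t0: float) -> tuple[float, float]:
    """Equilibrium (P0, M0) implied by the rate values at time ``t0``.

    The system is assumed at steady state with the rates as of the first
    observed/requested time; perturbations unfold from there.
    """
    return steady_state(model.k1(t0), model.k2(t0), model.k3(t0))


def _validate_times(times) -> np.ndarray:
    arr = np.asarray(times, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise DomainError("times must be a non-empty 1-D vector")
    if not np.all(np.isfinite(arr)):
        raise DomainError("times must be finite")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise DomainError("times must be strictly increasing")
    return arr


def solve(
    model: KineticModel,
    times,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    p0: float | None = None,
    m0: float | None = None,
    method: str = "lsoda",
) -> Trajectory:
    """Integrate the ODE system on ``times`` and return the trajectory.

    Initial conditions default to the equilibrium implied by the rates at
    ``times[0]``; pass ``p0``/``m0`` to study relaxation from an arbitrary
    state instead (non-default, mostly for testing).

    ``method="lsoda"`` (default) uses adaptive LSODA with dense output at
    the requested times, robust to stiff rate combinations;
    ``method="fast"`` uses the fixed-step exponential-midpoint scheme of
    :mod:`rnakinetics._fastsolve` (the fitting objective's path).
    """
    t = _validate_times(times)
    if not (rtol > 0 and atol > 0):
        raise DomainError("tolerances must be positive")
    if (p0 is None) != (m0 is None):
        raise DomainError("p0 and m0 must be overridden together")
    if p0 is None:
        p0, m0 = initial_conditions(model, t[0])
    if p0 < 0 or m0 < 0:
        raise DomainError("initial conditions must be non-negative")

    synth = np.asarray(model.k1(t), dtype=float)
    if t.size == 1:
        return Trajectory(t, np.array([p0]), np.array([m0]), synth)

    if method == "fast":
        codes, params = model._packed()
        h = _fastsolve.step_size(codes, params, t)
        out = _fastsolve.integrate(codes, params, t, h, float(p0), float(m0))
        return Trajectory(t, np.clip(out[:, 0], 0, None), np.clip(out[:, 1], 0, None), synth)
    if method != "lsoda":
        raise ConfigurationError(f"unknown solve method {method!r}")

    k1f, k2f, k3f = model.rates

    def rhs(tt, y):
        k1v = k1f(tt)
        k2v = k2f(tt)
        k3v = k3f(tt)
        return (k1v - k2v * y[0], k2v * y[0] - k3v * y[1])

    span = t[-1] - t[0]
    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        (float(p0), float(m0)),
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=atol,
        max_step=span / 25.0,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else float(t[0])
        raise NumericalError(f"ODE integration failed at t={last}: {sol.message}", last)
    P = np.clip(sol.y[0], 0, None)
    M = np.clip(sol.y[1], 0, None)
    return Trajectory(t, P, M, synth)


_DEGENERATE_RTOL = 1e-8  # |k2-k3| below this (relative) switches branches


def closed_form_constant(
    k1v: float,
    k2v: float,
    k3v: float,
    P0: float,
    M0: float,
    times,
) -> Trajectory:
    """Exact solution of the system for constant rates (test oracle).

    With tau measured from ``times[0]``::

        P(tau) = Pss + (P0 - Pss) e^{-k2 tau}
        M(tau) = Mss + A e^{-k3 tau} + B e^{-k2 tau},   B = k2 (P0-Pss)/(k3-k2)

    with A fixed by M(0) = M0.  When k2 == k3 (relative difference below
    1e-8) the degenerate-eigenvalue branch with the secular ``tau e^{-k tau}``
    term is used instead.
    """
    if not (k1v > 0 and k2v > 0 and k3v > 0):
        raise DomainError("closed-form solution requires positive rates")
    t = _validate_times(times)
    tau = t - t[0]
    Pss = k1v / k2v
    Mss = k1v / k3v
    dP = P0 - Pss
    e2 = np.exp(-k2v * tau)
    e3 = np.exp(-k3v * tau)
    P = Pss + dP * e2
    if abs(k3v - k2v) > _DEGENERATE_RTOL * (k2v + k3v):
        B = k2v * dP / (k3v - k2v)
        A = M0 - Mss - B
        M = Mss + A * e3 + B * e2
    else:
        M = Mss + (M0 - Mss) * e3 + k2v * dP * tau * e3
    synth = np.full_like(t, k1v)
    return Trajectory(t, P, M, synth)
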