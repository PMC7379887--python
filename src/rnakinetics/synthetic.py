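"""Ground-truth model and noisy profile generation.

This module is the package's test bed in place of experimental data: it
draws kinetic models of a requested regulatory class at plausible mammalian
scales, solves the life-cycle ODE for the clean trajectories, and layers
replicated Gaussian observation noise on top, producing profiles in the
exact shape the fitting module consumes.

Defaults mimic a perturbation time course: 12 time points over 16 h,
denser early; 3 replicates; Gaussian noise with a 10% coefficient of
variation, truncated at zero.  Variable rates change by a 2-4x fold — a
regulated rate that barely moves is indistinguishable from a constant one
and would not represent a regulated gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, DomainError
from .fitting import RegulatoryClass
from .kinetics import KineticModel, Trajectory, solve
from .profiles import ExpressionProfile
from .rates import Form, RateFunction

__all__ = [
    "NoiseModel",
    "random_model",
    "simulate_profile",
    "DEFAULT_TIMES",
    "DEFAULT_LEVEL_RANGES",
]

#: default sampling grid (hours): denser early, as in typical time courses
DEFAULT_TIMES = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0])

#: baseline level ranges per rate — plausible mammalian scales
#: (k1 in RNA units/h; k2, k3 in 1/h)
DEFAULT_LEVEL_RANGES: dict[str, tuple[float, float]] = {
    "k1": (0.5, 50.0),
    "k2": (0.5, 20.0),
    "k3": (0.05, 5.0),
}

#: fold-change range for variable rates (direction drawn at random)
DEFAULT_FOLD_RANGE = (2.0, 4.0)
#: slope range (1/h) for sigmoid/impulse transitions
DEFAULT_BETA_RANGE = (0.5, 2.0)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian observation noise, by coefficient of variation or absolute sd.

    ``gaussian_cv``: per-replicate sd = level * |true mean| (default level
    0.1).  ``gaussian_sd``: constant absolute sd = level.  ``per_species``
    overrides the level for individual species.
    """

    kind: str = "gaussian_cv"
    level: float = 0.1
    per_species: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.kind not in ("gaussian_cv", "gaussian_sd"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")
        if self.level <= 0:
            raise ConfigurationError("noise level must be > 0")
        if self.per_species:
            for sp, lv in self.per_species.items():
                if lv <= 0:
                    raise ConfigurationError(f"noise level for {sp} must be > 0")

    def sd_for(self, species: str, true_mean: np.ndarray) -> np.ndarray:
        level = self.level
        if self.per_species and species in self.per_species:
            level = self.per_species[species]
        if self.kind == "gaussian_cv":
            return level * np.abs(true_mean)
        return np.full_like(np.asarray(true_mean, dtype=float), level)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_model(
    cls: RegulatoryClass,
    seed,
    level_ranges: Mapping[str, tuple[float, float]] | None = None,
    time_window: tuple[float, float] = (0.0, 16.0),
    fold_range: tuple[float, float] = DEFAULT_FOLD_RANGE,
    beta_range: tuple[float, float] = DEFAULT_BETA_RANGE,
) -> KineticModel:
    """Draw a ground-truth model of the requested class.

    Baseline levels are log-uniform within ``level_ranges``; variable rates
    move by a log-uniform fold within ``fold_range``, up or down with equal
    probability; first transitions fall in the first half of the window so
    the response is observable, second (impulse) transitions later.
    """
    rng = _rng(seed)
    ranges = dict(DEFAULT_LEVEL_RANGES)
    if level_ranges:
        ranges.update(level_ranges)
    t_lo, t_hi = time_window
    span = t_hi - t_lo
    if span <= 0:
        raise ConfigurationError("time_window must have positive span")
    rates = []
    for name, form in zip(("k1", "k2", "k3"), cls.forms):
        lo, hi = ranges[name]
        if not (0 < lo < hi):
            raise ConfigurationError(f"invalid level range for {name}: ({lo}, {hi})")
        h0 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if form is Form.CONSTANT:
            rates.append(RateFunction.constant(h0))
            continue
        fold = float(np.exp(rng.uniform(np.log(fold_range[0]), np.log(fold_range[1]))))
        direction = 1.0 if rng.random() < 0.5 else -1.0
        beta = float(np.exp(rng.uniform(np.log(beta_range[0]), np.log(beta_range[1]))))
        t1 = float(rng.uniform(t_lo + 0.15 * span, t_lo + 0.5 * span))
        if form is Form.SIGMOID:
            h1 = h0 * fold**direction
            rates.append(RateFunction.sigmoid(h0, h1, t1, beta))
        else:
            h1 = h0 * fold**direction
            fold2 = float(np.exp(rng.uniform(np.log(fold_range[0]), np.log(fold_range[1]))))
            dir2 = 1.0 if rng.random() < 0.5 else -1.0
            h2 = h0 * fold2**dir2
            t2 = float(rng.uniform(t1 + 0.2 * span, t_lo + 0.9 * span))
            rates.append(RateFunction.impulse(h0, h1, h2, t1, t2, beta))
    return KineticModel(*rates)


def simulate_profile(
    model: KineticModel,
    times=DEFAULT_TIMES,
    n_replicates: int = 3,
    noise: NoiseModel | None = None,
    seed=None,
    include_synthesis: bool = True,
    sd_mode: str = "empirical",
) -> tuple[ExpressionProfile, Trajectory]:
    """Simulate a replicated noisy profile plus its clean trajectory.

    The ODE is solved for the true P(t), M(t) (and k1(t) when
    ``include_synthesis`` enables the nascent-RNA mode); ``n_replicates``
    Gaussian observations per species/time are drawn and truncated at zero.
    ``sd_mode`` picks the stored standard deviation: ``"empirical"``
    (default) the across-replicate sample sd, as a pipeline would compute
    from real replicates; ``"exact"`` the noise law's true sd, appropriate
    when the noise magnitude is known and the chi-squared weighting should
    be exact.
    """
    if n_replicates < 2:
        raise DomainError("n_replicates must be >= 2 for sd estimation")
    if sd_mode not in ("empirical", "exact"):
        raise ConfigurationError(f"unknown sd_mode {sd_mode!r}")
    noise = noise or NoiseModel()
    rng = _rng(seed)
    clean = solve(model, times)
    truths = {"premature": clean.premature, "mature": clean.mature}
    if include_synthesis:
        truths["synthesis"] = clean.synthesis

    fields: dict[str, np.ndarray | None] = {
        "synthesis_mean": None, "synthesis_sd": None,
    }
    n_truncated = 0
    for sp, truth in truths.items():
        sd_true = noise.sd_for(sp, truth)
        draws = rng.normal(loc=truth, scale=sd_true, size=(n_replicates, truth.size))
        n_truncated += int(np.sum(draws < 0))
        draws = np.clip(draws, 0.0, None)
        fields[f"{sp}_mean"] = draws.mean(axis=0)
        fields[f"{sp}_sd"] = sd_true if sd_mode == "exact" else draws.std(axis=0, ddof=1)
    if n_truncated:
        import logging

        logging.getLogger(__name__).debug(
            "truncated %d negative replicate draws to zero", n_truncated
        )
    profile = ExpressionProfile(
        times=np.asarray(times, dtype=float),
        n_replicates=n_replicates,
        **fields,
    )
    return profile, clean
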