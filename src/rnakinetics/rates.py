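"""Time-dependent functional forms for RNA kinetic rates.

Each kinetic rate of the RNA life cycle — synthesis (k1), processing (k2),
degradation (k3) — is parameterized as one of three analytic functions of
time:

* ``constant``: a fixed level ``h0``.
* ``sigmoid``: an S-shaped transition between a starting level ``h0`` and a
  final level ``h1``, centred at time ``t1`` with slope ``beta``:
  ``f(t) = h0 + (h1 - h0) * sigma(beta * (t - t1))`` where
  ``sigma(x) = 1 / (1 + exp(-x))``.
* ``impulse``: a product of two sigmoids allowing double-sigmoid or
  bell-shaped responses, with a second transition to level ``h2`` at time
  ``t2`` and a shared slope:
  ``f(t) = (1/h1) * [h0 + (h1-h0)*sigma(beta*(t-t1))]
                 * [h2 + (h1-h2)*sigma(-beta*(t-t2))]``.

Levels carry rate units (RNA units/h for synthesis, 1/h for processing and
degradation), times are in hours, and ``beta`` is in 1/h.  All levels and the
slope must be strictly positive, so every form evaluates to a finite,
strictly positive rate at any finite time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, DomainError

__all__ = ["Form", "RateFunction", "n_params"]


class Form(str, Enum):
    """Functional form of a kinetic rate."""

    CONSTANT = "constant"
    SIGMOID = "sigmoid"
    IMPULSE = "impulse"


_PARAM_NAMES: dict[Form, tuple[str, ...]] = {
    Form.CONSTANT: ("h0",),
    Form.SIGMOID: ("h0", "h1", "t1", "beta"),
    Form.IMPULSE: ("h0", "h1", "h2", "t1", "t2", "beta"),
}

#: parameter indices holding level parameters (must be > 0)
_LEVEL_IDX: dict[Form, tuple[int, ...]] = {
    Form.CONSTANT: (0,),
    Form.SIGMOID: (0, 1),
    Form.IMPULSE: (0, 1, 2),
}


def _coerce_form(form: Form | str) -> Form:
    try:
        return Form(form)
    except ValueError:
        raise ConfigurationError(
            f"unknown rate functional form {form!r}; "
            f"expected one of {[f.value for f in Form]}"
        ) from None


def n_params(form: Form | str) -> int:
    """Number of free parameters of a functional form (1, 4 or 6)."""
    return len(_PARAM_NAMES[_coerce_form(form)])


@dataclass(frozen=True)
class RateFunction:
    """One kinetic rate as a functional form plus its parameter vector.

    Parameters are ordered as named in the field's convention:
    constant ``(h0,)``; sigmoid ``(h0, h1, t1, beta)``;
    impulse ``(h0, h1, h2, t1, t2, beta)``.
    """

    form: Form
    params: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        form = _coerce_form(self.form)
        object.__setattr__(self, "form", form)
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        names = _PARAM_NAMES[form]
        if len(params) != len(names):
            raise ConfigurationError(
                f"{form.value} rate requires {len(names)} parameters "
                f"{names}, got {len(params)}"
            )
        if not all(np.isfinite(params)):
            raise ConfigurationError(f"non-finite parameter in {params}")
        for i in _LEVEL_IDX[form]:
            if params[i] <= 0.0:
                raise ConfigurationError(
                    f"level parameter {names[i]}={params[i]} must be > 0"
                )
        if form is not Form.CONSTANT and params[names.index("beta")] <= 0.0:
            raise ConfigurationError("slope beta must be > 0")
        if form is Form.IMPULSE and not params[3] < params[4]:
            raise ConfigurationError(
                f"impulse transition times must satisfy t1 < t2, "
                f"got t1={params[3]}, t2={params[4]}"
            )

    # -- constructors ----------------------------------------------------

    @classmethod
    def constant(cls, h0: float) -> "RateFunction":
        return cls(Form.CONSTANT, (h0,))

    @classmethod
    def sigmoid(cls, h0: float, h1: float, t1: float, beta: float) -> "RateFunction":
        return cls(Form.SIGMOID, (h0, h1, t1, beta))

    @classmethod
    def impulse(
        cls, h0: float, h1: float, h2: float, t1: float, t2: float, beta: float
    ) -> "RateFunction":
        return cls(Form.IMPULSE, (h0, h1, h2, t1, t2, beta))

    # -- evaluation ------------------------------------------------------

    def __call__(self, t):
        """Evaluate the rate at time(s) ``t`` (hours).

        Scalar input returns a float; array input returns an array of the
        same shape, elementwise in order.
        """
        arr = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise DomainError(f"rate evaluation requires finite time, got {t!r}")
        p = self.params
        if self.form is Form.CONSTANT:
            out = np.full_like(arr, p[0])
        elif self.form is Form.SIGMOID:
            h0, h1, t1, beta = p
            out = h0 + (h1 - h0) * expit(beta * (arr - t1))
        else:
            h0, h1, h2, t1, t2, beta = p
            first = h0 + (h1 - h0) * expit(beta * (arr - t1))
            second = h2 + (h1 - h2) * expit(-beta * (arr - t2))
            out = first * second / h1
        if arr.ndim == 0:
            return float(out)
        return out

    # -- structure -------------------------------------------------------

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAM_NAMES[self.form]

    def asymptotes(self) -> tuple[float, float]:
        """Limits of the rate at t -> -inf and t -> +inf.

        constant -> (h0, h0); sigmoid -> (h0, h1); impulse -> (h0, h2):
        far before t1 the impulse factors tend to h0 and h1 (product h0*h1/h1),
        far after t2 they tend to h1 and h2.
        """
        p = self.params
        if self.form is Form.CONSTANT:
            return (p[0], p[0])
        if self.form is Form.SIGMOID:
            return (p[0], p[1])
        return (p[0], p[2])

    @property
    def is_constant(self) -> bool:
        return self.form is Form.CONSTANT

    # -- configuration I/O -----------------------------------------------

    def to_dict(self) -> dict:
        """Serializable mapping ``{"form": ..., "params": {name: value}}``."""
        return {
            "form": self.form.value,
            "params": dict(zip(self.param_names, self.params)),
        }

    @classmethod
    def from_dict(cls, config: Mapping) -> "RateFunction":
        """Build from a configuration mapping; unknown keys are rejected."""
        if not isinstance(config, Mapping):
            raise ConfigurationError(f"rate configuration must be a mapping, got {config!r}")
        extra = set(config) - {"form", "params"}
        if extra:
            raise ConfigurationError(f"unknown keys in rate configuration: {sorted(extra)}")
        if "form" not in config:
            raise ConfigurationError("rate configuration missing 'form'")
        form = _coerce_form(config["form"])
        names = _PARAM_NAMES[form]
        raw = config.get("params", {})
        if not isinstance(raw, Mapping):
            raise ConfigurationError("'params' must be a mapping of name -> value")
        unknown = set(raw) - set(names)
        if unknown:
            raise ConfigurationError(
                f"unknown parameters {sorted(unknown)} for {form.value} form "
                f"(expected {names})"
            )
        missing = set(names) - set(raw)
        if missing:
            raise ConfigurationError(
                f"missing parameters {sorted(missing)} for {form.value} form"
            )
        return cls(form, tuple(float(raw[n]) for n in names))
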