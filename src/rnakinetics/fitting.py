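"""Rate-function parameter estimation, goodness of fit and model selection.

Given a replicated expression profile (premature and mature RNA, plus the
observed synthesis rate in the nascent-RNA mode), the fitter estimates the
parameters of the functional forms assigned to k1-k3 by minimizing a
weighted least-squares objective

    chi2 = sum_species sum_t  (prediction(t) - mean(t))^2 / (sd(t)^2 / n_rep)

i.e. residuals weighted by the variance of the replicate mean, which makes
the minimized objective a chi-squared statistic under Gaussian replicate
error.  Model predictions come from integrating the life-cycle ODE system
from equilibrium initial conditions at the first observed time.

Alternative regulatory models — which rates vary, and by which form — are
encoded by :class:`RegulatoryClass` (short codes as used in the field:
"sd" = variable synthesis and degradation, constant processing; "sp" =
variable synthesis and processing, constant degradation; "no-reg" = all
constant) and compared by AIC = chi2 + 2k, penalizing model complexity.
The chi-squared test p-value is two-tailed: a fit far better than the
stated replicate variances allow is as suspicious as a poor one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist

from . import _fastsolve
from .errors import ConfigurationError, DomainError, FitError
from .kinetics import KineticModel, solve
from .profiles import ExpressionProfile
from .rates import Form, RateFunction, n_params

__all__ = [
    "RegulatoryClass",
    "FitResult",
    "ParameterCI",
    "chi_squared",
    "goodness_of_fit",
    "fit",
    "refine",
    "select_model",
    "confidence_intervals",
]

logger = logging.getLogger(__name__)

_RATE_NAMES = ("k1", "k2", "k3")
_FORM_RANK = {Form.CONSTANT: 0, Form.SIGMOID: 1, Form.IMPULSE: 2}
_VARIABLE_FLAGS = ("s", "p", "d")  # synthesis, processing, degradation

#: optimizer tolerance used for "no worse than" comparisons between fits
OPTIMIZER_TOL = 1e-6


# ---------------------------------------------------------------------------
# regulatory classes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegulatoryClass:
    """Which kinetic rates are variable, and by which functional form."""

    k1_form: Form
    k2_form: Form
    k3_form: Form

    def __post_init__(self):
        for name in ("k1_form", "k2_form", "k3_form"):
            object.__setattr__(self, name, Form(getattr(self, name)))

    @property
    def forms(self) -> tuple[Form, Form, Form]:
        return (self.k1_form, self.k2_form, self.k3_form)

    @property
    def code(self) -> str:
        flags = "".join(
            flag
            for flag, form in zip(_VARIABLE_FLAGS, self.forms)
            if form is not Form.CONSTANT
        )
        return flags or "no-reg"

    @property
    def n_free_params(self) -> int:
        return sum(n_params(f) for f in self.forms)

    @property
    def is_constant(self) -> bool:
        return all(f is Form.CONSTANT for f in self.forms)

    @classmethod
    def from_code(
        cls, code: str, variable_form: Form | str = Form.SIGMOID
    ) -> "RegulatoryClass":
        """Expand a short code ("sd", "sp", "no-reg", ...) into explicit forms.

        ``variable_form`` (sigmoid by default, impulse on request) is used
        for every rate flagged variable.
        """
        vform = Form(variable_form)
        if vform is Form.CONSTANT:
            raise ConfigurationError("variable_form must be sigmoid or impulse")
        flags = "" if code in ("no-reg", "") else code
        if any(c not in _VARIABLE_FLAGS for c in flags) or len(set(flags)) != len(flags):
            raise ConfigurationError(
                f"invalid regulatory class code {code!r}; expected a subset of "
                f"'spd' in order, or 'no-reg'"
            )
        if "".join(c for c in _VARIABLE_FLAGS if c in flags) != flags:
            raise ConfigurationError(
                f"regulatory class code {code!r} must order flags as s, p, d"
            )
        forms = tuple(
            vform if flag in flags else Form.CONSTANT for flag in _VARIABLE_FLAGS
        )
        return cls(*forms)

    @classmethod
    def of_model(cls, model: KineticModel) -> "RegulatoryClass":
        return cls(*model.forms)

    def embeds(self, other: "RegulatoryClass") -> bool:
        """True if every fit of ``self`` is representable under ``other``."""
        return all(
            _FORM_RANK[a] <= _FORM_RANK[b] for a, b in zip(self.forms, other.forms)
        )


def embed_model(model: KineticModel, target: RegulatoryClass, t_lo: float, t_hi: float) -> KineticModel:
    """Re-express a fitted model under a richer class, preserving the time course.

    constant -> sigmoid uses equal levels; constant/sigmoid -> impulse uses
    h2 = h1, which makes the second impulse factor identically h1 and
    collapses the product to the simpler form exactly.
    """
    span = max(t_hi - t_lo, 1e-6)
    out = []
    for rf, form in zip(model.rates, target.forms):
        if rf.form is form:
            out.append(rf)
        elif rf.form is Form.CONSTANT and form is Form.SIGMOID:
            out.append(RateFunction.sigmoid(rf.params[0], rf.params[0], t_lo + span / 2, 1.0))
        elif rf.form is Form.CONSTANT and form is Form.IMPULSE:
            h0 = rf.params[0]
            out.append(
                RateFunction.impulse(h0, h0, h0, t_lo + span / 3, t_lo + 2 * span / 3, 1.0)
            )
        elif rf.form is Form.SIGMOID and form is Form.IMPULSE:
            h0, h1, t1, beta = rf.params
            out.append(RateFunction.impulse(h0, h1, h1, t1, t1 + span / 2, beta))
        else:
            raise ConfigurationError(
                f"cannot embed {rf.form.value} rate into {form.value} form"
            )
    return KineticModel(*out)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

_SD_ABS_FLOOR = 1e-6
_SD_REL_FLOOR = 0.01


def _effective_sd(mean: np.ndarray, sd: np.ndarray, label: str) -> np.ndarray:
    floor = np.maximum(_SD_ABS_FLOOR, _SD_REL_FLOOR * np.abs(mean))
    floored = sd < floor
    if np.any(floored):
        logger.debug("floored %d %s sd values to avoid infinite weights", floored.sum(), label)
    return np.maximum(sd, floor)


def _weights(data: ExpressionProfile) -> dict[str, np.ndarray]:
    """Per-species weights = n_replicates / floored sd^2 (inverse variance of the mean)."""
    return {
        sp: data.n_replicates / _effective_sd(data.mean(sp), data.sd(sp), sp) ** 2
        for sp in data.species()
    }


_SPECIES_COL = {"premature": 0, "mature": 1, "synthesis": 2}


def chi_squared(model: KineticModel, data: ExpressionProfile, method: str = "fast") -> float:
    """Weighted least-squares objective of a model against a profile.

    Species entering the sum are premature, mature, and — when the profile
    carries it — the synthesis rate, whose prediction is k1(t).
    """
    traj = solve(model, data.times, method=method)
    preds = {"premature": traj.premature, "mature": traj.mature, "synthesis": traj.synthesis}
    w = _weights(data)
    total = 0.0
    for sp in data.species():
        total += float(np.sum(w[sp] * (preds[sp] - data.mean(sp)) ** 2))
    return total


def goodness_of_fit(chisq: float, dof: int, n_free_params: int) -> tuple[float, float]:
    """Two-tailed chi-squared p-value and AIC for a minimized objective.

    ``p = 2 * min(F(chi2; dof), 1 - F(chi2; dof))`` capped at 1 — both
    too-poor and suspiciously-too-good fits are flagged.  ``AIC = chi2 + 2k``
    with k the free-parameter count; additive data-only constants of the
    Gaussian log-likelihood cancel when comparing models on the same data.
    """
    if dof < 1:
        raise DomainError(f"goodness-of-fit statistics undefined for dof={dof} < 1")
    if chisq < 0:
        raise DomainError("chi-squared objective must be non-negative")
    F = chi2_dist.cdf(chisq, df=dof)
    p = min(1.0, 2.0 * min(F, 1.0 - F))
    aic = chisq + 2.0 * n_free_params
    return p, aic


# ---------------------------------------------------------------------------
# parameter transform
# ---------------------------------------------------------------------------

_LOG_CLAMP = 50.0
_LOG_SOFT = 25.0


class _Transform:
    """Bijection between models of a class and the unconstrained search space.

    Levels and slopes are optimized as logarithms (positivity for free);
    transition times are unconstrained but quadratically penalized outside
    [t_first - span, t_last + span]; the impulse ordering t1 < t2 is kept by
    optimizing t1 and log(t2 - t1).
    """

    def __init__(self, cls: RegulatoryClass, times: np.ndarray):
        self.cls = cls
        self.t_lo = float(times[0])
        self.t_hi = float(times[-1])
        self.span = max(self.t_hi - self.t_lo, 1e-6)
        self.codes = np.array(
            [_fastsolve.FORM_CODES[f.value] for f in cls.forms], dtype=np.int64
        )
        self.names: list[str] = []
        self._slices: list[slice] = []
        start = 0
        for rate_name, form in zip(_RATE_NAMES, cls.forms):
            k = n_params(form)
            self._slices.append(slice(start, start + k))
            if form is Form.CONSTANT:
                self.names.append(f"{rate_name}.h0")
            elif form is Form.SIGMOID:
                self.names += [f"{rate_name}.{p}" for p in ("h0", "h1", "t1", "beta")]
            else:
                self.names += [f"{rate_name}.{p}" for p in ("h0", "h1", "h2", "t1", "t2", "beta")]
            start += k
        self.n = start

    def pack(self, model: KineticModel) -> np.ndarray:
        theta = np.empty(self.n)
        for sl, rf, form in zip(self._slices, model.rates, self.cls.forms):
            if rf.form is not form:
                raise ConfigurationError(
                    f"model form {rf.form.value} does not match class form {form.value}"
                )
            p = rf.params
            if form is Form.CONSTANT:
                theta[sl] = [np.log(p[0])]
            elif form is Form.SIGMOID:
                theta[sl] = [np.log(p[0]), np.log(p[1]), p[2], np.log(p[3])]
            else:
                theta[sl] = [
                    np.log(p[0]), np.log(p[1]), np.log(p[2]),
                    p[3], np.log(p[4] - p[3]), np.log(p[5]),
                ]
        return theta

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """Fast positional parameter matrices plus the soft-constraint penalty."""
        params = np.zeros((3, 6))
        penalty = 0.0
        lo = self.t_lo - self.span
        hi = self.t_hi + self.span
        for i, (sl, form) in enumerate(zip(self._slices, self.cls.forms)):
            seg = theta[sl]
            logs = seg if form is Form.CONSTANT else None
            if form is Form.CONSTANT:
                params[i, 0] = np.exp(min(seg[0], _LOG_CLAMP))
            elif form is Form.SIGMOID:
                params[i, 0] = np.exp(min(seg[0], _LOG_CLAMP))
                params[i, 1] = np.exp(min(seg[1], _LOG_CLAMP))
                params[i, 2] = seg[2]
                params[i, 3] = np.exp(min(seg[3], _LOG_CLAMP))
                penalty += self._time_penalty(seg[2], lo, hi)
            else:
                params[i, 0] = np.exp(min(seg[0], _LOG_CLAMP))
                params[i, 1] = np.exp(min(seg[1], _LOG_CLAMP))
                params[i, 2] = np.exp(min(seg[2], _LOG_CLAMP))
                params[i, 3] = seg[3]
                params[i, 4] = seg[3] + np.exp(min(seg[4], _LOG_CLAMP))
                params[i, 5] = np.exp(min(seg[5], _LOG_CLAMP))
                penalty += self._time_penalty(seg[3], lo, hi)
                penalty += self._time_penalty(params[i, 4], lo, hi)
            # soft guard against runaway log coordinates
            for j, x in enumerate(seg):
                is_time = (form is Form.SIGMOID and j == 2) or (form is Form.IMPULSE and j == 3)
                if not is_time and abs(x) > _LOG_SOFT:
                    penalty += 10.0 * (abs(x) - _LOG_SOFT) ** 2
        return self.codes, params, penalty

    def _time_penalty(self, t: float, lo: float, hi: float) -> float:
        if t < lo:
            return 100.0 * ((lo - t) / self.span) ** 2
        if t > hi:
            return 100.0 * ((t - hi) / self.span) ** 2
        return 0.0

    def unpack(self, theta: np.ndarray) -> KineticModel:
        _, params, _ = self.matrices(theta)
        rates = []
        for i, form in enumerate(self.cls.forms):
            rates.append(RateFunction(form, tuple(params[i, : n_params(form)])))
        return KineticModel(*rates)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterCI:
    lower: float
    upper: float
    lower_bounded: bool = True
    upper_bounded: bool = True


@dataclass
class FitResult:
    """Estimated model with its goodness-of-fit record."""

    model: KineticModel
    regulatory_class: RegulatoryClass
    objective: float
    dof: int
    p_value: float
    aic: float
    n_free_params: int
    converged: bool
    n_iterations: int
    optimizer: str
    seed: int | None = None
    ci: dict[str, ParameterCI] | None = None
    ci_level: float | None = None

    @property
    def parameters(self) -> dict[str, float]:
        """Flat name -> value view of the fitted parameters."""
        out = {}
        for rate_name, rf in zip(_RATE_NAMES, self.model.rates):
            for pname, val in zip(rf.param_names, rf.params):
                out[f"{rate_name}.{pname}"] = val
        return out

    def to_dict(self) -> dict:
        d = {
            "model": self.model.to_dict(),
            "regulatory_class": self.regulatory_class.code,
            "forms": [f.value for f in self.regulatory_class.forms],
            "objective": self.objective,
            "dof": self.dof,
            "p_value": self.p_value,
            "aic": self.aic,
            "n_free_params": self.n_free_params,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "optimizer": self.optimizer,
            "seed": self.seed,
        }
        if self.ci is not None:
            d["ci_level"] = self.ci_level
            d["ci"] = {
                name: {
                    "lower": ci.lower,
                    "upper": ci.upper,
                    "lower_bounded": ci.lower_bounded,
                    "upper_bounded": ci.upper_bounded,
                }
                for name, ci in self.ci.items()
            }
        return d


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_OPTIMIZERS = ("nelder-mead", "bfgs")


def _make_objective(transform: _Transform, data: ExpressionProfile):
    times = np.asarray(data.times, dtype=float)
    w = _weights(data)
    species = data.species()
    obs = {sp: data.mean(sp) for sp in species}

    def chi2_of(theta: np.ndarray) -> float:
        codes, params, _ = transform.matrices(theta)
        h = _fastsolve.step_size(codes, params, times)
        k1 = _fastsolve._rate(codes[0], params[0], times[0])
        k2 = _fastsolve._rate(codes[1], params[1], times[0])
        k3 = _fastsolve._rate(codes[2], params[2], times[0])
        out = _fastsolve.integrate(codes, params, times, h, k1 / k2, k1 / k3)
        total = 0.0
        for sp in species:
            col = out[:, _SPECIES_COL[sp]]
            total += float(np.sum(w[sp] * (col - obs[sp]) ** 2))
        return total

    def penalized(theta: np.ndarray) -> float:
        _, _, pen = transform.matrices(theta)
        val = chi2_of(theta)
        if not np.isfinite(val):
            return 1e300
        return val + pen

    return chi2_of, penalized


def _steepest_time(times: np.ndarray, values: np.ndarray) -> float:
    if times.size < 2:
        return float(times[0])
    slopes = np.abs(np.diff(values) / np.diff(times))
    i = int(np.argmax(slopes))
    return float(0.5 * (times[i] + times[i + 1]))


def _constant_anchors(data: ExpressionProfile) -> tuple[np.ndarray, np.ndarray]:
    """Crude (first, last) level estimates per rate from the steady-state relations.

    In the nascent-RNA mode k1 is read from the synthesis observations and
    k2, k3 follow from P = k1/k2, M = k1/k3 applied at the profile ends.
    Without synthesis the overall scale is anchored at k3 = 1/h.
    """
    eps = 1e-6
    P = np.maximum(data.premature_mean, eps)
    M = np.maximum(data.mature_mean, eps)
    if data.has_synthesis:
        S = np.maximum(data.synthesis_mean, eps)
        k1 = np.array([S[0], S[-1]])
    else:
        k1 = np.array([M[0], M[-1]])  # implies k3 ~ 1
    k2 = k1 / np.array([P[0], P[-1]])
    k3 = k1 / np.array([M[0], M[-1]])
    return np.stack([k1, k2, k3]), np.array([P[0], M[0]])


def _data_driven_model(data: ExpressionProfile, cls: RegulatoryClass) -> KineticModel:
    anchors, _ = _constant_anchors(data)
    t_lo, t_hi = float(data.times[0]), float(data.times[-1])
    span = max(t_hi - t_lo, 1e-6)
    steep_species = {
        0: "synthesis" if data.has_synthesis else "mature",
        1: "premature",
        2: "mature",
    }
    rates = []
    for i, form in enumerate(cls.forms):
        first, last = anchors[i]
        if form is Form.CONSTANT:
            rates.append(RateFunction.constant(float(np.sqrt(first * last))))
        elif form is Form.SIGMOID:
            t1 = _steepest_time(data.times, data.mean(steep_species[i]))
            rates.append(RateFunction.sigmoid(first, last, t1, 1.0))
        else:
            h1 = 1.5 * float(np.sqrt(first * last))
            rates.append(
                RateFunction.impulse(first, h1, last, t_lo + span / 3, t_lo + 2 * span / 3, 1.0)
            )
    return KineticModel(*rates)


def _flat_model(data: ExpressionProfile, cls: RegulatoryClass) -> KineticModel:
    anchors, _ = _constant_anchors(data)
    levels = np.sqrt(anchors[:, 0] * anchors[:, 1])
    const = KineticModel(*(RateFunction.constant(float(l)) for l in levels))
    return embed_model(const, cls, float(data.times[0]), float(data.times[-1]))


def _jitter(theta: np.ndarray, transform: _Transform, rng: np.random.Generator) -> np.ndarray:
    out = theta.copy()
    for sl, form in zip(transform._slices, transform.cls.forms):
        seg = out[sl]
        for j in range(seg.size):
            is_time = (form is Form.SIGMOID and j == 2) or (form is Form.IMPULSE and j == 3)
            if is_time:
                seg[j] += rng.normal(0.0, transform.span / 6.0)
            else:
                seg[j] += rng.normal(0.0, 0.5)
    return out


def _run_optimizer(penalized, theta0: np.ndarray, optimizer: str, max_iter: int):
    if optimizer == "nelder-mead":
        return minimize(
            penalized,
            theta0,
            method="Nelder-Mead",
            options={
                "maxiter": max_iter,
                "maxfev": max_iter,
                "xatol": 1e-5,
                "fatol": 1e-7,
                "adaptive": True,
            },
        )
    if optimizer == "bfgs":
        return minimize(penalized, theta0, method="BFGS", options={"maxiter": max_iter})
    raise ConfigurationError(f"unknown optimizer {optimizer!r}; expected one of {_OPTIMIZERS}")


def _steady_state_inversion(data: ExpressionProfile, cls: RegulatoryClass, optimizer: str, seed: int | None) -> FitResult:
    # one steady-state point with observed synthesis: three equations in
    # three unknowns, solved exactly (k1 = S, k2 = k1/P, k3 = k1/M)
    S = float(data.synthesis_mean[0])
    P = float(data.premature_mean[0])
    M = float(data.mature_mean[0])
    if min(S, P, M) <= 0:
        raise FitError("steady-state inversion requires positive observations")
    model = KineticModel(
        RateFunction.constant(S),
        RateFunction.constant(S / P),
        RateFunction.constant(S / M),
    )
    return FitResult(
        model=model,
        regulatory_class=cls,
        objective=0.0,
        dof=data.n_observations - cls.n_free_params,
        p_value=float("nan"),
        aic=0.0 + 2 * cls.n_free_params,
        n_free_params=cls.n_free_params,
        converged=True,
        n_iterations=0,
        optimizer=optimizer,
        seed=seed,
    )


def fit(
    data: ExpressionProfile,
    cls: RegulatoryClass,
    optimizer: str = "nelder-mead",
    max_iter: int = 5000,
    n_starts: int = 5,
    seed: int = 0,
    extra_starts: Sequence[KineticModel] = (),
) -> FitResult:
    """Estimate the parameters of a regulatory class on a profile.

    Runs a multi-start minimization of the chi-squared objective in the
    transformed parameter space: one data-driven start (steady-state
    relations at the profile ends, transition at the steepest observed
    change), one flat start (constant levels embedded in the class's
    forms), and seeded log-normal jitters of the data-driven start up to
    ``n_starts`` total.  ``extra_starts`` (fitted models of nested simpler
    classes, embedded) are appended; the best final objective wins.
    """
    if optimizer not in _OPTIMIZERS:
        raise ConfigurationError(f"unknown optimizer {optimizer!r}; expected one of {_OPTIMIZERS}")
    if (
        data.n_times == 1
        and cls.is_constant
        and data.has_synthesis
    ):
        return _steady_state_inversion(data, cls, optimizer, seed)
    dof = data.n_observations - cls.n_free_params
    if dof < 1:
        raise FitError(
            f"model too complex for data: {cls.n_free_params} free parameters vs "
            f"{data.n_observations} observations (dof={dof})"
        )
    if not cls.is_constant and data.n_times < 2:
        raise FitError("variable-rate fitting requires at least 2 time points")

    transform = _Transform(cls, data.times)
    chi2_of, penalized = _make_objective(transform, data)
    rng = np.random.default_rng(seed)

    starts = [transform.pack(_data_driven_model(data, cls))]
    starts.append(transform.pack(_flat_model(data, cls)))
    base = starts[0]
    for _ in range(max(0, n_starts - 2)):
        starts.append(_jitter(base, transform, rng))
    t_lo, t_hi = float(data.times[0]), float(data.times[-1])
    for m in extra_starts:
        starts.append(transform.pack(embed_model(m, cls, t_lo, t_hi)))

    best = None
    n_iter_total = 0
    for theta0 in starts:
        res = _run_optimizer(penalized, theta0, optimizer, max_iter)
        n_iter_total += int(res.nit)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    if not best.success:
        # a restart from the incumbent usually converges in few iterations
        polish = _run_optimizer(penalized, best.x, optimizer, max_iter)
        n_iter_total += int(polish.nit)
        if polish.fun <= best.fun:
            best = polish
    if not np.isfinite(best.fun):
        raise FitError("optimization diverged on all starts")

    model = transform.unpack(best.x)
    objective = chi2_of(best.x)
    if dof >= 1:
        p_value, aic = goodness_of_fit(objective, dof, cls.n_free_params)
    else:  # pragma: no cover - guarded above
        p_value, aic = float("nan"), objective + 2 * cls.n_free_params
    return FitResult(
        model=model,
        regulatory_class=cls,
        objective=objective,
        dof=dof,
        p_value=p_value,
        aic=aic,
        n_free_params=cls.n_free_params,
        converged=bool(best.success),
        n_iterations=int(best.nit),
        optimizer=optimizer,
        seed=seed,
    )


def refine(
    prev: FitResult,
    data: ExpressionProfile,
    extra_iter: int = 1000,
    optimizer: str | None = None,
    cls: RegulatoryClass | None = None,
) -> FitResult:
    """Continue optimization from a previous fit; never returns a worse one.

    ``extra_iter=0`` is a no-op.  A requested class that does not match the
    previous fit's forms is a configuration error.
    """
    if cls is not None and cls.forms != prev.regulatory_class.forms:
        raise ConfigurationError(
            f"requested class {cls.code} ({[f.value for f in cls.forms]}) does not "
            f"match previous fit {prev.regulatory_class.code}"
        )
    if extra_iter == 0:
        return prev
    optimizer = optimizer or prev.optimizer
    transform = _Transform(prev.regulatory_class, data.times)
    chi2_of, penalized = _make_objective(transform, data)
    theta0 = transform.pack(prev.model)
    res = _run_optimizer(penalized, theta0, optimizer, extra_iter)
    objective = chi2_of(res.x)
    if not np.isfinite(objective) or objective >= prev.objective:
        return prev
    model = transform.unpack(res.x)
    p_value, aic = goodness_of_fit(objective, prev.dof, prev.n_free_params)
    return replace(
        prev,
        model=model,
        objective=objective,
        p_value=p_value,
        aic=aic,
        converged=bool(res.success) or prev.converged,
        n_iterations=prev.n_iterations + int(res.nit),
        optimizer=optimizer,
        ci=None,
        ci_level=None,
    )


def select_model(
    data: ExpressionProfile,
    classes: Sequence[RegulatoryClass],
    **fit_kwargs,
) -> list[FitResult]:
    """Fit every candidate class and rank the results by ascending AIC.

    Classes are fitted in order of increasing complexity; each class's
    multi-start is augmented with the best already-fitted nested simpler
    model (embedded exactly), so a richer class can never score a worse
    chi-squared than a class it contains.  Ties on AIC break by fewer free
    parameters, then lexicographically by class code.
    """
    if len(classes) < 1:
        raise ConfigurationError("select_model requires at least one candidate class")
    order = sorted(range(len(classes)), key=lambda i: (classes[i].n_free_params, classes[i].code))
    fitted: dict[int, FitResult] = {}
    failures: dict[str, str] = {}
    for i in order:
        cls = classes[i]
        nested = sorted(
            (r for j, r in fitted.items() if classes[j].embeds(cls)),
            key=lambda r: r.objective,
        )
        extra = tuple(r.model for r in nested[:2])
        try:
            fitted[i] = fit(data, cls, extra_starts=extra, **fit_kwargs)
        except FitError as exc:
            failures[cls.code] = str(exc)
    if not fitted:
        raise FitError(f"all candidate classes failed: {failures}")
    results = list(fitted.values())
    results.sort(key=lambda r: (r.aic, r.n_free_params, r.regulatory_class.code))
    return results


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

_CI_MAX_EXPAND = 5.0  # search window half-width in transformed coordinates
_CI_COORD_TOL = 1e-3


def confidence_intervals(
    fit_result: FitResult,
    data: ExpressionProfile,
    level: float = 0.95,
    parameters: Sequence[str] | None = None,
    max_inner_iter: int = 300,
) -> dict[str, ParameterCI]:
    """Profile-likelihood intervals for fitted parameters.

    For each parameter the objective is re-minimized over all other
    parameters while the target is held fixed; the interval is where this
    profiled chi-squared stays within the 1-dof chi-squared quantile of the
    minimum (3.84 at 95%).  A bound that hits the search window (a factor
    ~150 on level parameters) is flagged unbounded on that side.
    """
    if not fit_result.converged:
        raise FitError("confidence intervals require a converged fit; refine it first")
    if fit_result.dof < 1:
        raise FitError("confidence intervals undefined for dof < 1")
    transform = _Transform(fit_result.regulatory_class, data.times)
    _, penalized = _make_objective(transform, data)
    theta_hat = transform.pack(fit_result.model)
    f_hat = penalized(theta_hat)
    threshold = f_hat + float(chi2_dist.ppf(level, df=1))

    names = transform.names
    if parameters is None:
        targets = list(range(len(names)))
    else:
        unknown = set(parameters) - set(names)
        if unknown:
            raise ConfigurationError(f"unknown parameters {sorted(unknown)}; available: {names}")
        targets = [names.index(p) for p in parameters]

    estimates = fit_result.parameters
    out: dict[str, ParameterCI] = {}
    for i in targets:
        free = [j for j in range(len(names)) if j != i]

        def profiled(x: float, warm: np.ndarray) -> tuple[float, np.ndarray]:
            full = warm.copy()
            full[i] = x
            if not free:
                return penalized(full), full
            def inner(sub):
                full[free] = sub
                return penalized(full)
            res = minimize(
                inner,
                warm[free],
                method="Nelder-Mead",
                options={"maxiter": max_inner_iter, "fatol": 1e-9, "adaptive": True},
            )
            full[free] = res.x
            return float(res.fun), full

        bounds: list[tuple[float, bool]] = []
        for direction in (-1.0, +1.0):
            step = 0.25
            inside_x = theta_hat[i]
            warm = theta_hat.copy()
            crossing = None
            while step <= _CI_MAX_EXPAND:
                x = theta_hat[i] + direction * step
                fval, warm_new = profiled(x, warm)
                if fval > threshold:
                    crossing = (inside_x, x, warm)
                    break
                inside_x, warm = x, warm_new
                step *= 2.0
            if crossing is None:
                # flat profile out to the window edge
                edge = theta_hat[i] + direction * _CI_MAX_EXPAND
                _, warm_edge = profiled(edge, warm)
                bounds.append((_natural_value(transform, warm_edge, edge, i), False))
                continue
            lo_x, hi_x, warm = crossing
            while abs(hi_x - lo_x) > _CI_COORD_TOL:
                mid = 0.5 * (lo_x + hi_x)
                fval, warm_mid = profiled(mid, warm)
                if fval > threshold:
                    hi_x = mid
                else:
                    lo_x, warm = mid, warm_mid
            bound_x = 0.5 * (lo_x + hi_x)
            bounds.append((_natural_value(transform, warm, bound_x, i), True))

        (low_val, low_b), (high_val, high_b) = bounds
        lo, hi = sorted((low_val, high_val))
        est = estimates[names[i]]
        out[names[i]] = ParameterCI(
            lower=min(lo, est),
            upper=max(hi, est),
            lower_bounded=low_b,
            upper_bounded=high_b,
        )
    return out


def _natural_value(transform: _Transform, warm: np.ndarray, x: float, i: int) -> float:
    full = warm.copy()
    full[i] = x
    model = transform.unpack(full)
    flat = {}
    for rate_name, rf in zip(_RATE_NAMES, model.rates):
        for pname, val in zip(rf.param_names, rf.params):
            flat[f"{rate_name}.{pname}"] = val
    return flat[transform.names[i]]
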