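"""Prior distributions and derived ("scaled/combined") parameters.

A model parameter carries one of five prior kinds:

``uniform``
    flat on ``[lo, hi]``;
``log10uniform``
    the base-10 logarithm is flat on ``[a, b]``; the parameter itself lives
    on ``[10^a, 10^b]`` with density ``1 / (x ln10 (b - a))``.  Such
    parameters are sampled and handed to simulators on the natural scale
    but *estimated* (grid, density, HPDI) on the log10 scale;
``normal``
    Gaussian with ``mean`` and ``sd > 0``;
``gamma``
    shape/rate parameterization (mean = shape / rate);
``fixed``
    a degenerate point mass, passed to simulators but never estimated.

*Derived parameters* are arithmetic formulas over prior-parameter names
(e.g. ``2*(1+beta)*N`` to rescale a female effective size into an autosomal
one); they are forwarded to simulators alongside the sampled values but are
never themselves estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ConfigError
from .expressions import Expression

KINDS = ("uniform", "log10uniform", "normal", "gamma", "fixed")

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class PriorSpec:
    """One model parameter's prior: kind, kind-specific constants, scale flag."""

    name: str
    kind: str
    params: tuple
    estimate_on_log_scale: bool | None = None

    def __post_init__(self):
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.kind not in KINDS:
            raise ConfigError(f"prior {self.name!r}: unknown kind {self.kind!r}")
        p = self.params
        if self.kind in ("uniform", "log10uniform"):
            if len(p) != 2 or not p[0] < p[1]:
                raise ConfigError(f"prior {self.name!r}: {self.kind} needs bounds lo < hi")
        elif self.kind == "normal":
            if len(p) != 2 or not p[1] > 0:
                raise ConfigError(f"prior {self.name!r}: normal needs mean and sd > 0")
        elif self.kind == "gamma":
            if len(p) != 2 or not (p[0] > 0 and p[1] > 0):
                raise ConfigError(f"prior {self.name!r}: gamma needs shape > 0 and rate > 0")
        elif len(p) != 1:
            raise ConfigError(f"prior {self.name!r}: fixed needs exactly one value")
        if self.estimate_on_log_scale is None:
            object.__setattr__(self, "estimate_on_log_scale", self.kind == "log10uniform")
        if self.estimate_on_log_scale and self.support()[0] <= 0:
            raise ConfigError(
                f"prior {self.name!r}: log-scale estimation needs a positive support")

    # -- basic properties ---------------------------------------------------
    @property
    def is_fixed(self) -> bool:
        return self.kind == "fixed"

    def support(self) -> tuple[float, float]:
        p = self.params
        if self.kind == "uniform":
            return p[0], p[1]
        if self.kind == "log10uniform":
            return 10.0 ** p[0], 10.0 ** p[1]
        if self.kind == "normal":
            return -math.inf, math.inf
        if self.kind == "gamma":
            return 0.0, math.inf
        return p[0], p[0]

    def estimation_support(self) -> tuple[float, float]:
        """Support on the estimation scale (log10 for log-scale parameters)."""
        lo, hi = self.support()
        if self.estimate_on_log_scale:
            return math.log10(lo), math.log10(hi)
        return lo, hi

    def proposal_scale(self) -> float:
        """A prior-range surrogate used to scale MCMC proposal widths.

        Bounded kinds use the support width; unbounded kinds use six
        standard deviations (covering >99.7% of the prior mass).
        """
        p = self.params
        if self.kind in ("uniform", "log10uniform"):
            lo, hi = self.support()
            return hi - lo
        if self.kind == "normal":
            return 6.0 * p[1]
        if self.kind == "gamma":
            return 6.0 * math.sqrt(p[0]) / p[1]
        return 0.0

    # -- sampling and density ----------------------------------------------
    def sample(self, rng: np.random.Generator, size=None):
        p = self.params
        if self.kind == "uniform":
            return rng.uniform(p[0], p[1], size)
        if self.kind == "log10uniform":
            return 10.0 ** rng.uniform(p[0], p[1], size)
        if self.kind == "normal":
            return rng.normal(p[0], p[1], size)
        if self.kind == "gamma":
            return rng.gamma(p[0], 1.0 / p[1], size)
        return np.full(size, p[0]) if size is not None else p[0]

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.kind == "uniform":
            out = np.where((x >= p[0]) & (x <= p[1]), 1.0 / (p[1] - p[0]), 0.0)
        elif self.kind == "log10uniform":
            lo, hi = self.support()
            with np.errstate(divide="ignore", invalid="ignore"):
                dens = 1.0 / (x * _LN10 * (p[1] - p[0]))
            out = np.where((x >= lo) & (x <= hi), dens, 0.0)
        elif self.kind == "normal":
            out = stats.norm.pdf(x, p[0], p[1])
        elif self.kind == "gamma":
            out = stats.gamma.pdf(x, p[0], scale=1.0 / p[1])
        else:
            out = np.where(x == p[0], 1.0, 0.0)
        return out if out.shape else float(out)


def parse_prior(directive: str) -> PriorSpec:
    """Parse a ``PRIOR`` directive value, e.g. ``N uniform 10 500``.

    A trailing ``log`` token requests estimation on the log10 scale for a
    kind that does not imply it already.
    """
    tokens = directive.split()
    if len(tokens) < 2:
        raise ConfigError(f"PRIOR directive too short: {directive!r}")
    name, kind, *rest = tokens
    log_flag = None
    if rest and rest[-1].lower() == "log":
        log_flag = True
        rest = rest[:-1]
    try:
        params = tuple(float(t) for t in rest)
    except ValueError as exc:
        raise ConfigError(f"PRIOR {name!r}: non-numeric argument in {directive!r}") from exc
    return PriorSpec(name=name, kind=kind, params=params, estimate_on_log_scale=log_flag)


@dataclass(frozen=True)
class DerivedParamRule:
    """A named arithmetic formula evaluated on each sampled parameter vector."""

    name: str
    expression: Expression

    @classmethod
    def parse(cls, directive: str) -> "DerivedParamRule":
        tokens = directive.split(None, 1)
        if len(tokens) != 2:
            raise ConfigError(f"RULE directive needs a name and a formula: {directive!r}")
        return cls(name=tokens[0], expression=Expression.parse(tokens[1]))


def check_rules(rules, specs) -> None:
    """Verify every rule references only declared parameter or earlier rule names."""
    known = {spec.name for spec in specs}
    for rule in rules:
        unknown = rule.expression.names - known
        if unknown:
            raise ConfigError(
                f"rule {rule.name!r} references unknown name(s): {sorted(unknown)}")
        known.add(rule.name)


def evaluate_derived(rules, theta_map: dict) -> dict:
    """Evaluate derived-parameter rules against a name -> value mapping.

    Later rules may reference earlier ones.  A non-finite result is a
    runtime error naming the rule.
    """
    env = dict(theta_map)
    out: dict = {}
    for rule in rules:
        value = rule.expression.evaluate(env)
        if not math.isfinite(value):
            raise RuntimeError(f"derived parameter {rule.name!r} evaluated to {value!r}")
        env[rule.name] = out[rule.name] = value
    return out


# -- vector-level helpers ---------------------------------------------------

def sample_prior(specs, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Draw independent parameter vectors; shape (p,) or (size, p)."""
    if size is None:
        return np.array([spec.sample(rng) for spec in specs])
    return np.column_stack([np.asarray(spec.sample(rng, size)) for spec in specs])

def prior_density(specs, theta) -> float:
    """Joint prior density: product of marginals, zero off-support."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape[-1] != len(specs):
        raise ValueError(f"theta has {theta.shape[-1]} components for {len(specs)} priors")
    dens = 1.0
    for spec, value in zip(specs, theta):
        dens *= spec.pdf(value)
        if dens == 0.0:
            return 0.0
    return float(dens)


def theta_map(specs, theta) -> dict:
    return {spec.name: float(v) for spec, v in zip(specs, theta)}
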