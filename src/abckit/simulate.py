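"""Turning a parameter vector into a summary-statistics vector.

Two routes are supported.  *External* simulators are arbitrary command-line
programs driven through template input files: parameter tags of the form
``[name]`` are substituted with concrete values, the program is invoked
with its concrete input file as sole argument, optional post-processing
hooks rewrite its output, and the resulting statistics file (2-line
header + values format) is read back.  Several programs may run per
iteration with the same parameter values — e.g. one call per marker type —
and their statistics are concatenated.

*Toy models* are bundled analytic simulators with known sampling laws,
used to exercise and validate every sampler and estimator without any
external dependency:

* ``NormalMeanModel`` — the statistic is the mean of ``n_obs`` draws from
  Normal(theta, sd), so its exact law Normal(theta, sd/sqrt(n_obs)) gives
  closed-form posteriors under a flat prior;
* ``LinearGaussianModel`` — statistics are ``c0 + C theta + eps`` with
  Gaussian noise, the exact setting assumed by the GLM posterior
  adjustment.

Any object exposing ``stat_names``, ``n_params`` and
``simulate(theta, rng) -> vector`` can serve as a simulator; a vectorized
``simulate_batch(thetas, rng)`` fast path is used by rejection sampling
when present.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from .exceptions import ConfigError, SimulationError
from .io import ObservedStats, read_observed
from .priors import evaluate_derived

logger = logging.getLogger(__name__)

_TAG_RE = re.compile(r"\[([A-Za-z_][A-Za-z0-9_]*)\]")


def _render(value) -> str:
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return format(float(value), ".17g")


def substitute_tags(template_text: str, value_map: dict) -> str:
    """Replace every ``[name]`` tag with its value at full precision.

    Text outside tags is untouched.  A tag whose name is not in
    ``value_map`` raises :class:`SimulationError` listing the tag.
    """
    missing = []

    def repl(match):
        name = match.group(1)
        if name not in value_map:
            missing.append(name)
            return match.group(0)
        return _render(value_map[name])

    out = _TAG_RE.sub(repl, template_text)
    if missing:
        raise SimulationError("undefined tag(s): " + ", ".join(sorted(set(missing))))
    return out


@runtime_checkable
class Simulator(Protocol):
    """Anything mapping a parameter vector to a statistics vector."""

    stat_names: list[str]
    n_params: int

    def simulate(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# Bundled analytic toy models
# ---------------------------------------------------------------------------

class NormalMeanModel:
    """Mean of ``n_obs`` Gaussian observations with known noise sd.

    One parameter (the population mean); one statistic whose exact
    sampling law is Normal(theta, sd / sqrt(n_obs)).
    """

    n_params = 1

    def __init__(self, n_obs: int = 10, sd: float = 1.0, stat_name: str = "xbar"):
        if n_obs < 1 or sd < 0:
            raise ConfigError("normal_mean toy needs n_obs >= 1 and sd >= 0")
        self.n_obs = int(n_obs)
        self.sd = float(sd)
        self.stat_names = [stat_name]

    def simulate(self, theta, rng):
        draws = theta[0] + self.sd * rng.standard_normal(self.n_obs)
        return np.array([draws.mean()])

    def simulate_batch(self, thetas, rng):
        noise = self.sd * rng.standard_normal((thetas.shape[0], self.n_obs))
        return (thetas[:, 0:1] + noise).mean(axis=1, keepdims=True)


class LinearGaussianModel:
    """Statistics ``c0 + C theta + eps`` with ``eps ~ Normal(0, noise_cov)``.

    ``noise_cov`` must be symmetric positive definite, or exactly zero for
    a noise-free model.
    """

    def __init__(self, c0, coef, noise_cov, stat_names=None):
        self.c0 = np.atleast_1d(np.asarray(c0, dtype=float))
        self.coef = np.atleast_2d(np.asarray(coef, dtype=float))
        cov = np.atleast_2d(np.asarray(noise_cov, dtype=float))
        k = self.c0.size
        if self.coef.shape[0] != k or cov.shape != (k, k):
            raise ConfigError("linear_gaussian toy: inconsistent c0/coef/noise_cov shapes")
        if not np.allclose(cov, cov.T):
            raise ConfigError("linear_gaussian toy: noise covariance must be symmetric")
        if np.all(cov == 0.0):
            self._chol = np.zeros_like(cov)
        else:
            try:
                self._chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                raise ConfigError(
                    "linear_gaussian toy: noise covariance must be positive definite") from None
        self.noise_cov = cov
        self.n_params = self.coef.shape[1]
        self.stat_names = list(stat_names) if stat_names else [f"s{i+1}" for i in range(k)]

    def simulate(self, theta, rng):
        eps = self._chol @ rng.standard_normal(self.c0.size)
        return self.c0 + self.coef @ np.asarray(theta, dtype=float) + eps

    def simulate_batch(self, thetas, rng):
        eps = rng.standard_normal((thetas.shape[0], self.c0.size)) @ self._chol.T
        return self.c0 + thetas @ self.coef.T + eps


def make_toy_model(directive: str):
    """Build a toy model from a ``TOYMODEL`` config value.

    ``normal_mean n_obs sd`` or ``linear_gaussian k p`` (the latter with
    unit coefficients and unit noise; richer models are built in code).
    """
    tokens = directive.split()
    kind = tokens[0]
    if kind == "normal_mean":
        n_obs = int(tokens[1]) if len(tokens) > 1 else 10
        sd = float(tokens[2]) if len(tokens) > 2 else 1.0
        return NormalMeanModel(n_obs=n_obs, sd=sd)
    if kind == "linear_gaussian":
        k = int(tokens[1]) if len(tokens) > 1 else 1
        p = int(tokens[2]) if len(tokens) > 2 else 1
        return LinearGaussianModel(np.zeros(k), np.ones((k, p)), np.eye(k))
    raise ConfigError(f"unknown toy model {kind!r}")


# ---------------------------------------------------------------------------
# External command-line simulators
# ---------------------------------------------------------------------------

@dataclass
class SimulatorCommand:
    """One external program invocation: templates in, statistics file out."""

    executable: str
    template_files: list  # list of (template path, concrete file name)
    output_stats_file: str
    post_hooks: tuple = ()

    @classmethod
    def parse(cls, directive: str) -> "SimulatorCommand":
        tokens = directive.split()
        if len(tokens) != 4:
            raise ConfigError(
                f"SIMULATOR directive needs 'exe template_in template_out statsfile': "
                f"{directive!r}")
        exe, template_in, template_out, statsfile = tokens
        return cls(executable=exe, template_files=[(template_in, template_out)],
                   output_stats_file=statsfile)


def run_external(commands, value_map: dict, workdir) -> ObservedStats:
    """Run each command in order inside ``workdir`` and concatenate statistics.

    For every command: substituted templates are written, the program is
    invoked with the first concrete input file as its sole argument, post
    hooks are run on the statistics file, and the statistics are read.
    A statistic name already produced by an earlier command is suffixed
    with the command index (a warning is logged).
    """
    workdir = Path(workdir)
    names: list[str] = []
    values: list[float] = []
    for index, command in enumerate(commands, start=1):
        concrete_paths = []
        for template_path, concrete_name in command.template_files:
            text = Path(template_path).read_text(encoding="utf-8")
            concrete = workdir / concrete_name
            concrete.write_text(substitute_tags(text, value_map), encoding="utf-8")
            concrete_paths.append(concrete)
        argv = [command.executable] + [str(concrete_paths[0])] if concrete_paths \
            else [command.executable]
        result = subprocess.run(argv, cwd=workdir, capture_output=True, text=True)
        if result.returncode != 0:
            raise SimulationError(
                f"command {command.executable!r} exited {result.returncode}: "
                f"{result.stderr.strip()[:500]}")
        stats_path = workdir / command.output_stats_file
        for hook in command.post_hooks:
            hook_result = subprocess.run([hook, str(stats_path)], cwd=workdir,
                                         capture_output=True, text=True)
            if hook_result.returncode != 0:
                raise SimulationError(
                    f"post hook {hook!r} exited {hook_result.returncode}: "
                    f"{hook_result.stderr.strip()[:500]}")
        if not stats_path.exists():
            raise SimulationError(
                f"command {command.executable!r} produced no statistics file "
                f"{command.output_stats_file!r}")
        try:
            produced = read_observed(stats_path)
        except Exception as exc:
            raise SimulationError(
                f"malformed statistics file from {command.executable!r}: {exc}") from exc
        for name, value in zip(produced.names, produced.values):
            if name in names:
                logger.warning("statistic name %r repeated by command %d; suffixed", name, index)
                name = f"{name}_{index}"
            names.append(name)
            values.append(value)
    return ObservedStats(names=names, values=np.array(values))


class ExternalSimulator:
    """Simulator protocol adapter around a list of external commands.

    Each iteration runs in a fresh scratch directory, removed on success
    and retained on failure for debugging.  ``stat_names`` is discovered
    from the first successful run.  If ``seed_tag`` is set, a fresh integer
    drawn from the sampler's RNG is exposed to the templates under that
    tag, keeping external runs reproducible under a fixed seed.
    """

    def __init__(self, commands, param_names, rules=(), seed_tag=None,
                 scratch_root=None, keep_failed=True):
        self.commands = list(commands)
        self.param_names = list(param_names)
        self.rules = tuple(rules)
        self.seed_tag = seed_tag
        self.scratch_root = scratch_root
        self.keep_failed = keep_failed
        self.stat_names: list[str] | None = None
        self.n_params = len(self.param_names)

    def simulate(self, theta, rng):
        values = dict(zip(self.param_names, (float(v) for v in theta)))
        values.update(evaluate_derived(self.rules, values))
        if self.seed_tag:
            values[self.seed_tag] = int(rng.integers(2 ** 31))
        workdir = tempfile.mkdtemp(prefix="abckit-sim-", dir=self.scratch_root)
        try:
            produced = run_external(self.commands, values, workdir)
        except SimulationError:
            if not self.keep_failed:
                shutil.rmtree(workdir, ignore_errors=True)
            else:
                logger.warning("failed simulation retained in %s", workdir)
            raise
        shutil.rmtree(workdir, ignore_errors=True)
        if self.stat_names is None:
            self.stat_names = list(produced.names)
        return produced.values_for(self.stat_names)
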