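"""Coverage validation of the estimation procedure on pseudo-observed data.

A *pseudo-observed dataset* (POD) is a simulation with known generating
parameters drawn from the prior.  Treating each POD's statistics as the
observed data and running the full retention + GLM pipeline against one
shared reference table yields, for every parameter,

* the posterior quantile of the true value (computed from the grid CDF, so
  the measure exercises the whole GLM machinery) — uniform on [0, 1] when
  the posteriors have correct coverage, which a Kolmogorov-Smirnov test
  checks with a Bonferroni correction across parameters;
* bias and RMSE of the posterior mode (on the estimation scale for
  log-scale parameters);
* empirical coverage of HPD intervals at the requested credibility levels.

One reference table serves all PODs — no per-record resimulation — so a
single large rejection run amortizes over the whole study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .exceptions import ABCKitError
from .glm import PosteriorDensity, estimate
from .io import ObservedStats, SimulationTable
from .priors import sample_prior
from .samplers import DistanceContext

logger = logging.getLogger(__name__)


@dataclass
class PseudoObservedSet:
    """M simulations with known generating parameters."""

    param_names: list[str]
    stat_names: list[str]
    thetas: np.ndarray   # (M, p)
    stats: np.ndarray    # (M, k)

    @property
    def count(self) -> int:
        return self.thetas.shape[0]


def make_pods(specs, simulator, m: int, rng: np.random.Generator) -> PseudoObservedSet:
    """Draw ``m`` independent (theta_true, S) records from prior + simulator."""
    if m < 1:
        raise ABCKitError("make_pods: M must be >= 1")
    thetas = sample_prior(specs, rng, size=m)
    batch = getattr(simulator, "simulate_batch", None)
    if batch is not None:
        stats = np.atleast_2d(batch(thetas, rng))
    else:
        stats = np.array([np.asarray(simulator.simulate(t, rng), dtype=float).ravel()
                          for t in thetas])
    return PseudoObservedSet(param_names=[s.name for s in specs],
                             stat_names=list(simulator.stat_names),
                             thetas=thetas, stats=stats)


def posterior_quantile(density: PosteriorDensity, theta_true: float) -> float:
    """Grid-CDF quantile of the true value; values off the grid clip to 0/1."""
    lo, hi = density.grid[0], density.grid[-1]
    if theta_true < lo or theta_true > hi:
        logger.debug("true value %g outside posterior grid [%g, %g]; clipped",
                     theta_true, lo, hi)
        return 0.0 if theta_true < lo else 1.0
    return float(density.cdf(theta_true))


def coverage_test(quantiles) -> tuple[float, float]:
    """Two-sided one-sample KS test of the quantiles against Uniform(0, 1).

    Returns ``(D, p)`` with the asymptotic Kolmogorov p-value.
    """
    q = np.sort(np.asarray(quantiles, dtype=float))
    m = q.size
    if m < 10:
        raise ABCKitError("coverage_test: need at least 10 quantiles")
    if np.any((q < 0) | (q > 1)):
        raise ABCKitError("coverage_test: quantiles must lie in [0, 1]")
    i = np.arange(1, m + 1)
    d = float(max(np.max(i / m - q), np.max(q - (i - 1) / m)))
    p = float(special.kolmogorov(np.sqrt(m) * d))
    return d, p


def accuracy_measures(estimates, truths, hpdis=None):
    """Bias, RMSE and empirical HPD coverage.

    ``hpdis`` maps a credibility level to a length-M list of interval
    unions (as produced by :meth:`PosteriorDensity.hpdi`).
    """
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.shape != truths.shape:
        raise ABCKitError("accuracy_measures: estimates and truths differ in length")
    errors = estimates - truths
    bias = float(errors.mean())
    rmse = float(np.sqrt(np.mean(errors ** 2)))
    coverage = {}
    for level, interval_lists in (hpdis or {}).items():
        hits = [any(lo <= t <= hi for lo, hi in intervals)
                for t, intervals in zip(truths, interval_lists)]
        coverage[level] = float(np.mean(hits))
    return bias, rmse, coverage


@dataclass
class ParameterValidation:
    """Per-parameter coverage results across all pseudo-observed datasets."""

    name: str
    quantiles: np.ndarray
    ks_statistic: float
    ks_pvalue: float
    significant: bool          # after Bonferroni correction
    bias: float
    rmse: float
    coverage: dict             # level -> empirical HPDI coverage
    n_clipped: int             # truths outside the posterior grid
    log10_scale: bool = False


@dataclass
class ValidationReport:
    parameters: dict = field(default_factory=dict)  # name -> ParameterValidation
    count: int = 0
    alpha: float = 0.05

    def all_uniform(self) -> bool:
        """True when no parameter's KS test is significant after Bonferroni."""
        return not any(p.significant for p in self.parameters.values())

    def to_rows(self):
        rows = []
        for p in self.parameters.values():
            row = {"parameter": p.name, "ks_statistic": p.ks_statistic,
                   "ks_pvalue": p.ks_pvalue, "significant": int(p.significant),
                   "bias": p.bias, "rmse": p.rmse, "n_clipped": p.n_clipped}
            for level, cov in p.coverage.items():
                row[f"coverage_{int(round(level * 100))}"] = cov
            rows.append(row)
        return rows


def run_validation(specs, simulator, ref_table: SimulationTable, m: int,
                   retain_count: int, rng: np.random.Generator, *,
                   hpdi_levels=(0.5, 0.9), grid_size: int = 100,
                   alpha: float = 0.05,
                   pods: PseudoObservedSet | None = None) -> ValidationReport:
    """Full coverage study: estimate every POD against one shared reference table."""
    if pods is None:
        pods = make_pods(specs, simulator, m, rng)
    ctx = DistanceContext.from_table(ref_table)
    by_name = {spec.name: spec for spec in specs}
    estimated = [n for n in pods.param_names
                 if n in set(ref_table.param_names) and not by_name[n].is_fixed]

    quantiles = {n: [] for n in estimated}
    modes = {n: [] for n in estimated}
    truths = {n: [] for n in estimated}
    hits = {n: {lv: [] for lv in hpdi_levels} for n in estimated}
    clipped = {n: 0 for n in estimated}

    for r in range(pods.count):
        observed = ObservedStats(names=pods.stat_names, values=pods.stats[r])
        result = estimate(ref_table, observed, list(specs),
                          count=retain_count, grid_size=grid_size, ctx=ctx)
        for i, name in enumerate(pods.param_names):
            if name not in quantiles:
                continue
            density = result.posteriors[name]
            truth = pods.thetas[r, i]
            if density.log10_scale:
                truth = np.log10(truth)
            q = posterior_quantile(density, truth)
            if truth < density.grid[0] or truth > density.grid[-1]:
                clipped[name] += 1
            quantiles[name].append(q)
            modes[name].append(density.mode())
            truths[name].append(truth)
            for level in hpdi_levels:
                hits[name][level].append(
                    any(lo <= truth <= hi for lo, hi in density.hpdi(level)))

    report = ValidationReport(count=pods.count, alpha=alpha)
    n_params = max(len(estimated), 1)
    for name in estimated:
        q = np.asarray(quantiles[name])
        d, p = coverage_test(q)
        bias, rmse, _ = accuracy_measures(modes[name], truths[name])
        spec = by_name[name]
        report.parameters[name] = ParameterValidation(
            name=name, quantiles=q, ks_statistic=d, ks_pvalue=p,
            significant=bool(p < alpha / n_params),  # Bonferroni across parameters
            bias=bias, rmse=rmse,
            coverage={lv: float(np.mean(hits[name][lv])) for lv in hpdi_levels},
            n_clipped=clipped[name], log10_scale=spec.estimate_on_log_scale)
    return report
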