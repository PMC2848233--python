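"""Likelihood-free samplers: rejection, MCMC without likelihood, PMC.

All three samplers share the same contract: draw parameter vectors, run a
simulator, and emit a :class:`~abckit.io.SimulationTable` of (theta, S)
rows.  Acceptance is always phrased in terms of a *standardized distance*

    d(S, S_obs) = || (S - S_obs) / sd ||_2

where the per-statistic standard deviations come from a calibration table
(statistics with zero variance are dropped from the distance with a logged
warning).  Rejection sampling performs no filtering at all — every
simulation is recorded and the retention step happens later in the
estimator — which lets one reference table serve many observed datasets.

The MCMC sampler follows the calibrated likelihood-free Metropolis scheme:
a pilot rejection run fixes the standardization constants, the distance
threshold (the empirical ``delta``-quantile of pilot distances to the
observed statistics) and the starting point (the closest pilot draw).
Proposals are componentwise symmetric uniform perturbations of half-width
``proposal_scale * phi * prior_range``, reflected at finite prior bounds;
a proposal is accepted iff its simulation lands within the threshold and a
uniform draw falls below the prior ratio.  On rejection the current row is
repeated, so retained-row frequencies match the chain's stationary law.

The PMC sampler is iterated importance sampling under a strictly
decreasing tolerance schedule, with particles perturbed by a Gaussian
kernel whose variance is twice the weighted empirical variance of the
previous generation (the standard adaptive choice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ABCKitError, SimulationError
from .io import ObservedStats, SimulationTable
from .priors import prior_density, sample_prior

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Standardized distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceContext:
    """Standardization constants plus the tolerance threshold.

    ``stat_names`` lists the statistics *retained* in the distance;
    ``dropped`` records any zero-variance statistics excluded from it.
    """

    stat_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    threshold: float = np.inf
    dropped: tuple = ()

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if np.any(self.sds <= 0):
            raise ABCKitError("DistanceContext: retained statistic with sd <= 0")
        if self.threshold < 0:
            raise ABCKitError("DistanceContext: negative tolerance threshold")

    @classmethod
    def from_table(cls, table: SimulationTable, threshold: float = np.inf) -> "DistanceContext":
        """Estimate standardization constants from a table's statistic columns."""
        stats = table.stats()
        means = stats.mean(axis=0)
        sds = stats.std(axis=0, ddof=1) if table.n_rows > 1 else np.zeros(stats.shape[1])
        keep = sds > 0
        dropped = tuple(n for n, k in zip(table.stat_names, keep) if not k)
        if dropped:
            logger.warning("zero-variance statistics dropped from distance: %s",
                           ", ".join(dropped))
        names = [n for n, k in zip(table.stat_names, keep) if k]
        if not names:
            raise ABCKitError("all statistics have zero variance; no usable distance")
        return cls(stat_names=names, means=means[keep], sds=sds[keep],
                   threshold=threshold, dropped=dropped)

    def distances(self, stats: np.ndarray, observed_values: np.ndarray) -> np.ndarray:
        """Standardized Euclidean distances of each row of ``stats`` to the observed vector."""
        z = (np.atleast_2d(stats) - observed_values) / self.sds
        return np.sqrt(np.einsum("ij,ij->i", z, z))


def standardized_distance(ctx: DistanceContext, s, s_obs) -> float:
    """Distance between two single statistic vectors under ``ctx``."""
    s = np.asarray(s, dtype=float).ravel()
    s_obs = np.asarray(s_obs, dtype=float).ravel()
    if s.size != len(ctx.stat_names) or s_obs.size != len(ctx.stat_names):
        raise ABCKitError(
            f"distance: expected {len(ctx.stat_names)} statistics, "
            f"got {s.size} and {s_obs.size}")
    return float(ctx.distances(s[None, :], s_obs)[0])


def _observed_for(ctx: DistanceContext, observed: ObservedStats) -> np.ndarray:
    return observed.values_for(ctx.stat_names)


# ---------------------------------------------------------------------------
# Rejection sampling
# ---------------------------------------------------------------------------

def _build_table(specs, simulator, thetas, stats, weights=None) -> SimulationTable:
    param_names = [spec.name for spec in specs]
    stat_names = list(simulator.stat_names)
    return SimulationTable(column_names=param_names + stat_names,
                           values=np.column_stack([thetas, stats]),
                           param_names=param_names, stat_names=stat_names,
                           weights=weights)


def rejection_sample(n_sims: int, specs, simulator, rng: np.random.Generator,
                     *, max_failure_fraction: float = 0.5) -> SimulationTable:
    """Simulate ``n_sims`` i.i.d. prior draws; record every (theta, S) row.

    No acceptance filtering happens here: retention against an observed
    dataset is the estimator's job.  A failed simulation (nonzero exit,
    malformed output) is logged and replaced by a fresh prior draw; if
    failures exceed ``max_failure_fraction`` of all attempts the run
    aborts.
    """
    if n_sims < 1:
        raise ABCKitError("rejection_sample: n_sims must be >= 1")
    batch = getattr(simulator, "simulate_batch", None)
    if batch is not None:
        thetas = sample_prior(specs, rng, size=n_sims)
        stats = np.atleast_2d(batch(thetas, rng))
        return _build_table(specs, simulator, thetas, stats)

    rows_theta, rows_stats, failures = [], [], 0
    i = 0
    while i < n_sims:
        theta = sample_prior(specs, rng)
        try:
            s = np.asarray(simulator.simulate(theta, rng), dtype=float).ravel()
        except SimulationError as exc:
            failures += 1
            logger.warning("simulation failed (%d so far): %s", failures, exc)
            attempts = i + failures
            if failures > 10 and failures > max_failure_fraction * attempts:
                raise ABCKitError(
                    f"rejection_sample: {failures} failures in {attempts} attempts "
                    f"exceeds the cap of {max_failure_fraction:.0%}") from exc
            continue
        rows_theta.append(theta)
        rows_stats.append(s)
        i += 1
    return _build_table(specs, simulator, np.array(rows_theta), np.array(rows_stats))


# ---------------------------------------------------------------------------
# Calibration (shared by MCMC; PMC uses the standardization part)
# ---------------------------------------------------------------------------

def calibrate(calib_table: SimulationTable, observed: ObservedStats,
              delta: float) -> tuple[DistanceContext, np.ndarray]:
    """Derive the distance context and chain start from a pilot rejection table.

    The threshold is the empirical ``delta``-quantile (linear interpolation
    between order statistics) of the standardized distances to the observed
    statistics; the start is the pilot draw with the smallest distance.
    """
    if not 0 < delta <= 1:
        raise ABCKitError("calibrate: delta must lie in (0, 1]")
    ctx = DistanceContext.from_table(calib_table)
    obs = _observed_for(ctx, observed)
    d = ctx.distances(calib_table.columns(ctx.stat_names), obs)
    if d.max() == d.min():
        raise ABCKitError("calibrate: all calibration distances identical "
                          "(degenerate statistics)")
    threshold = float(np.quantile(d, delta))
    start = calib_table.params()[int(np.argmin(d))].copy()
    return replace(ctx, threshold=threshold), start


# ---------------------------------------------------------------------------
# Likelihood-free MCMC
# ---------------------------------------------------------------------------

@dataclass
class MCMCConfig:
    """Settings for the calibrated likelihood-free Metropolis chain.

    ``delta`` is the calibration tolerance quantile and ``phi`` the
    proposal range multiplier; the proposal half-width for parameter ``i``
    is ``proposal_scale * phi * prior_range_i``.
    """

    chain_length: int
    delta: float = 0.1
    phi: float = 1.0
    calibration_size: int = 10_000
    thinning: int = 1
    proposal_scale: float = 0.05
    acceptance_floor: float = 0.01
    floor_window: int = 1_000

    def __post_init__(self):
        if self.chain_length < 1 or self.calibration_size < 1 or self.thinning < 1:
            raise ABCKitError("MCMCConfig: lengths must be positive")
        if not 0 < self.delta < 1:
            raise ABCKitError("MCMCConfig: delta must lie in (0, 1)")
        if self.phi <= 0:
            raise ABCKitError("MCMCConfig: phi must be positive")
        if self.calibration_size * self.delta < 1:
            raise ABCKitError("MCMCConfig: calibration_size too small to "
                              "estimate the delta-quantile")


def _reflect(x: float, lo: float, hi: float) -> float:
    if not (np.isfinite(lo) or np.isfinite(hi)):
        return x
    while x < lo or x > hi:
        if x < lo and np.isfinite(lo):
            x = 2 * lo - x
        elif x > hi and np.isfinite(hi):
            x = 2 * hi - x
        else:  # one-sided support; single reflection suffices
            break
    return x


def mcmc_sample(cfg: MCMCConfig, specs, simulator, observed: ObservedStats,
                rng: np.random.Generator, *, ctx: DistanceContext | None = None,
                start: np.ndarray | None = None) -> SimulationTable:
    """Run the likelihood-free Metropolis chain and return the thinned table.

    When ``ctx``/``start`` are not supplied, a pilot rejection run of
    ``cfg.calibration_size`` simulations calibrates them.  On rejection the
    current (theta, S) row is repeated; a failed simulation counts as a
    rejection.  The realized acceptance rate is logged, with a warning for
    any window of ``cfg.floor_window`` steps below ``cfg.acceptance_floor``.
    """
    if ctx is None or start is None:
        calib = rejection_sample(cfg.calibration_size, specs, simulator, rng)
        ctx, start = calibrate(calib, observed, cfg.delta)
    obs = _observed_for(ctx, observed)
    half_width = np.array([cfg.proposal_scale * cfg.phi * spec.proposal_scale()
                           for spec in specs])
    bounds = [spec.support() for spec in specs]

    theta = np.asarray(start, dtype=float).copy()
    for _ in range(100):
        try:
            s_current = np.asarray(simulator.simulate(theta, rng), dtype=float).ravel()
            break
        except SimulationError:
            continue
    else:
        raise ABCKitError("mcmc_sample: could not simulate at the starting point")

    dens_current = prior_density(specs, theta)
    rows = np.empty((cfg.chain_length, len(specs) + len(s_current)))
    accepted = window_accepted = 0
    for step in range(cfg.chain_length):
        proposal = theta + half_width * rng.uniform(-1.0, 1.0, size=len(specs))
        for i, (lo, hi) in enumerate(bounds):
            proposal[i] = _reflect(proposal[i], lo, hi)
        dens_proposal = prior_density(specs, proposal)
        accept = False
        if dens_proposal > 0.0:
            ratio = np.inf if dens_current == 0.0 else dens_proposal / dens_current
            if rng.uniform() < ratio:
                try:
                    s_proposal = np.asarray(simulator.simulate(proposal, rng),
                                            dtype=float).ravel()
                except SimulationError:
                    s_proposal = None
                if s_proposal is not None and \
                        standardized_distance(ctx, s_proposal, obs) <= ctx.threshold:
                    accept = True
        if accept:
            theta, s_current, dens_current = proposal, s_proposal, dens_proposal
            accepted += 1
            window_accepted += 1
        rows[step, :len(specs)] = theta
        rows[step, len(specs):] = s_current
        if (step + 1) % cfg.floor_window == 0:
            rate = window_accepted / cfg.floor_window
            if rate < cfg.acceptance_floor:
                logger.warning("MCMC acceptance rate %.4f below floor %.4f over steps %d-%d",
                               rate, cfg.acceptance_floor,
                               step + 1 - cfg.floor_window, step + 1)
            window_accepted = 0
    logger.info("MCMC overall acceptance rate: %.4f", accepted / cfg.chain_length)

    rows = rows[cfg.thinning - 1::cfg.thinning]
    return _build_table(specs, simulator, rows[:, :len(specs)], rows[:, len(specs):])


# ---------------------------------------------------------------------------
# Population Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class PMCConfig:
    """Settings for the adaptive population Monte Carlo sampler."""

    n_particles: int
    tolerance_schedule: tuple = field(default=())
    pilot_size: int = 1_000
    max_attempt_factor: int = 10_000

    def __post_init__(self):
        self.tolerance_schedule = tuple(float(t) for t in self.tolerance_schedule)
        if self.n_particles < 1 or not self.tolerance_schedule:
            raise ABCKitError("PMCConfig: need n_particles >= 1 and a tolerance schedule")
        if any(t <= 0 for t in self.tolerance_schedule):
            raise ABCKitError("PMCConfig: tolerances must be positive")
        if any(b >= a for a, b in zip(self.tolerance_schedule,
                                      self.tolerance_schedule[1:])):
            raise ABCKitError("PMCConfig: tolerance schedule must be strictly decreasing")

    @property
    def n_generations(self) -> int:
        return len(self.tolerance_schedule)


def _gaussian_kernel_density(theta, particles, sds, free):
    """Mixture-kernel density of ``theta`` given previous particles (free dims only)."""
    z = (theta[free] - particles[:, free]) / sds[free]
    log_k = -0.5 * np.einsum("ij,ij->i", z, z) \
        - np.sum(np.log(np.sqrt(2 * np.pi) * sds[free]))
    return np.exp(log_k)


def pmc_sample(cfg: PMCConfig, specs, simulator, observed: ObservedStats,
               rng: np.random.Generator, *,
               ctx: DistanceContext | None = None) -> SimulationTable:
    """Run the PMC sampler; returns the final generation with normalized weights.

    Generation 1 draws from the prior under the first tolerance with equal
    weights; each later generation resamples a previous particle by weight,
    perturbs it with a componentwise Gaussian kernel (variance twice the
    weighted empirical variance of the previous generation) and, when
    accepted under the next tolerance, weights it by
    ``prior(theta) / sum_j w_j K(theta | theta_j)``.
    """
    if ctx is None:
        pilot = rejection_sample(cfg.pilot_size, specs, simulator, rng)
        ctx = DistanceContext.from_table(pilot)
    obs = _observed_for(ctx, observed)
    p = len(specs)
    free = np.array([not spec.is_fixed for spec in specs])

    particles = np.empty((cfg.n_particles, p))
    stats = None
    weights = np.full(cfg.n_particles, 1.0 / cfg.n_particles)
    for gen, tol in enumerate(cfg.tolerance_schedule, start=1):
        new_particles = np.empty_like(particles)
        new_stats_rows = []
        attempts = 0
        cap = cfg.max_attempt_factor * cfg.n_particles
        if gen > 1:
            var = np.average((particles - np.average(particles, axis=0, weights=weights)) ** 2,
                             axis=0, weights=weights)
            kernel_sds = np.sqrt(2.0 * var)
            if np.any(kernel_sds[free] == 0):
                raise ABCKitError(f"pmc_sample: generation {gen}: degenerate particle cloud")
        accepted = 0
        while accepted < cfg.n_particles:
            attempts += 1
            if attempts > cap:
                raise ABCKitError(
                    f"pmc_sample: generation {gen} failed to accept "
                    f"{cfg.n_particles} particles within {cap} attempts")
            if gen == 1:
                theta = sample_prior(specs, rng)
            else:
                j = rng.choice(cfg.n_particles, p=weights)
                theta = particles[j].copy()
                theta[free] = theta[free] + kernel_sds[free] * rng.standard_normal(free.sum())
                if prior_density(specs, theta) == 0.0:
                    continue
            try:
                s = np.asarray(simulator.simulate(theta, rng), dtype=float).ravel()
            except SimulationError:
                continue
            s_kept = s if list(simulator.stat_names) == list(ctx.stat_names) \
                else _subset_stats(s, simulator.stat_names, ctx.stat_names)
            if float(ctx.distances(s_kept[None, :], obs)[0]) <= tol:
                new_particles[accepted] = theta
                new_stats_rows.append(s)
                accepted += 1
        new_stats = np.array(new_stats_rows)
        if gen == 1:
            new_weights = np.full(cfg.n_particles, 1.0 / cfg.n_particles)
        else:
            new_weights = np.empty(cfg.n_particles)
            for i in range(cfg.n_particles):
                denom = float(np.dot(weights, _gaussian_kernel_density(
                    new_particles[i], particles, kernel_sds, free)))
                new_weights[i] = prior_density(specs, new_particles[i]) / denom
        particles, stats, weights = new_particles, new_stats, new_weights / new_weights.sum()
        logger.info("PMC generation %d: tolerance %.4g, %d attempts for %d particles",
                    gen, tol, attempts, cfg.n_particles)
    return _build_table(specs, simulator, particles, stats, weights=weights)


def _subset_stats(s, names, wanted):
    index = {n: i for i, n in enumerate(names)}
    return s[[index[n] for n in wanted]]
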