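"""ABC posterior estimation by general-linear-model (GLM) adjustment.

Given a simulation table and an observed statistics vector, estimation
proceeds in three steps:

1. **Retention** — keep the ``J`` simulations whose standardized distance
   to the observed statistics is smallest.
2. **GLM fit** — model the retained statistics as a linear Gaussian
   function of the retained parameters, ``s = c0 + C theta + eps`` with
   ``eps ~ Normal(0, Sigma_s)``, by (weighted) ordinary least squares.
3. **Posterior assembly** — represent the truncated prior as an equally
   weighted Gaussian mixture centered at the retained parameter vectors
   ``theta_j`` with a common diagonal covariance ``Sigma_theta``
   (a Scott-type bandwidth by default).  Gaussian algebra then gives the
   posterior as a J-component Gaussian mixture with common covariance

       T = (C' Sigma_s^-1 C + Sigma_theta^-1)^-1,

   component means

       m_j = T (C' Sigma_s^-1 (s_obs - c0) + Sigma_theta^-1 theta_j),

   and component weights proportional to the density of ``s_obs`` under
   ``Normal(c0 + C theta_j, Sigma_s + C Sigma_theta C')``.

The same mixture yields the *marginal density* of the observed statistics
under the model (whose ratios across models are Bayes factors) and a
model-fit p-value: the weighted fraction of retained simulations whose own
marginal density does not exceed that of the observed data.

Parameters whose priors are declared on a log10 scale are estimated on
that scale: transform the retained set with :func:`to_estimation_scale`
before fitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg

from .exceptions import EstimationError
from .io import ObservedStats, SimulationTable
from .samplers import DistanceContext

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Retention
# ---------------------------------------------------------------------------

@dataclass
class RetainedSet:
    """The J simulations closest to the observed statistics, sorted by distance."""

    param_names: list[str]
    stat_names: list[str]
    params: np.ndarray      # (J, p)
    stats: np.ndarray       # (J, k)
    distances: np.ndarray   # (J,), non-decreasing
    weights: np.ndarray     # (J,), normalized to sum 1

    @property
    def J(self) -> int:
        return self.params.shape[0]

    def min_solvable(self) -> int:
        return self.params.shape[1] + self.stats.shape[1] + 2


def retain(table: SimulationTable, observed: ObservedStats,
           count: int | None = None, fraction: float | None = None,
           ctx: DistanceContext | None = None) -> RetainedSet:
    """Keep the ``count`` (or ``fraction``) closest rows; count wins if both given.

    Distances are standardized by ``ctx`` (derived from the table itself
    when not supplied); ties are broken by original row order.
    """
    if count is None and fraction is None:
        raise EstimationError("retain: give a retention count or fraction")
    if count is None:
        count = int(round(fraction * table.n_rows))
    if count > table.n_rows:
        raise EstimationError(f"retain: J={count} exceeds table rows {table.n_rows}")
    p, k = len(table.param_names), len(table.stat_names)
    minimum = p + k + 2
    if count < minimum:
        raise EstimationError(
            f"retain: J={count} too small; the GLM needs at least {minimum} rows "
            f"(p={p} parameters + k={k} statistics + 2)")
    if ctx is None:
        ctx = DistanceContext.from_table(table)
    obs = observed.values_for(ctx.stat_names)
    d = ctx.distances(table.columns(ctx.stat_names), obs)
    order = np.argsort(d, kind="stable")[:count]
    weights = table.normalized_weights()[order]
    return RetainedSet(param_names=list(table.param_names),
                       stat_names=list(table.stat_names),
                       params=table.params()[order],
                       stats=table.stats()[order],
                       distances=d[order],
                       weights=weights / weights.sum())


def to_estimation_scale(retained: RetainedSet, priors) -> RetainedSet:
    """Log10-transform the parameter columns flagged for log-scale estimation."""
    by_name = {spec.name: spec for spec in priors}
    params = retained.params.copy()
    for i, name in enumerate(retained.param_names):
        spec = by_name.get(name)
        if spec is not None and spec.estimate_on_log_scale:
            if np.any(params[:, i] <= 0):
                raise EstimationError(
                    f"parameter {name!r}: non-positive value under log-scale estimation")
            params[:, i] = np.log10(params[:, i])
    return replace(retained, params=params)


# ---------------------------------------------------------------------------
# GLM fit
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    """Fitted statistics-on-parameters linear model."""

    c0: np.ndarray       # (k,)
    coef: np.ndarray     # (k, p)
    sigma_s: np.ndarray  # (k, k), symmetric positive definite after regularization
    param_names: list[str]
    stat_names: list[str]


def fit_glm(retained: RetainedSet, *, condition_bound: float = 1e10) -> GLMFit:
    """Weighted least squares of each statistic on the retained parameters.

    The residual covariance uses the divisor ``J - p - 1``; if its
    condition number exceeds ``condition_bound`` (or it is not positive
    definite), a ridge ``lambda I`` with ``lambda = 1e-8 tr(Sigma_s)/k``
    is added and the event logged.
    """
    if retained.J < retained.min_solvable():
        raise EstimationError(
            f"fit_glm: J={retained.J} below the solvable minimum {retained.min_solvable()}")
    J, p = retained.params.shape
    X = np.column_stack([np.ones(J), retained.params])
    sw = np.sqrt(retained.weights * J)  # uniform weights give sw == 1
    Xw, Sw = X * sw[:, None], retained.stats * sw[:, None]

    _, r_diag, pivots = _qr_diag(Xw)
    tol = max(Xw.shape) * np.finfo(float).eps * (abs(r_diag[0]) if r_diag.size else 0.0)
    deficient = [pivots[i] for i in range(len(r_diag)) if abs(r_diag[i]) <= tol]
    deficient += list(pivots[len(r_diag):])
    constant = [name for j, name in enumerate(retained.param_names)
                if retained.params[:, j].std() == 0]
    if deficient or constant:
        names = {("intercept" if j == 0 else retained.param_names[j - 1])
                 for j in deficient} | set(constant)
        raise EstimationError("fit_glm: rank-deficient parameter design; "
                              "collinear column(s): " + ", ".join(sorted(names)))

    beta, *_ = np.linalg.lstsq(Xw, Sw, rcond=None)
    resid = retained.stats - X @ beta
    sigma_s = (resid * retained.weights[:, None]).T @ resid * (J / max(J - p - 1, 1))
    sigma_s = 0.5 * (sigma_s + sigma_s.T)

    evals = np.linalg.eigvalsh(sigma_s)
    needs_ridge = evals[0] <= 0 or (evals[0] > 0 and evals[-1] / evals[0] > condition_bound)
    if needs_ridge:
        k = sigma_s.shape[0]
        lam = 1e-8 * np.trace(sigma_s) / k
        if lam <= 0:
            lam = 1e-12
        while True:
            candidate = sigma_s + lam * np.eye(k)
            evals = np.linalg.eigvalsh(candidate)
            if evals[0] > 0 and evals[-1] / evals[0] <= condition_bound:
                break
            lam *= 10.0
        logger.info("fit_glm: residual covariance regularized with lambda=%.3g", lam)
        sigma_s = candidate

    return GLMFit(c0=beta[0].copy(), coef=beta[1:].T.copy(), sigma_s=sigma_s,
                  param_names=list(retained.param_names),
                  stat_names=list(retained.stat_names))


def _qr_diag(a):
    q, r, pivots = linalg.qr(a, mode="economic", pivoting=True)
    return q, np.abs(np.diag(r)), pivots


# ---------------------------------------------------------------------------
# Posterior densities on a grid
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDensity:
    """Per-parameter marginal posterior on a grid, trapezoid-normalized to 1."""

    parameter_name: str
    grid: np.ndarray
    densities: np.ndarray
    log10_scale: bool = False

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.grid.size < 2 or np.any(np.diff(self.grid) <= 0):
            raise EstimationError(
                f"posterior {self.parameter_name!r}: grid must be strictly increasing")
        if np.any(self.densities < 0):
            raise EstimationError(f"posterior {self.parameter_name!r}: negative density")

    # -- summaries ----------------------------------------------------------
    def integral(self) -> float:
        return float(np.trapezoid(self.densities, self.grid))

    def mode(self) -> float:
        """Grid value of the maximum density; ties break toward the smaller value."""
        top = float(self.densities.max())
        n_ties = int(np.sum(self.densities == top))
        if n_ties > 1:
            logger.warning("posterior %r: %d tied modes; reporting the smallest",
                           self.parameter_name, n_ties)
        return float(self.grid[int(np.argmax(self.densities))])

    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.densities, self.grid))

    def sd(self) -> float:
        m = self.mean()
        var = float(np.trapezoid((self.grid - m) ** 2 * self.densities, self.grid))
        return math.sqrt(max(var, 0.0))

    def _cell_masses(self) -> np.ndarray:
        """Trapezoid-rule probability mass attributed to each grid point."""
        h = np.diff(self.grid)
        w = np.zeros_like(self.grid)
        w[:-1] += h / 2.0
        w[1:] += h / 2.0
        masses = self.densities * w
        total = masses.sum()
        return masses / total if total > 0 else masses

    def cdf(self, x) -> np.ndarray | float:
        """Trapezoid CDF evaluated at ``x`` (clipped to [0, 1] outside the grid)."""
        cum = np.concatenate([[0.0], np.cumsum(
            0.5 * (self.densities[1:] + self.densities[:-1]) * np.diff(self.grid))])
        if cum[-1] > 0:
            cum = cum / cum[-1]
        out = np.interp(np.asarray(x, dtype=float), self.grid, cum, left=0.0, right=1.0)
        return float(out) if np.ndim(x) == 0 else out

    def hpdi(self, mass: float) -> list[tuple[float, float]]:
        """Highest posterior density region at probability ``mass``.

        Grid cells are added in decreasing density order until their summed
        probability reaches ``mass``; contiguous runs are merged, so a
        unimodal density yields a single interval.
        """
        if not 0 < mass < 1:
            raise EstimationError("hpdi: mass must lie in (0, 1)")
        masses = self._cell_masses()
        order = np.argsort(-self.densities, kind="stable")
        cum = np.cumsum(masses[order])
        n_cells = int(np.searchsorted(cum, mass)) + 1
        selected = np.zeros(self.grid.size, dtype=bool)
        selected[order[:min(n_cells, self.grid.size)]] = True
        intervals: list[tuple[float, float]] = []
        start = None
        for i, flag in enumerate(selected):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                intervals.append((float(self.grid[start]), float(self.grid[i - 1])))
                start = None
        if start is not None:
            intervals.append((float(self.grid[start]), float(self.grid[-1])))
        return intervals

    def to_natural_scale_value(self, value: float) -> float:
        return 10.0 ** value if self.log10_scale else value


def hpdi(density: PosteriorDensity, mass: float) -> list[tuple[float, float]]:
    return density.hpdi(mass)


def posterior_mode(density: PosteriorDensity) -> float:
    return density.mode()


# ---------------------------------------------------------------------------
# Gaussian-mixture posterior
# ---------------------------------------------------------------------------

def default_bandwidth(retained: RetainedSet) -> np.ndarray:
    """Scott-type diagonal bandwidth: sd_i = 1.06 sigma_i J^(-1/5) per parameter.

    ``sigma_i`` is the weighted standard deviation of retained parameter
    ``i``; a zero spread raises, since a constant parameter cannot be
    estimated.
    """
    mean = np.average(retained.params, axis=0, weights=retained.weights)
    var = np.average((retained.params - mean) ** 2, axis=0, weights=retained.weights)
    if np.any(var <= 0):
        bad = [n for n, v in zip(retained.param_names, var) if v <= 0]
        raise EstimationError("default_bandwidth: zero spread for parameter(s): "
                              + ", ".join(bad))
    return 1.06 * np.sqrt(var) * retained.J ** (-0.2)


def _mixture_components(fit: GLMFit, retained: RetainedSet, sigma_theta: np.ndarray,
                        s_obs: np.ndarray):
    """Common covariance T, component means m_j and normalized log weights."""
    C, S = fit.coef, fit.sigma_s
    k, p = C.shape
    sigma_theta = np.asarray(sigma_theta, dtype=float).ravel()
    if sigma_theta.size != p:
        raise EstimationError(f"bandwidth must have {p} components")
    dinv = 1.0 / sigma_theta ** 2
    try:
        cf_s = linalg.cho_factor(S)
    except linalg.LinAlgError as exc:
        raise EstimationError("sigma_s not positive definite; increase regularization") from exc
    CtSinv = linalg.cho_solve(cf_s, C).T            # (p, k)
    precision = CtSinv @ C + np.diag(dinv)          # (p, p)
    try:
        cf_t = linalg.cho_factor(precision)
    except linalg.LinAlgError as exc:
        raise EstimationError(
            "posterior precision numerically singular; use a larger bandwidth "
            "or stronger sigma_s regularization") from exc
    T = linalg.cho_solve(cf_t, np.eye(p))
    T = 0.5 * (T + T.T)
    b = CtSinv @ (s_obs - fit.c0)                   # (p,)
    means = (b[None, :] + retained.params * dinv[None, :]) @ T.T  # (J, p)
    log_w = _log_gaussian_weights(fit, retained, sigma_theta,
                                  s_obs[None, :]).ravel() + np.log(retained.weights)
    log_w = log_w - _logsumexp(log_w)
    return T, means, log_w


def _predictive_chol(fit: GLMFit, sigma_theta: np.ndarray):
    """Cholesky of Q = Sigma_s + C Sigma_theta C' and its log determinant."""
    C = fit.coef
    Q = fit.sigma_s + (C * sigma_theta ** 2) @ C.T
    Q = 0.5 * (Q + Q.T)
    try:
        L = np.linalg.cholesky(Q)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("predictive covariance not positive definite") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return L, logdet


def _log_gaussian_weights(fit, retained, sigma_theta, points):
    """Log N(point; c0 + C theta_j, Q) for each point (rows) and component j (cols)."""
    L, logdet = _predictive_chol(fit, sigma_theta)
    k = fit.c0.size
    means = fit.c0[None, :] + retained.params @ fit.coef.T   # (J, k)
    a = linalg.solve_triangular(L, np.atleast_2d(points).T, lower=True).T  # (n, k)
    bmat = linalg.solve_triangular(L, means.T, lower=True).T         # (J, k)
    d2 = (np.einsum("ij,ij->i", a, a)[:, None]
          + np.einsum("ij,ij->i", bmat, bmat)[None, :]
          - 2.0 * a @ bmat.T)
    return -0.5 * np.maximum(d2, 0.0) - 0.5 * logdet - 0.5 * k * _LOG_2PI


def _logsumexp(x, weights=None, axis=None):
    x = np.asarray(x, dtype=float)
    m = np.max(x, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    s = np.sum((np.exp(x - m) if weights is None else weights * np.exp(x - m)),
               axis=axis, keepdims=True)
    with np.errstate(divide="ignore"):
        out = m + np.log(s)
    return out.squeeze() if axis is not None or out.size == 1 else out


def glm_posterior(fit: GLMFit, retained: RetainedSet, priors, s_obs,
                  grid_size: int = 100, bandwidth=None) -> list[PosteriorDensity]:
    """Marginal posterior density of every parameter on a regular grid.

    The grid spans the retained parameter range extended 5% on each side
    and clipped to the prior support (on the estimation scale); densities
    are renormalized by the trapezoid rule.  ``priors`` may be a list of
    :class:`~abckit.priors.PriorSpec` covering (a superset of) the
    retained parameters; parameters without a spec are unclipped.
    """
    s_obs = np.asarray(s_obs, dtype=float).ravel()
    if bandwidth is None:
        bandwidth = default_bandwidth(retained)
    T, means, log_w = _mixture_components(fit, retained, bandwidth, s_obs)
    w = np.exp(log_w)
    by_name = {spec.name: spec for spec in priors} if priors else {}

    out = []
    for i, name in enumerate(retained.param_names):
        spec = by_name.get(name)
        lo = float(retained.params[:, i].min())
        hi = float(retained.params[:, i].max())
        pad = 0.05 * (hi - lo)
        lo, hi = lo - pad, hi + pad
        if spec is not None:
            s_lo, s_hi = spec.estimation_support()
            lo, hi = max(lo, s_lo), min(hi, s_hi)
        if not hi > lo:
            raise EstimationError(f"posterior grid degenerate for parameter {name!r}")
        grid = np.linspace(lo, hi, grid_size)
        sd_i = math.sqrt(max(T[i, i], 0.0))
        if sd_i <= 0:
            raise EstimationError(f"posterior {name!r}: zero component sd")
        z = (grid[:, None] - means[None, :, i]) / sd_i
        dens = (np.exp(-0.5 * z ** 2) @ w) / (sd_i * math.sqrt(2 * math.pi))
        total = np.trapezoid(dens, grid)
        if not total > 0:
            raise EstimationError(f"posterior {name!r}: density integrates to zero")
        out.append(PosteriorDensity(
            parameter_name=name, grid=grid, densities=dens / total,
            log10_scale=bool(spec.estimate_on_log_scale) if spec is not None else False))
    return out


# ---------------------------------------------------------------------------
# Marginal density, Bayes factors, model check
# ---------------------------------------------------------------------------

def log_marginal_density(fit: GLMFit, retained: RetainedSet, sigma_theta,
                         s) -> float:
    """Log of the model's marginal density of statistics vector ``s``."""
    s = np.asarray(s, dtype=float).ravel()
    if s.size != fit.c0.size:
        raise EstimationError(
            f"marginal_density: expected {fit.c0.size} statistics, got {s.size}")
    log_comp = _log_gaussian_weights(fit, retained, np.asarray(sigma_theta, float),
                                     s[None, :])
    return float(_logsumexp(log_comp.ravel() + np.log(retained.weights)))


def marginal_density(fit: GLMFit, retained: RetainedSet, sigma_theta, s) -> float:
    """Weighted-average density of ``s`` over the mixture components (>= 0)."""
    return math.exp(log_marginal_density(fit, retained, sigma_theta, s))


def bayes_factor(marginal_m1: float, marginal_m2: float) -> float:
    """Ratio of marginal densities of two models at the same observed statistics."""
    if marginal_m2 == 0.0:
        raise EstimationError("bayes_factor: second model has zero marginal density")
    return marginal_m1 / marginal_m2


def model_check_pvalue(fit: GLMFit, retained: RetainedSet, sigma_theta,
                       s_obs) -> float:
    """Model-fit p-value: weighted fraction of retained simulations whose
    marginal density does not exceed that of the observed data.

    A small value flags an observed dataset less probable under the model
    than the model's own simulations.
    """
    s_obs = np.asarray(s_obs, dtype=float).ravel()
    sigma_theta = np.asarray(sigma_theta, dtype=float).ravel()
    log_comp = _log_gaussian_weights(fit, retained, sigma_theta, retained.stats)
    log_dens = _logsumexp(log_comp + np.log(retained.weights)[None, :], axis=1)
    log_dens_obs = log_marginal_density(fit, retained, sigma_theta, s_obs)
    return float(np.sum(retained.weights * (log_dens <= log_dens_obs)))


# ---------------------------------------------------------------------------
# Convenience pipeline
# ---------------------------------------------------------------------------

@dataclass
class EstimationResult:
    posteriors: dict            # name -> PosteriorDensity
    fit: GLMFit
    retained: RetainedSet
    bandwidth: np.ndarray
    log_marginal: float
    model_fit_pvalue: float

    @property
    def marginal_density(self) -> float:
        return math.exp(self.log_marginal)


def estimate(table: SimulationTable, observed: ObservedStats, priors=(),
             *, count: int | None = None, fraction: float | None = None,
             grid_size: int = 100, bandwidth=None,
             ctx: DistanceContext | None = None) -> EstimationResult:
    """Full retain -> fit -> posterior pipeline on one observed dataset.

    Fixed-prior parameters are excluded from estimation (they carry no
    uncertainty); log-scale parameters are transformed before the fit.
    """
    fixed = {spec.name for spec in priors if spec.is_fixed}
    if fixed & set(table.param_names):
        keep = [n for n in table.param_names if n not in fixed]
        table = SimulationTable(column_names=table.column_names, values=table.values,
                                param_names=keep, stat_names=table.stat_names,
                                weights=table.weights)
    retained = retain(table, observed, count=count, fraction=fraction, ctx=ctx)
    retained = to_estimation_scale(retained, priors)
    fit = fit_glm(retained)
    bw = default_bandwidth(retained) if bandwidth is None else np.asarray(bandwidth, float)
    s_obs = observed.values_for(retained.stat_names)
    posteriors = glm_posterior(fit, retained, priors, s_obs,
                               grid_size=grid_size, bandwidth=bw)
    log_marg = log_marginal_density(fit, retained, bw, s_obs)
    pvalue = model_check_pvalue(fit, retained, bw, s_obs)
    return EstimationResult(posteriors={d.parameter_name: d for d in posteriors},
                            fit=fit, retained=retained, bandwidth=bw,
                            log_marginal=log_marg, model_fit_pvalue=pvalue)
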