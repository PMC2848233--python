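"""Linear transforms of summary statistics, including PLS reduction.

High-dimensional statistic vectors carry redundant and noisy directions;
partial least squares (PLS) finds a few orthogonal linear combinations of
the (centered, unit-scaled) statistics that best explain the variability
of the model parameters.  A fitted :class:`LinearTransform` is then applied
identically to every simulated row *and* to the observed statistics, which
keeps the two commensurable for distance computations downstream.

The PLS fit itself delegates to scikit-learn's NIPALS implementation
(``PLSRegression``); parameters are also centered and scaled internally
during fitting so that the components are scale free, but the stored
transform maps statistics only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .exceptions import TransformError
from .io import ObservedStats, SimulationTable

logger = logging.getLogger(__name__)


@dataclass
class LinearTransform:
    """Affine map from named statistics to component scores.

    Applying the transform computes ``loadings @ ((x - centers) / scales)``,
    so the centers vector maps to the zero vector by construction.
    """

    input_names: list[str]
    centers: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # (k, p): scaled inputs -> components
    component_names: list[str]

    def __post_init__(self):
        self.input_names = list(self.input_names)
        self.component_names = list(self.component_names)
        self.centers = np.asarray(self.centers, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        p, k = len(self.input_names), len(self.component_names)
        if self.centers.size != p or self.scales.size != p:
            raise TransformError("transform: centers/scales length mismatch")
        if self.loadings.shape != (k, p):
            raise TransformError(f"transform: loadings must be {k}x{p}, "
                                 f"got {self.loadings.shape}")
        if np.any(self.scales <= 0):
            raise TransformError("transform: scales must be positive")
        if not np.all(np.isfinite(self.loadings)):
            raise TransformError("transform: non-finite loading")
        if k > p:
            raise TransformError("transform: more components than inputs")

    @property
    def n_components(self) -> int:
        return len(self.component_names)

    def apply_vector(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (self.loadings @ ((x - self.centers) / self.scales).T).T


def fit_pls(table: SimulationTable, k: int, *,
            component_prefix: str = "LinearCombination") -> LinearTransform:
    """Fit ``k`` PLS components of the parameters on the statistics.

    Statistics are centered and scaled to unit variance (constant columns
    are dropped with a warning before fitting); responses are standardized
    internally.  Raises :class:`TransformError` when ``k`` exceeds the
    usable statistic count or the row count minus one.
    """
    if not table.param_names:
        raise TransformError("fit_pls: table has no parameter columns")
    stats = table.stats()
    names = list(table.stat_names)
    sds = stats.std(axis=0, ddof=1)
    keep = sds > 0
    if not np.all(keep):
        dropped = [n for n, kp in zip(names, keep) if not kp]
        logger.warning("constant statistics dropped before PLS fit: %s", ", ".join(dropped))
        names = [n for n, kp in zip(names, keep) if kp]
        stats, sds = stats[:, keep], sds[keep]
    if k > min(len(names), table.n_rows - 1):
        raise TransformError(
            f"fit_pls: k={k} exceeds min(#usable stats={len(names)}, "
            f"#rows-1={table.n_rows - 1})")
    centers = stats.mean(axis=0)
    x_scaled = (stats - centers) / sds
    params = table.params()
    y_sds = params.std(axis=0, ddof=1)
    if np.any(y_sds == 0):
        y_sds = np.where(y_sds == 0, 1.0, y_sds)
    y_scaled = (params - params.mean(axis=0)) / y_sds

    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(x_scaled, y_scaled)
    loadings = np.asarray(pls.x_rotations_).T  # (k, p)
    component_names = [f"{component_prefix}{i + 1}" for i in range(k)]
    return LinearTransform(input_names=names, centers=centers, scales=sds,
                           loadings=loadings, component_names=component_names)


def apply_transform(transform: LinearTransform, data):
    """Apply a linear transform to a vector, table, or observed statistics.

    For a :class:`SimulationTable` the parameter columns pass through
    untouched and the statistic columns are replaced by component scores;
    for an :class:`ObservedStats` the same map produces a transformed
    observed vector.  A missing input statistic is an error naming it.
    """
    if isinstance(data, SimulationTable):
        _check_names(transform, data.stat_names)
        scores = transform.apply_vector(data.columns(transform.input_names))
        params = data.params()
        return SimulationTable(
            column_names=data.param_names + transform.component_names,
            values=np.column_stack([params, scores]) if params.size or scores.size
            else np.empty((data.n_rows, 0)),
            param_names=list(data.param_names),
            stat_names=list(transform.component_names),
            weights=None if data.weights is None else data.weights.copy())
    if isinstance(data, ObservedStats):
        _check_names(transform, data.names)
        scores = transform.apply_vector(data.values_for(transform.input_names))
        return ObservedStats(names=list(transform.component_names), values=scores)
    x = np.asarray(data, dtype=float)
    if x.shape[-1] != len(transform.input_names):
        raise TransformError(
            f"apply_transform: expected {len(transform.input_names)} inputs, "
            f"got {x.shape[-1]}")
    return transform.apply_vector(x)


def _check_names(transform: LinearTransform, available) -> None:
    missing = [n for n in transform.input_names if n not in set(available)]
    if missing:
        raise TransformError("apply_transform: missing input statistic(s): "
                             + ", ".join(missing))


# ---------------------------------------------------------------------------
# Transform file format: header "k", then "name center scale loading_1..k"
# ---------------------------------------------------------------------------

def write_transform(transform: LinearTransform, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{transform.n_components}\n")
        for j, name in enumerate(transform.input_names):
            loads = "\t".join(format(v, ".17g") for v in transform.loadings[:, j])
            fh.write(f"{name}\t{format(transform.centers[j], '.17g')}\t"
                     f"{format(transform.scales[j], '.17g')}\t{loads}\n")


def read_transform(path) -> LinearTransform:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise TransformError(f"{path}: empty transform file")
    try:
        k = int(lines[0].split()[0])
    except ValueError:
        raise TransformError(f"{path}: first line must be the component count") from None
    names, centers, scales, columns = [], [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split()
        if len(fields) != 3 + k:
            raise TransformError(
                f"{path}:{lineno}: expected 'name center scale' plus {k} loadings")
        names.append(fields[0])
        centers.append(float(fields[1]))
        scales.append(float(fields[2]))
        columns.append([float(v) for v in fields[3:]])
    loadings = np.array(columns).T if columns else np.empty((k, 0))
    return LinearTransform(input_names=names, centers=np.array(centers),
                           scales=np.array(scales), loadings=loadings,
                           component_names=[f"LinearCombination{i+1}" for i in range(k)])
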