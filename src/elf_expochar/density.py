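"""Product-Gaussian kernel density estimation of event parameters.

Each subgroup's events form an m x 4 sample over (mu, sigma2, phi, T). The
joint density is estimated with a product of univariate Gaussian kernels,
one bandwidth per dimension from the normal-reference rule

    h_j = sd_j * n**(-1/(d+4)),   d = 4,

with sd_j the sample standard deviation of column j. Marginal curves are the
corresponding one-dimensional kernel estimates.

Dispersion values can sit below numerical resolution (segments that are
constant to machine precision). Smoothing those with the others would paint a
spurious bump near zero, so for dimensions with a configured resolution
threshold the below-threshold entries are split off as a point ("Dirac") mass
and only the remainder is smoothed; each marginal then integrates to
(1 - point mass), and masses are reported alongside.

phi is smoothed without boundary correction even though retained events have
|phi| < 1, so marginal curves may leak past +-1; that is a known artifact of
plain kernel smoothing, reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DIM_NAMES = ("mu", "sigma2", "phi", "T")
#: resolution threshold (µT^2) below which a dispersion counts as a point mass
DEFAULT_DIRAC_THRESHOLDS = {"sigma2": 1e-12}
_SQRT2PI = np.sqrt(2.0 * np.pi)


def bandwidths(data: np.ndarray) -> np.ndarray:
    """Normal-reference bandwidths h_j = sd_j * n**(-1/(d+4)) per column."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be an n x d matrix")
    n, d = x.shape
    if n < 2:
        raise ValueError("bandwidths need at least 2 samples (sample SD undefined)")
    sd = x.std(axis=0, ddof=1)
    degenerate = (sd == 0) | (np.ptp(x, axis=0) == 0)
    if np.any(degenerate):
        j = int(np.argmax(degenerate))
        raise ValueError(
            f"column {j} has zero spread; represent it as a point mass "
            f"(see the dirac handling in fit_kde) instead of smoothing"
        )
    return sd * n ** (-1.0 / (d + 4))


def dirac_mass(column: np.ndarray, threshold: float) -> float:
    """Fraction of entries strictly below the resolution threshold."""
    col = np.asarray(column, dtype=float)
    if col.size == 0:
        raise ValueError("empty column")
    if threshold <= 0:
        return 0.0
    return float(np.mean(col < threshold))


@dataclass
class KDEModel:
    """A fitted product-kernel density over event parameters.

    ``data`` holds all samples on the (possibly transformed) working scale.
    Per dimension: ``smooth_mask`` flags the rows entering the smooth part,
    ``bandwidths`` the kernel scale fitted on those rows (NaN when the smooth
    part is empty or degenerate), and ``dirac`` the list of (location, mass)
    point masses split off before smoothing.
    """

    data: np.ndarray
    bandwidths: np.ndarray
    transforms: tuple[str, ...]
    smooth_mask: np.ndarray  # n x d boolean
    dirac: list[list[tuple[float, float]]]
    dim_names: tuple[str, ...] = DIM_NAMES
    dirac_thresholds: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def d(self) -> int:
        return self.data.shape[1]

    def n_smooth(self, dim: int | str) -> int:
        return int(self.smooth_mask[:, self._dim_index(dim)].sum())

    def dirac_mass(self, dim: int | str) -> float:
        return float(sum(m for _, m in self.dirac[self._dim_index(dim)]))

    def _dim_index(self, dim: int | str) -> int:
        if isinstance(dim, str):
            if dim not in self.dim_names:
                raise ValueError(f"unknown dimension {dim!r}; have {self.dim_names}")
            return self.dim_names.index(dim)
        if not 0 <= dim < self.d:
            raise ValueError(f"dimension index {dim} out of range")
        return int(dim)


def _apply_transform(col: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return col
    if transform == "log10":
        if np.any(col <= 0):
            raise ValueError("log10 transform requires strictly positive values")
        return np.log10(col)
    raise ValueError(f"unknown transform {transform!r}")


def fit_kde(data: np.ndarray, dim_names: tuple[str, ...] = DIM_NAMES,
            transforms: dict | None = None,
            dirac_thresholds: dict | None = None) -> KDEModel:
    """Fit the product-Gaussian KDE with per-dimension point-mass handling.

    ``transforms`` maps dimension name -> 'identity' | 'log10' (default all
    identity: densities are estimated on the raw parameter scales).
    ``dirac_thresholds`` maps dimension name -> resolution threshold; entries
    below it form the point mass. A smooth part left with zero spread is
    itself collapsed to a point mass rather than smoothed.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be an n x d matrix")
    n, d = x.shape
    if len(dim_names) != d:
        raise ValueError("dim_names length must match data columns")
    if n < 1:
        raise ValueError("no samples")
    transforms = transforms or {}
    thresholds = DEFAULT_DIRAC_THRESHOLDS if dirac_thresholds is None else dirac_thresholds
    tnames = tuple(transforms.get(name, "identity") for name in dim_names)

    work = np.empty_like(x)
    smooth_mask = np.ones((n, d), dtype=bool)
    dirac: list[list[tuple[float, float]]] = []
    h = np.full(d, np.nan)
    for j, name in enumerate(dim_names):
        thr = thresholds.get(name, 0.0)
        below = x[:, j] < thr if thr > 0 else np.zeros(n, dtype=bool)
        masses: list[tuple[float, float]] = []
        if below.any():
            masses.append((float(x[below, j].mean()), float(below.mean())))
        smooth = ~below
        col = x[:, j].copy()
        col[smooth] = _apply_transform(x[smooth, j], tnames[j])
        work[:, j] = col
        if smooth.sum() >= 2 and np.ptp(col[smooth]) > 0:
            h[j] = col[smooth].std(ddof=1) * smooth.sum() ** (-1.0 / (d + 4))
        elif smooth.any():
            # all remaining values identical: a second point mass, nothing to smooth
            masses.append((float(col[smooth][0]), float(smooth.mean())))
            smooth = np.zeros(n, dtype=bool)
        smooth_mask[:, j] = smooth
        dirac.append(masses)
    return KDEModel(
        data=work, bandwidths=h, transforms=tnames, smooth_mask=smooth_mask,
        dirac=dirac, dim_names=tuple(dim_names), dirac_thresholds=dict(thresholds),
    )


def kde_density(model: KDEModel, x) -> float:
    """Joint density f(x) = (1/n) sum_i prod_j K((x_j - X_ij)/h_j)/h_j.

    Evaluated over the rows smooth in every dimension (the product kernel is
    only defined where each coordinate has a bandwidth); x is on the model's
    working scale.
    """
    pt = np.asarray(x, dtype=float)
    if pt.shape != (model.d,):
        raise ValueError(f"expected a {model.d}-vector, got shape {pt.shape}")
    if np.any(np.isnan(model.bandwidths)):
        bad = [model.dim_names[j] for j in range(model.d) if np.isnan(model.bandwidths[j])]
        raise ValueError(f"dimensions {bad} are pure point masses; no smooth joint density")
    rows = model.smooth_mask.all(axis=1)
    if not rows.any():
        return 0.0
    z = (pt - model.data[rows]) / model.bandwidths
    kern = np.exp(-0.5 * z * z) / (_SQRT2PI * model.bandwidths)
    return float(np.mean(np.prod(kern, axis=1)))


@dataclass
class MarginalCurve:
    """One-dimensional marginal: a smooth curve plus point masses."""

    dim: str
    grid: np.ndarray
    density: np.ndarray
    point_masses: list[tuple[float, float]]
    bandwidth: float
    transform: str

    @property
    def dirac_mass(self) -> float:
        return float(sum(m for _, m in self.point_masses))

    @property
    def smooth_area(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    @property
    def peak_location(self) -> float:
        return float(self.grid[np.argmax(self.density)])


def default_grid(model: KDEModel, dim: int | str, n_points: int = 512) -> np.ndarray:
    """Evaluation grid spanning the smooth data +- 3 bandwidths."""
    j = model._dim_index(dim)
    col = model.data[model.smooth_mask[:, j], j]
    h = model.bandwidths[j]
    if col.size == 0 or np.isnan(h):
        locs = [loc for loc, _ in model.dirac[j]] or [0.0]
        return np.linspace(min(locs) - 1.0, max(locs) + 1.0, n_points)
    return np.linspace(col.min() - 3 * h, col.max() + 3 * h, n_points)


def marginal_density(model: KDEModel, dim: int | str, grid: np.ndarray | None = None) -> MarginalCurve:
    """Smooth 1-D kernel estimate of one dimension, rescaled by (1 - point mass).

    For a product kernel the marginal of the joint estimate is exactly the
    univariate KDE of that column, so this is both the projection of the
    joint density and a standalone 1-D estimate.
    """
    j = model._dim_index(dim)
    grid = default_grid(model, j) if grid is None else np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) < 0):
        raise ValueError("grid must be 1-D and sorted")
    col = model.data[model.smooth_mask[:, j], j]
    h = model.bandwidths[j]
    mass = sum(m for _, m in model.dirac[j])
    if col.size == 0 or np.isnan(h):
        density = np.zeros_like(grid)
    else:
        z = (grid[:, None] - col[None, :]) / h
        density = (1.0 - mass) * np.exp(-0.5 * z * z).sum(axis=1) / (col.size * h * _SQRT2PI)
    return MarginalCurve(
        dim=model.dim_names[j], grid=grid, density=density,
        point_masses=list(model.dirac[j]), bandwidth=float(h), transform=model.transforms[j],
    )
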