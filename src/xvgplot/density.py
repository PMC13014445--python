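"""2D density surfaces and free-energy landscapes.

Scatter data — typically a projection of a molecular-dynamics
trajectory onto two collective coordinates — is turned into a binned
probability mass P per grid cell.  Boltzmann inversion converts P into
a Gibbs free-energy surface

    G = -k_B T ln(P / P0),

where P0 is the probability of the most populated bin, so the global
minimum of the landscape is exactly 0 kJ/mol.  Bins that received no
samples have undefined free energy and stay masked rather than being
assigned an arbitrary cap.  For sparse datasets a Gaussian kernel
density estimate provides a smooth alternative to binning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as _scipy_stats

from .errors import EstimationError, OptionError

__all__ = [
    "K_B",
    "DEFAULT_BINS",
    "DEFAULT_LEVELS",
    "DEFAULT_TEMPERATURE",
    "DensityGrid",
    "probability_density_2d",
    "gibbs_from_density",
    "kde_density",
    "contour_levels",
]

#: Boltzmann constant in kJ mol^-1 K^-1 (molar energy convention)
K_B = 0.008314462618

DEFAULT_BINS = 50
DEFAULT_LEVELS = 15
DEFAULT_TEMPERATURE = 298.15  # kelvin


@dataclass
class DensityGrid:
    """A 2D binned surface: bin edges plus per-bin values.

    ``kind`` is ``"probability"`` (dimensionless mass per bin, summing
    to 1), ``"energy"`` (kJ/mol, minimum 0) or ``"kde"`` (per-area
    density).  ``mask`` marks bins whose value is undefined (unsampled).
    ``temperature`` is set on energy grids only.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray
    kind: str = "probability"
    temperature: Optional[float] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.x_edges = np.asarray(self.x_edges, dtype=float)
        self.y_edges = np.asarray(self.y_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        expected = (len(self.x_edges) - 1, len(self.y_edges) - 1)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match edges {expected}"
            )
        if np.any(np.diff(self.x_edges) <= 0) or np.any(np.diff(self.y_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    def __eq__(self, other) -> bool:
        if not isinstance(other, DensityGrid):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.temperature == other.temperature
            and np.array_equal(self.x_edges, other.x_edges)
            and np.array_equal(self.y_edges, other.y_edges)
            and np.array_equal(self.values, other.values, equal_nan=True)
            and np.array_equal(self.mask, other.mask)
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def unmasked(self) -> np.ndarray:
        """Values of the defined bins, flattened."""
        return self.values[~self.mask]


def probability_density_2d(x, y, bins: int = DEFAULT_BINS) -> DensityGrid:
    """Bin scatter points onto a ``bins``x``bins`` grid of probability mass.

    The grid spans [min, max] of each coordinate; values are counts / N
    so they sum to exactly 1.  Zero-count bins are masked as undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise OptionError("cannot bin an empty point set")
    if x.shape != y.shape:
        raise OptionError("x and y must have equal length")
    if bins < 1:
        raise OptionError(f"bins must be >= 1, got {bins}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise OptionError(
            "degenerate coordinate range: all x (or all y) values are equal"
        )
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=bins)
    values = counts / x.size
    return DensityGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        values=values,
        kind="probability",
        mask=counts == 0,
    )


def gibbs_from_density(
    grid: DensityGrid, temperature: float = DEFAULT_TEMPERATURE
) -> DensityGrid:
    """Boltzmann inversion: G = -k_B T ln(P / P0), P0 the maximum bin.

    The most populated bin gets G = 0 by construction; empty bins stay
    masked.  Works on binned probability and KDE grids alike (the
    normalisation by P0 cancels any per-area factor).
    """
    if grid.kind not in ("probability", "kde"):
        raise TypeError(f"expected a probability or kde grid, got kind={grid.kind!r}")
    if temperature <= 0:
        raise OptionError(f"temperature must be positive, got {temperature}")
    p0 = grid.unmasked().max()
    if p0 <= 0:
        raise OptionError("grid has no positive probability mass")
    energy = np.zeros_like(grid.values)
    defined = ~grid.mask & (grid.values > 0)
    energy[defined] = -K_B * temperature * np.log(grid.values[defined] / p0)
    energy[defined] += 0.0  # fold -0.0 (the P == P0 bin) into +0.0
    new_mask = grid.mask | (grid.values <= 0)
    energy[new_mask] = np.nan
    return DensityGrid(
        x_edges=grid.x_edges.copy(),
        y_edges=grid.y_edges.copy(),
        values=energy,
        kind="energy",
        temperature=temperature,
        mask=new_mask,
    )


def kde_density(
    x, y, grid_size: int = DEFAULT_BINS, bandwidth: Optional[float] = None
) -> DensityGrid:
    """Gaussian kernel density estimate evaluated on a regular grid.

    ``bandwidth`` is the scalar factor passed to the estimator; the
    default is Scott's rule on the 2D sample.  The grid spans the data
    range padded by one bandwidth per axis, so a well-contained sample
    integrates to ~1 over the grid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise EstimationError(
            "kernel density estimation needs at least 3 points; "
            "use binning for smaller sets"
        )
    if grid_size < 2:
        raise OptionError(f"grid_size must be >= 2, got {grid_size}")
    try:
        kde = _scipy_stats.gaussian_kde(
            np.vstack([x, y]), bw_method=bandwidth if bandwidth is not None else "scott"
        )
    except np.linalg.LinAlgError:
        raise EstimationError(
            "singular covariance (collinear points); use binning instead"
        ) from None
    # per-axis bandwidth = kde factor * sample standard deviation
    bw_x = kde.factor * x.std(ddof=1)
    bw_y = kde.factor * y.std(ddof=1)
    x_edges = np.linspace(x.min() - bw_x, x.max() + bw_x, grid_size + 1)
    y_edges = np.linspace(y.min() - bw_y, y.max() + bw_y, grid_size + 1)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    grid_x, grid_y = np.meshgrid(xc, yc, indexing="ij")
    values = kde(np.vstack([grid_x.ravel(), grid_y.ravel()])).reshape(grid_x.shape)
    return DensityGrid(x_edges=x_edges, y_edges=y_edges, values=values, kind="kde")


def contour_levels(grid: DensityGrid, n_levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """``n_levels`` strictly increasing values evenly spaced over (min, max).

    A constant grid has no interior range; a single level at the
    constant value is returned with a warning.
    """
    if n_levels < 1:
        raise OptionError(f"n_levels must be >= 1, got {n_levels}")
    defined = grid.unmasked()
    if defined.size == 0:
        raise OptionError("grid has no unmasked bins")
    lo, hi = float(defined.min()), float(defined.max())
    if lo == hi:
        warnings.warn("constant grid: returning a single degenerate contour level")
        return np.array([lo])
    return np.linspace(lo, hi, n_levels + 2)[1:-1]
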