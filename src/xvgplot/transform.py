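"""Dataset-level transforms and the statistics shown in ``--stats`` legends.

A residual plot subtracts the x value from each y value, turning a
correlation plot around the identity line into deviations around zero.
Histograms rebin a series' y values.  ``compute_stats`` yields the RMSD
and R² pair appended to legends for correlation plots, with x treated
as the reference and y as the prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import OptionError
from .format_io import DataSet

__all__ = ["StatsSummary", "residual", "histogram", "compute_stats", "stats_legend"]

#: default bin count, shared with the 2D density grids
DEFAULT_BINS = 50


@dataclass(frozen=True)
class StatsSummary:
    """RMSD and squared correlation for one paired series.

    ``r2`` is the squared Pearson correlation coefficient; it is NaN when
    either series has zero variance (the statistic is then undefined).
    """

    rmsd: float
    r2: float
    n: int


def residual(ds: DataSet) -> DataSet:
    """Return a dataset with the same x and y' = y - x; legend preserved."""
    return replace(ds, x=ds.x.copy(), y=ds.y - ds.x)


def histogram(ds: DataSet, bins: int = DEFAULT_BINS) -> DataSet:
    """Bin the y values into ``bins`` equal-width bins over [min, max].

    Returns bin centers as x and counts as y, so the result plots like
    any other dataset.  The rightmost bin is closed; counts always sum
    to the number of input points.
    """
    if bins < 1:
        raise OptionError(f"bins must be >= 1, got {bins}")
    counts, edges = np.histogram(ds.y, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return replace(ds, x=centers, y=counts.astype(float))


def compute_stats(ds: DataSet) -> StatsSummary:
    """RMSD and squared Pearson correlation of (x, y) pairs.

    rmsd = sqrt( mean( (y_i - x_i)^2 ) );  r2 = corr(x, y)^2.
    Requires at least two points.  When either coordinate is constant the
    correlation is undefined and ``r2`` is NaN; the RMSD is still valid.
    """
    n = len(ds)
    if n < 2:
        raise OptionError("statistics require at least two points")
    rmsd = float(np.sqrt(np.mean((ds.y - ds.x) ** 2)))
    if np.ptp(ds.x) == 0 or np.ptp(ds.y) == 0:
        r2 = math.nan
    else:
        r = np.corrcoef(ds.x, ds.y)[0, 1]
        r2 = float(min(r * r, 1.0))  # guard float overshoot above 1
    return StatsSummary(rmsd=rmsd, r2=r2, n=n)


def stats_legend(legend: str | None, stats: StatsSummary) -> str:
    """Format the legend suffix: RMSD to 3 significant digits, R2 to 2 decimals."""
    r2_text = "undefined" if math.isnan(stats.r2) else f"{stats.r2:.2f}"
    suffix = f"(RMSD = {stats.rmsd:.3g}, R² = {r2_text})"
    return f"{legend} {suffix}" if legend else suffix
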