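"""Seeded synthetic-data generators shaped like simulation analysis output.

Each generator writes a file in one of the dialects the readers accept
and mimics a family of curves that molecular-simulation analysis tools
commonly produce: saturating time series (structural RMSD traces),
multi-observable series (temperature and pressure), noisy
reference-vs-prediction scatters (force-field train/test correlation),
and 2D Gaussian-mixture projections (principal-component landscapes).
All randomness flows from the explicit per-recipe seed, so the same
recipe always yields byte-identical files — no global random state is
touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .format_io import DataSet, XvgDocument, write_xvg

__all__ = [
    "FixtureRecipe",
    "make_timeseries",
    "make_multiseries",
    "make_scatter_correlation",
    "make_projection_2d",
]


@dataclass(frozen=True)
class FixtureRecipe:
    """Parameters shared by all generators.

    ``noise_sd`` is the standard deviation of the additive Gaussian
    noise, in the units of the generated observable; for the scatter
    generator it instead scales the residual noise relative to the
    level calibrated to the target correlation (1.0 keeps the
    calibration exact).
    """

    kind: str = "timeseries"
    n_points: int = 100
    seed: int = 0
    noise_sd: float = 0.1
    dialect: str = "xvg"  # or "csv", "dat"


def _rng(recipe: FixtureRecipe) -> np.random.Generator:
    return np.random.default_rng(recipe.seed)


def _write(doc: XvgDocument, path, dialect: str) -> Path:
    path = Path(path)
    if dialect == "xvg":
        write_xvg(doc, path)
    elif dialect in ("csv", "dat"):
        sep = "," if dialect == "csv" else " "
        lines = []
        if dialect == "csv":
            headers = [f'"{doc.x_label or "x"}"'] + [
                f'"{ds.legend or f"set {i}"}"' for i, ds in enumerate(doc.datasets)
            ]
            lines.append("#" + sep.join(headers))
        x = doc.datasets[0].x
        for row_i in range(len(x)):
            row = [repr(float(x[row_i]))] + [
                repr(float(ds.y[row_i])) for ds in doc.datasets
            ]
            lines.append(sep.join(row))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def make_timeseries(recipe: FixtureRecipe, path) -> Path:
    """A saturating trace: y(t) = a (1 - exp(-t/tau)) + noise.

    Emulates the shape of a structural-deviation time series that rises
    from zero and plateaus once the system equilibrates.
    """
    if recipe.n_points < 2:
        raise ValueError("need at least 2 points")
    rng = _rng(recipe)
    t = np.linspace(0.0, 10.0, recipe.n_points)  # ns
    plateau, tau = 0.25, 1.5
    mean = plateau * (1.0 - np.exp(-t / tau))
    y = mean + rng.normal(0.0, recipe.noise_sd, size=recipe.n_points)
    doc = XvgDocument(
        title="Backbone deviation",
        x_label="Time (ns)",
        y_label="RMSD (nm)",
        datasets=[DataSet(x=t, y=y, legend="trace", set_index=0)],
    )
    return _write(doc, path, recipe.dialect)


def make_multiseries(
    recipe: FixtureRecipe, path, n_series: int = 2, layout: str = "columns"
) -> Path:
    """Several observables over one time axis (e.g. temperature, pressure).

    ``layout`` selects the xvg encoding: ``"columns"`` writes one
    shared-x multi-column block, ``"blocks"`` writes one
    ampersand-separated block per series carrying the same data.
    """
    if n_series < 2:
        raise ValueError("need at least 2 series")
    rng = _rng(recipe)
    t = np.linspace(0.0, 10.0, recipe.n_points)
    baselines = 298.0 + 50.0 * np.arange(n_series)
    series = [
        base + rng.normal(0.0, max(recipe.noise_sd, 1e-12), size=recipe.n_points)
        for base in baselines
    ]
    datasets = [
        DataSet(x=t, y=y, legend=f"s{i} observable", set_index=i)
        for i, y in enumerate(series)
    ]
    doc = XvgDocument(
        title="Thermodynamic observables",
        x_label="Time (ns)",
        y_label="Value",
        datasets=datasets,
    )
    if recipe.dialect == "xvg" and layout == "blocks":
        # break the shared x so the writer emits &-separated blocks:
        # perturb nothing, just write blocks manually
        path = Path(path)
        lines = [f'@    title "{doc.title}"',
                 f'@    xaxis  label "{doc.x_label}"',
                 f'@    yaxis  label "{doc.y_label}"']
        lines += [f'@ s{i} legend "{ds.legend}"' for i, ds in enumerate(datasets)]
        for block_no, ds in enumerate(datasets):
            if block_no:
                lines.append("&")
            lines += [f"{float(xv)!r} {float(yv)!r}" for xv, yv in zip(ds.x, ds.y)]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path
    return _write(doc, path, recipe.dialect)


def make_scatter_correlation(recipe: FixtureRecipe, path, true_r2: float = 0.8) -> Path:
    """Paired (reference, prediction) points with a target squared correlation.

    Reference values are standard normal; predictions are the reference
    plus Gaussian noise whose variance is calibrated so the population
    squared correlation equals ``true_r2`` — the sample statistic
    converges to it as n grows.  ``recipe.noise_sd`` multiplies the
    calibrated noise level (1.0 leaves the calibration exact), which
    makes the RMSD scale linearly with it.
    """
    if not 0 < true_r2 <= 1:
        raise ValueError("true_r2 must be in (0, 1]")
    rng = _rng(recipe)
    x = rng.normal(0.0, 1.0, size=recipe.n_points)
    # corr(x, x+eps)^2 = var(x) / (var(x) + var(eps))
    sigma = float(np.sqrt(1.0 / true_r2 - 1.0))
    y = x + recipe.noise_sd * sigma * rng.normal(0.0, 1.0, size=recipe.n_points)
    doc = XvgDocument(
        title="Train/test correlation",
        x_label="Reference energy",
        y_label="Model energy",
        datasets=[DataSet(x=x, y=y, legend="model", set_index=0)],
    )
    return _write(doc, path, recipe.dialect)


def make_projection_2d(recipe: FixtureRecipe, path, n_modes: int = 2) -> Path:
    """A mixture of 2D Gaussian clusters with strictly decreasing weights.

    Emulates a trajectory projected onto two principal components:
    each cluster is one conformational basin.  Weights halve from mode
    to mode, so the most populated density bin sits in the first mode
    and the free-energy minimum is unambiguous.  Mode centers are
    spread on a circle of radius 3; cluster spread is ``noise_sd``.
    """
    if n_modes < 1:
        raise ValueError("need at least 1 mode")
    rng = _rng(recipe)
    weights = 0.5 ** np.arange(n_modes)
    weights /= weights.sum()
    angles = 2.0 * np.pi * np.arange(n_modes) / max(n_modes, 2)
    centers = 3.0 * np.column_stack([np.cos(angles), np.sin(angles)])
    assignments = rng.choice(n_modes, size=recipe.n_points, p=weights)
    spread = max(recipe.noise_sd, 1e-12)
    points = centers[assignments] + rng.normal(
        0.0, spread, size=(recipe.n_points, 2)
    )
    doc = XvgDocument(
        title="Principal-component projection",
        x_label="PC1",
        y_label="PC2",
        datasets=[
            DataSet(x=points[:, 0], y=points[:, 1], legend="projection", set_index=0)
        ],
    )
    return _write(doc, path, recipe.dialect)


def heavy_mode_center(recipe: FixtureRecipe, n_modes: int = 2) -> tuple[float, float]:
    """Center of the most-weighted mode for a projection recipe (mode 0)."""
    angles = 2.0 * np.pi * np.arange(n_modes) / max(n_modes, 2)
    return (3.0 * float(np.cos(angles[0])), 3.0 * float(np.sin(angles[0])))
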