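import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from xvgplot.fixtures import (
    FixtureRecipe,
    make_multiseries,
    make_projection_2d,
    make_scatter_correlation,
    make_timeseries,
)
from xvgplot.format_io import DataSet, XvgDocument

#: CLI token lists (file keys a-d get replaced by real paths) exercising the
#: whole flag surface; used for CLI/API spec-equivalence checks
INVOCATION_MATRIX = [
    ["a"],
    ["a", "b"],
    ["a", "b", "--panels"],
    ["a", "b", "--panels", "side"],
    ["a", "b", "--panels", "top"],
    ["c", "--stats"],
    ["c", "--stats", "--equalaxes"],
    ["c", "--residual"],
    ["c", "--histogram", "--bins", "20"],
    ["a", "--logy"],
    ["a", "--xmin", "-1", "--xmax", "11"],
    ["a", "--ymin", "-0.5", "--ymax", "0.9"],
    ["b", "--linestyle", "-", "None", "--marker", "None", "o"],
    ["b", "--datasetlegends", "hot", "cold"],
    ["a", "--title", "demo run"],
    ["d", "--heatmap"],
    ["d", "--heatmap", "--gibbs", "--temperature", "310"],
    ["d", "--contour", "--levels", "9"],
    ["d", "--contour", "--gibbs", "--showdots"],
    ["d", "--kde", "--bins", "25"],
    ["d", "--heatmap", "--cmap", "plasma", "--bins", "30"],
    ["a", "--allfontsizes", "1.4", "--squarefig"],
    ["a", "b", "--panels", "side", "--sharelabel"],
]


@pytest.fixture
def sample_files(tmp_path):
    """One file of each fixture family, keyed a-d."""
    a = make_timeseries(FixtureRecipe(seed=1, n_points=50), tmp_path / "a.xvg")
    b = make_multiseries(
        FixtureRecipe(seed=2, n_points=50, noise_sd=1.0), tmp_path / "b.xvg"
    )
    c = make_scatter_correlation(
        FixtureRecipe(seed=3, n_points=300, noise_sd=1.0, dialect="csv"),
        tmp_path / "c.csv",
        true_r2=0.8,
    )
    d = make_projection_2d(
        FixtureRecipe(seed=4, n_points=800, noise_sd=0.5), tmp_path / "d.xvg"
    )
    return {"a": str(a), "b": str(b), "c": str(c), "d": str(d)}


@pytest.fixture
def write_file(tmp_path):
    """Write literal text to a temporary file and return its path."""

    def _write(name, text):
        path = tmp_path / name
        path.write_text(text, encoding="utf-8")
        return path

    return _write


@pytest.fixture
def two_set_doc():
    x = np.array([0.0, 1.0, 2.0])
    return XvgDocument(
        title="demo",
        x_label="Time (ns)",
        y_label="RMSD (nm)",
        datasets=[
            DataSet(x=x, y=np.array([1.0, 3.0, 2.0]), legend="a", set_index=0),
            DataSet(x=x, y=np.array([2.0, 4.0, 5.0]), set_index=1),
        ],
    )
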