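"""Styles, panel layout, spec building and headless rendering."""

import numpy as np
import pytest

from xvgplot.errors import OptionError
from xvgplot.figure_model import (
    COLOR_CYCLE,
    PlotOptions,
    assign_styles,
    build_plot_spec,
    layout_panels,
    render,
)
from xvgplot.format_io import DataSet, XvgDocument


def make_doc(n_sets=1, n_points=20, seed=0, title="", legend_prefix=None):
    rng = np.random.default_rng(seed)
    x = np.linspace(0, 1, n_points)
    datasets = [
        DataSet(
            x=x,
            y=rng.normal(size=n_points),
            legend=f"{legend_prefix}{i}" if legend_prefix else None,
            set_index=i,
        )
        for i in range(n_sets)
    ]
    return XvgDocument(title=title, x_label="x", y_label="y", datasets=datasets)


def scatter_doc(seed=1, n=200):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = x + 0.3 * rng.normal(size=n)
    return XvgDocument(datasets=[DataSet(x=x, y=y, legend="model")])


# ---------------------------------------------------------------------------
# styles


def test_mixed_user_styles():
    styles = assign_styles(3, ["-", "None", "-"], ["None", ".", "o"])
    assert styles[0].linestyle == "-" and styles[0].marker is None
    assert styles[1].linestyle is None and styles[1].marker == "."
    assert styles[1].marker_size < styles[2].marker_size
    assert styles[2].linestyle == "-" and styles[2].marker == "o"
    assert len({s.color for s in styles}) == 3


def test_partial_linestyles_autocompleted():
    styles = assign_styles(3, ["-"], [])
    assert styles[0].linestyle == "-"
    assert all(s.linestyle is not None for s in styles)
    assert len({s.color for s in styles}) == 3


def test_single_default_style_is_visible():
    (style,) = assign_styles(1)
    assert style.linestyle is not None or style.marker is not None


def test_unknown_style_token_named_in_error():
    with pytest.raises(OptionError, match="wiggly"):
        assign_styles(2, ["wiggly"], [])
    with pytest.raises(OptionError, match="blob"):
        assign_styles(2, [], ["blob"])


def test_disabled_line_gets_marker_fallback():
    (style,) = assign_styles(1, ["None"], [])
    assert style.marker is not None


@pytest.mark.parametrize("n", [1, 5, 10, 25, 40])
def test_style_triples_unique(n):
    styles = assign_styles(n)
    triples = {s.triple for s in styles}
    assert len(triples) == n


def test_color_cycle_has_ten_distinct_colors():
    assert len(set(COLOR_CYCLE)) >= 10


# ---------------------------------------------------------------------------
# layout


@pytest.mark.parametrize(
    "n, mode, nrows, ncols",
    [
        (1, "off", 1, 1),
        (3, "off", 1, 1),
        (2, "stacked", 2, 1),
        (2, "top", 2, 1),
        (2, "side", 1, 2),
        (4, "side", 1, 4),
    ],
)
def test_layout_geometry(n, mode, nrows, ncols):
    layout = layout_panels(n, mode)
    assert (layout.nrows, layout.ncols) == (nrows, ncols)


@pytest.mark.parametrize("n", range(1, 9))
def test_panel_labels_are_consecutive_letters(n):
    layout = layout_panels(n, "stacked")
    if n == 1:
        assert layout.labels == ()
    else:
        assert layout.labels == tuple("ABCDEFGH"[:n])


def test_layout_rejects_unknown_mode():
    with pytest.raises(OptionError, match="sideways"):
        layout_panels(2, "sideways")


# ---------------------------------------------------------------------------
# spec building


def test_multiple_files_merge_into_one_panel():
    docs = [make_doc(seed=0), make_doc(seed=1)]
    spec = build_plot_spec(docs, PlotOptions())
    assert len(spec.panels) == 1
    assert len(spec.panels[0].series) == 2
    assert spec.panels[0].label is None


def test_panels_mode_one_panel_per_file_with_labels():
    docs = [make_doc(seed=s, title=f"file {s}") for s in range(3)]
    spec = build_plot_spec(docs, PlotOptions(panels="stacked"))
    assert [p.label for p in spec.panels] == ["A", "B", "C"]
    assert (spec.nrows, spec.ncols) == (3, 1)


def test_stats_flag_appends_statistics_to_legend():
    spec = build_plot_spec([scatter_doc()], PlotOptions(stats=True))
    (_, _, label) = spec.panels[0].series[0]
    assert "RMSD = " in label and "R² = " in label and label.startswith("model")


def test_equal_axes_forces_shared_range():
    spec = build_plot_spec([scatter_doc()], PlotOptions(equal_axes=True))
    panel = spec.panels[0]
    assert panel.x_range == panel.y_range
    ds = panel.series[0][0]
    lo = min(ds.x.min(), ds.y.min())
    hi = max(ds.x.max(), ds.y.max())
    assert panel.x_range == (lo, hi)


def test_axis_limits_applied_exactly():
    spec = build_plot_spec(
        [make_doc()], PlotOptions(x_min=-0.5, x_max=2.5, y_min=-3.0, y_max=3.0)
    )
    assert spec.panels[0].x_range == (-0.5, 2.5)
    assert spec.panels[0].y_range == (-3.0, 3.0)


def test_font_scaling_multiplies_every_size():
    base = build_plot_spec([make_doc()], PlotOptions())
    scaled = build_plot_spec([make_doc()], PlotOptions(allfontsizes=1.5))
    for attr in (
        "tick_font_size",
        "label_font_size",
        "legend_font_size",
        "title_font_size",
    ):
        assert getattr(scaled, attr) == pytest.approx(1.5 * getattr(base, attr))


def test_share_label_suppresses_inner_labels():
    docs = [make_doc(seed=s) for s in range(3)]
    spec = build_plot_spec(docs, PlotOptions(panels="stacked", share_label=True))
    assert [p.show_x_label for p in spec.panels] == [False, False, True]
    assert all(p.show_y_label for p in spec.panels)
    side = build_plot_spec(docs, PlotOptions(panels="side", share_label=True))
    assert [p.show_y_label for p in side.panels] == [True, False, False]
    assert all(p.show_x_label for p in side.panels)


def test_residual_then_histogram_transform_order():
    doc = scatter_doc()
    spec = build_plot_spec(
        [doc], PlotOptions(residual=True, histogram=True, bins=10)
    )
    out = spec.panels[0].series[0][0]
    assert out.y.sum() == len(doc.datasets[0])  # histogram of the residuals
    resid = doc.datasets[0].y - doc.datasets[0].x
    assert out.x.min() >= resid.min() and out.x.max() <= resid.max()


def test_histogram_relabels_axes():
    doc = make_doc()
    spec = build_plot_spec([doc], PlotOptions(histogram=True))
    assert spec.panels[0].x_label == "y"
    assert spec.panels[0].y_label == "Count"


def test_legend_overrides_positional():
    docs = [make_doc(n_sets=2, legend_prefix="orig")]
    spec = build_plot_spec(docs, PlotOptions(legends=["first"]))
    labels = [label for _, _, label in spec.panels[0].series]
    assert labels == ["first", "orig1"]


def test_density_panel_pools_all_datasets():
    docs = [scatter_doc(seed=1), scatter_doc(seed=2)]
    spec = build_plot_spec(docs, PlotOptions(heatmap=True, bins=10))
    assert len(spec.panels) == 1
    grid = spec.panels[0].grid
    assert grid.kind == "probability"
    assert grid.values.sum() == pytest.approx(1.0)


def test_gibbs_spec_uses_requested_temperature():
    spec = build_plot_spec(
        [scatter_doc()], PlotOptions(contour=True, gibbs=True, temperature=350.0)
    )
    grid = spec.panels[0].grid
    assert grid.kind == "energy" and grid.temperature == 350.0
    assert spec.panels[0].levels is not None


@pytest.mark.parametrize(
    "opts",
    [
        PlotOptions(gibbs=True),
        PlotOptions(heatmap=True, contour=True),
        PlotOptions(histogram=True, heatmap=True),
        PlotOptions(x_min=2.0, x_max=1.0),
        PlotOptions(panels="diagonal"),
        PlotOptions(temperature=-5.0),
        PlotOptions(output_path="fig.svg"),
    ],
)
def test_option_conflicts_rejected(opts):
    with pytest.raises(OptionError):
        build_plot_spec([scatter_doc()], opts)


def test_showdots_carries_pooled_points():
    doc = scatter_doc(n=50)
    spec = build_plot_spec([doc], PlotOptions(heatmap=True, showdots=True, bins=5))
    dots_x, dots_y = spec.panels[0].dots
    np.testing.assert_array_equal(dots_x, doc.datasets[0].x)


# ---------------------------------------------------------------------------
# rendering


def test_render_png_magic_bytes(tmp_path):
    opts = PlotOptions(output_path=str(tmp_path / "out.png"))
    spec = build_plot_spec([make_doc()], opts)
    out = render(spec, opts)
    data = out.read_bytes()
    assert data.startswith(b"\x89PNG\r\n\x1a\n") and len(data) > 0


def test_render_pdf_magic_bytes(tmp_path):
    opts = PlotOptions(output_path=str(tmp_path / "out.pdf"))
    spec = build_plot_spec([make_doc()], opts)
    out = render(spec, opts)
    assert out.read_bytes().startswith(b"%PDF")


@pytest.mark.parametrize("ext", ["png", "pdf"])
def test_render_is_deterministic(tmp_path, ext):
    """The same spec rendered twice gives byte-identical output."""
    doc = make_doc(n_sets=2, legend_prefix="s")
    first = PlotOptions(output_path=str(tmp_path / f"a.{ext}"))
    second = PlotOptions(output_path=str(tmp_path / f"b.{ext}"))
    render(build_plot_spec([doc], first), first)
    render(build_plot_spec([doc], second), second)
    assert (tmp_path / f"a.{ext}").read_bytes() == (tmp_path / f"b.{ext}").read_bytes()


def test_render_density_figure(tmp_path):
    opts = PlotOptions(
        contour=True, gibbs=True, showdots=True,
        output_path=str(tmp_path / "fel.png"),
    )
    spec = build_plot_spec([scatter_doc(n=500)], opts)
    assert render(spec, opts).stat().st_size > 0


def test_render_rejects_unknown_extension(tmp_path):
    spec = build_plot_spec([make_doc()], PlotOptions())
    bad = PlotOptions()
    bad.output_path = str(tmp_path / "out.svg")
    with pytest.raises(OptionError, match="svg"):
        render(spec, bad)
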