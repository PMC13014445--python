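"""From parsed documents plus user options to a rendered figure.

The pipeline is deliberately split in two: :func:`build_plot_spec`
produces a :class:`PlotSpec` — a complete, backend-free description of
the figure (panels, styled series, density grids, axes, fonts) — and
:func:`render` hands that description to Matplotlib.  Tests and
interactive callers can inspect or modify the spec without touching any
rendering state, and the CLI and the programmatic API share the same
spec-building path.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from matplotlib.markers import MarkerStyle

from . import density as _density
from . import transform as _transform
from .density import DensityGrid
from .errors import OptionError
from .format_io import DataSet, XvgDocument

__all__ = [
    "COLOR_CYCLE",
    "LINESTYLE_CYCLE",
    "MARKER_CYCLE",
    "PlotOptions",
    "SeriesStyle",
    "PanelSpec",
    "PlotSpec",
    "assign_styles",
    "layout_panels",
    "build_plot_spec",
    "render",
]

#: fixed qualitative 10-color cycle (Matplotlib "tab10" palette)
COLOR_CYCLE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)
LINESTYLE_CYCLE = ("-", "--", "-.", ":")
MARKER_CYCLE = ("o", "s", "^", "D", "v", "P", "X", "*", "<", ">")

_VALID_LINESTYLES = {"-", "--", "-.", ":", "solid", "dashed", "dashdot", "dotted"}

_PANEL_MODES = ("off", "stacked", "top", "side")


@dataclass
class PlotOptions:
    """Every user-tunable knob, shared between the CLI and the API."""

    x_min: Optional[float] = None
    x_max: Optional[float] = None
    y_min: Optional[float] = None
    y_max: Optional[float] = None
    log_y: bool = False
    titles: list[str] = field(default_factory=list)
    legends: list[str] = field(default_factory=list)
    linestyles: list[str] = field(default_factory=list)
    markers: list[str] = field(default_factory=list)
    panels: str = "off"
    equal_axes: bool = False
    square_fig: bool = False
    share_label: bool = False
    stats: bool = False
    histogram: bool = False
    residual: bool = False
    heatmap: bool = False
    contour: bool = False
    gibbs: bool = False
    kde: bool = False
    showdots: bool = False
    bins: int = _density.DEFAULT_BINS
    levels: int = _density.DEFAULT_LEVELS
    temperature: float = _density.DEFAULT_TEMPERATURE
    cmap: str = "viridis"
    tick_font_size: float = 10.0
    label_font_size: float = 12.0
    legend_font_size: float = 10.0
    title_font_size: float = 14.0
    allfontsizes: float = 1.0
    label_placement: str = "best"
    output_path: Optional[str] = None

    def validate(self) -> None:
        if self.heatmap and self.contour:
            raise OptionError("heatmap and contour are mutually exclusive")
        if self.gibbs and not (self.heatmap or self.contour or self.kde):
            raise OptionError(
                "gibbs requires a density plot: add heatmap, contour or kde"
            )
        if self.histogram and (self.heatmap or self.contour or self.kde):
            raise OptionError("histogram cannot be combined with a 2D density plot")
        if self.x_min is not None and self.x_max is not None and not self.x_min < self.x_max:
            raise OptionError(f"x_min ({self.x_min}) must be below x_max ({self.x_max})")
        if self.y_min is not None and self.y_max is not None and not self.y_min < self.y_max:
            raise OptionError(f"y_min ({self.y_min}) must be below y_max ({self.y_max})")
        if self.panels not in _PANEL_MODES:
            raise OptionError(
                f"unknown panels mode {self.panels!r}; choose from {_PANEL_MODES}"
            )
        if self.temperature <= 0:
            raise OptionError(f"temperature must be positive, got {self.temperature}")
        if self.bins < 1:
            raise OptionError(f"bins must be >= 1, got {self.bins}")
        if self.levels < 1:
            raise OptionError(f"levels must be >= 1, got {self.levels}")
        if self.allfontsizes <= 0:
            raise OptionError("allfontsizes scale factor must be positive")
        if self.output_path is not None:
            suffix = Path(self.output_path).suffix.lower()
            if suffix not in (".pdf", ".png"):
                raise OptionError(
                    f"unsupported output extension {suffix!r}: use .pdf or .png"
                )

    @property
    def density_mode(self) -> bool:
        return self.heatmap or self.contour or self.kde


@dataclass(frozen=True)
class SeriesStyle:
    """How one series is drawn; at least one of linestyle/marker is set."""

    color: str
    linestyle: Optional[str] = None
    marker: Optional[str] = None
    marker_size: float = 6.0

    def __post_init__(self):
        if self.linestyle is None and self.marker is None:
            raise ValueError("a series needs a linestyle or a marker to be visible")

    @property
    def triple(self) -> tuple:
        return (self.color, self.linestyle, self.marker)


@dataclass
class PanelSpec:
    """One subplot: styled series or a density grid, plus its axes."""

    label: Optional[str] = None  # "A", "B", ... on multi-panel figures
    series: list[tuple[DataSet, SeriesStyle, Optional[str]]] = field(
        default_factory=list
    )
    grid: Optional[DensityGrid] = None
    grid_style: str = "heatmap"  # or "contour"
    levels: Optional[np.ndarray] = None
    cmap: str = "viridis"
    dots: Optional[tuple[np.ndarray, np.ndarray]] = None
    title: str = ""
    x_label: str = ""
    y_label: str = ""
    x_range: Optional[tuple[float, float]] = None
    y_range: Optional[tuple[float, float]] = None
    show_x_label: bool = True
    show_y_label: bool = True

    def __eq__(self, other) -> bool:
        if not isinstance(other, PanelSpec):
            return NotImplemented
        if self.levels is None or other.levels is None:
            levels_equal = self.levels is None and other.levels is None
        else:
            levels_equal = np.array_equal(self.levels, other.levels)
        if self.dots is None or other.dots is None:
            dots_equal = self.dots is None and other.dots is None
        else:
            dots_equal = np.array_equal(self.dots[0], other.dots[0]) and np.array_equal(
                self.dots[1], other.dots[1]
            )
        return (
            levels_equal
            and dots_equal
            and self.label == other.label
            and self.series == other.series
            and self.grid == other.grid
            and self.grid_style == other.grid_style
            and self.cmap == other.cmap
            and self.title == other.title
            and self.x_label == other.x_label
            and self.y_label == other.y_label
            and self.x_range == other.x_range
            and self.y_range == other.y_range
            and self.show_x_label == other.show_x_label
            and self.show_y_label == other.show_y_label
        )


@dataclass
class PlotSpec:
    """A complete renderable figure description."""

    panels: list[PanelSpec]
    nrows: int = 1
    ncols: int = 1
    log_y: bool = False
    square_fig: bool = False
    share_label: bool = False
    legend_placement: str = "best"
    tick_font_size: float = 10.0
    label_font_size: float = 12.0
    legend_font_size: float = 10.0
    title_font_size: float = 14.0


# ---------------------------------------------------------------------------
# styles and layout


def _normalise_token(token: Optional[str], valid: set | None, kind: str) -> Optional[str]:
    """Map the literal string "None" to a disabled channel; validate the rest."""
    if token is None or token == "None" or token == "none":
        return None
    if kind == "marker":
        if token in MarkerStyle.markers:
            return token
        raise OptionError(f"unknown marker token {token!r}")
    if token in valid:
        return token
    raise OptionError(f"unknown linestyle token {token!r}")


def assign_styles(
    n: int,
    user_linestyles: Sequence[str] = (),
    user_markers: Sequence[str] = (),
) -> list[SeriesStyle]:
    """Build one style per series, filling gaps from the default cycles.

    User-provided linestyle and marker tokens apply positionally;
    positions beyond the user lists fall back to the documented default
    cycles.  Colors always come from the fixed 10-color cycle so series
    within a panel stay distinguishable.  The literal token ``"None"``
    disables that channel; a series whose line is disabled and whose
    marker is unspecified gets a marker from the default cycle so it
    stays visible.
    """
    if n < 1:
        raise OptionError("need at least one series")
    styles = []
    for i in range(n):
        color = COLOR_CYCLE[i % len(COLOR_CYCLE)]
        # shift the linestyle cycle on each colour wrap so style triples
        # stay unique for up to 40 auto-styled series
        auto_ls = LINESTYLE_CYCLE[(i + i // len(COLOR_CYCLE)) % len(LINESTYLE_CYCLE)]
        if i < len(user_linestyles):
            ls = _normalise_token(user_linestyles[i], _VALID_LINESTYLES, "linestyle")
        else:
            ls = auto_ls
        if i < len(user_markers):
            marker = _normalise_token(user_markers[i], None, "marker")
        else:
            marker = None
        if ls is None and marker is None:
            marker = MARKER_CYCLE[i % len(MARKER_CYCLE)]
        marker_size = 3.0 if marker == "." else 6.0
        styles.append(
            SeriesStyle(color=color, linestyle=ls, marker=marker, marker_size=marker_size)
        )
    return styles


@dataclass(frozen=True)
class PanelLayout:
    nrows: int
    ncols: int
    labels: tuple[str, ...]


def layout_panels(n_files: int, mode: str = "off") -> PanelLayout:
    """Grid geometry for ``n_files`` panels.

    ``off`` merges everything into a single axes; ``stacked`` (the
    default once panelling is requested) and its synonym ``top`` stack
    panels in one column; ``side`` puts them in one row.  Panels get
    letter labels A, B, ... when there is more than one.
    """
    if n_files < 1:
        raise OptionError("need at least one input file")
    if mode not in _PANEL_MODES:
        raise OptionError(f"unknown panels mode {mode!r}; choose from {_PANEL_MODES}")
    if mode == "off":
        return PanelLayout(1, 1, ())
    if mode == "side":
        nrows, ncols = 1, n_files
    else:  # stacked / top
        nrows, ncols = n_files, 1
    labels = tuple(string.ascii_uppercase[:n_files]) if n_files > 1 else ()
    return PanelLayout(nrows, ncols, labels)


# ---------------------------------------------------------------------------
# spec building


def _pool_points(docs: Sequence[XvgDocument]) -> tuple[np.ndarray, np.ndarray]:
    xs = np.concatenate([ds.x for doc in docs for ds in doc.datasets])
    ys = np.concatenate([ds.y for doc in docs for ds in doc.datasets])
    return xs, ys


def _density_panel(docs: Sequence[XvgDocument], opts: PlotOptions) -> PanelSpec:
    xs, ys = _pool_points(docs)
    if opts.kde:
        grid = _density.kde_density(xs, ys, grid_size=opts.bins)
    else:
        grid = _density.probability_density_2d(xs, ys, bins=opts.bins)
    if opts.gibbs:
        grid = _density.gibbs_from_density(grid, temperature=opts.temperature)
    panel = PanelSpec(
        grid=grid,
        grid_style="contour" if (opts.contour or opts.kde) else "heatmap",
        cmap=opts.cmap,
        title=docs[0].title,
        x_label=docs[0].x_label,
        y_label=docs[0].y_label,
    )
    if opts.contour or opts.kde:
        panel.levels = _density.contour_levels(grid, opts.levels)
    if opts.showdots:
        panel.dots = (xs, ys)
    return panel


def _series_panel(
    docs: Sequence[XvgDocument],
    opts: PlotOptions,
    styles: Sequence[SeriesStyle],
    legends: Sequence[Optional[str]],
    offset: int,
) -> PanelSpec:
    panel = PanelSpec(
        title=docs[0].title,
        x_label=docs[0].x_label,
        y_label=docs[0].y_label,
    )
    if opts.histogram:
        panel.x_label = docs[0].y_label
        panel.y_label = "Count"
    i = offset
    for doc in docs:
        for ds in doc.datasets:
            label = legends[i]
            if opts.stats:
                stats = _transform.compute_stats(ds)
                label = _transform.stats_legend(label, stats)
            plotted = ds
            if opts.residual:
                plotted = _transform.residual(plotted)
            if opts.histogram:
                plotted = _transform.histogram(plotted, bins=opts.bins)
            panel.series.append((plotted, styles[i], label))
            i += 1
    return panel


def _apply_ranges(panel: PanelSpec, opts: PlotOptions) -> None:
    if opts.equal_axes:
        if panel.series:
            lo = min(min(ds.x.min(), ds.y.min()) for ds, _, _ in panel.series)
            hi = max(max(ds.x.max(), ds.y.max()) for ds, _, _ in panel.series)
        elif panel.grid is not None:
            lo = min(panel.grid.x_edges[0], panel.grid.y_edges[0])
            hi = max(panel.grid.x_edges[-1], panel.grid.y_edges[-1])
        else:  # pragma: no cover - empty panel cannot be built
            lo, hi = 0.0, 1.0
        panel.x_range = (lo, hi)
        panel.y_range = (lo, hi)
    if opts.x_min is not None or opts.x_max is not None:
        panel.x_range = (
            opts.x_min if opts.x_min is not None else _data_min(panel, "x"),
            opts.x_max if opts.x_max is not None else _data_max(panel, "x"),
        )
    if opts.y_min is not None or opts.y_max is not None:
        panel.y_range = (
            opts.y_min if opts.y_min is not None else _data_min(panel, "y"),
            opts.y_max if opts.y_max is not None else _data_max(panel, "y"),
        )


def _data_min(panel: PanelSpec, axis: str) -> float:
    if panel.series:
        return min(getattr(ds, axis).min() for ds, _, _ in panel.series)
    edges = panel.grid.x_edges if axis == "x" else panel.grid.y_edges
    return float(edges[0])


def _data_max(panel: PanelSpec, axis: str) -> float:
    if panel.series:
        return max(getattr(ds, axis).max() for ds, _, _ in panel.series)
    edges = panel.grid.x_edges if axis == "x" else panel.grid.y_edges
    return float(edges[-1])


def build_plot_spec(docs: Sequence[XvgDocument], opts: PlotOptions) -> PlotSpec:
    """Assemble the complete figure description for a set of documents.

    Without panelling every dataset of every file lands in one shared
    panel; with panelling each file becomes its own lettered panel.
    Transforms run in the order residual, then histogram; the stats
    legend suffix is computed on the untransformed pairs.
    """
    if not docs:
        raise OptionError("need at least one document")
    opts.validate()
    layout = layout_panels(len(docs), opts.panels)
    doc_groups = [list(docs)] if opts.panels == "off" else [[d] for d in docs]

    total_sets = sum(len(doc.datasets) for doc in docs)
    legends: list[Optional[str]] = []
    i = 0
    for doc in docs:
        for ds in doc.datasets:
            legends.append(opts.legends[i] if i < len(opts.legends) else ds.legend)
            i += 1

    panels: list[PanelSpec] = []
    if opts.density_mode:
        for group in doc_groups:
            panels.append(_density_panel(group, opts))
    else:
        styles = assign_styles(total_sets, opts.linestyles, opts.markers)
        offset = 0
        for group in doc_groups:
            panels.append(_series_panel(group, opts, styles, legends, offset))
            offset += sum(len(doc.datasets) for doc in group)

    for k, panel in enumerate(panels):
        if k < len(layout.labels):
            panel.label = layout.labels[k]
        if k < len(opts.titles):
            panel.title = opts.titles[k]
        _apply_ranges(panel, opts)

    if opts.share_label and len(panels) > 1:
        for k, panel in enumerate(panels):
            row, col = divmod(k, layout.ncols)
            panel.show_x_label = row == layout.nrows - 1
            panel.show_y_label = col == 0

    s = opts.allfontsizes
    return PlotSpec(
        panels=panels,
        nrows=layout.nrows,
        ncols=layout.ncols,
        log_y=opts.log_y,
        square_fig=opts.square_fig,
        share_label=opts.share_label,
        legend_placement=opts.label_placement,
        tick_font_size=opts.tick_font_size * s,
        label_font_size=opts.label_font_size * s,
        legend_font_size=opts.legend_font_size * s,
        title_font_size=opts.title_font_size * s,
    )


# ---------------------------------------------------------------------------
# rendering


def _draw_panel(ax, panel: PanelSpec, spec: PlotSpec, fig) -> None:
    if panel.grid is not None:
        grid = panel.grid
        values = np.ma.masked_array(grid.values, mask=grid.mask)
        if panel.grid_style == "heatmap":
            mesh = ax.pcolormesh(
                grid.x_edges, grid.y_edges, values.T, cmap=panel.cmap
            )
        else:
            xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
            yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
            mesh = ax.contourf(xc, yc, values.T, levels=panel.levels, cmap=panel.cmap)
        bar = fig.colorbar(mesh, ax=ax)
        bar_label = {
            "probability": "P",
            "kde": "density",
            "energy": "G (kJ/mol)",
        }[grid.kind]
        bar.set_label(bar_label, fontsize=spec.label_font_size)
        bar.ax.tick_params(labelsize=spec.tick_font_size)
        if panel.dots is not None:
            ax.plot(
                panel.dots[0], panel.dots[1], linestyle="", marker=".",
                markersize=2, color="black", alpha=0.4,
            )
    for ds, style, label in panel.series:
        ax.plot(
            ds.x,
            ds.y,
            color=style.color,
            linestyle=style.linestyle if style.linestyle is not None else "",
            marker=style.marker if style.marker is not None else "",
            markersize=style.marker_size,
            label=label,
        )
    if spec.log_y:
        ax.set_yscale("log")
    if panel.x_range is not None:
        ax.set_xlim(panel.x_range)
    if panel.y_range is not None:
        ax.set_ylim(panel.y_range)
    if panel.title:
        ax.set_title(panel.title, fontsize=spec.title_font_size)
    if panel.x_label and panel.show_x_label:
        ax.set_xlabel(panel.x_label, fontsize=spec.label_font_size)
    if panel.y_label and panel.show_y_label:
        ax.set_ylabel(panel.y_label, fontsize=spec.label_font_size)
    ax.tick_params(labelsize=spec.tick_font_size)
    if panel.label:
        ax.text(
            -0.08, 1.04, panel.label, transform=ax.transAxes,
            fontsize=spec.title_font_size, fontweight="bold", va="bottom",
        )
    if any(label for _, _, label in panel.series):
        ax.legend(loc=spec.legend_placement, fontsize=spec.legend_font_size)


def _make_figure(spec: PlotSpec):
    from matplotlib.figure import Figure

    panel_w = 5.0 if not spec.square_fig else 5.0
    panel_h = 5.0 if spec.square_fig else 3.8
    fig = Figure(
        figsize=(panel_w * spec.ncols, panel_h * spec.nrows),
        constrained_layout=True,
    )
    axes = fig.subplots(spec.nrows, spec.ncols, squeeze=False)
    flat = [axes[r][c] for r in range(spec.nrows) for c in range(spec.ncols)]
    for ax, panel in zip(flat, spec.panels):
        _draw_panel(ax, panel, spec, fig)
    for ax in flat[len(spec.panels):]:  # pragma: no cover - grid always exact
        ax.set_visible(False)
    return fig


def render(spec: PlotSpec, opts: PlotOptions) -> Optional[Path]:
    """Render a spec to a file (headless) or to an interactive window.

    With ``opts.output_path`` set the figure is written as PDF or PNG
    without any display; PDF metadata that would vary between runs
    (creation date) is suppressed so repeated renders of the same spec
    are byte-identical.  Without an output path the figure opens in an
    interactive Matplotlib window.
    """
    if opts.output_path is None:
        import matplotlib.pyplot as plt  # pragma: no cover - needs a display

        fig = _make_figure(spec)  # pragma: no cover
        dummy = plt.figure()  # pragma: no cover
        new_manager = dummy.canvas.manager  # pragma: no cover
        new_manager.canvas.figure = fig  # pragma: no cover
        fig.set_canvas(new_manager.canvas)  # pragma: no cover
        plt.show()  # pragma: no cover
        return None  # pragma: no cover

    out = Path(opts.output_path)
    suffix = out.suffix.lower()
    if suffix not in (".pdf", ".png"):
        raise OptionError(f"unsupported output extension {suffix!r}: use .pdf or .png")
    fig = _make_figure(spec)
    if suffix == ".pdf":
        fig.savefig(out, format="pdf", metadata={"CreationDate": None})
    else:
        fig.savefig(out, format="png")
    return out
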