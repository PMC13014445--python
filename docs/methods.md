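# Methods

## Document model and the xvg dialect

All readers produce the same in-memory model: an `XvgDocument` holding
a title, two axis labels and an ordered list of `DataSet` objects (one
x/y pair plus an optional legend). The xvg reader interprets exactly
the metadata subset GROMACS emits — `@ title`, `@ xaxis label`,
`@ yaxis label`, `@ s<N> legend` — and ignores every other `@` record
(`TYPE`, `view`, `world`, `legend on`, ...), so a document parses
identically with or without them. Quoted values are taken between the
first and last `"` on the line with embedded quotes kept verbatim; this
is the simplest rule consistent with GROMACS output and makes the
writer/reader pair an exact round trip. Within a data block column 0 is
x and every further column one dataset; a `&` line closes a block, and
`s<N>` legends bind by N to the N-th dataset in global reading order
(the dialect itself does not say whether `&` resets legend numbering;
we bind globally because that matches GROMACS emission order). Rows may
carry trailing `#` comments; blank lines are ignored; a trailing `&`
produces no empty dataset. Non-finite tokens (`nan`/`inf`) are parse
errors because every downstream transform assumes finite data.

Delimited files are sniffed comma → semicolon → whitespace (first
delimiter yielding ≥ 2 columns on the first row). A non-numeric first
row is a header: column 0 becomes the x-axis label, the rest become
legends, and a leading `#` (OpenMM's CSV reporter dialect) is stripped.

The writer emits a single multi-column block when all datasets share
one x vector and `&`-separated blocks otherwise, with floats printed at
`repr` precision so parse(write(d)) == d exactly.

## Statistics

For paired reference x and prediction y (n ≥ 2):

- RMSD = √( (1/n) Σᵢ (yᵢ − xᵢ)² ), in the units of y.
- R² = squared Pearson correlation of x and y. The alternative reading
  — the coefficient of determination about the identity line,
  1 − SSres/SStot — was considered and rejected: squared correlation is
  the quantity conventionally quoted on correlation plots, is bounded
  in [0, 1], and is invariant under affine maps of y, which the test
  suite asserts. When either coordinate has zero variance the
  correlation is undefined and R² is reported as NaN ("undefined" in
  legends); the RMSD is still returned.

Legend formatting is `<legend> (RMSD = <3 significant digits>,
R² = <2 decimals>)`. Statistics are computed on the untransformed
pairs, before any residual or histogram transform, because they are
meaningful only for (reference, prediction) data.

## Density surfaces and Boltzmann inversion

`probability_density_2d` bins points onto a square grid spanning
[min, max] of each coordinate (rightmost edges closed). Values are bin
probability **mass** counts/N, not per-area density, so Σ P = 1 holds
and is testable; the Gibbs formula uses the ratio P/P₀, so the
distinction cancels there. Zero-count bins are masked as undefined —
ln 0 does not exist, and capping the energy would invent data; renderers
leave masked bins blank.

`gibbs_from_density` applies G = −k_B T ln(P/P₀) per unmasked bin with
P₀ = max P, giving the most populated bin G = 0 exactly (the −0.0 the
logarithm produces is normalised to +0.0). k_B is 0.008314462618
kJ mol⁻¹ K⁻¹ — the molar-energy convention used by simulation engines —
and T defaults to 298.15 K. The transform is monotone (higher P never
yields higher G) and linear in T, both asserted as properties. It is
also accepted on KDE grids: the formula is the same and the per-area
normalisation cancels in P/P₀.

`kde_density` wraps a Gaussian kernel estimator (Scott's-rule bandwidth
by default; a scalar override is accepted). The evaluation grid spans
the data range padded by one bandwidth per axis so the tails are
captured and the Riemann sum of the grid approximates 1 for
well-contained samples (asserted within 5 %). Fewer than 3 points or a
singular (collinear) sample covariance raises an error that points the
user back to binning.

`contour_levels` returns n evenly spaced values strictly inside
(min, max) of the unmasked values — `linspace(min, max, n+2)[1:-1]` —
so no contour coincides with the degenerate extremes; a constant grid
returns its single value with a warning.

Defaults everywhere: 50 bins per axis, 15 contour levels, 298.15 K.
The 1D histogram reuses the 50-bin default for consistency.

## Styling and layout

Colors come from a fixed 10-color qualitative cycle (the Matplotlib
tab10 palette), linestyles from (`-`, `--`, `-.`, `:`), markers from a
10-token cycle. User linestyle/marker lists apply positionally across
all datasets in reading order; positions beyond the lists are filled
from the default cycles, and the literal token `None` disables a
channel. A series whose line is disabled and whose marker was not given
receives a marker from the cycle so it cannot become invisible. On each
wrap of the color cycle the auto linestyle cycle is shifted, keeping
the full (color, linestyle, marker) triple unique for up to 40
auto-styled series; beyond that, explicit styles are required.

Panel modes: `off` merges every dataset of every file into one panel;
`stacked` and `top` are synonyms for an n×1 column (the tool's default
stacking once panelling is requested); `side` is a 1×n row. With more
than one panel, labels A, B, C, ... are attached outside the top-left
corner. `--equalaxes` sets both axis ranges of each panel to the
min/max of the union of its x and y data (useful for correlation
plots); `--squarefig` instead makes each panel physically square by
shaping the figure. `--sharelabel` keeps axis labels only on the outer
panels (bottom row for x, left column for y). `--allfontsizes s`
multiplies every font size in the spec by s. Explicit `--xmin/--xmax/
--ymin/--ymax` are applied to the axis range exactly as given.

## CLI design

Every flag has a short single-hyphen and a long double-hyphen spelling
and is matched case-sensitively in lowercase; an uppercase variant of a
known flag gets a dedicated "flags are lowercase" diagnostic, an
unknown flag a near-match hint. Multi-valued flags consume tokens until
the next recognised flag, which is what lets `-`, `--` and `None`
appear as linestyle values and negative numbers as axis limits. One
refinement: an unknown token starting with `--` (other than the bare
`--` linestyle) terminates a value list and raises the unknown-flag
error instead of being silently taken as a file name. The parser is
hand-written because these rules (lowercase-only matching, flag-like
value tokens) fight the prefix handling of argparse/click. Headless
batch mode is triggered precisely by the presence of `-o/--output`;
without it the figure opens interactively. The API function
`xvgplot.plot` shares the spec-building code path with the CLI, so
mirrored invocations produce equal `PlotSpec` objects — asserted over a
23-entry invocation matrix.

Rendering determinism: PDF output suppresses the embedded creation
date, so rendering the same spec twice gives byte-identical files (PNG
output is already timestamp-free).

## Synthetic data generators

The `fixtures` module emulates the *shapes* of simulation analysis
output so the whole pipeline is testable without running an MD engine:

- `make_timeseries`: a saturating curve a(1 − e^(−t/τ)) + noise
  (plateau 0.25 nm, τ 1.5 ns over 10 ns) — the shape of a structural
  RMSD trace approaching equilibrium.
- `make_multiseries`: several observables on one time axis (baselines
  298, 348, ... with Gaussian noise), writable either as one
  multi-column block or as `&`-separated blocks carrying identical data.
- `make_scatter_correlation`: unit-variance Gaussian references with
  predictions y = x + ε, Var(ε) calibrated so the population squared
  correlation equals the requested `true_r2` (σ = √(1/r² − 1)); the
  recipe's `noise_sd` multiplies that calibrated level, so RMSD grows
  linearly with it while r² recovery is exact at the default 1.0.
- `make_projection_2d`: a mixture of 2D Gaussian modes with weights
  halving mode to mode, centers on a circle of radius 3 — a stand-in
  for a trajectory projected onto two principal components with one
  dominant basin.

All randomness flows from the per-recipe seed through one
`numpy.random.Generator`; no global state is touched, so identical
recipes give byte-identical files.

What these generators do **not** emulate: autocorrelated noise, drift,
non-Gaussian basins, or the metadata quirks of specific GROMACS tools.
Passing tests therefore demonstrate the correctness of parsing,
transforms and the density/energy math on well-behaved inputs, not
robustness to every real-world trajectory.

## Problem sizes

Property suites run on modest sizes chosen to make the asserted
identities sharp rather than statistical: 200 randomized round-trip
documents, 100 random stats pairs checked to 1e−12, densities of
~1000–6000 points on 7–50-bin grids. Parameter-recovery checks use
n = 10⁴ scatter points (±0.05 on r²) and 5000–6000-point two-mode
mixtures. The acceptance script uses 1000 points on the default 50×50
grid.

## Known limitations

- Only the GROMACS-emitted metadata subset of the Grace format is
  understood; full Grace project files, fonts and colors are out of
  scope, as are EPS/SVG output and 3D surfaces.
- Energy landscapes carry no error estimate and no reweighting for
  biased sampling.
- Auto-style uniqueness is guaranteed for ≤ 40 series.
- KDE output is a per-area density while binned output is per-bin
  mass; the two kinds are not interchangeable except through the Gibbs
  transform, where the normalisation cancels.
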