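"""Reading and writing Grace-dialect xvg files and delimited text tables.

The xvg dialect is the plain-text plot format emitted by the GROMACS
analysis tools: ``#`` starts a comment line, ``@`` starts a metadata
record, data rows are whitespace-separated numeric columns (column 0 is
x, every further column one dataset), and a line starting with ``&``
closes the current block so several datasets can follow one another.
Only the metadata subset that GROMACS actually writes is interpreted:
the plot title, the two axis labels, and per-set legends.  Everything
else (``TYPE``, ``view``, ``world``, ...) is ignored without complaint.

Delimited files (CSV from OpenMM energy reporters, ``.dat``/``.txt``
tables) are mapped onto the same document model so every downstream
operation is format-agnostic.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import EmptyDocumentError, FormatError, ParseError

__all__ = [
    "DataSet",
    "XvgDocument",
    "read_xvg",
    "read_delimited",
    "read_any",
    "write_xvg",
    "describe",
]


@dataclass
class DataSet:
    """One x/y series with an optional legend label."""

    x: np.ndarray
    y: np.ndarray
    legend: Optional[str] = None
    set_index: int = 0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) < 1:
            raise ValueError("a dataset needs at least one point")

    def __len__(self) -> int:
        return len(self.x)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DataSet):
            return NotImplemented
        return (
            self.legend == other.legend
            and self.set_index == other.set_index
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )


@dataclass
class XvgDocument:
    """A parsed file: figure-level metadata plus ordered datasets."""

    title: str = ""
    x_label: str = ""
    y_label: str = ""
    datasets: list[DataSet] = field(default_factory=list)
    source_path: str = ""
    dialect: str = "xvg"  # or "delimited"

    def __eq__(self, other) -> bool:
        # source_path and dialect are provenance, not content
        if not isinstance(other, XvgDocument):
            return NotImplemented
        return (
            self.title == other.title
            and self.x_label == other.x_label
            and self.y_label == other.y_label
            and self.datasets == other.datasets
        )

    def __len__(self) -> int:
        return len(self.datasets)


# ---------------------------------------------------------------------------
# xvg reading

_METADATA_RE = re.compile(
    r"""^@\s*(?:
        (?P<title>title)\s |
        (?P<xaxis>xaxis\s+label)\s |
        (?P<yaxis>yaxis\s+label)\s |
        s(?P<setnum>\d+)\s+legend\s
    )""",
    re.VERBOSE,
)


def _quoted_value(line: str) -> Optional[str]:
    """Text between the first and last double quote, embedded quotes kept."""
    first = line.find('"')
    last = line.rfind('"')
    if first < 0 or last <= first:
        return None
    return line[first + 1 : last]


def _strip_trailing_comment(line: str) -> str:
    hash_pos = line.find("#")
    return line if hash_pos < 0 else line[:hash_pos]


def _parse_row(tokens: Sequence[str], path, lineno: int) -> list[float]:
    values = []
    for tok in tokens:
        try:
            v = float(tok)
        except ValueError:
            raise ParseError(f"non-numeric token {tok!r} in data line", path, lineno)
        if not math.isfinite(v):
            raise ParseError(f"non-finite value {tok!r} in data line", path, lineno)
        values.append(v)
    return values


def read_xvg(path) -> XvgDocument:
    """Parse a Grace-dialect xvg file.

    Raises :class:`ParseError` on non-numeric tokens or ragged rows and
    :class:`EmptyDocumentError` when the file holds no data rows.
    """
    path = Path(path)
    doc = XvgDocument(source_path=str(path), dialect="xvg")
    legends: dict[int, str] = {}
    blocks: list[list[list[float]]] = []
    current: list[list[float]] = []

    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            stripped = raw.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                continue
            if stripped.startswith("@"):
                match = _METADATA_RE.match(stripped)
                if match is None:
                    continue  # unsupported metadata record
                value = _quoted_value(stripped)
                if value is None:
                    continue
                if match.group("title"):
                    doc.title = value
                elif match.group("xaxis"):
                    doc.x_label = value
                elif match.group("yaxis"):
                    doc.y_label = value
                else:
                    legends[int(match.group("setnum"))] = value
                continue
            if stripped.startswith("&"):
                if current:
                    blocks.append(current)
                    current = []
                continue
            tokens = _strip_trailing_comment(stripped).split()
            if not tokens:
                continue
            row = _parse_row(tokens, path, lineno)
            if len(row) < 2:
                raise ParseError(
                    "data line has a single column; need x plus at least one y",
                    path,
                    lineno,
                )
            if current and len(row) != len(current[0]):
                raise ParseError(
                    f"ragged row: {len(row)} columns where block started with "
                    f"{len(current[0])}",
                    path,
                    lineno,
                )
            current.append(row)
    if current:
        blocks.append(current)
    if not blocks:
        raise EmptyDocumentError("file contains no data rows", path)

    index = 0
    for block in blocks:
        table = np.asarray(block, dtype=float)
        for col in range(1, table.shape[1]):
            doc.datasets.append(
                DataSet(x=table[:, 0], y=table[:, col], set_index=index)
            )
            index += 1
    for n, legend in legends.items():
        if 0 <= n < len(doc.datasets):
            doc.datasets[n].legend = legend
        # out-of-range legend indices are ignored (surfaced by describe())
    return doc


# ---------------------------------------------------------------------------
# delimited reading


def _sniff_delimiter(first_data_line: str) -> Optional[str]:
    """First of comma, semicolon, whitespace giving >= 2 columns; else None."""
    for delim in (",", ";"):
        if len([t for t in first_data_line.split(delim) if t.strip()]) >= 2:
            return delim
    if len(first_data_line.split()) >= 2:
        return None  # whitespace: use str.split()
    raise FormatError("could not determine a delimiter yielding two columns")


def _split(line: str, delimiter: Optional[str]) -> list[str]:
    if delimiter is None:
        return line.split()
    return [t.strip() for t in line.split(delimiter)]


def _is_numeric_row(tokens: Sequence[str]) -> bool:
    try:
        for tok in tokens:
            if not math.isfinite(float(tok)):
                return False
    except ValueError:
        return False
    return True


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == '"' and token[-1] == '"':
        return token[1:-1]
    return token


def read_delimited(path, delimiter: Optional[str] = None) -> XvgDocument:
    """Parse a comma-, semicolon- or whitespace-delimited table.

    A non-numeric first row is taken as a header: column 0 names the x
    axis and the remaining columns become dataset legends.  A leading
    ``#`` on the header row (OpenMM CSV dialect) is stripped.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as handle:
        lines = [
            (lineno, line.strip())
            for lineno, line in enumerate(handle, start=1)
            if line.strip()
        ]
    if not lines:
        raise EmptyDocumentError("file contains no data rows", path)

    if delimiter is None:
        try:
            delimiter = _sniff_delimiter(lines[0][1])
        except FormatError as exc:
            raise FormatError(str(exc), path, lines[0][0]) from None

    doc = XvgDocument(source_path=str(path), dialect="delimited")
    rows: list[list[float]] = []
    start = 0
    header_tokens = _split(lines[0][1].lstrip("#"), delimiter)
    if not _is_numeric_row(header_tokens):
        names = [_unquote(t) for t in header_tokens]
        doc.x_label = names[0]
        header_legends = names[1:]
        start = 1
    else:
        header_legends = []

    for lineno, line in lines[start:]:
        tokens = [t for t in _split(line, delimiter) if t]
        row = _parse_row(tokens, path, lineno)
        if len(row) < 2:
            raise FormatError("row has a single column", path, lineno)
        if rows and len(row) != len(rows[0]):
            raise ParseError(
                f"ragged row: {len(row)} columns where table started with "
                f"{len(rows[0])}",
                path,
                lineno,
            )
        rows.append(row)
    if not rows:
        raise EmptyDocumentError("file contains no data rows", path)

    table = np.asarray(rows, dtype=float)
    for col in range(1, table.shape[1]):
        legend = header_legends[col - 1] if col - 1 < len(header_legends) else None
        doc.datasets.append(
            DataSet(x=table[:, 0], y=table[:, col], legend=legend, set_index=col - 1)
        )
    return doc


def read_any(path, delimiter: Optional[str] = None) -> XvgDocument:
    """Dispatch on extension; unknown extensions try xvg then delimited."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xvg":
        return read_xvg(path)
    if suffix in (".csv", ".dat", ".txt"):
        return read_delimited(path, delimiter)
    try:
        return read_xvg(path)
    except ParseError as xvg_err:
        try:
            return read_delimited(path, delimiter)
        except ParseError as delim_err:
            raise FormatError(
                f"not parseable as xvg ({xvg_err}) nor as delimited text "
                f"({delim_err})",
                path,
            ) from None


# ---------------------------------------------------------------------------
# writing


def _shared_x(doc: XvgDocument) -> bool:
    first = doc.datasets[0].x
    return all(
        len(ds.x) == len(first) and np.array_equal(ds.x, first)
        for ds in doc.datasets[1:]
    )


def write_xvg(doc: XvgDocument, path) -> None:
    """Write a document back to the xvg dialect.

    Documents whose datasets share one x vector are emitted as a single
    multi-column block; otherwise each dataset gets its own
    ``&``-terminated block.  ``read_xvg(write_xvg(d))`` reproduces the
    title, labels, legends and values exactly (floats are written with
    ``repr`` precision).
    """
    if not doc.datasets:
        raise ValueError("cannot write a document without datasets")
    buf = io.StringIO()
    if doc.title:
        buf.write(f'@    title "{doc.title}"\n')
    if doc.x_label:
        buf.write(f'@    xaxis  label "{doc.x_label}"\n')
    if doc.y_label:
        buf.write(f'@    yaxis  label "{doc.y_label}"\n')
    for i, ds in enumerate(doc.datasets):
        if ds.legend is not None:
            buf.write(f'@ s{i} legend "{ds.legend}"\n')
    if _shared_x(doc):
        columns = [doc.datasets[0].x] + [ds.y for ds in doc.datasets]
        for row in zip(*columns):
            buf.write(" ".join(repr(float(v)) for v in row) + "\n")
    else:
        for block_no, ds in enumerate(doc.datasets):
            if block_no:
                buf.write("&\n")
            for xv, yv in zip(ds.x, ds.y):
                buf.write(f"{float(xv)!r} {float(yv)!r}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# introspection


def describe(doc: XvgDocument) -> str:
    """Human-readable report of a document, used by the ``-debug`` flag."""
    lines = [
        f"file: {doc.source_path or '<in memory>'} (dialect: {doc.dialect})",
        f"title: {doc.title!r}",
        f"x-axis label: {doc.x_label!r}",
        f"y-axis label: {doc.y_label!r}",
        f"datasets: {len(doc.datasets)}",
    ]
    for ds in doc.datasets:
        label = ds.legend if ds.legend is not None else f"set {ds.set_index}"
        lines.append(
            f"  [{ds.set_index}] {label}: {len(ds)} points, "
            f"x in [{ds.x.min():g}, {ds.x.max():g}], "
            f"y in [{ds.y.min():g}, {ds.y.max():g}]"
        )
    return "\n".join(lines)
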