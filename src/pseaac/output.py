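"""Streaming descriptor-matrix writers: CSV, TSV and svmlight.

Writers consume an iterator of ``(accession, values)`` rows so batch runs
never hold more than one descriptor vector in memory.  Floats are printed
at 12 significant digits (``%.12g``), which round-trips bit-stably for
the magnitudes these descriptors produce.
"""

from __future__ import annotations

from typing import IO, Iterable, Sequence

import numpy as np

from .errors import ArgumentError

FORMATS = ("csv", "tsv", "svmlight")


def _fmt(v: float) -> str:
    return f"{v:.12g}"


class MatrixWriter:
    """Incremental writer for one output file."""

    def __init__(self, handle: IO[str], feature_names: Sequence[str], fmt: str):
        if fmt not in FORMATS:
            raise ArgumentError(f"unknown output format {fmt!r}; expected {FORMATS}")
        self.handle = handle
        self.fmt = fmt
        self.feature_names = list(feature_names)
        self.rows_written = 0
        if fmt in ("csv", "tsv"):
            sep = "," if fmt == "csv" else "\t"
            self._sep = sep
            handle.write(sep.join(["id"] + self.feature_names) + "\n")

    def write_row(self, accession: str, values: np.ndarray) -> None:
        if self.fmt in ("csv", "tsv"):
            cells = [accession] + [_fmt(v) for v in values]
            self.handle.write(self._sep.join(cells) + "\n")
        else:  # svmlight: 1-based indices, zeros omitted, accession as comment
            nz = np.flatnonzero(values)
            feats = " ".join(f"{j + 1}:{_fmt(values[j])}" for j in nz)
            self.handle.write(f"0 {feats} # {accession}\n".replace("  #", " #"))
        self.rows_written += 1


def write_output(
    rows: Iterable[tuple[str, np.ndarray]],
    feature_names: Sequence[str],
    handle: IO[str],
    fmt: str = "csv",
) -> int:
    """Stream ``rows`` to ``handle``; returns the number of rows written."""
    writer = MatrixWriter(handle, feature_names, fmt)
    for accession, values in rows:
        writer.write_row(accession, values)
    return writer.rows_written


def read_matrix_csv(source, sep: str = ","):
    """Read back a csv/tsv written by :func:`write_output`.

    Returns ``(ids, feature_names, values)``; intended for round-trip
    checks and small downstream analyses, not for streaming.
    """
    from .io import _open_text

    handle, owns = _open_text(source)
    try:
        header = handle.readline().rstrip("\n").split(sep)
        ids: list[str] = []
        rows: list[list[float]] = []
        for line in handle:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(sep)
            ids.append(cells[0])
            rows.append([float(v) for v in cells[1:]])
    finally:
        if owns:
            handle.close()
    values = np.array(rows) if rows else np.zeros((0, len(header) - 1))
    return ids, header[1:], values
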