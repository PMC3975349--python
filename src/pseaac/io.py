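"""FASTA input/output and physicochemical property tables.

Sequences flow through the package as :class:`ProteinRecord` objects read
from FASTA; per-amino-acid numeric properties (hydrophobicity and friends)
are held in a :class:`PropertyTable` loaded from either an AAindex1 flat
file or a simple TSV.  Both loaders re-map values into the canonical
alphabetical residue order (see :mod:`pseaac.alphabet`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .alphabet import AA_INDEX, AAINDEX_TO_CANONICAL, AMBIGUITY_MAP, AMINO_ACIDS
from .errors import (
    ArgumentError,
    DegeneratePropertyError,
    FastaParseError,
    FormatError,
    SequenceValidationError,
)

logger = logging.getLogger(__name__)

#: Accepted ambiguity policies for :func:`read_fasta`.
AMBIGUOUS_POLICIES = ("error", "skip_record", "map_to_nearest")


@dataclass(frozen=True)
class ProteinRecord:
    """One validated protein sequence.

    ``seq`` is uppercase over the 20-letter canonical alphabet; validation
    happens in :func:`read_fasta` (or :meth:`validated` for records built
    in code).
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ArgumentError("ProteinRecord requires a non-empty id")
        if len(self.seq) < 1:
            raise ArgumentError(f"record {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    def validated(self) -> "ProteinRecord":
        """Return self after checking the canonical-alphabet invariant."""
        for c in self.seq:
            if c not in AA_INDEX:
                raise SequenceValidationError(self.id, c)
        return self


def _open_text(source) -> tuple[IO[str], bool]:
    """Accept a path, str of FASTA text is NOT guessed: str/Path = filesystem
    path; file-like objects are used as-is.  Returns (handle, owns_handle)."""
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_fasta(
    source,
    ambiguous_policy: str = "error",
) -> Iterator[ProteinRecord]:
    """Stream :class:`ProteinRecord` objects from FASTA text.

    Parameters
    ----------
    source:
        Path or open text handle containing FASTA.
    ambiguous_policy:
        ``error`` (default): any non-canonical letter aborts with
        :class:`SequenceValidationError`.
        ``skip_record``: offending records are dropped with a logged warning.
        ``map_to_nearest``: B→D, Z→E, U→C, O→K, J→L; a record containing
        ``X`` (fully unknown residue) is still skipped with a warning.

    Memory use is one record at a time regardless of file size, so whole
    databases can be converted in a single pass.
    """
    if ambiguous_policy not in AMBIGUOUS_POLICIES:
        raise ArgumentError(
            f"unknown ambiguity policy {ambiguous_policy!r}; "
            f"expected one of {AMBIGUOUS_POLICIES}"
        )
    handle, owns = _open_text(source)
    try:
        # SimpleFastaParser silently discards text before the first '>':
        # detect that malformation ourselves, with a line number.
        first_chunk = handle.readline()
        line_no = 1
        while first_chunk and not first_chunk.strip():
            first_chunk = handle.readline()
            line_no += 1
        if first_chunk and not first_chunk.startswith(">"):
            raise FastaParseError(
                "expected FASTA header starting with '>'", line=line_no
            )
        # re-join the consumed header line with the rest of the handle
        chained = _chain_handles(first_chunk, handle) if first_chunk else handle
        for title, raw_seq in SimpleFastaParser(chained):
            rec = _build_record(title, raw_seq, ambiguous_policy)
            if rec is not None:
                yield rec
    finally:
        if owns:
            handle.close()


def _chain_handles(prefix: str, rest: IO[str]) -> Iterator[str]:
    yield prefix
    yield from rest


def _build_record(
    title: str, raw_seq: str, policy: str
) -> ProteinRecord | None:
    parts = title.split(None, 1)
    if not parts:
        raise FastaParseError("empty FASTA header ('>' with no identifier)")
    rec_id = parts[0]
    desc = parts[1] if len(parts) > 1 else ""
    seq = raw_seq.upper().replace(" ", "")
    cleaned = []
    for c in seq:
        if c in AA_INDEX:
            cleaned.append(c)
            continue
        if policy == "error":
            raise SequenceValidationError(rec_id, c)
        if policy == "skip_record":
            logger.warning(
                "skipping record %r: non-canonical residue %r", rec_id, c
            )
            return None
        # map_to_nearest
        if c in AMBIGUITY_MAP:
            cleaned.append(AMBIGUITY_MAP[c])
        else:
            logger.warning(
                "skipping record %r: residue %r has no canonical mapping",
                rec_id,
                c,
            )
            return None
    if not cleaned:
        logger.warning("skipping record %r: empty sequence", rec_id)
        return None
    return ProteinRecord(id=rec_id, seq="".join(cleaned), description=desc)


def write_fasta(records: Iterable[ProteinRecord], handle, width: int = 60) -> int:
    """Write records as wrapped FASTA; returns the number written."""
    n = 0
    for rec in records:
        header = f">{rec.id}"
        if rec.description:
            header += f" {rec.description}"
        handle.write(header + "\n")
        for i in range(0, rec.length, width):
            handle.write(rec.seq[i : i + width] + "\n")
        n += 1
    return n


# ---------------------------------------------------------------------------
# property tables
# ---------------------------------------------------------------------------


def normalize_property(raw) -> np.ndarray:
    """Standardize 20 per-residue values to zero mean and unit SD.

    The SD uses divisor 20 (population convention), the standard conversion
    applied to amino-acid indices before they enter sequence-correlation
    factors.  Constant properties cannot be standardized and raise
    :class:`DegeneratePropertyError`.
    """
    vals = np.asarray(raw, dtype=np.float64)
    if vals.shape != (20,):
        raise ArgumentError(f"expected 20 values, got shape {vals.shape}")
    if not np.all(np.isfinite(vals)):
        raise ArgumentError("property contains non-finite values")
    mean = vals.mean()
    sd = vals.std()  # ddof=0 -> divisor 20
    if np.all(vals == vals[0]) or sd == 0.0 or not math.isfinite(sd):
        raise DegeneratePropertyError(
            "property is constant over the 20 amino acids; cannot standardize"
        )
    return (vals - mean) / sd


@dataclass
class PropertyTable:
    """Ordered map property-accession -> 20 raw values (canonical order).

    ``normalized(acc)`` returns the zero-mean, unit-SD (divisor 20) variant
    used by the correlation-based descriptor families; results are cached.
    ``dropped`` counts entries discarded at load time for missing values.
    """

    entries: dict[str, np.ndarray] = field(default_factory=dict)
    dropped: int = 0
    _norm_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, acc: str) -> bool:
        return acc in self.entries

    def __iter__(self):
        return iter(self.entries)

    def ids(self) -> list[str]:
        return list(self.entries)

    def raw(self, acc: str) -> np.ndarray:
        try:
            return self.entries[acc]
        except KeyError:
            raise KeyError(
                f"property {acc!r} not in table (has {len(self)} entries)"
            ) from None

    def normalized(self, acc: str) -> np.ndarray:
        if acc not in self._norm_cache:
            self._norm_cache[acc] = normalize_property(self.raw(acc))
        return self._norm_cache[acc]

    def add(self, acc: str, values) -> None:
        vals = np.asarray(values, dtype=np.float64)
        if vals.shape != (20,):
            raise FormatError(
                f"property {acc!r}: expected 20 values, got {vals.shape[0]}"
            )
        if not np.all(np.isfinite(vals)):
            raise FormatError(f"property {acc!r}: non-finite value")
        self.entries[acc] = vals

    def subset(self, accs: Iterable[str]) -> "PropertyTable":
        sub = PropertyTable()
        for acc in accs:
            sub.add(acc, self.raw(acc))
        return sub


def load_property_table(source, format: str = "tsv") -> PropertyTable:
    """Load a property table from ``aaindex1`` or ``tsv`` format.

    TSV layout: header ``property<TAB>A<TAB>C...<TAB>Y`` then one row per
    property with 20 numeric columns in canonical alphabetical order.

    AAindex1 flat files carry each property as an ``H <accession>`` line
    and an ``I`` line followed by two rows of ten values in the historical
    ``ARNDCQEGHILKMFPSTWYV`` order; values are re-mapped to canonical order
    on load.  Entries with any ``NA`` value are dropped and counted in
    ``table.dropped`` with one summary log line.
    """
    handle, owns = _open_text(source)
    try:
        if format == "tsv":
            return _load_tsv(handle)
        if format == "aaindex1":
            return _load_aaindex1(handle)
        raise ArgumentError(f"unknown property-table format {format!r}")
    finally:
        if owns:
            handle.close()


def _load_tsv(handle) -> PropertyTable:
    table = PropertyTable()
    header = handle.readline()
    if not header:
        raise FormatError("empty property TSV", line=1)
    cols = header.rstrip("\n").split("\t")
    if len(cols) != 21 or "".join(cols[1:]) != AMINO_ACIDS:
        raise FormatError(
            "property TSV header must be 'property' followed by the 20 "
            f"residues in order {AMINO_ACIDS}",
            line=1,
        )
    for line_no, line in enumerate(handle, start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        acc = fields[0]
        if len(fields) != 21:
            raise FormatError(
                f"property {acc!r}: expected 20 values, got {len(fields) - 1}",
                line=line_no,
            )
        if any(v.strip() in ("NA", "") for v in fields[1:]):
            table.dropped += 1
            continue
        try:
            vals = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise FormatError(
                f"property {acc!r}: non-numeric value ({exc})", line=line_no
            ) from None
        table.add(acc, vals)
    if table.dropped:
        logger.info("dropped %d properties with NA values", table.dropped)
    return table


def _load_aaindex1(handle) -> PropertyTable:
    table = PropertyTable()
    acc: str | None = None
    collecting = False
    values: list[str] = []
    for line_no, line in enumerate(handle, start=1):
        if line.startswith("H "):
            acc = line[2:].strip()
            collecting = False
            values = []
        elif line.startswith("I "):
            collecting = True
            values = []
        elif line.startswith("//"):
            if acc is not None and collecting:
                _finish_aaindex_entry(table, acc, values, line_no)
            acc, collecting, values = None, False, []
        elif collecting and (line.startswith(" ") or line.startswith("\t")):
            values.extend(line.split())
        elif collecting:
            # any other record line (C, R, ...) ends the I block
            collecting = False
            if acc is not None:
                _finish_aaindex_entry(table, acc, values, line_no)
                acc = None
    if acc is not None and collecting:
        _finish_aaindex_entry(table, acc, values, line_no)
    if table.dropped:
        logger.info("dropped %d properties with NA values", table.dropped)
    return table


def _finish_aaindex_entry(
    table: PropertyTable, acc: str, raw: list[str], line_no: int
) -> None:
    if any(v == "NA" for v in raw):
        table.dropped += 1
        return
    if len(raw) != 20:
        raise FormatError(
            f"AAindex entry {acc!r}: expected 20 values, got {len(raw)}",
            line=line_no,
        )
    try:
        vals = np.array([float(v) for v in raw], dtype=np.float64)
    except ValueError:
        raise FormatError(
            f"AAindex entry {acc!r}: non-numeric value", line=line_no
        ) from None
    table.add(acc, vals[list(AAINDEX_TO_CANONICAL)])
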