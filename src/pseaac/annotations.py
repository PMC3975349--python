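"""Binary annotation modes: gene-ontology and functional-domain vectors.

Both modes share one mechanism: a term universe (GO accessions, domain
identifiers, or any other descriptive label set) plus per-protein term
assignments, vectorized into {0,1} presence vectors whose column order is
the lexicographically sorted universe.  Proteins absent from the map get
an all-zero row (with a logged warning) so descriptor matrices stay
aligned with FASTA record order.

The on-disk contract is a TSV ``accession<TAB>term1;term2;...`` with an
optional universe file (one term per line).  For large universes a
compact binary cache (magic ``PSBEM1``: versioned header, term list,
bitset rows) gives fast reload; it is a cache, never the source of truth.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError
from .io import _open_text
from .vector import DescriptorVector

logger = logging.getLogger(__name__)

_BEM_MAGIC = b"PSBEM1"


@dataclass
class AnnotationMap:
    """Ordered term universe + accession -> term-set assignments."""

    universe: tuple[str, ...]
    assignments: dict[str, frozenset[str]]
    #: terms seen in assignments but missing from an explicit universe
    unknown_terms: int = 0
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if len(set(self.universe)) != len(self.universe):
            raise FormatError("term universe contains duplicates")
        self._index = {t: j for j, t in enumerate(self.universe)}

    @property
    def n_terms(self) -> int:
        return len(self.universe)

    def binary_vector(self, rec_id: str, mode_name: str = "go") -> DescriptorVector:
        """{0,1} presence vector over the universe for one accession."""
        values = np.zeros(self.n_terms)
        terms = self.assignments.get(rec_id)
        if terms is None:
            logger.warning(
                "accession %r has no annotations; emitting all-zero vector",
                rec_id,
            )
        else:
            for t in terms:
                j = self._index.get(t)
                if j is not None:
                    values[j] = 1.0
        names = tuple(f"{mode_name.upper()}_{t}" for t in self.universe)
        return DescriptorVector(mode_name, names, values)


def load_annotation_map(source, universe_source=None) -> AnnotationMap:
    """Load assignments from TSV; duplicate accession lines merge by union.

    Without a universe file the universe is the sorted union of observed
    terms.  With one, assigned terms outside it are dropped but tallied in
    ``unknown_terms`` for audit.
    """
    assignments: dict[str, set[str]] = {}
    handle, owns = _open_text(source)
    try:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            acc = fields[0].strip()
            if not acc:
                raise FormatError("empty accession field", line=line_no)
            terms = set()
            if len(fields) > 1 and fields[1].strip():
                terms = {t.strip() for t in fields[1].split(";") if t.strip()}
            assignments.setdefault(acc, set()).update(terms)
    finally:
        if owns:
            handle.close()

    unknown = 0
    if universe_source is not None:
        uhandle, uowns = _open_text(universe_source)
        try:
            universe = sorted(
                {ln.strip() for ln in uhandle if ln.strip()}
            )
        finally:
            if uowns:
                uhandle.close()
        uset = set(universe)
        for acc, terms in assignments.items():
            extra = terms - uset
            unknown += len(extra)
            assignments[acc] = terms & uset
        if unknown:
            logger.warning(
                "%d assigned terms were outside the declared universe", unknown
            )
    else:
        universe = sorted(set().union(*assignments.values()) if assignments else set())

    return AnnotationMap(
        universe=tuple(universe),
        assignments={a: frozenset(t) for a, t in assignments.items()},
        unknown_terms=unknown,
    )


def save_annotation_map(amap: AnnotationMap, handle) -> None:
    """Write the TSV form (accessions sorted, terms ';'-joined sorted)."""
    for acc in sorted(amap.assignments):
        terms = ";".join(sorted(amap.assignments[acc]))
        handle.write(f"{acc}\t{terms}\n")


def binary_vector(rec_id: str, amap: AnnotationMap, mode_name: str = "go") -> DescriptorVector:
    """Module-level convenience wrapper around AnnotationMap.binary_vector."""
    return amap.binary_vector(rec_id, mode_name)


# ---------------------------------------------------------------------------
# compact binary cache ("PSBEM1")
# ---------------------------------------------------------------------------


def write_bem_cache(amap: AnnotationMap, path) -> None:
    """Serialize to the compact cache: magic, universe, bitset rows."""
    with open(path, "wb") as fh:
        fh.write(_BEM_MAGIC)
        uni_blob = "\n".join(amap.universe).encode()
        fh.write(struct.pack("<II", len(amap.universe), len(uni_blob)))
        fh.write(uni_blob)
        fh.write(struct.pack("<I", len(amap.assignments)))
        n_bytes = (amap.n_terms + 7) // 8
        index = {t: j for j, t in enumerate(amap.universe)}
        for acc in sorted(amap.assignments):
            acc_b = acc.encode()
            fh.write(struct.pack("<H", len(acc_b)))
            fh.write(acc_b)
            bits = bytearray(n_bytes)
            for t in amap.assignments[acc]:
                j = index[t]
                bits[j // 8] |= 1 << (j % 8)
            fh.write(bytes(bits))


def read_bem_cache(path) -> AnnotationMap:
    """Load a cache written by :func:`write_bem_cache`."""
    with open(path, "rb") as fh:
        if fh.read(len(_BEM_MAGIC)) != _BEM_MAGIC:
            raise FormatError(f"{path}: not a PSBEM1 annotation cache")
        n_terms, blob_len = struct.unpack("<II", fh.read(8))
        universe = tuple(fh.read(blob_len).decode().split("\n")) if blob_len else ()
        if len(universe) != n_terms:
            raise FormatError(f"{path}: corrupt universe block")
        (n_rows,) = struct.unpack("<I", fh.read(4))
        n_bytes = (n_terms + 7) // 8
        assignments: dict[str, frozenset[str]] = {}
        for _ in range(n_rows):
            (acc_len,) = struct.unpack("<H", fh.read(2))
            acc = fh.read(acc_len).decode()
            bits = fh.read(n_bytes)
            terms = frozenset(
                universe[j]
                for j in range(n_terms)
                if bits[j // 8] & (1 << (j % 8))
            )
            assignments[acc] = terms
    return AnnotationMap(universe=universe, assignments=assignments)
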