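"""Deterministic synthetic fixtures: proteins, property tables, annotation
maps and PSSMs.

Everything here is driven by one integer seed through
``numpy.random.default_rng``, so fixtures are byte-reproducible across
runs and platforms.  Synthetic proteins draw residues uniformly from the
canonical alphabet — adequate for exercising descriptor arithmetic and
dimensionality, though real proteomes have non-uniform composition and
local structure (see the methods note for what that implies about tests).
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass

import numpy as np

from .alphabet import AMINO_ACIDS
from .annotations import AnnotationMap
from .errors import ArgumentError
from .io import PropertyTable, ProteinRecord, write_fasta
from .pssm import PSSMatrix


def synth_proteins(
    seed: int, n: int, length_range: tuple[int, int] = (50, 300)
) -> list[ProteinRecord]:
    """``n`` uniform-random proteins with lengths in ``length_range``."""
    lo, hi = length_range
    if lo < 1:
        raise ArgumentError(f"length_range lower bound must be >= 1, got {lo}")
    if hi < lo:
        raise ArgumentError(f"invalid length_range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    records = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = bytes(letters[rng.integers(0, 20, size=L)]).decode()
        records.append(ProteinRecord(id=f"synth{i + 1:05d}", seq=seq))
    return records


def synth_fasta(seed: int, n: int, length_range: tuple[int, int] = (50, 300)) -> str:
    """FASTA text for :func:`synth_proteins` (byte-stable for a seed)."""
    buf = _stdio.StringIO()
    write_fasta(synth_proteins(seed, n, length_range), buf)
    return buf.getvalue()


def synth_property_table(seed: int, n_properties: int = 3) -> PropertyTable:
    """Standard-normal property values; accessions SYN0001..SYN{n}.

    ``n_properties=544`` yields a full-size placeholder table for
    dimensionality checks; values are random, not curated indices.
    """
    rng = np.random.default_rng(seed)
    table = PropertyTable()
    for i in range(n_properties):
        table.add(f"SYN{i + 1:04d}", rng.normal(size=20))
    return table


def synth_annotation_map(
    seed: int, accessions: list[str], n_terms: int = 20, mean_terms: float = 3.0
) -> AnnotationMap:
    """Random term assignments over a GO-style universe of ``n_terms``."""
    rng = np.random.default_rng(seed)
    universe = tuple(sorted(f"GO:{7000000 + i:07d}" for i in range(n_terms)))
    assignments = {}
    for acc in accessions:
        k = min(n_terms, int(rng.poisson(mean_terms)))
        chosen = rng.choice(n_terms, size=k, replace=False) if k else []
        assignments[acc] = frozenset(universe[j] for j in chosen)
    return AnnotationMap(universe=universe, assignments=assignments)


def synth_pssm(seed: int, rec: ProteinRecord, scale: float = 4.0) -> PSSMatrix:
    """Integer log-odds-like scores with a +scale bump on the query residue."""
    rng = np.random.default_rng(seed)
    scores = rng.integers(-6, 7, size=(rec.length, 20)).astype(float)
    for i, c in enumerate(rec.seq):
        scores[i, AMINO_ACIDS.index(c)] += scale
    return PSSMatrix(rec.id, scores, rec.seq)


@dataclass(frozen=True)
class FixtureBundle:
    """One coherent set of synthetic inputs for a batch run."""

    fasta_text: str
    records: tuple[ProteinRecord, ...]
    property_table: PropertyTable
    annotation_map: AnnotationMap
    pssms: dict[str, PSSMatrix]


def synth_fixtures(
    seed: int,
    n: int,
    length_range: tuple[int, int] = (50, 300),
    n_properties: int = 3,
) -> FixtureBundle:
    """Deterministic bundle: FASTA + properties + annotations + PSSMs.

    Sub-seeds are derived from ``seed`` so the components are independent
    but jointly reproducible.
    """
    records = synth_proteins(seed, n, length_range)
    buf = _stdio.StringIO()
    write_fasta(records, buf)
    ids = [r.id for r in records]
    return FixtureBundle(
        fasta_text=buf.getvalue(),
        records=tuple(records),
        property_table=synth_property_table(seed + 1, n_properties),
        annotation_map=synth_annotation_map(seed + 2, ids),
        pssms={r.id: synth_pssm(seed + 3 + i, r) for i, r in enumerate(records)},
    )
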