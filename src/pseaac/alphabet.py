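"""Canonical amino-acid alphabet and index maps.

Every module in the package stores per-residue values in one fixed order:
the 20 canonical amino acids sorted alphabetically by one-letter code
(``ACDEFGHIKLMNPQRSTVWY``).  External formats that use the historical
AAindex / PSI-BLAST column order (``ARNDCQEGHILKMFPSTWYV``) are re-mapped
to this canonical order at parse time, so indexing bugs cannot creep in
downstream.
"""

from __future__ import annotations

#: Canonical internal ordering (alphabetical one-letter codes).
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Column order used by AAindex flat files and PSI-BLAST ASCII PSSMs.
AAINDEX_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: letter -> 0..19 in canonical order
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: permutation p such that canonical[i] = aaindex_values[AAINDEX_TO_CANONICAL[i]]
AAINDEX_TO_CANONICAL: tuple[int, ...] = tuple(
    AAINDEX_ORDER.index(aa) for aa in AMINO_ACIDS
)

#: Ambiguity codes mapped to the nearest canonical residue
#: (B: Asx->D, Z: Glx->E, U: selenocysteine->C, O: pyrrolysine->K, J: Xle->L).
AMBIGUITY_MAP: dict[str, str] = {"B": "D", "Z": "E", "U": "C", "O": "K", "J": "L"}


def is_canonical(seq: str) -> bool:
    """Return True if every character of ``seq`` is a canonical residue."""
    return all(c in AA_INDEX for c in seq)


def encode(seq: str) -> list[int]:
    """Map a canonical sequence to integer indices 0..19.

    Raises ``KeyError`` on non-canonical characters; callers that accept
    raw input must validate first (see :func:`pseaac.io.read_fasta`).
    """
    return [AA_INDEX[c] for c in seq]
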