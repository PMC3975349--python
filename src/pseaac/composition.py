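"""Conventional amino-acid, di-peptide and tri-peptide composition.

All three descriptors are overlapping-window *frequencies*: counts divided
by the number of windows (L, L-1, L-2), so vectors are comparable across
sequence lengths and each family sums to exactly 1.
"""

from __future__ import annotations

import itertools

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS
from .errors import SequenceLengthError
from .io import ProteinRecord
from .vector import DescriptorVector

AAC_NAMES = tuple(f"AAC_{a}" for a in AMINO_ACIDS)
DPC_NAMES = tuple(
    f"DPC_{a}{b}" for a, b in itertools.product(AMINO_ACIDS, repeat=2)
)
TPC_NAMES = tuple(
    f"TPC_{a}{b}{c}" for a, b, c in itertools.product(AMINO_ACIDS, repeat=3)
)


def _encoded(rec: ProteinRecord) -> np.ndarray:
    return np.fromiter((AA_INDEX[c] for c in rec.seq), dtype=np.intp,
                       count=rec.length)


def aac(rec: ProteinRecord) -> DescriptorVector:
    """Amino-acid composition f_u = count(u)/L (20 features)."""
    idx = _encoded(rec)
    counts = np.bincount(idx, minlength=20).astype(np.float64)
    return DescriptorVector("aac", AAC_NAMES, counts / rec.length)


def aac_frequencies(rec: ProteinRecord) -> np.ndarray:
    """Raw frequency vector f (sums to 1); shared by the pseudo-composition
    and quasi-sequence-order normalizations."""
    idx = _encoded(rec)
    return np.bincount(idx, minlength=20).astype(np.float64) / rec.length


def dipeptide(rec: ProteinRecord) -> DescriptorVector:
    """Di-peptide composition over the L-1 adjacent pairs (400 features)."""
    if rec.length < 2:
        raise SequenceLengthError(rec.id, rec.length, 2, "di-peptide composition")
    idx = _encoded(rec)
    pair_codes = idx[:-1] * 20 + idx[1:]
    counts = np.bincount(pair_codes, minlength=400).astype(np.float64)
    return DescriptorVector("dpc", DPC_NAMES, counts / (rec.length - 1))


def tripeptide(rec: ProteinRecord, sparse: bool = False):
    """Tri-peptide composition over the L-2 windows (8000 features).

    With ``sparse=True`` returns ``(names, {flat_index: frequency})`` for
    the at most L-2 non-zero entries instead of a dense vector.
    """
    if rec.length < 3:
        raise SequenceLengthError(rec.id, rec.length, 3, "tri-peptide composition")
    idx = _encoded(rec)
    codes = idx[:-2] * 400 + idx[1:-1] * 20 + idx[2:]
    n_windows = rec.length - 2
    if sparse:
        uniq, cnt = np.unique(codes, return_counts=True)
        return TPC_NAMES, {
            int(u): c / n_windows for u, c in zip(uniq, cnt)
        }
    counts = np.bincount(codes, minlength=8000).astype(np.float64)
    return DescriptorVector("tpc", TPC_NAMES, counts / n_windows)
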