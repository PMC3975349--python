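"""Composition-Transition-Distribution (CTD) descriptors.

Each physicochemical attribute partitions the 20 amino acids into three
classes (e.g. polar / neutral / hydrophobic).  Per attribute the sequence
yields 21 features, all on a 0-100 percent scale:

* Composition (3): percent of residues in each class;
* Transition (3): percent of adjacent pairs whose two residues fall in
  different classes, for the unordered class pairs (1,2), (1,3), (2,3);
* Distribution (15): for each class, the sequence position (as percent of
  L) at which the first, 25%, 50%, 75% and 100% of that class's residues
  have been seen.  The occurrence index for fraction q is ceil(q * n_k);
  a class absent from the sequence contributes five zeros.

Note the percent (x100) scaling: a [0, 1] dialect of these descriptors
also circulates, so values from other tools may differ by that factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS
from .errors import ArgumentError, SequenceLengthError
from .io import ProteinRecord
from .vector import DescriptorVector


@dataclass(frozen=True)
class PropertyGrouping:
    """A named partition of the 20 amino acids into 3 disjoint classes."""

    name: str
    groups: tuple[str, str, str]

    def __post_init__(self):
        letters = "".join(self.groups)
        if sorted(letters) != sorted(AMINO_ACIDS):
            raise ArgumentError(
                f"grouping {self.name!r}: classes must partition the 20 "
                f"amino acids exactly (got {letters!r})"
            )

    def class_of(self) -> np.ndarray:
        """Residue-index -> class label (0, 1, 2) lookup array."""
        lookup = np.empty(20, dtype=np.intp)
        for k, members in enumerate(self.groups):
            for aa in members:
                lookup[AA_INDEX[aa]] = k
        return lookup


def _class_profile(rec: ProteinRecord, grouping: PropertyGrouping) -> np.ndarray:
    idx = np.fromiter(
        (AA_INDEX[c] for c in rec.seq), dtype=np.intp, count=rec.length
    )
    return grouping.class_of()[idx]


def ctd_composition(rec: ProteinRecord, grouping: PropertyGrouping) -> np.ndarray:
    """C_k = 100 * count(class k) / L for k = 1..3."""
    classes = _class_profile(rec, grouping)
    counts = np.bincount(classes, minlength=3).astype(np.float64)
    return 100.0 * counts / rec.length


def ctd_transition(rec: ProteinRecord, grouping: PropertyGrouping) -> np.ndarray:
    """T_kl = 100 * (pairs crossing k<->l in either direction) / (L-1)."""
    if rec.length < 2:
        raise SequenceLengthError(rec.id, rec.length, 2, "CTD transition")
    classes = _class_profile(rec, grouping)
    a, b = classes[:-1], classes[1:]
    out = np.empty(3)
    for slot, (k, l) in enumerate(((0, 1), (0, 2), (1, 2))):
        crossings = np.sum(((a == k) & (b == l)) | ((a == l) & (b == k)))
        out[slot] = 100.0 * crossings / (rec.length - 1)
    return out


_FRACTIONS = (0.0, 0.25, 0.50, 0.75, 1.0)  # 0.0 means "first occurrence"


def ctd_distribution(rec: ProteinRecord, grouping: PropertyGrouping) -> np.ndarray:
    """Positional distribution: 5 percentile positions per class (15 values)."""
    classes = _class_profile(rec, grouping)
    out = np.zeros(15)
    for k in range(3):
        positions = np.flatnonzero(classes == k) + 1  # 1-based
        n_k = positions.size
        if n_k == 0:
            continue  # absent class -> five zeros
        for qi, q in enumerate(_FRACTIONS):
            occurrence = 1 if q == 0.0 else math.ceil(q * n_k)
            out[5 * k + qi] = 100.0 * positions[occurrence - 1] / rec.length
    return out


def ctd_vector(
    rec: ProteinRecord, groupings: list[PropertyGrouping]
) -> DescriptorVector:
    """3 C + 3 T + 15 D = 21 features per grouping, concatenated."""
    if not groupings:
        raise ArgumentError("CTD requires at least one property grouping")
    names: list[str] = []
    chunks: list[np.ndarray] = []
    for g in groupings:
        names += [f"CTD_{g.name}_C{k}" for k in (1, 2, 3)]
        names += [f"CTD_{g.name}_T{kl}" for kl in ("12", "13", "23")]
        names += [
            f"CTD_{g.name}_D{k}_{pct}"
            for k in (1, 2, 3)
            for pct in ("first", "25", "50", "75", "100")
        ]
        chunks.append(ctd_composition(rec, g))
        chunks.append(ctd_transition(rec, g))
        chunks.append(ctd_distribution(rec, g))
    return DescriptorVector("ctd", tuple(names), np.concatenate(chunks))
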