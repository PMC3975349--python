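"""Quasi-sequence-order descriptors and sequence-order coupling numbers.

The coupling number at lag d sums squared physicochemical distances
between residues d apart,

    tau_d = sum_{i=1..L-d} d(R_i, R_{i+d})**2,

where d(a, b) comes from a 20x20 amino-acid distance matrix.  The
quasi-sequence-order vector renormalizes the 20 amino-acid frequencies
together with the weighted coupling numbers:

    X_u      = f_u     / (sum_b f_b + w * sum_d tau_d)   (u = 1..20)
    X_{20+d} = w*tau_d / (same denominator)              (d = 1..D)

All components are non-negative and sum to exactly 1.  The full built-in
mode concatenates one such block per distance matrix (two are bundled).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS
from .composition import aac_frequencies, _encoded
from .errors import ArgumentError, FormatError, LagError, SequenceLengthError
from .io import ProteinRecord, _open_text
from .vector import DescriptorVector


@dataclass(frozen=True)
class DistanceMatrix:
    """Named 20x20 non-negative amino-acid distance matrix, canonical order."""

    name: str
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        if vals.shape != (20, 20):
            raise ArgumentError(
                f"distance matrix {self.name!r}: expected 20x20, got {vals.shape}"
            )
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ArgumentError(
                f"distance matrix {self.name!r}: entries must be finite and >= 0"
            )
        if np.any(np.diagonal(vals) != 0):
            raise ArgumentError(
                f"distance matrix {self.name!r}: diagonal must be zero"
            )

    def scaled(self, c: float) -> "DistanceMatrix":
        return DistanceMatrix(self.name, self.values * c)


def load_distance_matrix(source, name: str | None = None) -> DistanceMatrix:
    """Read a 20x20 distance matrix TSV with canonical-order header row
    and first column; ``name`` defaults to the file stem."""
    handle, owns = _open_text(source)
    try:
        header = handle.readline().rstrip("\n").split("\t")
        if len(header) != 21 or "".join(header[1:]) != AMINO_ACIDS:
            raise FormatError(
                "distance matrix header must be a label followed by the 20 "
                f"residues in order {AMINO_ACIDS}",
                line=1,
            )
        rows = np.zeros((20, 20))
        seen: list[str] = []
        for line_no, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 21:
                raise FormatError(
                    f"expected residue label + 20 values, got {len(fields)}",
                    line=line_no,
                )
            aa = fields[0]
            if aa not in AA_INDEX:
                raise FormatError(f"unknown residue row {aa!r}", line=line_no)
            rows[AA_INDEX[aa]] = [float(v) for v in fields[1:]]
            seen.append(aa)
        if sorted(seen) != list(AMINO_ACIDS):
            raise FormatError(
                f"matrix must contain one row per residue; got {len(seen)}"
            )
    finally:
        if owns:
            handle.close()
    if name is None:
        name = Path(source).stem if isinstance(source, (str, Path)) else "custom"
    return DistanceMatrix(name, rows)


def coupling_number(rec: ProteinRecord, dm: DistanceMatrix, d: int) -> float:
    """Sequence-order coupling number tau_d (sum of squared distances)."""
    if not 1 <= d < rec.length:
        raise LagError(
            f"record {rec.id!r}: lag {d} must satisfy 1 <= d < L ({rec.length})"
        )
    idx = _encoded(rec)
    return float(np.sum(dm.values[idx[:-d], idx[d:]] ** 2))


def qso_vector(
    rec: ProteinRecord,
    dm: DistanceMatrix,
    max_lag: int = 30,
    w: float = 0.1,
) -> DescriptorVector:
    """Quasi-sequence-order block for one distance matrix (20 + D features)."""
    if not w > 0:
        raise ArgumentError(f"weight w must be > 0, got {w}")
    if max_lag < 1:
        raise ArgumentError(f"max_lag must be >= 1, got {max_lag}")
    if rec.length <= max_lag:
        raise SequenceLengthError(
            rec.id, rec.length, max_lag + 1,
            f"quasi-sequence-order requires L > max_lag ({max_lag})",
        )
    f = aac_frequencies(rec)
    taus = np.array(
        [coupling_number(rec, dm, d) for d in range(1, max_lag + 1)]
    )
    denom = f.sum() + w * taus.sum()  # f.sum() == 1, taus >= 0
    values = np.concatenate([f, w * taus]) / denom
    names = tuple(f"QSO_{dm.name}_{a}" for a in AMINO_ACIDS) + tuple(
        f"QSO_{dm.name}_tau{d}" for d in range(1, max_lag + 1)
    )
    return DescriptorVector("qso", names, values)


def qso_mode_vector(
    rec: ProteinRecord,
    matrices: list[DistanceMatrix],
    max_lag: int = 30,
    w: float = 0.1,
) -> DescriptorVector:
    """Concatenated quasi-sequence-order blocks, one per distance matrix."""
    if not matrices:
        raise ArgumentError("quasi-sequence-order requires >= 1 distance matrix")
    blocks = [qso_vector(rec, dm, max_lag, w) for dm in matrices]
    return DescriptorVector(
        "qso",
        tuple(n for b in blocks for n in b.feature_names),
        np.concatenate([b.values for b in blocks]),
    )
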