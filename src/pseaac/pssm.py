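"""Sequential-evolution mode: descriptors from PSI-BLAST PSSMs.

A position-specific scoring matrix (PSSM) encodes, for each sequence
position, 20 log-odds substitution scores produced by iterative profile
search.  The mode first standardizes each row (z-score over its 20
scores, divisor 20), then emits

* 20 column means  a_j = (1/L) * sum_i E'_{i,j}, and
* for each lag g = 1..xi and column j the lagged squared-difference
  correlation  theta_j(g) = (1/(L-g)) * sum_i (E'_{i,j} - E'_{i+g,j})**2,

giving 20 + 20*xi features (means first, then lag-major blocks of 20).
Row standardization is used rather than the logistic squashing dialect
that also appears in the literature; see the methods note.

PSSM files are caller-supplied PSI-BLAST ``-out_ascii_pssm`` text; this
package never runs PSI-BLAST itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alphabet import AAINDEX_ORDER, AAINDEX_TO_CANONICAL, AMINO_ACIDS
from .errors import FormatError, SequenceLengthError
from .io import _open_text
from .vector import DescriptorVector

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PSSMatrix:
    """L x 20 log-odds score matrix, columns in canonical residue order."""

    accession: str
    scores: np.ndarray
    residues: str = ""  # the query residue per row, if known

    def __post_init__(self):
        vals = np.asarray(self.scores, dtype=np.float64)
        object.__setattr__(self, "scores", vals)
        if vals.ndim != 2 or vals.shape[1] != 20 or vals.shape[0] < 1:
            raise FormatError(
                f"PSSM {self.accession!r}: expected Lx20 scores, got {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise FormatError(f"PSSM {self.accession!r}: non-finite score")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def parse_pssm(source, accession: str = "pssm") -> PSSMatrix:
    """Parse PSI-BLAST ASCII PSSM text into canonical column order.

    Data rows look like ``pos res <20 log-odds ints> <20 percent ints> ...``;
    only the first 20-column (log-odds) block is kept.  Columns are
    re-mapped from the file's ARNDCQEGHILKMFPSTWYV order.
    """
    handle, owns = _open_text(source)
    rows: list[list[float]] = []
    residues: list[str] = []
    expected_pos = 1
    try:
        for line_no, line in enumerate(handle, start=1):
            fields = line.split()
            # data rows start with an integer position then a residue letter
            if len(fields) < 2 or not fields[0].isdigit():
                continue
            if not (len(fields[1]) == 1 and fields[1].isalpha()):
                continue
            pos = int(fields[0])
            numeric = fields[2:]
            # trailing per-row information content / weight columns are
            # floats; the two 20-column integer blocks come first
            if len(numeric) < 40:
                raise FormatError(
                    f"PSSM row {pos}: expected 40 score fields, got "
                    f"{len(numeric)}",
                    line=line_no,
                )
            if pos != expected_pos:
                raise FormatError(
                    f"non-contiguous PSSM positions: expected {expected_pos}, "
                    f"got {pos}",
                    line=line_no,
                )
            try:
                logodds = [float(v) for v in numeric[:20]]
            except ValueError:
                raise FormatError(
                    f"PSSM row {pos}: non-numeric score", line=line_no
                ) from None
            rows.append(logodds)
            residues.append(fields[1].upper())
            expected_pos += 1
    finally:
        if owns:
            handle.close()
    if not rows:
        raise FormatError("PSSM file contains no score rows")
    scores = np.asarray(rows)[:, list(AAINDEX_TO_CANONICAL)]
    return PSSMatrix(accession, scores, "".join(residues))


def write_pssm_ascii(matrix: PSSMatrix, handle) -> None:
    """Write the PSI-BLAST ASCII dialect (round-trips through parse_pssm).

    Used by the synthetic-fixture generator; emits integer-rounded
    log-odds plus a zero percent block, matching the two-block layout.
    """
    handle.write("\n")
    handle.write("Last position-specific scoring matrix computed\n")
    header = "            " + "  ".join(AAINDEX_ORDER) + "   " + "  ".join(AAINDEX_ORDER)
    handle.write(header + "\n")
    inv = [AMINO_ACIDS.index(a) for a in AAINDEX_ORDER]
    for i in range(matrix.length):
        res = matrix.residues[i] if matrix.residues else "A"
        logodds = " ".join(f"{int(round(matrix.scores[i, j])):3d}" for j in inv)
        percents = " ".join("  0" for _ in range(20))
        handle.write(f"{i + 1:5d} {res} {logodds} {percents}  0.00 0.00\n")


def normalize_pssm(matrix: PSSMatrix) -> PSSMatrix:
    """Standardize each row over its 20 scores (divisor 20).

    Constant rows (zero variance) become all-zero rows with a warning.
    """
    scores = matrix.scores
    means = scores.mean(axis=1, keepdims=True)
    sds = scores.std(axis=1, keepdims=True)  # ddof=0
    flat = sds[:, 0] == 0.0
    if np.any(flat):
        logger.warning(
            "PSSM %r: %d constant rows set to zero during normalization",
            matrix.accession, int(flat.sum()),
        )
    safe_sds = np.where(sds == 0.0, 1.0, sds)
    normed = (scores - means) / safe_sds
    normed[flat] = 0.0
    return PSSMatrix(matrix.accession, normed, matrix.residues)


def psepssm(matrix: PSSMatrix, xi: int = 10) -> DescriptorVector:
    """Pseudo-PSSM features from a row-standardized matrix (20 + 20*xi)."""
    if xi < 1:
        raise FormatError(f"xi must be >= 1, got {xi}")
    L = matrix.length
    if L <= xi:
        raise SequenceLengthError(
            matrix.accession, L, xi + 1, f"pseudo-PSSM requires L > xi ({xi})"
        )
    E = matrix.scores
    means = E.mean(axis=0)
    names = [f"PSEPSSM_mean_{a}" for a in AMINO_ACIDS]
    chunks = [means]
    for g in range(1, xi + 1):
        diff = E[:-g] - E[g:]
        chunks.append(np.mean(diff**2, axis=0))
        names += [f"PSEPSSM_theta_{a}_g{g}" for a in AMINO_ACIDS]
    return DescriptorVector("psepssm", tuple(names), np.concatenate(chunks))
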