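"""Type I and Type II pseudo-amino-acid composition.

Both variants augment the 20 amino-acid frequencies f_u with lambda tiers
of sequence-order correlation factors tau_j and renormalize so that the
whole vector shares one denominator:

* Type I ("parallel correlation", 20+lambda features) couples residues
  ``j`` apart through the averaged squared difference of k standardized
  physicochemical properties,
  ``Theta(a,b) = (1/k) * sum_p (P_p(b) - P_p(a))**2``, and
  ``tau_j = mean_i Theta(R_i, R_{i+j})``.  Theta >= 0 makes every
  component non-negative and the vector sums to exactly 1.

* Type II ("amphiphilic" / series correlation, 20+2*lambda features) uses
  per-property *products* instead: for each tier j a hydrophobicity factor
  ``tau_{2j-1} = mean_i H1(R_i) * H1(R_{i+j})`` and a hydrophilicity factor
  ``tau_{2j} = mean_i H2(R_i) * H2(R_{i+j})``.  Products can be negative,
  so the denominator ``1 + w * sum(tau)`` is checked and a degenerate
  normalization is a hard error rather than a silent sign flip.

The default property set for Type I is the classic hydrophobicity /
hydrophilicity / side-chain-mass triple; any non-empty selection from the
loaded property table is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS
from .composition import aac_frequencies, _encoded
from .errors import (
    ArgumentError,
    DegenerateNormalizationError,
    SequenceLengthError,
)
from .io import PropertyTable, ProteinRecord
from .vector import DescriptorVector

#: accessions of the classic property triple bundled with the package
CLASSIC_TRIPLE = ("hydrophobicity", "hydrophilicity", "side_chain_mass")
CLASSIC_PAIR = ("hydrophobicity", "hydrophilicity")


@dataclass(frozen=True)
class PseAACParams:
    """Tier count lambda, weight w, and the property accessions to couple."""

    lam: int = 30
    w: float = 0.05
    properties: tuple[str, ...] = CLASSIC_TRIPLE

    def __post_init__(self):
        if self.lam < 1:
            raise ArgumentError(f"lambda must be >= 1, got {self.lam}")
        if not self.w > 0:
            raise ArgumentError(f"weight w must be > 0, got {self.w}")
        if not self.properties:
            raise ArgumentError("at least one property accession is required")
        object.__setattr__(self, "properties", tuple(self.properties))


def _property_matrix(
    table: PropertyTable, accessions: Sequence[str]
) -> np.ndarray:
    """Stack standardized property rows into a (k, 20) matrix."""
    return np.stack([table.normalized(acc) for acc in accessions])


def correlation_theta(
    a: str, b: str, props: Sequence[np.ndarray] | np.ndarray
) -> float:
    """Theta(a, b): mean squared difference of standardized properties."""
    mat = np.asarray(props, dtype=np.float64)
    if mat.ndim == 1:
        mat = mat[None, :]
    if mat.shape[-1] != 20 or mat.shape[0] < 1:
        raise ArgumentError(f"expected (k, 20) property array, got {mat.shape}")
    try:
        ia, ib = AA_INDEX[a], AA_INDEX[b]
    except KeyError as exc:
        raise ArgumentError(f"unknown residue {exc.args[0]!r}") from None
    diff = mat[:, ib] - mat[:, ia]
    return float(np.mean(diff**2))


def _tier_thetas(
    rec: ProteinRecord, prop_mat: np.ndarray, lam: int
) -> np.ndarray:
    """tau_j for j=1..lam, tau_j = mean over i of Theta(R_i, R_{i+j})."""
    idx = _encoded(rec)
    per_residue = prop_mat[:, idx]  # (k, L)
    taus = np.empty(lam)
    for j in range(1, lam + 1):
        diff = per_residue[:, j:] - per_residue[:, :-j]  # (k, L-j)
        taus[j - 1] = np.mean(diff**2, axis=0).mean()
    return taus


def type1_pseaac(
    rec: ProteinRecord, params: PseAACParams, table: PropertyTable
) -> DescriptorVector:
    """Type I pseudo-amino-acid composition (20 + lambda features)."""
    if rec.length <= params.lam:
        raise SequenceLengthError(
            rec.id, rec.length, params.lam + 1,
            f"Type I requires L > lambda ({params.lam})",
        )
    prop_mat = _property_matrix(table, params.properties)
    f = aac_frequencies(rec)
    taus = _tier_thetas(rec, prop_mat, params.lam)
    denom = f.sum() + params.w * taus.sum()  # f.sum() == 1, taus >= 0
    values = np.concatenate([f, params.w * taus]) / denom
    names = tuple(f"PAAC1_{a}" for a in AMINO_ACIDS) + tuple(
        f"PAAC1_lam{j}" for j in range(1, params.lam + 1)
    )
    return DescriptorVector("pseaac1", names, values)


def type2_pseaac(
    rec: ProteinRecord, params: PseAACParams, table: PropertyTable
) -> DescriptorVector:
    """Type II (amphiphilic) pseudo-amino-acid composition (20 + 2*lambda).

    Requires exactly two properties (hydrophobicity, hydrophilicity by
    default); emits interleaved per-tier factors tau_1..tau_{2*lambda}.
    """
    if len(params.properties) != 2:
        raise ArgumentError(
            "Type II couples exactly two properties (hydrophobicity, "
            f"hydrophilicity); got {len(params.properties)}"
        )
    if rec.length <= params.lam:
        raise SequenceLengthError(
            rec.id, rec.length, params.lam + 1,
            f"Type II requires L > lambda ({params.lam})",
        )
    prop_mat = _property_matrix(table, params.properties)  # (2, 20)
    idx = _encoded(rec)
    per_residue = prop_mat[:, idx]  # (2, L)
    taus = np.empty(2 * params.lam)
    for j in range(1, params.lam + 1):
        prod = per_residue[:, :-j] * per_residue[:, j:]  # (2, L-j)
        taus[2 * j - 2] = prod[0].mean()
        taus[2 * j - 1] = prod[1].mean()
    denom = 1.0 + params.w * taus.sum()
    if denom <= 0:
        raise DegenerateNormalizationError(float(taus.sum()))
    f = aac_frequencies(rec)
    values = np.concatenate([f, params.w * taus]) / denom
    names = tuple(f"PAAC2_{a}" for a in AMINO_ACIDS) + tuple(
        f"PAAC2_tau{k}" for k in range(1, 2 * params.lam + 1)
    )
    return DescriptorVector("pseaac2", names, values)
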