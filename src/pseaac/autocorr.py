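"""Moreau-Broto, Moran and Geary sequence autocorrelation descriptors.

Each family maps a sequence and one standardized physicochemical property
P to a profile over lags d = 1..D:

* normalized Moreau-Broto: ``AC(d) = (1/(L-d)) * sum_i P_i * P_{i+d}``
  ("normalized" refers to the property being standardized over the 20
  amino acids before use, and to the 1/(L-d) window average);
* Moran: covariance-style, centred on the sequence mean P-bar and divided
  by the sequence variance (divisor L) — the sequence analogue of spatial
  autocorrelation, ~0 for i.i.d. sequences, positive for smooth profiles;
* Geary: squared-difference form divided by the sample variance
  (divisor L-1); 1 is the null value, <1 indicates positive correlation.

Zero-variance sequences (every residue carrying the same property value)
would make Moran/Geary 0/0; they return 0 with a logged warning so batch
matrices stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .composition import _encoded
from .errors import ArgumentError, LagError
from .io import PropertyTable, ProteinRecord
from .vector import DescriptorVector

logger = logging.getLogger(__name__)

FAMILIES = ("nmbroto", "moran", "geary")
_FAMILY_LABEL = {"nmbroto": "NMBROTO", "moran": "MORAN", "geary": "GEARY"}


@dataclass(frozen=True)
class AutocorrParams:
    """Maximum lag D and the property accessions to profile."""

    max_lag: int = 30
    properties: tuple[str, ...] = ()

    def __post_init__(self):
        if self.max_lag < 1:
            raise ArgumentError(f"max_lag must be >= 1, got {self.max_lag}")
        object.__setattr__(self, "properties", tuple(self.properties))


def _profile(rec: ProteinRecord, prop: np.ndarray) -> np.ndarray:
    """Per-position property values P_1..P_L for a standardized property."""
    return np.asarray(prop, dtype=np.float64)[_encoded(rec)]


def _check_lag(rec: ProteinRecord, d: int) -> None:
    if not 1 <= d < rec.length:
        raise LagError(
            f"record {rec.id!r}: lag {d} must satisfy 1 <= d < L ({rec.length})"
        )


def moreau_broto(rec: ProteinRecord, prop: np.ndarray, d: int) -> float:
    """Normalized Moreau-Broto autocorrelation at lag d."""
    _check_lag(rec, d)
    p = _profile(rec, prop)
    return float(np.mean(p[:-d] * p[d:]))


def moran(rec: ProteinRecord, prop: np.ndarray, d: int) -> float:
    """Moran autocorrelation I(d); 0 for zero-variance sequences."""
    _check_lag(rec, d)
    p = _profile(rec, prop)
    pbar = p.mean()
    denom = np.mean((p - pbar) ** 2)  # divisor L
    if denom == 0.0:
        logger.warning(
            "record %r: zero sequence variance; Moran I(%d) set to 0",
            rec.id, d,
        )
        return 0.0
    num = np.mean((p[:-d] - pbar) * (p[d:] - pbar))  # divisor L-d
    return float(num / denom)


def geary(rec: ProteinRecord, prop: np.ndarray, d: int) -> float:
    """Geary autocorrelation C(d); 0 for zero-variance sequences."""
    _check_lag(rec, d)
    p = _profile(rec, prop)
    pbar = p.mean()
    denom = np.sum((p - pbar) ** 2) / (rec.length - 1)  # divisor L-1
    if denom == 0.0:
        logger.warning(
            "record %r: zero sequence variance; Geary C(%d) set to 0",
            rec.id, d,
        )
        return 0.0
    num = np.sum((p[:-d] - p[d:]) ** 2) / (2.0 * (rec.length - d))
    return float(num / denom)


_FAMILY_FN = {"nmbroto": moreau_broto, "moran": moran, "geary": geary}


def autocorr_vector(
    rec: ProteinRecord,
    params: AutocorrParams,
    family: str,
    table: PropertyTable,
) -> DescriptorVector:
    """|properties| x D features, property-major then lag order.

    Feature names follow ``<FAMILY>_<property>_d<lag>``.
    """
    if family not in FAMILIES:
        raise ArgumentError(f"unknown family {family!r}; expected {FAMILIES}")
    if not params.properties:
        raise ArgumentError("autocorrelation requires >= 1 property accession")
    if rec.length <= params.max_lag:
        raise LagError(
            f"record {rec.id!r}: L ({rec.length}) must exceed max_lag "
            f"({params.max_lag})"
        )
    fn = _FAMILY_FN[family]
    label = _FAMILY_LABEL[family]
    names: list[str] = []
    values: list[float] = []
    for acc in params.properties:
        prop = table.normalized(acc)
        for d in range(1, params.max_lag + 1):
            names.append(f"{label}_{acc}_d{d}")
            values.append(fn(rec, prop, d))
    return DescriptorVector(family, tuple(names), np.array(values))
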