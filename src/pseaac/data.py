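"""Loaders for the data fixtures bundled with the package.

* ``chou_properties.tsv`` — the classic hydrophobicity / hydrophilicity /
  side-chain-mass triple used as the default Type I property set.
* ``ctd_groupings.tsv`` — the seven standard 3-class attribute partitions
  (hydrophobicity, normalized van der Waals volume, polarity,
  polarizability, charge, secondary structure, solvent accessibility).
* ``grantham.tsv`` — amino-acid distances computed from the published
  composition/polarity/volume formula, scaled so the mean over the 190
  unordered pairs is 100 and rounded to integers.
* ``synthetic_schneider_wrede.tsv`` — a synthetic stand-in for the
  Schneider-Wrede physicochemical distance (whose published values are
  not vendored): Euclidean distance over the z-scored classic property
  triple, max-scaled to 1.  Suitable as a second coupling matrix; not the
  published matrix.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .ctd import PropertyGrouping
from .errors import FormatError
from .io import PropertyTable, load_property_table
from .qso import DistanceMatrix, load_distance_matrix


def _data_text(name: str):
    return resources.files("pseaac").joinpath("data", name).open("r")


@lru_cache(maxsize=None)
def classic_property_table() -> PropertyTable:
    """Hydrophobicity, hydrophilicity and side-chain mass (canonical order)."""
    with _data_text("chou_properties.tsv") as fh:
        return load_property_table(fh, format="tsv")


@lru_cache(maxsize=None)
def standard_groupings() -> tuple[PropertyGrouping, ...]:
    """The seven bundled CTD attribute partitions, in file order."""
    groupings = []
    with _data_text("ctd_groupings.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["attribute", "g1", "g2", "g3"]:
            raise FormatError("ctd_groupings.tsv: unexpected header", line=1)
        for line in fh:
            if not line.strip():
                continue
            name, g1, g2, g3 = line.rstrip("\n").split("\t")
            groupings.append(PropertyGrouping(name, (g1, g2, g3)))
    return tuple(groupings)


@lru_cache(maxsize=None)
def grantham_matrix() -> DistanceMatrix:
    with _data_text("grantham.tsv") as fh:
        return load_distance_matrix(fh, name="grantham")


@lru_cache(maxsize=None)
def synthetic_schneider_wrede_matrix() -> DistanceMatrix:
    """Synthetic stand-in for the Schneider-Wrede distance (see module doc)."""
    with _data_text("synthetic_schneider_wrede.tsv") as fh:
        return load_distance_matrix(fh, name="synthetic_schneider_wrede")


def default_distance_matrices() -> list[DistanceMatrix]:
    """The two coupling matrices applied by the quasi-sequence-order mode."""
    return [synthetic_schneider_wrede_matrix(), grantham_matrix()]
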