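"""Vendored AAindex physicochemical property vectors.

Eight AAindex entries drive the per-position property (AIP) encoding:

========== ======================================================
NAKH920108 amino-acid composition of membrane-spanning proteins
CEDJ970104 composition of intracellular proteins
LIFS790101 conformational preference for beta strands
BLAM930101 alpha-helix propensity (T4 lysozyme position 44 scale)
MAXF760101 normalized frequency of alpha helix
TSAJ990101 residue volume (incl. crystallographic waters)
NOZY710101 transfer free energy, organic solvent/water
KLEP840101 net charge
========== ======================================================

Values are transcribed from the public AAindex database (release 9.1) in
the database's native residue order and stored here remapped to the
package-wide alphabetical order.  Before use each 20-vector is min-max
scaled to [0, 1] so every index lives on a common scale and the padding gap
(which contributes 0) sits at the bottom of the range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import AMINO_ACIDS

# AAindex prints residues in the order A R N D C Q E G H I L K M F P S T W Y V.
_AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"

_RAW: dict[str, tuple[float, ...]] = {
    "NAKH920108": (9.36, 0.27, 2.31, 0.94, 2.56, 1.14, 0.94, 6.17, 0.47, 13.73,
                   16.64, 0.58, 3.93, 10.99, 1.96, 5.58, 4.68, 2.20, 3.13, 12.43),
    "CEDJ970104": (7.9, 4.9, 4.0, 5.5, 1.9, 4.4, 7.1, 7.1, 2.1, 5.2,
                   8.6, 6.7, 2.4, 3.9, 5.3, 6.6, 5.3, 1.2, 3.1, 6.8),
    "LIFS790101": (0.92, 0.93, 0.60, 0.48, 1.16, 0.95, 0.61, 0.61, 0.93, 1.81,
                   1.30, 0.70, 1.19, 1.25, 0.40, 0.82, 1.12, 1.54, 1.53, 1.81),
    "BLAM930101": (0.96, 0.77, 0.39, 0.42, 0.42, 0.80, 0.53, 0.00, 0.57, 0.84,
                   0.92, 0.73, 0.86, 0.59, -2.50, 0.53, 0.54, 0.58, 0.72, 0.63),
    "MAXF760101": (1.43, 1.18, 0.64, 0.92, 0.94, 1.22, 1.67, 0.46, 0.98, 1.04,
                   1.36, 1.27, 1.53, 1.19, 0.49, 0.70, 0.78, 1.01, 0.69, 0.98),
    "TSAJ990101": (89.3, 190.3, 122.4, 114.4, 102.5, 146.9, 138.8, 63.8, 157.5, 163.0,
                   163.1, 165.1, 165.8, 190.8, 121.6, 94.2, 119.6, 226.4, 194.6, 138.2),
    "NOZY710101": (0.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.5, 1.8,
                   1.8, 0.0, 1.3, 2.5, 1.4, 0.0, 0.4, 3.4, 2.3, 1.5),
    "KLEP840101": (0.0, 1.0, 0.0, -1.0, 0.0, 0.0, -1.0, 0.0, 0.0, 0.0,
                   0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
}

ACCESSIONS: tuple[str, ...] = tuple(_RAW)


@dataclass(frozen=True)
class AAIndexTable:
    """Mapping accession -> per-residue values in alphabetical residue order."""

    values: dict[str, np.ndarray]
    normalized: bool

    def __post_init__(self) -> None:
        if len(self.values) != 8:
            raise ValueError(f"expected exactly 8 indices, got {len(self.values)}")
        for acc, v in self.values.items():
            if v.shape != (20,) or not np.all(np.isfinite(v)):
                raise ValueError(f"index {acc} must hold 20 finite values")
            if self.normalized and not (
                np.isclose(v.min(), 0.0) and np.isclose(v.max(), 1.0)
            ):
                raise ValueError(f"normalized index {acc} must span [0, 1]")

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(self.values)

    def value(self, accession: str, residue: str) -> float:
        return float(self.values[accession][AMINO_ACIDS.index(residue)])


def _remap(raw: tuple[float, ...]) -> np.ndarray:
    by_residue = dict(zip(_AAINDEX_ORDER, raw))
    return np.array([by_residue[aa] for aa in AMINO_ACIDS], dtype=float)


def aaindex_table(normalized: bool = True) -> AAIndexTable:
    """The 8-entry property table, min-max scaled to [0, 1] by default."""
    values: dict[str, np.ndarray] = {}
    for acc in ACCESSIONS:
        v = _remap(_RAW[acc])
        if normalized:
            v = (v - v.min()) / (v.max() - v.min())
        values[acc] = v
    return AAIndexTable(values=values, normalized=normalized)
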