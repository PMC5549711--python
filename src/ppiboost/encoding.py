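"""Physicochemical property channels and per-residue sequence encoding.

Thirteen channels are built in: seven *qualitative* properties, each a
partition of the 20 amino acids into three labelled groups (hydrophobicity,
normalized van der Waals volume, polarity, polarizability, charge, secondary
structure, solvent accessibility), and six *quantitative* per-residue scales
(hydrophobicity H, side-chain volume VSC, polarity P1, polarizability P2,
solvent-accessible surface area SASA, net charge index of side chains NCISC).

A sequence is encoded under a qualitative property by replacing each residue
with its group index (1, 2 or 3), and under a quantitative property by
replacing each residue with the property value standardized to zero mean and
unit standard deviation across the 20 canonical residues:

    P'_{i,j} = (P_{i,j} - mean_j) / sd_j

where the mean and (population) standard deviation are taken over the 20
amino-acid values of scale j, not over the positions of any particular
sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .sequence_io import ALPHABET, ProteinSequence

_ALPHABET_SET = frozenset(ALPHABET)
_RESIDUE_INDEX = {r: i for i, r in enumerate(ALPHABET)}


class PropertyError(ValueError):
    """Raised for malformed property tables (bad partition, degenerate scale)."""


@dataclass(frozen=True)
class QualitativeProperty:
    """A named 3-group partition of the 20 amino acids.

    ``groups`` maps group index (1, 2, 3) to a frozenset of residues; the
    three groups are disjoint and jointly cover the full alphabet.
    """

    name: str
    groups: Mapping[int, frozenset[str]]

    def __post_init__(self) -> None:
        if set(self.groups) != {1, 2, 3}:
            raise PropertyError(f"{self.name}: groups must be indexed 1, 2, 3")
        union: set[str] = set()
        total = 0
        for g in self.groups.values():
            union |= g
            total += len(g)
        if total != 20 or union != _ALPHABET_SET:
            raise PropertyError(
                f"{self.name}: groups must disjointly cover all 20 residues "
                f"(got {total} members, union size {len(union)})"
            )

    def group_of(self, residue: str) -> int:
        for idx, members in self.groups.items():
            if residue in members:
                return idx
        raise PropertyError(f"{self.name}: residue {residue!r} not in any group")


@dataclass(frozen=True)
class QuantitativeProperty:
    """A named per-residue numeric scale with its 20-residue mean and sd."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != _ALPHABET_SET:
            raise PropertyError(
                f"{self.name}: scale must give exactly one value per residue"
            )
        if self.sd == 0.0:
            raise PropertyError(f"{self.name}: degenerate scale (zero sd)")

    @property
    def _array(self) -> np.ndarray:
        return np.array([self.values[r] for r in ALPHABET], dtype=float)

    @property
    def mean(self) -> float:
        return float(self._array.mean())

    @property
    def sd(self) -> float:
        # population sd over the 20 canonical residues
        return float(self._array.std())


@dataclass(frozen=True)
class PropertyTableSet:
    """The ordered collection of qualitative partitions and quantitative scales."""

    qualitative: tuple[QualitativeProperty, ...]
    quantitative: tuple[QuantitativeProperty, ...]

    @property
    def n_encodings(self) -> int:
        """Number of distinct per-protein encodings this table set produces."""
        return len(self.qualitative) + len(self.quantitative)


def _part(name: str, g1: str, g2: str, g3: str) -> QualitativeProperty:
    return QualitativeProperty(
        name=name,
        groups={
            1: frozenset(g1.replace(",", "")),
            2: frozenset(g2.replace(",", "")),
            3: frozenset(g3.replace(",", "")),
        },
    )


_QUALITATIVE = (
    _part("hydrophobicity", "R,K,E,D,Q,N", "G,A,S,T,P,H,Y", "C,L,V,I,M,F,W"),
    _part("vdw_volume", "G,A,S,T,P,D", "N,V,E,C,Q,I,L", "M,H,K,F,R,Y,W"),
    _part("polarity", "L,I,F,W,C,M,V,Y", "P,A,T,G,S", "H,Q,R,K,N,E,D"),
    _part("polarizability", "G,A,S,D,T", "C,P,N,V,E,Q,I,L", "K,M,H,F,R,Y,W"),
    _part("charge", "K,R", "A,N,C,Q,G,H,I,L,M,F,P,S,T,W,Y,V", "D,E"),
    # The source table prints the Strand group as "V,I,T,C,W,F,T" — T twice
    # and Y absent, covering only 19 residues. Amended to Y (the standard CTD
    # strand group), restoring a complete partition.
    _part("secondary_structure", "E,A,L,M,Q,K,R,H", "V,I,Y,C,W,F,T", "G,N,P,S,D"),
    _part("solvent_accessibility", "A,L,F,C,G,I,V,W", "R,K,Q,E,N,D", "M,S,P,T,H,Y"),
)

# Rows: A C D E F G H I K L M N P Q R S T V W Y.
# Columns: H, VSC, P1, P2, SASA, NCISC.
_QUANT_ROWS = {
    "A": (0.62, 27.5, 8.1, 0.046, 1.181, 0.007187),
    "C": (0.29, 44.6, 5.5, 0.128, 1.461, -0.03661),
    "D": (-0.9, 40.0, 13.0, 0.105, 1.587, -0.02382),
    "E": (-0.74, 62.0, 12.3, 0.151, 1.862, -0.006802),
    "F": (1.19, 115.5, 5.2, 0.29, 2.228, 0.037552),
    "G": (0.48, 0.0, 9.0, 0.0, 0.881, 0.179052),
    "H": (-0.4, 79.0, 10.4, 0.23, 2.025, -0.01069),
    "I": (1.38, 93.5, 5.2, 0.186, 1.81, 0.021631),
    "K": (-1.5, 100.0, 11.3, 0.219, 2.258, 0.017708),
    "L": (1.06, 93.5, 4.9, 0.186, 1.931, 0.051672),
    "M": (0.64, 94.1, 5.7, 0.221, 2.034, 0.002683),
    "N": (-0.78, 58.7, 11.6, 0.134, 1.655, 0.005392),
    "P": (0.12, 41.9, 8.0, 0.131, 1.468, 0.239531),
    "Q": (-0.85, 80.7, 10.5, 0.18, 1.932, 0.049211),
    "R": (-2.53, 105.0, 10.5, 0.291, 2.56, 0.043587),
    "S": (-0.18, 29.3, 9.2, 0.062, 1.298, 0.004627),
    "T": (-0.05, 51.3, 8.6, 0.108, 1.525, 0.003352),
    "V": (1.08, 71.5, 5.9, 0.14, 1.645, 0.057004),
    "W": (0.81, 145.5, 5.4, 0.409, 2.663, 0.037977),
    "Y": (0.26, 117.3, 6.2, 0.298, 2.368, 0.0323599),
}

QUANTITATIVE_NAMES = ("H", "VSC", "P1", "P2", "SASA", "NCISC")

_QUANTITATIVE = tuple(
    QuantitativeProperty(
        name=name, values={r: row[j] for r, row in _QUANT_ROWS.items()}
    )
    for j, name in enumerate(QUANTITATIVE_NAMES)
)

_BUILTIN = PropertyTableSet(qualitative=_QUALITATIVE, quantitative=_QUANTITATIVE)


def builtin_property_tables() -> PropertyTableSet:
    """Return the built-in set of 7 qualitative + 6 quantitative properties."""
    return _BUILTIN


def load_property_tables(path: str | Path) -> PropertyTableSet:
    """Load a property-table override file (JSON), merged over the built-ins.

    The file maps property names to either three residue-set strings
    (qualitative, e.g. ``{"charge": ["KR", "ANCQGHILMFPSTWYV", "DE"]}``) or a
    residue->value mapping of 20 entries (quantitative). Properties not named
    keep their built-in definition; new names are appended.
    """
    overrides = json.loads(Path(path).read_text())
    qual = {p.name: p for p in _BUILTIN.qualitative}
    quant = {p.name: p for p in _BUILTIN.quantitative}
    qual_order = [p.name for p in _BUILTIN.qualitative]
    quant_order = [p.name for p in _BUILTIN.quantitative]
    for name, spec in overrides.items():
        if isinstance(spec, list):
            if len(spec) != 3:
                raise PropertyError(f"{name}: expected three residue-set strings")
            prop = _part(name, *spec)
            if name not in qual:
                qual_order.append(name)
            qual[name] = prop
        elif isinstance(spec, dict):
            prop_q = QuantitativeProperty(
                name=name, values={str(k): float(v) for k, v in spec.items()}
            )
            if name not in quant:
                quant_order.append(name)
            quant[name] = prop_q
        else:
            raise PropertyError(f"{name}: unrecognized property definition")
    return PropertyTableSet(
        qualitative=tuple(qual[n] for n in qual_order),
        quantitative=tuple(quant[n] for n in quant_order),
    )


def encode_qualitative(
    seq: ProteinSequence | str, prop: QualitativeProperty
) -> np.ndarray:
    """Encode a sequence as group indices: position i carries the group of s_i."""
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    lookup = np.zeros(len(ALPHABET), dtype=np.int8)
    for idx, members in prop.groups.items():
        for r in members:
            lookup[_RESIDUE_INDEX[r]] = idx
    codes = np.fromiter(
        (_RESIDUE_INDEX[r] for r in residues), dtype=np.intp, count=len(residues)
    )
    return lookup[codes]


def normalize_property_scale(prop: QuantitativeProperty) -> np.ndarray:
    """Standardize a quantitative scale over the 20 canonical residues.

    Returns the 20 normalized values in alphabet order; the result has mean 0
    and (population) sd 1.
    """
    vals = np.array([prop.values[r] for r in ALPHABET], dtype=float)
    sd = vals.std()
    if sd == 0.0:
        raise PropertyError(f"{prop.name}: degenerate scale (zero sd)")
    return (vals - vals.mean()) / sd


def encode_quantitative(
    seq: ProteinSequence | str, prop: QuantitativeProperty | np.ndarray
) -> np.ndarray:
    """Encode a sequence as normalized property values per position.

    ``prop`` may be a :class:`QuantitativeProperty` (normalized internally) or
    a pre-normalized 20-value array in alphabet order.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    scale = (
        prop
        if isinstance(prop, np.ndarray)
        else normalize_property_scale(prop)
    )
    codes = np.fromiter(
        (_RESIDUE_INDEX[r] for r in residues), dtype=np.intp, count=len(residues)
    )
    return scale[codes]
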