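"""Reading and validating protein sequences and labelled interaction pairs.

Sequences come in as FASTA (multi-record, wrapped lines allowed) and are
sanitized to the 20-letter amino-acid alphabet. Interaction pairs are a
delimited table (TSV or CSV, dialect auto-detected) with columns
``id_a``, ``id_b``, ``label`` where label is 0 (non-interacting) or
1 (interacting).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from Bio import SeqIO

#: The 20 canonical amino acids, alphabetical by one-letter code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

#: Ambiguity/non-standard codes rejected under the strict policy.
NON_STANDARD = frozenset("BJOUXZ*")

SanitizePolicy = Literal["strict", "drop-unknown"]


class SequenceError(ValueError):
    """Raised for invalid sequence content or malformed sequence files."""


class PairTableError(ValueError):
    """Raised for malformed or unresolvable interaction-pair tables."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein identified by ``id`` with residues over the 20-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"protein {self.id!r}: empty residue string")
        bad = set(self.residues) - _ALPHABET_SET
        if bad:
            pos = next(
                i for i, r in enumerate(self.residues, start=1) if r in bad
            )
            raise SequenceError(
                f"protein {self.id!r}: non-standard residue "
                f"{self.residues[pos - 1]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class InteractionPair:
    """A labelled protein pair: ``label`` 1 = interacting, 0 = non-interacting."""

    id_a: str
    id_b: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise PairTableError(
                f"pair ({self.id_a}, {self.id_b}): label must be 0 or 1, "
                f"got {self.label!r}"
            )


def sanitize_sequence(
    raw: str,
    policy: SanitizePolicy = "strict",
    *,
    record_id: str = "?",
) -> tuple[str, int]:
    """Uppercase ``raw``, strip whitespace, and resolve non-standard letters.

    Under ``strict`` any letter outside the 20-residue alphabet is an error;
    under ``drop-unknown`` such letters are removed. Returns the clean residue
    string and the number of dropped characters (always 0 under strict).
    Idempotent: sanitizing a sanitized string is a no-op.
    """
    if not raw or not raw.strip():
        raise SequenceError(f"record {record_id!r}: empty sequence")
    cleaned = "".join(raw.split()).upper()
    dropped = 0
    if policy == "strict":
        for i, ch in enumerate(cleaned, start=1):
            if ch not in _ALPHABET_SET:
                raise SequenceError(
                    f"record {record_id!r}: non-standard residue {ch!r} "
                    f"at position {i} (use drop-unknown policy to remove)"
                )
    elif policy == "drop-unknown":
        kept = [ch for ch in cleaned if ch in _ALPHABET_SET]
        dropped = len(cleaned) - len(kept)
        cleaned = "".join(kept)
        if not cleaned:
            raise SequenceError(
                f"record {record_id!r}: sequence empty after dropping "
                f"{dropped} non-standard residue(s)"
            )
    else:
        raise ValueError(f"unknown sanitize policy {policy!r}")
    return cleaned, dropped


def read_fasta(
    path: str | Path, policy: SanitizePolicy = "strict"
) -> list[ProteinSequence]:
    """Read a FASTA file into validated :class:`ProteinSequence` records.

    Residues are sanitized with :func:`sanitize_sequence`; duplicate record
    ids and empty files are rejected with descriptive errors.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        residues, _ = sanitize_sequence(str(rec.seq), policy, record_id=rec.id)
        out.append(ProteinSequence(id=rec.id, residues=residues))
    return out


def write_fasta(
    sequences: Iterable[ProteinSequence], path: str | Path, width: int = 60
) -> None:
    """Write sequences as FASTA with lines wrapped at ``width`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def _sniff_delimiter(sample: str) -> str:
    first = sample.splitlines()[0] if sample else ""
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    raise PairTableError("pair table: could not detect a tab or comma delimiter")


def _looks_like_header(row: Sequence[str]) -> bool:
    # conservative: only a literal label-ish third column marks a header,
    # so a malformed data row still raises instead of being skipped
    return len(row) >= 3 and row[2].strip().lower() in {"label", "class", "y"}


def read_pair_table(
    path: str | Path,
    sequences: Mapping[str, ProteinSequence] | Sequence[ProteinSequence],
) -> list[InteractionPair]:
    """Read a delimited (id_a, id_b, label) table, resolving ids against ``sequences``.

    Tab- or comma-delimited is auto-detected; a header row is skipped if the
    third column is not a 0/1 label. Row order is preserved.
    """
    if not isinstance(sequences, Mapping):
        sequences = {s.id: s for s in sequences}
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise PairTableError(f"{path}: empty pair table")
    delim = _sniff_delimiter(text)
    pairs: list[InteractionPair] = []
    rows = list(csv.reader(text.splitlines(), delimiter=delim))
    start = 1 if rows and _looks_like_header(rows[0]) else 0
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if not row or not any(cell.strip() for cell in row):
            continue
        if len(row) < 3:
            raise PairTableError(
                f"{path}:{lineno}: expected 3 columns (id_a, id_b, label), "
                f"got {len(row)}"
            )
        id_a, id_b, raw_label = (cell.strip() for cell in row[:3])
        if raw_label not in {"0", "1"}:
            raise PairTableError(
                f"{path}:{lineno}: malformed label {raw_label!r} (expected 0 or 1)"
            )
        for pid in (id_a, id_b):
            if pid not in sequences:
                raise PairTableError(
                    f"{path}:{lineno}: unknown protein id {pid!r} "
                    "(not in the sequence set)"
                )
        pairs.append(InteractionPair(id_a=id_a, id_b=id_b, label=int(raw_label)))
    if not pairs:
        raise PairTableError(f"{path}: no pair rows found")
    return pairs


def write_pair_table(
    pairs: Iterable[InteractionPair], path: str | Path, header: bool = True
) -> None:
    """Write pairs as a TSV with columns id_a, id_b, label."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write("id_a\tid_b\tlabel\n")
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.label}\n")
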