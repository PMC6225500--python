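"""Sequence, label and structure input/output.

Reads gapped multi-FASTA alignments (via Biopython), tab-separated
``id<TAB>species`` label tables and Vienna-style dot-bracket structure files,
and assembles them into :class:`AlignedMatrix` objects.  All alignment
coordinates in this package are 1-based and inclusive at both ends.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .alphabet import ALPHABET, normalize_residues


class SeqIOError(ValueError):
    """Malformed sequence, label or structure input."""


@dataclass
class SequenceRecord:
    """A single (possibly gapped) nucleotide sequence with its species label.

    Residues are stored uppercase over the IUPAC alphabet plus ``-``;
    ``U`` is folded to ``T`` on construction.
    """

    id: str
    residues: str
    species: str = ""
    region_tag: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence id must be non-empty")
        if not self.residues:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        self.residues = normalize_residues(self.residues)
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in ALPHABET:
                raise SeqIOError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignedMatrix:
    """An alignment: equal-length records plus an id -> species map."""

    records: list[SequenceRecord]
    label_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise SeqIOError("alignment must contain at least one record")
        n = len(self.records[0])
        bad = [r.id for r in self.records if len(r) != n]
        if bad:
            raise SeqIOError(f"records not all the same length as the first: {bad}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species_present(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            if r.species:
                seen.setdefault(r.species, None)
        return list(seen)

    def records_of(self, species: str) -> list[SequenceRecord]:
        return [r for r in self.records if r.species == species]

    def __len__(self) -> int:
        return len(self.records)


def read_fasta(path: str | Path, region_tag: str = "") -> list[SequenceRecord]:
    """Read a (gapped) FASTA file into validated records.

    The id is the pre-whitespace header token; species labels are *not*
    parsed from headers (use :func:`read_labels`).
    """
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq), region_tag=region_tag)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SeqIOError(f"no FASTA records found in {path}")
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise SeqIOError(f"duplicate sequence id {r.id!r}")
        seen.add(r.id)
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta-2line")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a TSV of ``id<TAB>species`` (no header) into a label map."""
    label_map: dict[str, str] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.rstrip("\r\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise SeqIOError(f"{path}:{lineno}: expected >=2 tab-separated columns")
        seq_id, species = parts[0].strip(), parts[1].strip()
        if seq_id in label_map:
            raise SeqIOError(f"{path}:{lineno}: duplicate id {seq_id!r}")
        label_map[seq_id] = species
    return label_map


def write_labels(label_map: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, species in label_map.items():
            fh.write(f"{seq_id}\t{species}\n")


def build_alignment(
    records: list[SequenceRecord], label_map: dict[str, str] | None = None
) -> AlignedMatrix:
    """Assemble records and labels into an alignment.

    Records without a label get ``species=""`` (treated as queries
    downstream).  Unequal lengths raise with the offending ids.
    """
    label_map = dict(label_map or {})
    n = len(records[0]) if records else 0
    bad = [r.id for r in records if len(r) != n]
    if bad:
        raise SeqIOError(f"records with length differing from the first: {bad}")
    labelled = [
        SequenceRecord(
            id=r.id,
            residues=r.residues,
            species=label_map.get(r.id, ""),
            region_tag=r.region_tag,
        )
        for r in records
    ]
    return AlignedMatrix(records=labelled, label_map=label_map)


def trim_region(alignment: AlignedMatrix, start: int, end: int) -> AlignedMatrix:
    """Extract columns ``start..end`` (1-based, inclusive) into a new alignment."""
    if not (1 <= start <= end <= alignment.n_columns):
        raise SeqIOError(
            f"invalid trim window [{start}, {end}] for a "
            f"{alignment.n_columns}-column alignment (1-based, inclusive)"
        )
    trimmed = [
        SequenceRecord(
            id=r.id,
            residues=r.residues[start - 1 : end],
            species=r.species,
            region_tag=r.region_tag,
        )
        for r in alignment.records
    ]
    return AlignedMatrix(records=trimmed, label_map=dict(alignment.label_map))


def read_dot_bracket(path: str | Path) -> tuple[str, str]:
    """Read a Vienna-style file: a sequence line and a dot-bracket line.

    An optional leading ``>header`` line is skipped.  Returns
    ``(sequence, structure)``; both are validated for equal length and the
    structure for balanced parentheses.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise SeqIOError(f"{path}: expected a sequence line and a structure line")
    sequence, structure = lines[0], lines[1]
    if len(sequence) != len(structure):
        raise SeqIOError(
            f"{path}: sequence length {len(sequence)} != structure length "
            f"{len(structure)}"
        )
    depth = 0
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise SeqIOError(f"{path}: unbalanced ')' at position {pos}")
        elif ch != ".":
            raise SeqIOError(f"{path}: illegal structure character {ch!r} at {pos}")
    if depth != 0:
        raise SeqIOError(f"{path}: {depth} unclosed '(' in structure")
    return sequence, structure
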