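"""Per-species IUPAC consensus profiles and species-specific diagnostic sites.

The consensus of a species at a column is the *union* of every non-gap state
observed in that species (degenerate input residues expand to their sets
first), encoded as the matching IUPAC code — so within-species polymorphism
surfaces as a degenerate code (A/G -> R, C/T -> Y, ...).  A column where the
species shows only gaps is a gap column; a mixed gap/base column keeps the
base set but is flagged.

A column is *species-specific* (diagnostic) for species S when S's state set
is disjoint from the union of every other species' set; a fully gapped
column versus bases counts as disjoint (an indel difference), and a
degenerate code overlapping another species' state is NOT diagnostic.  The
same disjointness rule defines the inter-consensus difference count and
query identification.

:func:`load_uncaria_reference` ships a curated diagnostic-position table for
the ITS region of the 12 Chinese *Uncaria* species (Gouteng and relatives),
stored sparsely over its 31 informative alignment positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .alphabet import GAP, code_for, expand
from .seqio import AlignedMatrix, SequenceRecord


class ConsensusError(ValueError):
    """Inconsistent consensus profiles or malformed consensus tables."""


@dataclass
class ConsensusProfile:
    """One species' consensus: per 1-based position, a state set.

    The empty set denotes a gap column; ``gap_seen`` flags columns where
    some but not all members were gapped.
    """

    species: str
    positions: tuple[int, ...]
    states: tuple[frozenset[str], ...]
    gap_seen: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.states):
            raise ConsensusError("positions and states must align")
        if not self.gap_seen:
            self.gap_seen = tuple(False for _ in self.positions)

    def code(self, i: int) -> str:
        """IUPAC code at column index i (0-based into the profile)."""
        return code_for(self.states[i])

    def codes(self) -> list[str]:
        return [self.code(i) for i in range(len(self.positions))]

    def effective_set(self, i: int) -> frozenset[str]:
        """State set with the gap treated as an explicit extra state."""
        s = self.states[i]
        if not s or self.gap_seen[i]:
            s = s | {GAP}
        return s


@dataclass
class DiagnosticTable:
    """Species-specific sites: rows of (species, 1-based position, code)."""

    rows: list[tuple[str, int, str]]
    reference_species: str | None = None

    def sites_of(self, species: str) -> list[tuple[int, str]]:
        return [(pos, code) for sp, pos, code in self.rows if sp == species]


def build_consensus(
    alignment: AlignedMatrix,
    label_map: dict[str, str],
    species: str,
) -> ConsensusProfile:
    """Union consensus of one species over all alignment columns."""
    members = [
        r for r in alignment.records if label_map.get(r.id, r.species) == species
    ]
    if not members:
        raise ConsensusError(f"no sequences labeled {species!r}")
    n = alignment.n_columns
    states: list[frozenset[str]] = []
    gap_seen: list[bool] = []
    for col in range(n):
        union: frozenset[str] = frozenset()
        gapped = False
        for r in members:
            ch = r.residues[col]
            if ch == GAP:
                gapped = True
            else:
                union = union | expand(ch)
        states.append(union)
        gap_seen.append(gapped and bool(union))
    return ConsensusProfile(
        species=species,
        positions=tuple(range(1, n + 1)),
        states=tuple(states),
        gap_seen=tuple(gap_seen),
    )


def build_all_consensus(
    alignment: AlignedMatrix, label_map: dict[str, str] | None = None
) -> list[ConsensusProfile]:
    label_map = label_map or {r.id: r.species for r in alignment.records}
    species = sorted({s for s in label_map.values() if s})
    return [build_consensus(alignment, label_map, sp) for sp in species]


def _check_same_positions(profiles: list[ConsensusProfile]) -> None:
    ref = profiles[0].positions
    for p in profiles[1:]:
        if p.positions != ref:
            raise ConsensusError(
                f"profiles cover different positions: {p.species!r} differs "
                f"from {profiles[0].species!r}"
            )


def find_species_specific_sites(
    profiles: list[ConsensusProfile],
) -> DiagnosticTable:
    """Columns where one species' states are disjoint from all others' union."""
    if len(profiles) < 2:
        raise ConsensusError("need at least two profiles")
    _check_same_positions(profiles)
    rows: list[tuple[str, int, str]] = []
    n = len(profiles[0].positions)
    for i in range(n):
        sets = [p.effective_set(i) for p in profiles]
        for p, s in zip(profiles, sets):
            rest: frozenset[str] = frozenset()
            for q, t in zip(profiles, sets):
                if q is not p:
                    rest = rest | t
            if not (s & rest):
                rows.append((p.species, p.positions[i], code_for(p.states[i])))
    rows.sort(key=lambda r: (r[0], r[1]))
    return DiagnosticTable(rows=rows)


def _incompatible(a: frozenset[str], b: frozenset[str]) -> bool:
    return not (a & b)


def count_consensus_differences(p1: ConsensusProfile, p2: ConsensusProfile) -> int:
    """Number of incompatible columns between two consensus profiles.

    A column counts when the effective state sets (gap included as a state)
    are disjoint: so gap-vs-base is a difference, and a degenerate code that
    shares a state with the other side is compatible.
    """
    _check_same_positions([p1, p2])
    return sum(
        _incompatible(p1.effective_set(i), p2.effective_set(i))
        for i in range(len(p1.positions))
    )


def differing_positions(p1: ConsensusProfile, p2: ConsensusProfile) -> list[int]:
    """1-based positions of the incompatible columns."""
    _check_same_positions([p1, p2])
    return [
        p1.positions[i]
        for i in range(len(p1.positions))
        if _incompatible(p1.effective_set(i), p2.effective_set(i))
    ]


def identify_query(
    query: SequenceRecord | str,
    profiles: list[ConsensusProfile],
) -> list[tuple[str, int, list[int]]]:
    """Rank species by compatibility with an aligned query sequence.

    Returns (species, n_incompatible_columns, matched_diagnostic_positions)
    sorted by ascending incompatibility, ties broken by more matched
    species-specific sites, then alphabetically.  The query must be aligned
    to the profiles' coordinate system (one residue per profile position).
    """
    _check_same_positions(profiles)
    residues = query.residues if isinstance(query, SequenceRecord) else query
    n = len(profiles[0].positions)
    if len(residues) != n:
        raise ConsensusError(
            f"query length {len(residues)} != profile column count {n}"
        )
    qsets = [
        frozenset({GAP}) if ch == GAP else expand(ch) for ch in residues
    ]
    diagnostics = find_species_specific_sites(profiles)
    scored = []
    for p in profiles:
        n_bad = sum(
            _incompatible(qsets[i], p.effective_set(i)) for i in range(n)
        )
        matched = [
            pos
            for pos, _code in diagnostics.sites_of(p.species)
            if qsets[p.positions.index(pos)] & p.effective_set(
                p.positions.index(pos)
            )
        ]
        scored.append((p.species, n_bad, matched))
    scored.sort(key=lambda t: (t[1], -len(t[2]), t[0]))
    return scored


def read_consensus_table(path: str | Path) -> list[ConsensusProfile]:
    """Read a sparse consensus table (TSV) into profiles.

    Layout: a ``position`` header row of 1-based positions, then one row per
    species of IUPAC codes; ``.`` means "same as the first (reference) row"
    and ``-`` a gap.  The first species row is the reference.
    """
    lines = [
        ln.rstrip("\r\n")
        for ln in Path(path).read_text().splitlines()
        if ln.strip()
    ]
    header = lines[0].split("\t")
    if header[0].lower() != "position":
        raise ConsensusError("first row must start with 'position'")
    positions = tuple(int(x) for x in header[1:])
    profiles: list[ConsensusProfile] = []
    reference: list[str] | None = None
    for ln in lines[1:]:
        parts = ln.split("\t")
        species, codes = parts[0], parts[1:]
        if len(codes) != len(positions):
            raise ConsensusError(
                f"row {species!r}: {len(codes)} codes for "
                f"{len(positions)} positions"
            )
        if reference is None:
            if any(c == "." for c in codes):
                raise ConsensusError("reference (first) row may not contain '.'")
            reference = codes
        resolved = [
            reference[i] if c == "." else c for i, c in enumerate(codes)
        ]
        states = tuple(
            frozenset() if c == GAP else expand(c) for c in resolved
        )
        profiles.append(
            ConsensusProfile(species=species, positions=positions, states=states)
        )
    if len(profiles) < 1:
        raise ConsensusError("no species rows in consensus table")
    return profiles


def write_consensus_table(
    profiles: list[ConsensusProfile], path: str | Path
) -> None:
    """Serialize profiles to the sparse TSV layout (first row = reference)."""
    _check_same_positions(profiles)
    ref = profiles[0]
    with open(path, "w") as fh:
        fh.write(
            "position\t" + "\t".join(str(p) for p in ref.positions) + "\n"
        )
        ref_codes = ref.codes()
        fh.write(ref.species + "\t" + "\t".join(ref_codes) + "\n")
        for p in profiles[1:]:
            codes = [
                "." if c == r and c != GAP else c
                for c, r in zip(p.codes(), ref_codes)
            ]
            fh.write(p.species + "\t" + "\t".join(codes) + "\n")


def load_uncaria_reference() -> list[ConsensusProfile]:
    """The packaged *Uncaria* ITS diagnostic-position consensus table.

    Twelve species over the 31 informative positions of the genus-wide ITS
    alignment (positions numbered from the 5'-TTTCCG anchor);
    *U. rhynchophylloides* is the reference row.
    """
    with resources.as_file(
        resources.files("barcodekit.data").joinpath("uncaria_its_consensus.tsv")
    ) as path:
        return read_consensus_table(path)
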