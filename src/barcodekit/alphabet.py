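"""IUPAC nucleotide alphabet: codes, state sets, and helpers shared across modules.

DNA is stored uppercase with ``U`` normalized to ``T``; ``-`` is the gap
character.  Degenerate (ambiguity) codes map to sets of the four canonical
bases, e.g. ``R`` = A/G, ``Y`` = C/T.
"""

from __future__ import annotations

GAP = "-"

CANONICAL = ("A", "C", "G", "T")

#: IUPAC code -> set of canonical bases
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "M": frozenset("AC"),
    "K": frozenset("GT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: set of canonical bases -> IUPAC code
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

#: every residue character accepted in aligned input
ALPHABET = frozenset(IUPAC_SETS) | {GAP}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def normalize_residues(raw: str) -> str:
    """Uppercase and fold RNA onto DNA (U -> T)."""
    return raw.upper().replace("U", "T")


def expand(residue: str) -> frozenset[str]:
    """State set of a single residue; the gap expands to the empty set."""
    if residue == GAP:
        return frozenset()
    try:
        return IUPAC_SETS[residue]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {residue!r}") from None


def code_for(states: frozenset[str] | set[str]) -> str:
    """IUPAC code for a set of canonical bases; the empty set encodes a gap."""
    states = frozenset(states)
    if not states:
        return GAP
    try:
        return CODE_FOR_SET[states]
    except KeyError:
        raise ValueError(f"not a set of canonical bases: {sorted(states)}") from None
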