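"""ITS2 secondary-structure pair tables and compensatory base change (CBC)
counting.

A CBC between two aligned sequences at a paired structural position (i, j)
means *both* partners changed while canonical pairing (Watson-Crick A-U/G-C
plus the G-U wobble) is preserved on both sides; a hemi-CBC changes exactly
one partner.  CBCs in the ITS2 helices correlate with sexual incompatibility
and have been proposed as a species-distinctness indicator.

A single shared (consensus) structure is applied to every sequence of the
alignment; pairs where either sequence carries a gap or a non-pairing
residue combination are skipped, not counted.  Residues are compared as RNA
(T displayed/treated as U) inside this module only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WATSON_CRICK = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE = frozenset({("G", "U"), ("U", "G")})


class StructureError(ValueError):
    pass


@dataclass
class PairedStructure:
    """A sequence with its set of 1-based base-pair coordinates (i < j)."""

    sequence: str
    pairs: set[tuple[int, int]]
    source: str = ""


@dataclass
class CBCReport:
    pair_of_ids: tuple[str, str]
    n_cbc: int
    n_hemi_cbc: int
    detail: list[tuple[int, int, str, str, str]] = field(default_factory=list)
    n_skipped_pairs: int = 0


def pair_table(structure: str) -> set[tuple[int, int]]:
    """Matching-parenthesis pairs of a dot-bracket string (1-based, i < j)."""
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"illegal character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unclosed '(' at position {stack[-1]}")
    return pairs


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _canonical(a: str, b: str, allow_wobble: bool) -> bool:
    if (a, b) in WATSON_CRICK:
        return True
    return allow_wobble and (a, b) in WOBBLE


def count_cbc(
    seq_a: str,
    seq_b: str,
    shared_pairs: set[tuple[int, int]],
    id_a: str = "a",
    id_b: str = "b",
    allow_wobble: bool = True,
) -> CBCReport:
    """CBC / hemi-CBC counts between two aligned sequences on a shared
    structure.

    A pair contributes only when both sequences pair canonically at (i, j);
    gaps or non-pairing residues skip the pair.
    """
    if len(seq_a) != len(seq_b):
        raise StructureError("sequences must be aligned to equal length")
    a, b = _to_rna(seq_a), _to_rna(seq_b)
    n = len(a)
    detail: list[tuple[int, int, str, str, str]] = []
    n_cbc = n_hemi = n_skip = 0
    for i, j in sorted(shared_pairs):
        if not (1 <= i < j <= n):
            raise StructureError(f"pair ({i}, {j}) out of range for length {n}")
        ra = (a[i - 1], a[j - 1])
        rb = (b[i - 1], b[j - 1])
        if not _canonical(*ra, allow_wobble) or not _canonical(*rb, allow_wobble):
            n_skip += 1
            continue
        changed = (ra[0] != rb[0]) + (ra[1] != rb[1])
        if changed == 2:
            n_cbc += 1
            detail.append((i, j, "".join(ra), "".join(rb), "cbc"))
        elif changed == 1:
            n_hemi += 1
            detail.append((i, j, "".join(ra), "".join(rb), "hemi"))
    return CBCReport(
        pair_of_ids=(id_a, id_b),
        n_cbc=n_cbc,
        n_hemi_cbc=n_hemi,
        detail=detail,
        n_skipped_pairs=n_skip,
    )


def cbc_matrix(alignment, shared_pairs: set[tuple[int, int]]):
    """Symmetric matrix of pairwise CBC counts over an alignment.

    Returns (ids, counts) with ``counts`` an integer numpy array.
    """
    ids = alignment.ids
    seqs = [r.residues for r in alignment.records]
    n = len(ids)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            rep = count_cbc(
                seqs[i], seqs[j], shared_pairs, id_a=ids[i], id_b=ids[j]
            )
            counts[i, j] = counts[j, i] = rep.n_cbc
    return ids, counts
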