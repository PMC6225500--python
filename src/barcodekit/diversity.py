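"""Haplotype and nucleotide diversity, site counts and GC content.

Haplotype (gene) diversity follows Nei's unbiased estimator
h = n(1 - sum p_i^2)/(n - 1) with its standard sampling variance; nucleotide
diversity pi is the mean pairwise per-site p-distance within a group
(pairwise deletion of gap/ambiguous sites), with the standard sampling
variance for the no-recombination case.  Degenerate residues count as
missing for site counts and pi; for GC content the S (G/C) code counts
toward GC and all other ambiguity codes are excluded entirely.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .alphabet import CANONICAL
from .distances import _pair_counts
from .seqio import AlignedMatrix


@dataclass
class DiversityStats:
    species: str
    n: int
    n_haplotypes: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float


def collapse_haplotypes(sequences: list[str]) -> list[int]:
    """Multiset of haplotype counts; identity is full-column, gaps included."""
    if not sequences:
        raise ValueError("need at least one sequence")
    n = len(sequences[0])
    if any(len(s) != n for s in sequences):
        raise ValueError("sequences must be aligned to equal length")
    return sorted(Counter(s.upper() for s in sequences).values(), reverse=True)


def haplotype_diversity(counts: list[int]) -> tuple[float, float]:
    """(h, sd) for a haplotype count multiset.

    h = n(1 - sum p^2)/(n-1); the variance is Nei's sampling variance for
    gene diversity:
    V = 2/(n(n-1)) [ 2(n-2)(sum p^3 - (sum p^2)^2) + sum p^2 - (sum p^2)^2 ].
    """
    n = sum(counts)
    if n <= 1:
        return 0.0, 0.0
    p2 = sum((c / n) ** 2 for c in counts)
    p3 = sum((c / n) ** 3 for c in counts)
    h = n * (1.0 - p2) / (n - 1)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (p3 - p2 * p2) + p2 - p2 * p2
    )
    return h, math.sqrt(max(var, 0.0))


def nucleotide_diversity(sequences: list[str]) -> tuple[float, float]:
    """(pi, sd): mean pairwise per-site p-distance within a group.

    Pairwise deletion; a pair with zero comparable sites is skipped.  The
    variance is the standard sampling approximation
    V = (n+1)/(3(n-1)L) pi + 2(n^2+n+3)/(9n(n-1)) pi^2
    with L the mean number of comparable sites per pair.
    """
    n = len(sequences)
    if n < 2:
        return 0.0, 0.0
    dists: list[float] = []
    overlaps: list[int] = []
    for i in range(n):
        for j in range(i + 1, n):
            comp, ts, tv = _pair_counts(sequences[i], sequences[j])
            if comp > 0:
                dists.append((ts + tv) / comp)
                overlaps.append(comp)
    if not dists:
        return 0.0, 0.0
    pi = sum(dists) / len(dists)
    L = sum(overlaps) / len(overlaps)
    var = ((n + 1) / (3.0 * (n - 1) * L)) * pi + (
        2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    ) * pi * pi
    return pi, math.sqrt(max(var, 0.0))


def site_counts(alignment: AlignedMatrix) -> tuple[int, int]:
    """(variable, parsimony-informative) column counts.

    Gaps and degenerate codes are treated as missing.  A column is variable
    with >=2 distinct canonical states; parsimony-informative when >=2
    states each occur in >=2 sequences.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 records")
    n_var = 0
    n_pi = 0
    canon = set(CANONICAL)
    for col in range(alignment.n_columns):
        counts = Counter(
            r.residues[col]
            for r in alignment.records
            if r.residues[col] in canon
        )
        if len(counts) >= 2:
            n_var += 1
            if sum(1 for c in counts.values() if c >= 2) >= 2:
                n_pi += 1
    return n_var, n_pi


def gc_content(residues: str) -> float:
    """Percent G+C among unambiguous residues (S = G/C counts as GC)."""
    residues = residues.upper()
    gc = sum(residues.count(b) for b in "GCS")
    total = sum(residues.count(b) for b in "ACGTS")
    if total == 0:
        raise ValueError("no unambiguous residues (all gaps or ambiguity codes)")
    return 100.0 * gc / total


def species_diversity(
    alignment: AlignedMatrix, species: str
) -> DiversityStats:
    """Per-species diversity row (haplotypes, h, pi with SDs)."""
    seqs = [r.residues for r in alignment.records_of(species)]
    if not seqs:
        raise ValueError(f"no sequences labeled {species!r}")
    counts = collapse_haplotypes(seqs)
    h, h_sd = haplotype_diversity(counts)
    pi, pi_sd = nucleotide_diversity(seqs)
    return DiversityStats(
        species=species,
        n=len(seqs),
        n_haplotypes=len(counts),
        h=h,
        h_sd=h_sd,
        pi=pi,
        pi_sd=pi_sd,
    )


def diversity_table(alignment: AlignedMatrix) -> list[DiversityStats]:
    """Per-species rows plus an all-sequences summary row."""
    rows = [
        species_diversity(alignment, sp) for sp in sorted(alignment.species_present)
    ]
    all_seqs = [r.residues for r in alignment.records]
    counts = collapse_haplotypes(all_seqs)
    h, h_sd = haplotype_diversity(counts)
    pi, pi_sd = nucleotide_diversity(all_seqs)
    rows.append(
        DiversityStats(
            species="ALL",
            n=len(all_seqs),
            n_haplotypes=len(counts),
            h=h,
            h_sd=h_sd,
            pi=pi,
            pi_sd=pi_sd,
        )
    )
    return rows
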