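"""Synthetic multi-species barcode alignments with known ground truth.

The generator emulates a typical nuclear-ribosomal (ITS-like) barcode study:
a dozen species clusters, a few hundred aligned columns, within-species
divergence a few tenths of a percent and between-species divergence a few
percent, occasional whole-species indel columns, and planted diagnostic
sites that must surface downstream as species-specific consensus states.

The substitution process is deliberately simple: a single round of per-site
independent mutation from an ancestor, split into transitions and
transversions with ratio ``kappa``.  At the <=5% divergences simulated here
multiple hits are negligible, so expected p-distances are closed-form:
individuals sit ~``intra_divergence/2`` from their species ancestor, hence
~``intra_divergence`` from each other, and species ancestors sit
~``inter_divergence`` apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import CANONICAL, TRANSITION_PARTNER
from .seqio import AlignedMatrix, SequenceRecord, build_alignment


class SimulationError(ValueError):
    """Unsatisfiable simulation parameters."""


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults mirror the barcode regime above.

    individuals_per_species may be a single count (applied to every species)
    or one count per species.
    """

    n_species: int = 12
    individuals_per_species: int | list[int] = 4
    n_columns: int = 680
    intra_divergence: float = 0.003
    inter_divergence: float = 0.03
    kappa: float = 2.0
    n_diagnostic_sites_per_species: int = 1
    indel_column_rate: float = 0.01
    gc_content: float = 0.62
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.intra_divergence < self.inter_divergence <= 0.75):
            raise SimulationError(
                "require 0 <= intra_divergence < inter_divergence <= 0.75"
            )
        if self.kappa <= 0:
            raise SimulationError("kappa must be positive")
        if self.n_species < 1 or self.n_columns < 1:
            raise SimulationError("counts must be positive")
        if isinstance(self.individuals_per_species, int):
            self.individuals_per_species = [
                self.individuals_per_species
            ] * self.n_species
        if len(self.individuals_per_species) != self.n_species:
            raise SimulationError(
                "individuals_per_species must have one entry per species"
            )
        if any(k < 1 for k in self.individuals_per_species):
            raise SimulationError("each species needs >=1 individual")
        if not (0 <= self.indel_column_rate < 1):
            raise SimulationError("indel_column_rate must be in [0, 1)")
        n_planted = self.n_species * self.n_diagnostic_sites_per_species
        if n_planted > self.n_columns:
            raise SimulationError(
                f"cannot plant {n_planted} diagnostic sites in "
                f"{self.n_columns} columns"
            )


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset.

    ``planted_diagnostic_sites`` holds (species, 1-based column, state)
    triples; the planted state is absent from every other species at that
    column and the column is shielded from further mutation.
    """

    ancestral_sequences: dict[str, str]
    planted_diagnostic_sites: list[tuple[str, int, str]]
    label_map: dict[str, str]
    indel_columns: dict[int, str] = field(default_factory=dict)


_BASE_IDX = {b: i for i, b in enumerate(CANONICAL)}
_TS_IDX = np.array([_BASE_IDX[TRANSITION_PARTNER[b]] for b in CANONICAL])
# the two transversion alternatives for each base, index-encoded
_TV_IDX = np.array(
    [
        [j for j in range(4) if j != i and j != _TS_IDX[i]]
        for i in range(4)
    ]
)


def _mutate(
    seq: np.ndarray,
    rate: float,
    kappa: float,
    rng: np.random.Generator,
    protected: np.ndarray,
) -> np.ndarray:
    """One round of per-site mutation at probability ``rate`` per site.

    A mutated site becomes a transition with probability kappa/(kappa+1),
    otherwise one of the two transversions uniformly.  ``protected`` columns
    never mutate.
    """
    out = seq.copy()
    hit = (rng.random(seq.size) < rate) & ~protected
    idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return out
    is_ts = rng.random(idx.size) < kappa / (kappa + 1.0)
    ts_sites = idx[is_ts]
    out[ts_sites] = _TS_IDX[seq[ts_sites]]
    tv_sites = idx[~is_ts]
    pick = rng.integers(0, 2, size=tv_sites.size)
    out[tv_sites] = _TV_IDX[seq[tv_sites], pick]
    return out


def simulate_dataset(
    params: SimulationParams,
) -> tuple[AlignedMatrix, SimulationTruth]:
    """Generate one labeled alignment plus its ground truth.

    Deterministic for a fixed ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    L = params.n_columns
    p = params

    # root sequence, GC-weighted
    probs = np.array(
        [
            (1 - p.gc_content) / 2,  # A
            p.gc_content / 2,  # C
            p.gc_content / 2,  # G
            (1 - p.gc_content) / 2,  # T
        ]
    )
    root = rng.choice(4, size=L, p=probs)

    species_names = [f"species_{k + 1:02d}" for k in range(p.n_species)]

    # diagnostic columns: pairwise distinct across all species
    n_planted = p.n_species * p.n_diagnostic_sites_per_species
    planted_cols = rng.choice(L, size=n_planted, replace=False)
    protected = np.zeros(L, dtype=bool)
    protected[planted_cols] = True

    # species ancestors: one round of mutation from the root at inter/2 per
    # site, so two ancestors sit ~inter apart
    ancestors = {
        name: _mutate(root, p.inter_divergence / 2, p.kappa, rng, protected)
        for name in species_names
    }

    # plant diagnostic sites: the target species gets a state no other
    # species carries at that column (all others are reset to the root state)
    planted: list[tuple[str, int, str]] = []
    for k, name in enumerate(species_names):
        cols = planted_cols[
            k * p.n_diagnostic_sites_per_species : (k + 1)
            * p.n_diagnostic_sites_per_species
        ]
        for c in cols:
            base = root[c]
            for other in species_names:
                ancestors[other][c] = base
            state = _TS_IDX[base]  # any state != base works; use the transition
            ancestors[name][c] = state
            planted.append((name, int(c) + 1, CANONICAL[state]))

    # whole-species gap columns (outside planted columns)
    free_cols = np.setdiff1d(np.arange(L), planted_cols)
    n_indel = int(round(p.indel_column_rate * L))
    n_indel = min(n_indel, free_cols.size)
    indel_cols = rng.choice(free_cols, size=n_indel, replace=False)
    gap_species = rng.integers(0, p.n_species, size=n_indel)
    indel_map = {
        int(c) + 1: species_names[s] for c, s in zip(indel_cols, gap_species)
    }

    # individuals: one round of mutation from the ancestor at intra/2 per site
    records: list[SequenceRecord] = []
    label_map: dict[str, str] = {}
    for k, name in enumerate(species_names):
        anc = ancestors[name]
        for i in range(p.individuals_per_species[k]):
            ind = _mutate(anc, p.intra_divergence / 2, p.kappa, rng, protected)
            residues = np.array([CANONICAL[b] for b in ind], dtype="<U1")
            for col_1b, sp in indel_map.items():
                if sp == name:
                    residues[col_1b - 1] = "-"
            seq_id = f"{name}_ind{i + 1:02d}"
            records.append(
                SequenceRecord(
                    id=seq_id, residues="".join(residues), species=name
                )
            )
            label_map[seq_id] = name

    truth = SimulationTruth(
        ancestral_sequences={
            name: "".join(CANONICAL[b] for b in anc)
            for name, anc in ancestors.items()
        },
        planted_diagnostic_sites=sorted(planted, key=lambda t: (t[0], t[1])),
        label_map=label_map,
        indel_columns=indel_map,
    )
    return build_alignment(records, label_map), truth


def plant_degenerate_polymorphism(
    alignment: AlignedMatrix,
    species: str,
    column: int,
    states: set[str],
) -> AlignedMatrix:
    """Force a within-species polymorphism at one column.

    The species' individuals are reassigned states from ``states`` so that
    every state occurs at least once; downstream the species consensus at
    that column becomes the corresponding degenerate IUPAC code.
    """
    states_sorted = sorted(states)
    if len(states_sorted) < 2:
        raise SimulationError("a polymorphism needs at least two states")
    if not set(states_sorted) <= set(CANONICAL):
        raise SimulationError(f"states must be canonical bases, got {states_sorted}")
    members = alignment.records_of(species)
    if len(members) < len(states_sorted):
        raise SimulationError(
            f"species {species!r} has {len(members)} individuals, fewer than "
            f"{len(states_sorted)} states to plant"
        )
    if not (1 <= column <= alignment.n_columns):
        raise SimulationError(f"column {column} out of range")
    assigned = {
        m.id: states_sorted[i % len(states_sorted)] for i, m in enumerate(members)
    }
    new_records = []
    for r in alignment.records:
        if r.id in assigned:
            res = r.residues[: column - 1] + assigned[r.id] + r.residues[column:]
            r = SequenceRecord(
                id=r.id, residues=res, species=r.species, region_tag=r.region_tag
            )
        new_records.append(r)
    return AlignedMatrix(records=new_records, label_map=dict(alignment.label_map))
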