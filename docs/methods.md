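# Methods

This note documents the models, estimators and numerical conventions used
by `barcodekit`, and the design choices made where more than one defensible
convention exists.

## Coordinates and alphabet

All alignment coordinates are 1-based and inclusive at both ends (so
`trim_region(aln, s, e)` keeps `e − s + 1` columns). Sequences are stored
uppercase over the IUPAC nucleotide alphabet plus `-`; RNA input is folded
onto DNA (`U → T`) at the boundary and re-displayed as RNA only inside the
structure module. Sequence ids are the pre-whitespace FASTA header token;
species labels come exclusively from the id → species TSV, never from
headers, because headers in public-database dumps are unreliable.

## Distances

Two models are provided and the choice is always explicit, because the two
serve different roles in a barcoding study: the uncorrected *p*-distance
(proportion of differing comparable sites) for barcoding-gap histograms,
and the Kimura 2-parameter distance for discrimination and trees:

d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),

with P and Q the transition and transversion proportions. Comparable sites
are those where **both** residues are canonical A/C/G/T — gaps and
degenerate codes are removed pair by pair ("pairwise deletion"). A pair
with fewer comparable sites than `min_overlap` (default 100 bp) or with a
non-positive K2P log argument (saturation) is *undefined*: it is stored as
NaN and propagated, never replaced by a sentinel value. Undefined pairs are
excluded from means and thresholds; in discrimination they behave as
non-matches; tree building refuses them outright and directs the user to
complete deletion. Distances are stored as proportions; reports print
percent with 2 decimals.

The tree module uses a different site-filter — *complete deletion*, which
removes every column containing any gap or degenerate residue in any
sequence — because distance-based trees should be built on a single shared
set of columns so that all pairwise distances are estimated from the same
data. Both filters are exposed; they are deliberately not interchangeable
defaults.

## Best Match / Best Close Match

Discrimination is leave-one-out: each sequence in turn is a query against
all others. The nearest set contains **every** sequence whose distance
equals the minimum exactly (no epsilon); a mixed-species nearest set is
*ambiguous*. Rounding-before-comparison variants exist in the wild, but
exact ties are the only convention that is order-independent and
reproducible, so that is what is implemented.

The BCM threshold is rank-based: the smallest intraspecific distance v such
that at least 95 % (configurable) of all intraspecific distances are ≤ v —
i.e. the value at the ⌈0.95·n⌉-th rank of the sorted list, with no
interpolation. Interpolated percentile definitions give systematically
different thresholds on small samples and are not used. Singleton species
are retained as queries even though they can never be scored *correct*
(there is no conspecific to match); excluding them would overstate marker
performance. Queries with zero defined distances are tallied separately as
*unmatchable* under BM rather than folded into *incorrect*; under BCM they
fall in *no match* with every other thresholded-out query, which keeps the
four BCM percentages summing to 100.

## Consensus profiles and diagnostic sites

The consensus of a species at a column is the **union** of all states
observed in that species (degenerate input residues expand to their state
sets first), encoded as the matching IUPAC code. Union — not majority rule
— is the only consensus consistent with using degenerate codes to represent
within-species polymorphism: a site where some individuals carry A and
others G must read R.

Disjointness of state sets defines everything downstream:

- a column is **species-specific** for S iff S's set shares no state with
  the union of all other species' sets (so K = {G,T} against a T elsewhere
  is *not* diagnostic);
- two consensus profiles **differ** at a column iff their sets are
  disjoint, with the gap treated as an explicit extra state — so gap versus
  base is a difference (an indel), gap versus gap is identity, and a column
  where one species reads Y = {C,T} and another T is compatible;
- a query residue is **incompatible** with a species at a column iff its
  state set is disjoint from the species' set; queries are ranked by
  ascending incompatible-column count, ties broken by more matched
  species-specific sites, then alphabetically.

Mixed gap/base columns within one species keep the base set plus a gap
flag, and the flagged gap participates in compatibility tests; fully gapped
columns are pure gap. Whether diagnostic sites should additionally be
required to be non-degenerate on the target species' side is a genuinely
open convention; the disjointness rule is used uniformly here, and
degenerate-but-disjoint sites are visible as such in the output (their code
is printed).

The packaged *Uncaria* ITS table stores the 12 species' consensus states
sparsely over the 31 informative positions of the genus-wide alignment
(numbering anchored at the 5′-TTTCCG motif), with the
*U. rhynchophylloides* consensus as the reference row and `.` denoting
identity with it. Two internal consistency checks are kept as acceptance
tests: *U. sinensis* differs from the reference at exactly the six sites
118/152/247/447/493/580, and *U. yunnanensis* differs from *U. lanosa* at
exactly one site (the 602 gap/T insertion), the 611 Y-vs-T column being
compatible.

## Diversity statistics

Haplotype identity is full-column string identity including gaps (an
optional flag excludes gap columns; default off, since different programs
disagree and the choice must be the user's). Haplotype (gene) diversity is
Nei's unbiased estimator h = n(1 − Σp²)/(n − 1) with sampling variance

V(h) = 2/(n(n−1)) · [ 2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)² ].

Nucleotide diversity π is the mean pairwise per-site p-distance within the
group (pairwise deletion), with the standard sampling approximation

V(π) = (n+1)/(3(n−1)L) · π + 2(n²+n+3)/(9n(n−1)) · π²,

L being the mean number of comparable sites per pair. Published tables of
h ± SD computed with other software are often not reproducible from any
stated estimator (the partition of individuals into haplotypes and the
variance formula both vary between programs), so no external h/π values are
asserted anywhere; the estimators above are documented and tested against
hand-computed examples instead.

Site counts treat gaps and degenerate residues as missing: a column is
variable with ≥ 2 distinct canonical states, parsimony-informative when
≥ 2 states each occur in ≥ 2 sequences. GC content counts G, C and S (= G
or C, either way a G/C pair) over the denominator A/C/G/T/S; all other
ambiguity codes are excluded from both numerator and denominator because
their GC status is undefined.

## Neighbor joining and bootstrap

NJ is the standard Saitou–Nei agglomeration with the rate-corrected
criterion Q(i,j) = (m−2)·d(i,j) − r_i − r_j and the usual two-point branch
lengths. Determinism over floating-point coincidences: taxa are sorted
lexicographically before agglomeration, tie candidates are canonicalized to
the upper triangle (Q is only float-symmetric), and the smallest (i,j)
index pair wins. Negative branch lengths are clamped to zero with the
deficit moved to the sibling edge — the standard repair — and the raw
lengths are retained on each edge for diagnostics. The implementation
recovers any additive (four-point) matrix exactly; this is asserted in the
test suite on random additive matrices, and the topology is cross-checked
against an independent NJ implementation.

Bootstrap resamples columns **of the complete-deletion alignment** with
replacement (resampling the original and re-deleting would change the
column universe per replicate); support for each bipartition of the
full-data tree is the percentage of successful replicate trees containing
it. Replicates whose matrix has an undefined pair are skipped and counted.
Trees are unrooted; an outgroup only re-roots the drawing and never changes
bipartitions, so monophyly queries are performed directly on bipartitions.
Agreement of exact topology with other NJ programs on real data is not
promised — tie-breaking and negative-branch policies differ between
implementations.

## CBC counting

Canonical pairs are Watson–Crick plus the G·U wobble (a strict
Watson–Crick flag exists, since some workflows exclude wobble). CBCs are
evaluated on one shared consensus structure applied to both sequences,
matching the common consensus-structure workflow; per-sequence individual
structures are consumed, not predicted — minimum-free-energy folding is out
of scope and dot-bracket files from any folding server can be fed in. A
pair is counted as CBC when both partners differ and both sequences pair
canonically, hemi-CBC when exactly one partner differs; pairs with gaps or
non-pairing residue combinations in either sequence are skipped (ITS2
alignments contain indels, so erroring would be wrong) and the skip count
is reported.

## Synthetic data generator

The generator emulates a typical ITS-like barcode study: K species
clusters (default 12), a few individuals per species (default 4), ~680
aligned columns, GC-weighted root composition (default 0.62), within- and
between-species divergence defaulting to 0.3 % and 3 %, occasional
whole-species gap columns (default 1 % of columns), and planted diagnostic
sites (default one per species).

The substitution process is a single round of per-site independent
mutation from an ancestor — no multiple hits — which keeps expectations
closed-form and is adequate at the ≤ 5 % divergences simulated: species
ancestors mutate from a common root at rate inter/2 per site (so two
ancestors sit ≈ inter apart), individuals mutate from their ancestor at
intra/2 (so two conspecifics sit ≈ intra apart). A mutated site becomes a
transition with probability κ/(κ+1) (default κ = 2), else one of the two
transversions uniformly. Planted diagnostic sites overwrite the ancestors
(target species gets a state carried by no other species at that column)
and are shielded from further mutation so they are recoverable by
construction; indel columns are whole-species gap blocks. Everything is
deterministic under a fixed seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: coalescent genealogical structure within species,
rate heterogeneity across sites, multiple hits and back-mutation,
realistic indel evolution, paralogous ITS copies, and alignment error. The
parameter-recovery tests validate the estimators against the generator's
own closed-form expectations, not against biology.

## Problem sizes and stochastic tails

The acceptance-level parameter-recovery study uses 200 replicate datasets
of 12 species × 4 individuals × 680 columns for the mean-distance
recovery (tolerance ± 20 %), and a single fixed-seed dataset with 1000
bootstrap replicates for discrimination, monophyly and diagnostic-site
recovery — sizes chosen so the whole suite runs comfortably on one CPU.

Two quantities have known stochastic tails across seeds at these study
conditions: (i) the BCM *no match* class is occasionally (order 20 % of
seeds) non-empty, because the rank-based threshold sits at ≈ 5 mutated
sites and a query with an unusually mutated private branch can exceed it
to every conspecific; (ii) the minimum per-species bootstrap support
occasionally dips below 95 when a species ancestor happens to carry few
private substitutions. Both are properties of the simulated regime, not
implementation artifacts; the fixed-seed acceptance tests document the
expected behavior and `scripts/acceptance.py` reports whatever the given
seed actually produces.

## Known limitations

- ITS2 extraction from full ITS sequences is coordinate-based trimming
  only; HMM-based annotation of ITS2 boundaries is out of scope, so
  published boundary choices can only be reproduced if the coordinates are
  known.
- Maximum-likelihood and Bayesian tree inference are out of scope; the
  Newick/FASTA outputs are suitable inputs for external tools.
- The distance models are p and K2P only (no Gamma correction, no T92/GTR).
- Queries must be pre-aligned to the consensus profiles' coordinate
  system; automatic alignment of raw queries is not provided.
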