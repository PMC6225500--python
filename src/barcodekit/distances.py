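"""Pairwise sequence distances: uncorrected p and Kimura 2-parameter (K2P).

Sites where either sequence carries a gap or a degenerate code are excluded
pair-by-pair ("pairwise deletion").  A pair with fewer comparable sites than
``min_overlap`` — or a saturated K2P log argument — is *undefined* and is
stored as NaN, never silently replaced by a large value.

The K2P distance separates the transition proportion P from the transversion
proportion Q over the comparable sites:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import CANONICAL
from .seqio import AlignedMatrix

DEFAULT_MIN_OVERLAP = 100

_ENCODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(CANONICAL):
    _ENCODE[ord(_b)] = _i


def encode_alignment(sequences: list[str]) -> np.ndarray:
    """Encode residue strings to an int8 matrix: A,C,G,T -> 0..3, else -1.

    Gaps and degenerate codes share the -1 "not comparable" value.
    """
    arr = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    return _ENCODE[arr].reshape(len(sequences), -1)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair overlap counts.

    ``values`` holds proportions (not percent); undefined entries are NaN.
    """

    ids: list[str]
    values: np.ndarray
    overlaps: np.ndarray
    model: str

    @property
    def undefined_pairs(self) -> set[tuple[str, str]]:
        out = set()
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.values[i, j]):
                    out.add((self.ids[i], self.ids[j]))
        return out

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", na_rep="NA")


@dataclass
class GapSummary:
    """Histogram summary of the barcoding gap (intra vs inter distances)."""

    intra_distances: list[float]
    inter_distances: list[float]
    bins: np.ndarray
    intra_counts: np.ndarray
    inter_counts: np.ndarray
    overlap_flag: bool


def site_pair_filter(a: str, b: str) -> list[int]:
    """1-based columns where *both* residues are canonical A/C/G/T."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    x, y = encode_alignment([a, b])
    return [int(i) + 1 for i in np.nonzero((x >= 0) & (y >= 0))[0]]


def _pair_counts(a: str, b: str) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) for one aligned pair."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    x, y = encode_alignment([a, b])
    comp = (x >= 0) & (y >= 0)
    diff = comp & (x != y)
    # purines encode to even values (A=0, G=2)
    same_class = (x % 2) == (y % 2)
    ts = int(np.count_nonzero(diff & same_class))
    tv = int(np.count_nonzero(diff & ~same_class))
    return int(np.count_nonzero(comp)), ts, tv


def p_distance(a: str, b: str, min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """Uncorrected proportion of differing comparable sites (NaN if undefined)."""
    n, ts, tv = _pair_counts(a, b)
    if n < min_overlap:
        return math.nan
    return (ts + tv) / n


def k2p_distance(a: str, b: str, min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """Kimura 2-parameter distance (NaN if undefined or saturated)."""
    n, ts, tv = _pair_counts(a, b)
    if n < min_overlap:
        return math.nan
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # avoid -0.0


def _counts_from_encoded(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-pair (overlap, transition, transversion) count matrices."""
    valid = X >= 0
    overlap = valid.astype(np.int32) @ valid.T.astype(np.int32)
    diff = (X[:, None, :] != X[None, :, :]) & valid[:, None, :] & valid[None, :, :]
    same_class = (X % 2)[:, None, :] == (X % 2)[None, :, :]
    ts = np.count_nonzero(diff & same_class, axis=2)
    tv = np.count_nonzero(diff & ~same_class, axis=2)
    return overlap, ts, tv


def matrix_from_encoded(
    X: np.ndarray, model: str = "k2p", min_overlap: int = DEFAULT_MIN_OVERLAP
) -> tuple[np.ndarray, np.ndarray]:
    """(distance, overlap) arrays from an encoded alignment; NaN = undefined.

    Fast path shared by :func:`pairwise_matrix` and the bootstrap loop.
    """
    overlap, ts, tv = _counts_from_encoded(X)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.where(overlap > 0, overlap, 1)
        P = ts / denom
        Q = tv / denom
        if model == "p":
            d = P + Q
        elif model == "k2p":
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            d = np.where(
                (w1 > 0) & (w2 > 0),
                -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
                - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
                np.nan,
            )
        else:
            raise ValueError(f"unknown distance model {model!r}")
    d = np.where(overlap >= min_overlap, d, np.nan) + 0.0  # -0.0 -> 0.0
    np.fill_diagonal(d, 0.0)
    return d, overlap


def pairwise_matrix(
    alignment: AlignedMatrix,
    model: str = "k2p",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """All-pairs distance matrix for an alignment."""
    if len(alignment) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    X = encode_alignment([r.residues for r in alignment.records])
    d, overlap = matrix_from_encoded(X, model=model, min_overlap=min_overlap)
    return DistanceMatrix(
        ids=list(alignment.ids), values=d, overlaps=overlap, model=model
    )


def partition_intra_inter(
    matrix: DistanceMatrix, label_map: dict[str, str]
) -> tuple[list[float], list[float]]:
    """Split defined distances into conspecific and heterospecific lists."""
    intra: list[float] = []
    inter: list[float] = []
    for seq_id in matrix.ids:
        if seq_id not in label_map or not label_map[seq_id]:
            raise ValueError(f"unlabeled sequence id {seq_id!r}")
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            v = matrix.values[i, j]
            if math.isnan(v):
                continue
            if label_map[matrix.ids[i]] == label_map[matrix.ids[j]]:
                intra.append(float(v))
            else:
                inter.append(float(v))
    return intra, inter


def barcode_gap_summary(
    intra: list[float], inter: list[float], n_bins: int = 20
) -> GapSummary:
    """Shared-bin histograms of intra vs inter distances plus an overlap flag."""
    if not intra or not inter:
        raise ValueError("both distance lists must be non-empty")
    hi = max(max(intra), max(inter))
    edges = np.linspace(0.0, hi if hi > 0 else 1.0, n_bins + 1)
    intra_counts, _ = np.histogram(intra, bins=edges)
    inter_counts, _ = np.histogram(inter, bins=edges)
    return GapSummary(
        intra_distances=list(intra),
        inter_distances=list(inter),
        bins=edges,
        intra_counts=intra_counts,
        inter_counts=inter_counts,
        overlap_flag=max(intra) >= min(inter),
    )


def plot_barcode_gap(summary: GapSummary, path) -> None:
    """Render the paired intra/inter histogram to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = (summary.bins[:-1] + summary.bins[1:]) / 2
    width = (summary.bins[1] - summary.bins[0]) * 0.4
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(centers - width / 2, summary.intra_counts, width=width,
           label="intraspecific", color="tab:blue")
    ax.bar(centers + width / 2, summary.inter_counts, width=width,
           label="interspecific", color="tab:orange")
    ax.set_xlabel("pairwise distance")
    ax.set_ylabel("number of pairs")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
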