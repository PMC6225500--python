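"""End-to-end orchestration: alignment -> distances -> discrimination ->
consensus -> diversity -> tree -> (optional) CBC, with machine-readable
reports.

Every artifact is stamped with the seed and a hash of the configuration, and
the whole bundle is deterministic for a fixed seed.  The pipeline
cross-checks that the per-species nucleotide diversity equals the mean of
the intraspecific p-distances computed independently by the distance module,
so numbers in different reports cannot drift apart.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import consensus as cns
from . import discrimination as disc
from . import distances as dist
from . import diversity as div
from . import njtree
from . import seqio
from . import structure as struct

log = logging.getLogger("barcodekit")


@dataclass
class PipelineConfig:
    fasta: str
    labels: str
    structure: str | None = None
    model: str = "k2p"
    min_overlap: int = 100
    bcm_percentile: float = 95.0
    bootstrap_replicates: int = 1000
    seed: int = 0
    outdir: str = "barcodekit_out"

    def digest(self) -> str:
        # analysis parameters only: the output location must not change it
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def validate_config(config: PipelineConfig) -> list[str]:
    """Issues that would prevent (or degrade) a run; empty list = runnable."""
    issues = []
    if not Path(config.fasta).exists():
        issues.append(f"fasta not found: {config.fasta}")
    if not Path(config.labels).exists():
        issues.append(f"labels not found: {config.labels}")
    if config.structure is not None and not Path(config.structure).exists():
        issues.append(f"structure not found: {config.structure}")
    if config.model not in ("p", "k2p"):
        issues.append(f"unknown model {config.model!r}")
    if config.min_overlap < 1:
        issues.append("warning: min_overlap < 1 degenerates discrimination")
    if not (0 < config.bcm_percentile <= 100):
        issues.append("bcm_percentile must be in (0, 100]")
    return issues


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    Emits: summary.json, diversity.tsv, consensus.tsv, diagnostics.tsv,
    discrimination.tsv, tree.nwk and (when a structure is given) cbc.tsv.
    Any stage failure aborts with a stage-named error and removes partial
    outputs.
    """
    issues = [i for i in validate_config(config) if not i.startswith("warning")]
    if issues:
        raise ValueError("; ".join(issues))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stamp = {"seed": config.seed, "config_hash": config.digest()}

    def emit(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    try:
        stage = "seq_io"
        records = seqio.read_fasta(config.fasta)
        label_map = seqio.read_labels(config.labels)
        aln = seqio.build_alignment(records, label_map)
        log.info("seq_io: %d records, %d columns", len(aln), aln.n_columns)

        stage = "distances"
        matrix = dist.pairwise_matrix(
            aln, model=config.model, min_overlap=config.min_overlap
        )
        intra, inter = dist.partition_intra_inter(matrix, label_map)
        gap = dist.barcode_gap_summary(intra, inter) if intra and inter else None
        log.info(
            "distances: %d intra, %d inter, %d undefined pairs",
            len(intra), len(inter), len(matrix.undefined_pairs),
        )

        stage = "discrimination"
        bm = disc.discriminate_matrix(matrix, label_map, method="best_match")
        bcm = disc.discriminate_matrix(
            matrix, label_map, method="best_close_match",
            percentile=config.bcm_percentile,
        )
        rows = []
        for o in bcm.outcomes:
            rows.append(
                {
                    "query_id": o.query_id,
                    "species": label_map[o.query_id],
                    "category": o.category,
                    "nearest_ids": ",".join(o.nearest_ids),
                    "nearest_distance": o.nearest_distance,
                }
            )
        pd.DataFrame(rows).to_csv(emit("discrimination.tsv"), sep="\t", index=False)

        stage = "consensus"
        profiles = cns.build_all_consensus(aln, label_map)
        cns.write_consensus_table(profiles, emit("consensus.tsv"))
        diagnostics = cns.find_species_specific_sites(profiles)
        pd.DataFrame(
            diagnostics.rows, columns=["species", "position", "code"]
        ).to_csv(emit("diagnostics.tsv"), sep="\t", index=False)

        stage = "diversity"
        table = div.diversity_table(aln)
        pd.DataFrame([asdict(r) for r in table]).to_csv(
            emit("diversity.tsv"), sep="\t", index=False
        )
        n_var, n_pi = div.site_counts(aln)

        # cross-module consistency: pi must equal the mean intraspecific
        # p-distance computed by the distance module
        pmat = dist.pairwise_matrix(aln, model="p", min_overlap=1)
        for row in table:
            if row.species == "ALL" or row.n < 2:
                continue
            member_ids = [r.id for r in aln.records_of(row.species)]
            vals = [
                pmat.get(a, b)
                for k, a in enumerate(member_ids)
                for b in member_ids[k + 1 :]
                if not math.isnan(pmat.get(a, b))
            ]
            if vals:
                mean_p = sum(vals) / len(vals)
                if abs(mean_p - row.pi) > 1e-9:
                    raise AssertionError(
                        f"pi mismatch for {row.species}: {row.pi} vs {mean_p}"
                    )

        stage = "nj_tree"
        tree = njtree.bootstrap_support(
            aln,
            model=config.model,
            replicates=config.bootstrap_replicates,
            seed=config.seed,
            min_overlap=1,
        )
        emit("tree.nwk").write_text(tree.to_newick() + "\n")

        cbc_out = None
        if config.structure is not None:
            stage = "structure_cbc"
            _, db = seqio.read_dot_bracket(config.structure)
            pairs = struct.pair_table(db)
            ids, counts = struct.cbc_matrix(aln, pairs)
            pd.DataFrame(counts, index=ids, columns=ids).to_csv(
                emit("cbc.tsv"), sep="\t"
            )
            cbc_out = {"n_pairs": len(pairs), "max_cbc": int(counts.max())}

        stage = "summary"
        summary = {
            **stamp,
            "n_sequences": len(aln),
            "aligned_length": aln.n_columns,
            "variable_sites": n_var,
            "parsimony_informative_sites": n_pi,
            "mean_gc_pct": round(
                sum(div.gc_content(r.residues) for r in aln.records) / len(aln), 2
            ),
            "mean_intraspecific_pct": round(
                100 * sum(intra) / len(intra), 2
            ) if intra else None,
            "mean_interspecific_pct": round(
                100 * sum(inter) / len(inter), 2
            ) if inter else None,
            "barcode_gap_overlap": gap.overlap_flag if gap else None,
            "best_match": {
                "correct_pct": round(bm.pct_correct, 2),
                "ambiguous_pct": round(bm.pct_ambiguous, 2),
                "incorrect_pct": round(bm.pct_incorrect, 2),
            },
            "best_close_match": {
                "correct_pct": round(bcm.pct_correct, 2),
                "ambiguous_pct": round(bcm.pct_ambiguous, 2),
                "incorrect_pct": round(bcm.pct_incorrect, 2),
                "no_match_pct": round(bcm.pct_no_match, 2),
                "threshold_pct": round(100 * bcm.threshold, 4),
            },
            "full_precision": {
                "mean_intraspecific": sum(intra) / len(intra) if intra else None,
                "mean_interspecific": sum(inter) / len(inter) if inter else None,
                "bm_correct": bm.pct_correct,
                "bcm_correct": bcm.pct_correct,
                "bcm_threshold": bcm.threshold,
            },
            "n_diagnostic_sites": len(diagnostics.rows),
            "bootstrap_replicates": config.bootstrap_replicates,
            "cbc": cbc_out,
        }
        emit("summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        return summary
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
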