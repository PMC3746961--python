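"""End-to-end bench: fixture -> MA -> mapping -> resolution -> metrics -> augmentation.

``run_bench`` chains every stage of the toolkit on a fully synthetic
experiment and writes one machine-readable JSON report plus flat TSV tables.
All randomness flows from the single seed in the fixture config, so a rerun
with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import formats_io as fio
from .augmentation import augment_assembly
from .fixtures import CorruptionPlan, FixtureConfig, corrupt_assembly, generate_reads, generate_transcriptome
from .hit_resolution import resolve
from .mapping import MapperConfig, map_sequences
from .metrics import (
    misassembly_classify,
    recovery_stats,
    roc_point,
    summarize_assembly,
)
from .model_assembly import build_model_assembly, extract_fragment_sequences, mark_exclusions
from .redundancy import ClusterParams, greedy_cluster

logger = logging.getLogger("maeval")


@dataclass
class BenchConfig:
    """Everything the bench pipeline needs; defaults are the method's stated
    parameters (word 28, unique-coverage threshold 10, min fragment 76,
    clustering at 0.95 identity / word 8)."""

    fixture: FixtureConfig = field(default_factory=FixtureConfig)
    plan: CorruptionPlan = field(
        default_factory=lambda: CorruptionPlan(
            truncate_prob=0.2, chimera_prob=0.1, duplicate_prob=0.1, dropout_prob=0.05
        )
    )
    word_size: int = 28
    unique_threshold: int = 10
    min_region: int = 76
    cluster_identity: float = 0.95
    cluster_word: int = 8


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_bench(config: BenchConfig, outdir: os.PathLike | str) -> Dict:
    """Run the full pipeline, write report files under ``outdir``, return the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "fixture"
    try:
        transcripts, annotations, tx_manifest = generate_transcriptome(config.fixture)
        reads, placements = generate_reads(transcripts, config.fixture)
        fio.write_fasta(transcripts, outdir / "transcripts.fasta")
        fio.write_gff3(annotations, outdir / "annotation.gff3")
        _write_tsv(placements, outdir / "read_placements.tsv")

        stage = "model_assembly"
        tlens = {t.id: len(t) for t in transcripts}
        ma = build_model_assembly(
            placements[["transcript_id", "start", "end"]].itertuples(index=False),
            tlens,
            read_length=config.fixture.read_length,
        )
        ma = mark_exclusions(ma, annotations)
        ma_seqs = extract_fragment_sequences(ma, transcripts)
        ma_total = sum(f.length for f in ma)
        fio.write_fasta(ma_seqs, outdir / "ma.fasta")
        ma_table = pd.DataFrame(
            {
                "ma_id": [f.ma_id for f in ma],
                "length": [f.length for f in ma],
                "read_count": [f.read_count for f in ma],
                "pnc": [f.pnc for f in ma],
                "bin": [f.bin for f in ma],
                "excluded": [f.excluded for f in ma],
            }
        )
        _write_tsv(ma_table, outdir / "ma_table.tsv")

        stage = "corruption"
        assembly, truth = corrupt_assembly(ma_seqs, config.plan, seed=config.fixture.seed)
        fio.write_fasta(assembly, outdir / "assembly.fasta")
        _write_tsv(truth, outdir / "assembly_truth.tsv")

        stage = "mapping"
        mapper = MapperConfig(word_size=config.word_size)
        hits = map_sequences(assembly, ma_seqs, mapper)
        fio.write_hit_table(hits, outdir / "hits.tsv")

        stage = "resolution"
        chains_q = resolve(hits, axis="query", unique_threshold=config.unique_threshold)
        chains_s = resolve(hits, axis="subject", unique_threshold=config.unique_threshold)

        stage = "metrics"
        summary = summarize_assembly(assembly, ma_total=ma_total)
        records, bin_counts = recovery_stats(chains_s, ma)
        mis_records, mis_cells = misassembly_classify(
            chains_q, {a.id: len(a) for a in assembly}
        )
        roc = roc_point(records, ma_total, chains_q, [a.id for a in assembly])
        _write_tsv(
            pd.DataFrame(
                {
                    "ma_id": [r.ma_id for r in records],
                    "bin": [r.bin for r in records],
                    "ma_len": [r.ma_len for r in records],
                    "recovered_len": [r.recovered_len for r in records],
                    "pct_recovered": [round(r.pct_recovered, 4) for r in records],
                    "detected": [r.detected for r in records],
                    "excluded": [r.excluded for r in records],
                }
            ),
            outdir / "recovery.tsv",
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "fragment_id": [r.fragment_id for r in mis_records],
                    "length": [r.length for r in mis_records],
                    "best_fraction": [round(r.best_fraction, 6) for r in mis_records],
                    "best_subject": [r.best_subject or "" for r in mis_records],
                    "category": [r.category for r in mis_records],
                }
            ),
            outdir / "misassembly.tsv",
        )

        stage = "clustering"
        params = ClusterParams(
            identity_threshold=config.cluster_identity, word_size=config.cluster_word
        )
        clusters, nonredundant = greedy_cluster(assembly, params)
        fio.write_fasta(nonredundant, outdir / "nonredundant.fasta")

        stage = "augmentation"
        augmented, aug_report, unique_ivs = augment_assembly(
            assembly, ma_seqs, config=mapper, min_region=config.min_region
        )
        fio.write_fasta(augmented, outdir / "augmented.fasta")
        fio.write_bed6(
            [(tid, s, e, f"{tid}:{s}-{e}", 0, "+") for tid, (s, e) in unique_ivs],
            outdir / "unique_regions.bed",
        )
        aug_hits = map_sequences(augmented, ma_seqs, mapper)
        aug_chains_s = resolve(aug_hits, axis="subject", unique_threshold=config.unique_threshold)
        aug_records, _ = recovery_stats(aug_chains_s, ma)
        detected_before = {r.ma_id for r in records if r.detected}
        detected_after = {r.ma_id for r in aug_records if r.detected}
        aug_report.new_ma_detected = len(detected_after - detected_before)
        aug_report.recovery_gain_nt = sum(r.recovered_len for r in aug_records) - sum(
            r.recovered_len for r in records
        )

        label_counts = truth["label"].value_counts().to_dict()
        mis_totals: Dict[str, int] = {}
        for (_, cat), cnt in mis_cells.items():
            mis_totals[cat] = mis_totals.get(cat, 0) + cnt
        report = {
            "seed": config.fixture.seed,
            "config": {
                "fixture": dataclasses.asdict(config.fixture),
                "plan": dataclasses.asdict(config.plan),
                "word_size": config.word_size,
                "unique_threshold": config.unique_threshold,
                "min_region": config.min_region,
            },
            "model_assembly": {
                "n_fragments": len(ma),
                "total_nt": ma_total,
                "n_excluded": sum(f.excluded for f in ma),
                "per_bin": {
                    b: int((ma_table["bin"] == b)[~ma_table["excluded"]].sum())
                    for b in sorted(ma_table["bin"].unique())
                },
            },
            "assembly_summary": dataclasses.asdict(summary),
            "recovery": {
                "detected": len(detected_before),
                "recovered_nt": sum(r.recovered_len for r in records),
                "per_bin_detected": bin_counts,
            },
            "misassembly": {c: mis_totals.get(c, 0) for c in ("ge90", "b60_90", "lt60")},
            "roc": {"tpr_percent": roc.tpr_percent, "fpr_percent": roc.fpr_percent},
            "clustering": {
                "n_input": len(assembly),
                "n_clusters": clusters.n_clusters,
                "n_absorbed": len(assembly) - clusters.n_clusters,
            },
            "augmentation": dataclasses.asdict(aug_report),
            "truth_labels": {k: int(v) for k, v in sorted(label_counts.items())},
        }
    except Exception as err:  # noqa: BLE001 - stage context then re-raise
        (outdir / "FAILED").write_text(f"stage {stage}: {err}\n")
        raise RuntimeError(f"bench failed at stage {stage}: {err}") from err

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("bench complete: %s", outdir / "report.json")
    return report
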