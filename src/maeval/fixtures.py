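"""Synthetic transcriptomes, expression-graded reads, corrupted assemblies.

Everything downstream is testable against these generators because every
emitted object carries a ground-truth manifest: reads know their source
placement, corrupted fragments know their label and source interval.  The
generators emulate the statistical shape of a simulated plant transcriptome
experiment: multi-exon genes, a fraction of genes with two splice isoforms
(shared and unique exons), a fraction of paralog pairs sharing a planted
sub-sequence longer than the mapper word, 76 nt paired-end reads with a
N(300, 30) insert and lognormal expression across transcripts (dense at low
coverage, sparse at high coverage).

All generators are bit-reproducible under a fixed seed: each stage derives
its own ``numpy`` generator from ``(seed, stage)`` so adding a stage never
perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .formats_io import ExonAnnotation, SeqRecord
from .mapping import reverse_complement

_BASES = np.array(list("ACGT"))

# Stage tags for per-stage RNG derivation.
_STAGE_TRANSCRIPTOME = 1
_STAGE_READS = 2
_STAGE_CORRUPTION = 3

PARALOG_BLOCK = 100  # planted shared sub-sequence length between paralogs
MIN_EXON = 100
DUPLICATE_DIVERGENCE = 0.02  # substitution rate of near-copies (>=95% identity)


class ConfigError(ValueError):
    """Infeasible or inconsistent generator configuration."""


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic experiment.

    Read geometry follows the simulated dataset the method was developed on:
    76 nt paired reads, insert N(300, 30).  Desk-scale defaults elsewhere
    (gene count, read number) keep every stage fast while preserving the
    dense-low / sparse-high expression spectrum.
    """

    n_genes: int = 30
    isoform_fraction: float = 0.2
    paralog_fraction: float = 0.1
    transcript_length: Tuple[int, int] = (400, 2000)
    read_length: int = 76
    n_reads: int = 4000  # total reads (mates); read pairs = n_reads // 2
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    expression_sigma: float = 1.2
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.transcript_length
        if self.read_length < 1 or self.n_reads < 0:
            raise ConfigError("read_length >= 1 and n_reads >= 0 required")
        for frac in (self.isoform_fraction, self.paralog_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must be in [0, 1]")
        if lo < self.read_length:
            raise ConfigError("minimum transcript length must cover one read")
        if lo < 2 * MIN_EXON or hi < lo:
            raise ConfigError(
                f"transcript length range ({lo}, {hi}) infeasible: need "
                f">= {2 * MIN_EXON} nt for a two-exon gene"
            )
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigError("error_rate must be in [0, 1)")


@dataclass
class CorruptionPlan:
    """Assembler pathologies to plant, with per-fragment truth labels.

    Each surviving fragment gets exactly one label: faithful, truncated,
    chimeric, or duplicate (a near-copy at >= 95% identity of an emitted
    fragment, possibly reverse-complemented).  Chimeras concatenate segments
    from two distinct sources, each >= 40% of the fragment, so no single
    source can reach the 90% mapping threshold.
    """

    truncate_prob: float = 0.0
    truncation_range: Tuple[float, float] = (0.25, 0.5)
    chimera_prob: float = 0.0
    duplicate_prob: float = 0.0
    dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        probs = (
            self.truncate_prob,
            self.chimera_prob,
            self.duplicate_prob,
            self.dropout_prob,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("corruption probabilities must be in [0, 1]")
        if self.truncate_prob + self.chimera_prob + self.duplicate_prob > 1.0 + 1e-9:
            raise ConfigError("truncate+chimera+duplicate probabilities exceed 1")
        lo, hi = self.truncation_range
        if not 0.0 < lo <= hi < 1.0:
            raise ConfigError("truncation_range must satisfy 0 < lo <= hi < 1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    if mask.any():
        shifts = rng.integers(1, 4, size=int(mask.sum()))
        lut = {b: i for i, b in enumerate("ACGT")}
        idx = np.nonzero(mask)[0]
        for pos, shift in zip(idx, shifts):
            base = arr[pos]
            if base in lut:
                arr[pos] = "ACGT"[(lut[base] + shift) % 4]
    return "".join(arr)


def _substitute_exact(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    """Substitute exactly ``n_sub`` distinct positions (bounded divergence)."""
    if n_sub <= 0:
        return seq
    arr = np.array(list(seq))
    idx = rng.choice(len(arr), size=min(n_sub, len(arr)), replace=False)
    lut = {b: i for i, b in enumerate("ACGT")}
    for pos in idx:
        base = arr[pos]
        shift = int(rng.integers(1, 4))
        if base in lut:
            arr[pos] = "ACGT"[(lut[base] + shift) % 4]
    return "".join(arr)


def _partition(rng: np.random.Generator, total: int, parts: int, floor: int) -> List[int]:
    """Split ``total`` into ``parts`` integers each >= floor."""
    extra = total - floor * parts
    assert extra >= 0
    alloc = rng.multinomial(extra, [1.0 / parts] * parts)
    return [floor + int(a) for a in alloc]


def generate_transcriptome(
    config: FixtureConfig,
) -> Tuple[List[SeqRecord], List[ExonAnnotation], pd.DataFrame]:
    """Multi-exon genes with isoforms and paralogs, plus a truth manifest.

    Isoform genes emit two transcripts sharing at least one exon and
    differing by exactly one skipped exon; paralog pairs share a planted
    ``PARALOG_BLOCK`` nt sub-sequence.  Exon coordinates live on a per-gene
    genomic scaffold (plus strand) with random intron spacers.
    """
    rng = np.random.default_rng([config.seed, _STAGE_TRANSCRIPTOME])
    n = config.n_genes
    n_iso = round(config.isoform_fraction * n)
    n_par = round(config.paralog_fraction * n)

    gene_ids = [f"g{i:03d}" for i in range(n)]
    iso_genes = set(rng.choice(n, size=n_iso, replace=False).tolist()) if n_iso else set()
    non_iso = [i for i in range(n) if i not in iso_genes]
    par_pool = non_iso + [i for i in range(n) if i in iso_genes]
    par_genes = par_pool[:n_par]
    paralog_pairs = [
        (par_genes[2 * k], par_genes[2 * k + 1]) for k in range(len(par_genes) // 2)
    ]

    lo, hi = config.transcript_length
    exon_seqs: Dict[int, List[str]] = {}
    exon_coords: Dict[int, List[Tuple[int, int]]] = {}
    skip_exon: Dict[int, int] = {}
    for gi in range(n):
        total = int(rng.integers(lo, hi + 1))
        n_exons = max(2, min(6, total // 250))
        lens = _partition(rng, total, n_exons, MIN_EXON)
        seqs = [_random_seq(rng, l) for l in lens]
        introns = rng.integers(50, 201, size=n_exons - 1)
        coords, pos = [], 0
        for li, l in enumerate(lens):
            coords.append((pos, pos + l))
            pos += l + (int(introns[li]) if li < n_exons - 1 else 0)
        exon_seqs[gi] = seqs
        exon_coords[gi] = coords
        if gi in iso_genes:
            skip_exon[gi] = int(rng.integers(0, n_exons))

    # Plant paralog blocks: copy the first PARALOG_BLOCK nt of the donor's
    # first exon into the recipient's first exon (exons are >= 100 nt).
    for donor_gi, recip_gi in paralog_pairs:
        block = exon_seqs[donor_gi][0][:PARALOG_BLOCK]
        tgt = exon_seqs[recip_gi][0]
        exon_seqs[recip_gi][0] = block + tgt[PARALOG_BLOCK:]

    transcripts: List[SeqRecord] = []
    annotations: List[ExonAnnotation] = []
    rows = []
    partner = {a: b for a, b in paralog_pairs} | {b: a for a, b in paralog_pairs}
    for gi in range(n):
        gid = gene_ids[gi]
        variants = [(f"{gid}.1", list(range(len(exon_seqs[gi]))))]
        if gi in iso_genes:
            kept = [k for k in range(len(exon_seqs[gi])) if k != skip_exon[gi]]
            variants.append((f"{gid}.2", kept))
        for tid, exon_idx in variants:
            seq = "".join(exon_seqs[gi][k] for k in exon_idx)
            transcripts.append(SeqRecord(tid, seq))
            annotations.append(
                ExonAnnotation(
                    gene_id=gid,
                    transcript_id=tid,
                    strand="+",
                    exons=[exon_coords[gi][k] for k in exon_idx],
                    is_isoform=gi in iso_genes,
                )
            )
            rows.append(
                {
                    "transcript_id": tid,
                    "gene_id": gid,
                    "length": len(seq),
                    "n_exons": len(exon_idx),
                    "is_isoform": gi in iso_genes,
                    "paralog_partner": gene_ids[partner[gi]] if gi in partner else "",
                    "planted_block_len": PARALOG_BLOCK if gi in partner else 0,
                }
            )
    return transcripts, annotations, pd.DataFrame(rows)


def generate_reads(
    transcripts: Sequence[SeqRecord], config: FixtureConfig
) -> Tuple[List[SeqRecord], pd.DataFrame]:
    """Paired 76 nt reads with lognormal expression and a placement manifest.

    Per-transcript read counts are multinomial over lognormal weights;
    fragment (insert) lengths are N(insert_mean, insert_sd) clipped to the
    transcript; mate 2 is the reverse complement of the fragment's 3' end.
    The manifest records the true 0-based placement of every mate.
    """
    rng = np.random.default_rng([config.seed, _STAGE_READS])
    rl = config.read_length
    for t in transcripts:
        if len(t) < rl:
            raise ConfigError(f"transcript {t.id} shorter than read length")
    weights = rng.lognormal(mean=0.0, sigma=config.expression_sigma, size=len(transcripts))
    probs = weights / weights.sum()
    counts = rng.multinomial(config.n_reads // 2, probs)  # pairs per transcript

    reads: List[SeqRecord] = []
    rows = []
    ridx = 0
    for t, cnt in zip(transcripts, counts):
        tlen = len(t)
        for _ in range(int(cnt)):
            frag = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            frag = max(rl, min(tlen, frag))
            start = int(rng.integers(0, tlen - frag + 1))
            m1 = t.sequence[start : start + rl]
            m2 = reverse_complement(t.sequence[start + frag - rl : start + frag])
            for mate, seq, ms, me in (
                (1, m1, start, start + rl),
                (2, m2, start + frag - rl, start + frag),
            ):
                rid = f"r{ridx:07d}/{mate}"
                reads.append(SeqRecord(rid, _substitute(rng, seq, config.error_rate)))
                rows.append(
                    {
                        "read_id": rid,
                        "transcript_id": t.id,
                        "start": ms,
                        "end": me,
                        "mate": mate,
                    }
                )
            ridx += 1
    return reads, pd.DataFrame(rows)


def corrupt_assembly(
    sources: Sequence[SeqRecord],
    plan: CorruptionPlan,
    seed: int = 0,
) -> Tuple[List[SeqRecord], pd.DataFrame]:
    """Derive a deliberately corrupted assembly from source fragments.

    Dropout removes a fragment entirely; survivors are independently
    truncated, turned into a chimera with a second source, emitted with a
    >= 95%-identical near-copy, or passed through verbatim.  The manifest
    records labels, source ids, and source intervals, sufficient to compute
    every downstream statistic without alignment.
    """
    if not sources:
        raise ConfigError("corrupt_assembly needs at least one source")
    if plan.chimera_prob > 0 and len(sources) < 2:
        raise ConfigError("chimeras need at least two distinct sources")
    rng = np.random.default_rng([seed, _STAGE_CORRUPTION])
    out: List[SeqRecord] = []
    rows = []
    p_tr, p_ch, p_du = plan.truncate_prob, plan.chimera_prob, plan.duplicate_prob
    chim_n = 0
    for i, src in enumerate(sources):
        if rng.random() < plan.dropout_prob:
            rows.append(
                {
                    "fragment_id": "",
                    "label": "dropped",
                    "source_id": src.id,
                    "source_start": 0,
                    "source_end": len(src),
                    "partner_id": "",
                }
            )
            continue
        u = rng.random()
        L = len(src)
        if u < p_tr:
            f = float(rng.uniform(*plan.truncation_range))
            keep = max(1, int(round((1.0 - f) * L)))
            if rng.random() < 0.5:
                s, e = 0, keep
            else:
                s, e = L - keep, L
            out.append(SeqRecord(f"{src.id}|trunc", src.sequence[s:e]))
            rows.append(
                {
                    "fragment_id": f"{src.id}|trunc",
                    "label": "truncated",
                    "source_id": src.id,
                    "source_start": s,
                    "source_end": e,
                    "partner_id": "",
                }
            )
        elif u < p_tr + p_ch:
            j = int(rng.integers(0, len(sources) - 1))
            if j >= i:
                j += 1
            other = sources[j]
            total = min(L, len(other))
            frac = float(rng.uniform(0.42, 0.58))
            a = int(round(frac * total))
            seq = src.sequence[:a] + other.sequence[: total - a]
            fid = f"chim{chim_n:04d}|{src.id}|{other.id}"
            chim_n += 1
            out.append(SeqRecord(fid, seq))
            rows.append(
                {
                    "fragment_id": fid,
                    "label": "chimeric",
                    "source_id": src.id,
                    "source_start": 0,
                    "source_end": a,
                    "partner_id": other.id,
                }
            )
        elif u < p_tr + p_ch + p_du:
            out.append(SeqRecord(src.id, src.sequence))
            rows.append(
                {
                    "fragment_id": src.id,
                    "label": "faithful",
                    "source_id": src.id,
                    "source_start": 0,
                    "source_end": L,
                    "partner_id": "",
                }
            )
            dup = _substitute_exact(
                rng, src.sequence, int(DUPLICATE_DIVERGENCE * L)
            )
            if rng.random() < 0.5:
                dup = reverse_complement(dup)
            out.append(SeqRecord(f"{src.id}|dup", dup))
            rows.append(
                {
                    "fragment_id": f"{src.id}|dup",
                    "label": "duplicate",
                    "source_id": src.id,
                    "source_start": 0,
                    "source_end": L,
                    "partner_id": src.id,
                }
            )
        else:
            out.append(SeqRecord(src.id, src.sequence))
            rows.append(
                {
                    "fragment_id": src.id,
                    "label": "faithful",
                    "source_id": src.id,
                    "source_start": 0,
                    "source_end": L,
                    "partner_id": "",
                }
            )
    return out, pd.DataFrame(rows)
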