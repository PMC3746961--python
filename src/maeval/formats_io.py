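"""Readers and writers for the standard formats the toolkit touches.

Dialects are strict and documented:

* FASTA — id is the first whitespace-delimited header token; sequence folded
  to upper case; alphabet restricted to ``{A,C,G,T,N}``; duplicate ids are an
  error.
* GFF3 — only ``exon`` features with a ``Parent`` attribute are consumed;
  1-based closed coordinates are converted to the internal 0-based half-open
  convention on read.
* Tabular hits — the common 12-column tab-separated alignment format
  (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
  evalue bitscore).  Minus-strand hits are encoded on disk by
  ``sstart > send`` and normalized on read to an ascending subject interval
  plus a strand flag.  Writing what was read reproduces the file byte for
  byte for files in the canonical formatting below.
* BED6 — written only, 0-based half-open as the format requires.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import gffutils
from Bio import SeqIO

from .intervals import Interval


class FormatError(ValueError):
    """Input does not conform to the declared dialect."""


class DuplicateIdError(FormatError):
    """Two records in one collection share an identifier."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class SeqRecord:
    """An identified nucleotide sequence (transcript, read, or fragment)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"invalid sequence id: {self.id!r}")
        if len(self.sequence) < 1:
            raise ValidationError(f"empty sequence for {self.id}")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ExonAnnotation:
    """Exon structure of one transcript.

    ``exons`` are 0-based half-open intervals, sorted and non-overlapping,
    on whatever axis the annotation uses (a genomic scaffold here).
    ``is_isoform`` is true when the parent gene has more than one transcript.
    """

    gene_id: str
    transcript_id: str
    strand: str
    exons: List[Interval]
    is_isoform: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"overlapping exons in transcript {self.transcript_id}: "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def transcript_exon_intervals(ann: ExonAnnotation) -> List[Interval]:
    """Exon intervals projected onto the transcript (spliced) axis."""
    out, pos = [], 0
    for s, e in ann.exons:
        out.append((pos, pos + (e - s)))
        pos += e - s
    return out


@dataclass
class HitRow:
    """One ungapped local alignment between a query and a subject.

    Coordinates are stored 0-based half-open with ascending intervals on both
    axes; strand ``-`` means the query segment matches the reverse complement
    of the subject segment.  On disk (1-based closed) a minus-strand row
    carries a descending subject interval.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatch: int
    gap_open: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str = "+"
    evalue: float = 0.0
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValidationError("hit intervals must be ascending internally")
        if self.aln_len < 1:
            raise ValidationError("alignment length must be >= 1")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValidationError("pct_identity outside [0, 100]")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def q_interval(self) -> Interval:
        return (self.q_start, self.q_end)

    @property
    def s_interval(self) -> Interval:
        return (self.s_start, self.s_end)

    @property
    def score(self) -> float:
        """Surrogate score: identity fraction x aligned length."""
        return self.pct_identity * self.aln_len / 100.0


# ----------------------------------------------------------------- FASTA ----


def read_fasta(path: os.PathLike | str) -> List[SeqRecord]:
    records: List[SeqRecord] = []
    seen: set = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: os.PathLike | str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path: os.PathLike | str) -> None:
    """Write reads as FASTQ with constant placeholder qualities (ignored here)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{'I' * len(rec.sequence)}\n")


def read_fastq(path: os.PathLike | str) -> List[SeqRecord]:
    records = [
        SeqRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]
    if not records:
        raise FormatError(f"no FASTQ records in {path}")
    return records


# ------------------------------------------------------------------ GFF3 ----


def parse_gff_exons(path: os.PathLike | str) -> List[ExonAnnotation]:
    """Collect exon structures per transcript from a GFF3 file.

    Exon features must carry a ``Parent`` attribute naming the transcript;
    the transcript's own ``Parent`` (when present) names the gene.  A gene
    with >1 transcript marks all its transcripts ``is_isoform``.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    per_tx: Dict[str, List[Interval]] = {}
    tx_strand: Dict[str, str] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent")
        if not parents:
            raise FormatError(f"exon at {exon.seqid}:{exon.start} has no Parent")
        for tid in parents:
            # GFF is 1-based closed; internal is 0-based half-open.
            per_tx.setdefault(tid, []).append((exon.start - 1, exon.end))
            tx_strand.setdefault(tid, exon.strand if exon.strand in "+-" else "+")

    tx_gene: Dict[str, str] = {}
    for tid in per_tx:
        try:
            feat = db[tid]
            parents = feat.attributes.get("Parent")
            tx_gene[tid] = parents[0] if parents else tid
        except gffutils.FeatureNotFoundError:
            tx_gene[tid] = tid

    gene_counts: Dict[str, int] = {}
    for gid in tx_gene.values():
        gene_counts[gid] = gene_counts.get(gid, 0) + 1

    return [
        ExonAnnotation(
            gene_id=tx_gene[tid],
            transcript_id=tid,
            strand=tx_strand[tid],
            exons=exons,
            is_isoform=gene_counts[tx_gene[tid]] > 1,
        )
        for tid, exons in sorted(per_tx.items())
    ]


def write_gff3(annotations: Sequence[ExonAnnotation], path: os.PathLike | str) -> None:
    """Write gene/mRNA/exon features; seqid is the gene id (per-gene scaffold)."""
    by_gene: Dict[str, List[ExonAnnotation]] = {}
    for ann in annotations:
        by_gene.setdefault(ann.gene_id, []).append(ann)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(by_gene):
            anns = by_gene[gid]
            gs = min(a.exons[0][0] for a in anns)
            ge = max(a.exons[-1][1] for a in anns)
            strand = anns[0].strand
            fh.write(
                f"{gid}\tmaeval\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\tID={gid}\n"
            )
            for ann in sorted(anns, key=lambda a: a.transcript_id):
                ts, te = ann.exons[0][0], ann.exons[-1][1]
                fh.write(
                    f"{gid}\tmaeval\tmRNA\t{ts + 1}\t{te}\t.\t{strand}\t.\t"
                    f"ID={ann.transcript_id};Parent={gid}\n"
                )
                for s, e in ann.exons:
                    fh.write(
                        f"{gid}\tmaeval\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                        f"Parent={ann.transcript_id}\n"
                    )


# ------------------------------------------------------------- hit table ----


def read_hit_table(path: os.PathLike | str) -> List[HitRow]:
    rows: List[HitRow] = []
    with open(path, newline="") as fh:
        for lineno, parts in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not parts or (len(parts) == 1 and not parts[0].strip()):
                continue
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}"
                )
            try:
                (q, s, pident, length, mm, go, qs, qe, ss, se, ev, bits) = (
                    parts[0],
                    parts[1],
                    float(parts[2]),
                    int(parts[3]),
                    int(parts[4]),
                    int(parts[5]),
                    int(parts[6]),
                    int(parts[7]),
                    int(parts[8]),
                    int(parts[9]),
                    float(parts[10]),
                    float(parts[11]),
                )
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: {err}") from err
            if ss <= se:
                strand, s0, s1 = "+", ss - 1, se
            else:
                strand, s0, s1 = "-", se - 1, ss
            rows.append(
                HitRow(
                    query_id=q,
                    subject_id=s,
                    pct_identity=pident,
                    aln_len=length,
                    mismatch=mm,
                    gap_open=go,
                    q_start=qs - 1,
                    q_end=qe,
                    s_start=s0,
                    s_end=s1,
                    strand=strand,
                    evalue=ev,
                    bitscore=bits,
                )
            )
    return rows


def write_hit_table(rows: Iterable[HitRow], path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for r in rows:
            if r.strand == "+":
                ss, se = r.s_start + 1, r.s_end
            else:
                ss, se = r.s_end, r.s_start + 1
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.pct_identity:.2f}\t{r.aln_len}\t"
                f"{r.mismatch}\t{r.gap_open}\t{r.q_start + 1}\t{r.q_end}\t"
                f"{ss}\t{se}\t{r.evalue:g}\t{r.bitscore:.1f}\n"
            )


# -------------------------------------------------------------------- BED ----


def write_bed6(
    rows: Iterable[Tuple[str, int, int, str, float, str]],
    path: os.PathLike | str,
) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")
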