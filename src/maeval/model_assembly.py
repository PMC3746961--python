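"""Model Assembly construction, per-nucleotide coverage, expression bins.

The Model Assembly (MA) is the set of maximal contiguously read-covered
regions of the reference transcripts; it is the recovery reference every
candidate assembly is scored against.  Each MA fragment carries a
per-nucleotide coverage

    pnc = (number of reads x read length) / fragment length

used as an expression proxy, and an expression bin B1..B8 with right-closed
boundaries at pnc 1, 2, 3, 4, 5, 10 and 30.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from .formats_io import ExonAnnotation, SeqRecord, ValidationError
from .intervals import merge_intervals

BIN_BOUNDARIES = (1.0, 2.0, 3.0, 4.0, 5.0, 10.0, 30.0)
BIN_LABELS = ("B1", "B2", "B3", "B4", "B5", "B6", "B7", "B8")


class DomainError(ValueError):
    """Argument outside the mathematical domain of an operation."""


def compute_pnc(read_count: int, read_length: int, length: int) -> float:
    """Per-nucleotide coverage: (reads x read length) / fragment length."""
    if length < 1:
        raise DomainError("fragment length must be >= 1")
    if read_count < 1:
        raise ValidationError(
            "an MA fragment is read-covered by construction; read_count >= 1"
        )
    return read_count * read_length / length


def assign_expression_bin(pnc: float) -> str:
    """Bin label for a pnc value; boundaries are closed on the right.

    pnc <= 1 is B1, >1 & <= 2 is B2, ..., >10 & <= 30 is B7, >30 is B8.
    """
    if pnc <= 0:
        raise DomainError(f"pnc must be positive, got {pnc}")
    for label, bound in zip(BIN_LABELS, BIN_BOUNDARIES):
        if pnc <= bound:
            return label
    return BIN_LABELS[-1]


@dataclass
class MAFragment:
    """One contiguously read-covered transcript region."""

    transcript_id: str
    start: int
    end: int
    read_count: int
    pnc: float
    bin: str
    excluded: bool = False

    @property
    def ma_id(self) -> str:
        return f"{self.transcript_id}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start


def build_model_assembly(
    placements: Iterable[Tuple[str, int, int]],
    transcript_lengths: Dict[str, int],
    read_length: int = 76,
) -> List[MAFragment]:
    """MA fragments as maximal unions of read intervals per transcript.

    ``placements`` are (transcript_id, start, end) read intervals, 0-based
    half-open.  Touching/overlapping intervals merge; a read counts toward
    the fragment that fully contains it (every read is fully contained in
    exactly one fragment, because fragments are the connected components of
    the read coverage).
    """
    per_tx: Dict[str, List[Tuple[int, int]]] = {}
    for tid, start, end in placements:
        if tid not in transcript_lengths:
            raise ValidationError(f"placement references unknown transcript {tid}")
        if start < 0 or end > transcript_lengths[tid] or end <= start:
            raise ValidationError(
                f"placement [{start},{end}) out of bounds for {tid} "
                f"(length {transcript_lengths[tid]})"
            )
        per_tx.setdefault(tid, []).append((start, end))

    fragments: List[MAFragment] = []
    for tid in sorted(per_tx):
        reads = per_tx[tid]
        merged = merge_intervals(reads)
        counts = {iv: 0 for iv in merged}
        # Count reads fully contained in each fragment.
        idx = 0
        for rs, re_ in sorted(reads):
            while merged[idx][1] < re_:
                idx += 1
            fs, fe = merged[idx]
            assert fs <= rs and re_ <= fe
            counts[(fs, fe)] += 1
        for fs, fe in merged:
            pnc = compute_pnc(counts[(fs, fe)], read_length, fe - fs)
            fragments.append(
                MAFragment(
                    transcript_id=tid,
                    start=fs,
                    end=fe,
                    read_count=counts[(fs, fe)],
                    pnc=pnc,
                    bin=assign_expression_bin(pnc),
                )
            )
    return fragments


def extract_fragment_sequences(
    fragments: Sequence[MAFragment], transcripts: Sequence[SeqRecord]
) -> List[SeqRecord]:
    """MA fragment sequences cut from their source transcripts."""
    by_id = {t.id: t.sequence for t in transcripts}
    out = []
    for frag in fragments:
        if frag.transcript_id not in by_id:
            raise ValidationError(f"unknown transcript {frag.transcript_id}")
        out.append(
            SeqRecord(frag.ma_id, by_id[frag.transcript_id][frag.start : frag.end])
        )
    return out


def mark_exclusions(
    fragments: Iterable[MAFragment],
    annotations: Sequence[ExonAnnotation],
    transposon_transcripts: Iterable[str] = (),
) -> List[MAFragment]:
    """Flag fragments from isoform-bearing genes or transposon transcripts.

    Excluded fragments keep their pnc and bin but are skipped by the binned
    statistics downstream: repeated subsequence between isoforms (or within
    transposable elements) makes read and assembly mapping to the correct
    source unreliable, so their pnc is not trustworthy.
    """
    iso = {a.transcript_id for a in annotations if a.is_isoform}
    known = {a.transcript_id for a in annotations}
    tes = set(transposon_transcripts)
    out = []
    for frag in fragments:
        if frag.transcript_id not in known:
            raise ValidationError(
                f"fragment transcript {frag.transcript_id} not annotated"
            )
        frag.excluded = frag.transcript_id in iso or frag.transcript_id in tes
        out.append(frag)
    return out
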