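"""Seed-and-extend ungapped local aligner producing 12-column hit rows.

The aligner indexes every exact word of ``word_size`` (default 28 nt) in the
subject set, seeds on shared words, and reports the maximal positive-scoring
ungapped segments on each seeded diagonal (match +1, mismatch -2, the classic
ungapped BLAST scoring).  Every reported hit therefore contains at least one
exact shared word of ``word_size``; gaps in homology appear as separate hits
on neighbouring diagonals, which downstream chaining consumes as intervals.

No gapped extension, E-values or bit scores: the evaluation built on top is
interval arithmetic on hit coordinates, and the surrogate score
``identity x aligned length`` orders hits deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

from .formats_io import HitRow, SeqRecord

_COMP = str.maketrans("ACGTN", "TGCAN")

MATCH_SCORE = 1
MISMATCH_SCORE = -2


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class MapperConfig:
    """Parameters of the bundled word mapper.

    word_size
        Exact-word seed length, default 28 nt (the Megablast default word).
    min_identity
        Percent identity floor applied to reported hits; 0 reports every
        maximal segment (evaluation use), 95 is the clustering default.
    min_hit_len
        Minimum reported hit length; defaults to ``word_size``.
    both_strands
        Search the reverse complement of each query as well.
    """

    word_size: int = 28
    min_identity: float = 0.0
    min_hit_len: int | None = None
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError("min_identity must be in [0, 100]")
        if self.min_hit_len is None:
            self.min_hit_len = self.word_size


def _max_scoring_segments(
    scores: Sequence[int], min_sum: int
) -> List[Tuple[int, int]]:
    """All disjoint maximal positive segments with sum >= min_sum.

    Repeated Kadane with recursion on the flanks: find the leftmost maximal
    segment, record it, recurse left and right.  Deterministic; ties on sum
    prefer the leftmost start and, for the same start, the longest extent.
    """
    segments: List[Tuple[int, int]] = []
    stack = [(0, len(scores))]
    while stack:
        lo, hi = stack.pop()
        best_sum = 0
        best = None
        cur_sum = 0
        cur_start = lo
        for i in range(lo, hi):
            cur_sum += scores[i]
            if cur_sum < 0:
                cur_sum = 0
                cur_start = i + 1
                continue
            if cur_sum > best_sum or (
                best is not None
                and cur_sum == best_sum
                and cur_start == best[0]
                and i + 1 > best[1]
            ):
                best_sum = cur_sum
                best = (cur_start, i + 1)
        if best is None or best_sum < min_sum:
            continue
        segments.append(best)
        stack.append((lo, best[0]))
        stack.append((best[1], hi))
    return sorted(segments)


def _diagonal_hits(
    qseq: str, sseq: str, diag: int, word_size: int
) -> List[Tuple[int, int, int]]:
    """(q_start, q_end, matches) for maximal segments on one diagonal.

    ``diag = q_pos - s_pos``.  Only segments containing an exact run of
    ``word_size`` matches qualify (such a run scores >= word_size, so the
    Kadane floor prunes safely).
    """
    q_lo = max(0, diag)
    q_hi = min(len(qseq), len(sseq) + diag)
    if q_hi - q_lo < word_size:
        return []
    scores = [
        MATCH_SCORE if qseq[i] == sseq[i - diag] and qseq[i] != "N" else MISMATCH_SCORE
        for i in range(q_lo, q_hi)
    ]
    out: List[Tuple[int, int, int]] = []
    for a, b in _max_scoring_segments(scores, word_size):
        qa, qb = q_lo + a, q_lo + b
        run = best_run = matches = 0
        for i in range(qa, qb):
            if qseq[i] == sseq[i - diag] and qseq[i] != "N":
                matches += 1
                run += 1
                best_run = max(best_run, run)
            else:
                run = 0
        if best_run >= word_size:
            out.append((qa, qb, matches))
    return out


def map_sequences(
    queries: Sequence[SeqRecord],
    subjects: Sequence[SeqRecord],
    config: MapperConfig | None = None,
) -> List[HitRow]:
    """Map every query against every subject; deterministic hit order.

    Output is sorted by (query id, subject id, query start, strand, subject
    start).  Empty inputs yield an empty hit list.
    """
    config = config or MapperConfig()
    w = config.word_size

    index: Dict[str, List[Tuple[int, int]]] = {}
    for si, sub in enumerate(subjects):
        if len(sub.sequence) < w:
            warnings.warn(
                f"subject {sub.id} shorter than word size {w}; unsearchable",
                stacklevel=2,
            )
            continue
        s = sub.sequence
        for pos in range(len(s) - w + 1):
            word = s[pos : pos + w]
            if "N" not in word:
                index.setdefault(word, []).append((si, pos))

    hits: List[HitRow] = []
    seen: Set[Tuple[str, str, str, int, int, int, int]] = set()
    strands = ("+", "-") if config.both_strands else ("+",)
    for q in queries:
        for strand in strands:
            qseq = q.sequence if strand == "+" else reverse_complement(q.sequence)
            if len(qseq) < w:
                continue
            diags: Dict[int, Set[int]] = {}
            for qpos in range(len(qseq) - w + 1):
                for si, spos in index.get(qseq[qpos : qpos + w], ()):
                    diags.setdefault(si, set()).add(qpos - spos)
            for si in sorted(diags):
                sseq = subjects[si].sequence
                for diag in sorted(diags[si]):
                    for qa, qb, matches in _diagonal_hits(qseq, sseq, diag, w):
                        length = qb - qa
                        identity = 100.0 * matches / length
                        if length < config.min_hit_len or identity < config.min_identity:
                            continue
                        sa, sb = qa - diag, qb - diag
                        if strand == "+":
                            q0, q1 = qa, qb
                        else:
                            q0, q1 = len(qseq) - qb, len(qseq) - qa
                        key = (q.id, subjects[si].id, strand, q0, q1, sa, sb)
                        if key in seen:
                            continue
                        seen.add(key)
                        hits.append(
                            HitRow(
                                query_id=q.id,
                                subject_id=subjects[si].id,
                                pct_identity=identity,
                                aln_len=length,
                                mismatch=length - matches,
                                gap_open=0,
                                q_start=q0,
                                q_end=q1,
                                s_start=sa,
                                s_end=sb,
                                strand=strand,
                                evalue=0.0,
                                bitscore=identity * length / 100.0,
                            )
                        )
    hits.sort(
        key=lambda h: (h.query_id, h.subject_id, h.q_start, h.strand, h.s_start)
    )
    return hits
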