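"""Evaluation statistics: N50 / N_MA50, recovery, misassembly, isoforms, ROC.

All statistics score a candidate assembly against the Model Assembly (MA).
N_MA50 is the N50 recomputed with half the MA cumulative size as the target
instead of half the assembly's own size, which normalizes the statistic to
the recoverable transcriptome rather than to whatever the assembler chose to
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from statistics import median
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .formats_io import SeqRecord, ValidationError
from .hit_resolution import CoverageChain, best_single_source_fraction
from .intervals import merge_intervals, subtract_intervals, total_length
from .mapping import MapperConfig, map_sequences
from .model_assembly import DomainError, MAFragment

# Fragment-length categories used for length-stratified recovery summaries.
DEFAULT_LENGTH_BINS: Tuple[Tuple[int, int, str], ...] = (
    (0, 76, "<=76"),
    (76, 300, "76-300"),
    (300, 500, "300-500"),
    (500, 1000, "500-1000"),
    (1000, 1500, "1000-1500"),
    (1500, 2000, "1500-2000"),
    (2000, 3000, "2000-3000"),
    (3000, 4000, "3000-4000"),
    (4000, 5000, "4000-5000"),
    (5000, 6500, "5000-6500"),
)

MISASSEMBLY_CATEGORIES = ("ge90", "b60_90", "lt60")

# Exon length-recovery categories; lower bound open, upper bound closed.
ISOFORM_CATEGORIES = ("0%", ">0-20%", ">20-40%", ">40-60%", ">60-80%", ">80-100%")


def length_bin_label(
    length: int, bins: Sequence[Tuple[int, int, str]] = DEFAULT_LENGTH_BINS
) -> str:
    for lo, hi, label in bins:
        if lo < length <= hi:
            return label
    return f">{bins[-1][1]}"


@dataclass
class AssemblySummary:
    n_fragments: int
    total_nt: int
    n50: int
    n_ma50: int
    median_len: float
    min_len: int
    max_len: int


@dataclass
class RecoveryRecord:
    ma_id: str
    bin: str
    ma_len: int
    recovered_len: int
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.recovered_len > self.ma_len:
            raise ValidationError(
                f"recovered_len {self.recovered_len} > ma_len {self.ma_len} "
                f"for {self.ma_id}"
            )

    @property
    def pct_recovered(self) -> float:
        return 100.0 * self.recovered_len / self.ma_len

    @property
    def detected(self) -> bool:
        return self.recovered_len >= 1


@dataclass
class MisassemblyRecord:
    fragment_id: str
    length: int
    best_fraction: float
    best_subject: Optional[str]

    @property
    def category(self) -> str:
        # Boundary values go to the upper category (0.9 -> ge90, 0.6 -> b60_90).
        if self.best_fraction >= 0.9:
            return "ge90"
        if self.best_fraction >= 0.6:
            return "b60_90"
        return "lt60"


@dataclass
class ROCPoint:
    tpr_percent: float
    fpr_percent: float


# ------------------------------------------------------------------- N50 ----


def n50(lengths: Sequence[int], denominator_total: Optional[int] = None) -> int:
    """Smallest length whose descending cumulative sum reaches half the total.

    With ``denominator_total`` set to the MA cumulative size this computes
    N_MA50.  If the assembly is smaller than half the denominator the
    statistic is undefined; 0 is returned with a warning.
    """
    lengths = list(lengths)
    if not lengths:
        raise DomainError("N50 of an empty length list is undefined")
    if any(l < 1 for l in lengths):
        raise DomainError("lengths must be >= 1")
    denom = sum(lengths) if denominator_total is None else denominator_total
    if denom < 1:
        raise DomainError("denominator_total must be >= 1")
    cum = 0
    for l in sorted(lengths, reverse=True):
        cum += l
        if 2 * cum >= denom:
            return l
    warnings.warn(
        "assembly total below half the denominator; N50 undefined, returning 0",
        stacklevel=2,
    )
    return 0


def summarize_assembly(
    fragments: Sequence[SeqRecord], ma_total: Optional[int] = None
) -> AssemblySummary:
    """Length-multiset summary of an assembly; N_MA50 when ``ma_total`` given."""
    if not fragments:
        raise DomainError("cannot summarize an empty assembly")
    lengths = [len(f) for f in fragments]
    own_n50 = n50(lengths)
    return AssemblySummary(
        n_fragments=len(lengths),
        total_nt=sum(lengths),
        n50=own_n50,
        n_ma50=n50(lengths, ma_total) if ma_total is not None else own_n50,
        median_len=float(median(lengths)),
        min_len=min(lengths),
        max_len=max(lengths),
    )


# -------------------------------------------------------------- recovery ----


def recovery_stats(
    chains: Mapping[str, CoverageChain],
    ma_fragments: Sequence[MAFragment],
) -> Tuple[List[RecoveryRecord], Dict[str, int]]:
    """Per-MA-fragment recovery plus detected counts per expression bin.

    ``chains`` are subject-axis chains keyed by MA fragment id; a fragment
    with no chain has recovered_len 0.  The per-bin counts skip excluded
    fragments (isoforms / transposons are left out of binned statistics).
    """
    known = {f.ma_id for f in ma_fragments}
    for anchor, chain in chains.items():
        if chain.axis != "subject":
            raise DomainError("recovery_stats needs subject-axis chains")
        if anchor not in known:
            raise ValidationError(f"chain references unknown MA fragment {anchor}")
    records = []
    bin_counts: Dict[str, int] = {}
    for frag in ma_fragments:
        chain = chains.get(frag.ma_id)
        recovered = min(chain.covered_len, frag.length) if chain else 0
        rec = RecoveryRecord(
            ma_id=frag.ma_id,
            bin=frag.bin,
            ma_len=frag.length,
            recovered_len=recovered,
            excluded=frag.excluded,
        )
        records.append(rec)
        if rec.detected and not frag.excluded:
            bin_counts[frag.bin] = bin_counts.get(frag.bin, 0) + 1
    return records, bin_counts


def intersection_histogram(
    detected_sets: Mapping[str, Set[str]]
) -> Dict[int, int]:
    """How many MA ids are detected by exactly k of the assemblies."""
    counts: Dict[str, int] = {}
    for ids in detected_sets.values():
        for ma_id in ids:
            counts[ma_id] = counts.get(ma_id, 0) + 1
    hist: Dict[int, int] = {}
    for k in counts.values():
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


def length_recovery_table(
    records: Sequence[RecoveryRecord],
    length_bins: Sequence[Tuple[int, int, str]] = DEFAULT_LENGTH_BINS,
) -> List[Dict[str, object]]:
    """Box-plot summaries of % recovery per (length bin x expression bin) cell.

    Per cell: median, Q1, Q3, whiskers at the min/max of the non-outlier
    range, and outliers outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].  Empty cells
    are simply absent.
    """
    if not records:
        raise DomainError("no recovery records")
    cells: Dict[Tuple[str, str], List[float]] = {}
    for rec in records:
        if rec.excluded:
            continue
        key = (length_bin_label(rec.ma_len, length_bins), rec.bin)
        cells.setdefault(key, []).append(rec.pct_recovered)
    out = []
    for (lbin, ebin) in sorted(cells):
        vals = np.asarray(cells[(lbin, ebin)], dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inliers = vals[(vals >= lo) & (vals <= hi)]
        outliers = vals[(vals < lo) | (vals > hi)]
        out.append(
            {
                "length_bin": lbin,
                "expression_bin": ebin,
                "n": int(vals.size),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_low": float(inliers.min()) if inliers.size else float(med),
                "whisker_high": float(inliers.max()) if inliers.size else float(med),
                "n_outliers": int(outliers.size),
                "outliers": [float(v) for v in sorted(outliers)],
            }
        )
    return out


# ----------------------------------------------------------- misassembly ----


def misassembly_classify(
    chains: Mapping[str, CoverageChain],
    fragment_lengths: Mapping[str, int],
    length_bins: Sequence[Tuple[int, int, str]] = DEFAULT_LENGTH_BINS,
) -> Tuple[List[MisassemblyRecord], Dict[Tuple[str, str], int]]:
    """Single-source fraction per assembled fragment, categorized.

    A fragment mapping >= 90% of its length to one MA source is considered
    correctly assembled; below 90% it is chimeric across sources, with
    60-90% and <60% reported separately.  Fragments without hits land in
    lt60.  Also returns counts per (length bin, category).
    """
    records = []
    by_cell: Dict[Tuple[str, str], int] = {}
    for fid in sorted(fragment_lengths):
        length = fragment_lengths[fid]
        chain = chains.get(fid)
        if chain is not None:
            frac, subject = best_single_source_fraction(chain, length)
        else:
            frac, subject = 0.0, None
        rec = MisassemblyRecord(
            fragment_id=fid, length=length, best_fraction=frac, best_subject=subject
        )
        records.append(rec)
        cell = (length_bin_label(length, length_bins), rec.category)
        by_cell[cell] = by_cell.get(cell, 0) + 1
    return records, by_cell


# -------------------------------------------------------------- isoforms ----


def isoform_category(pct: float) -> str:
    """Exon length-recovery category; upper bounds closed, 0 on its own."""
    if pct <= 0:
        return "0%"
    for hi, label in zip((20, 40, 60, 80, 100), ISOFORM_CATEGORIES[1:]):
        if pct <= hi:
            return label
    return ISOFORM_CATEGORIES[-1]


def isoform_recovery(
    exon_records: Sequence[RecoveryRecord],
    exon_to_isoform: Mapping[str, str],
    isoform_pnc: Mapping[str, float],
) -> Tuple[Dict[str, Dict[str, int]], Dict[str, float]]:
    """Exon counts per recovery category per isoform, and median pnc per category.

    ``exon_records`` score each exon region (as its own subject) against an
    assembly; ``exon_to_isoform`` maps exon ids to their isoform.  An isoform
    is a member of a category when at least one of its exons falls in it; the
    per-category median pnc is taken over member isoforms.
    """
    per_isoform: Dict[str, Dict[str, int]] = {}
    members: Dict[str, Set[str]] = {c: set() for c in ISOFORM_CATEGORIES}
    for rec in exon_records:
        if rec.ma_id not in exon_to_isoform:
            raise ValidationError(f"exon {rec.ma_id} has no isoform mapping")
        iso = exon_to_isoform[rec.ma_id]
        cat = isoform_category(rec.pct_recovered)
        counts = per_isoform.setdefault(iso, {c: 0 for c in ISOFORM_CATEGORIES})
        counts[cat] += 1
        members[cat].add(iso)
    median_pnc = {
        cat: float(median(isoform_pnc[i] for i in isos))
        for cat, isos in members.items()
        if isos
    }
    return per_isoform, median_pnc


# --------------------------------------------------- shared/unique regions ----


def shared_unique_regions(
    transcripts: Sequence[SeqRecord],
    config: Optional[MapperConfig] = None,
) -> Dict[str, Dict[str, List[Tuple[int, int]]]]:
    """Partition each pooled transcript into shared and unique intervals.

    Shared = union of regions covered by hits from *other* transcripts in
    the pool (self-hits excluded); unique = the complement.  Isoform pairs
    surface their common exons as shared regions this way.
    """
    config = config or MapperConfig()
    out: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}
    if len(transcripts) < 2:
        return {
            t.id: {"shared": [], "unique": [(0, len(t))]} for t in transcripts
        }
    hits = map_sequences(transcripts, transcripts, config)
    covered: Dict[str, List[Tuple[int, int]]] = {t.id: [] for t in transcripts}
    for hit in hits:
        if hit.query_id == hit.subject_id:
            continue
        covered[hit.subject_id].append(hit.s_interval)
    for t in transcripts:
        shared = merge_intervals(covered[t.id])
        out[t.id] = {
            "shared": shared,
            "unique": subtract_intervals([(0, len(t))], shared),
        }
    return out


# ------------------------------------------------------------------- ROC ----


def roc_point(
    recovery_records: Sequence[RecoveryRecord],
    ma_total: int,
    query_chains: Mapping[str, CoverageChain],
    fragment_ids: Iterable[str],
) -> ROCPoint:
    """Sensitivity/specificity of one assembly against the MA.

    TPR = % of the total MA length recovered; FPR = % of assembled fragments
    with no retained hit to any MA fragment.
    """
    if ma_total < 1:
        raise DomainError("ma_total must be >= 1")
    fragment_ids = list(fragment_ids)
    if not fragment_ids:
        raise DomainError("assembly has no fragments")
    recovered = sum(r.recovered_len for r in recovery_records)
    unmapped = sum(
        1
        for fid in fragment_ids
        if fid not in query_chains or query_chains[fid].covered_len == 0
    )
    return ROCPoint(
        tpr_percent=100.0 * recovered / ma_total,
        fpr_percent=100.0 * unmapped / len(fragment_ids),
    )
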