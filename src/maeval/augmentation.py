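"""Augment a base assembly with the regions unique to a donor assembly.

The base assembly is mapped against the donor (donor = subject); the union
of hit intervals is subtracted from each donor sequence, and the remaining
intervals of at least ``min_region`` nt (default 76, the global minimum
fragment length) are cut out and appended to the base.  This mirrors the
combine-the-strengths strategy of merging a fragmented but sensitive
assembly with a full-length but sparse one: only donor material the base
does not already contain is added, so the size increase is exactly the
unique-region total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .formats_io import SeqRecord, ValidationError
from .hit_resolution import resolve
from .intervals import Interval, subtract_intervals
from .mapping import MapperConfig, map_sequences


@dataclass
class AugmentationReport:
    base_total_nt: int
    donor_total_nt: int
    unique_region_count: int
    unique_total_nt: int
    augmented_total_nt: int
    new_ma_detected: Optional[int] = None
    recovery_gain_nt: Optional[int] = None

    def __post_init__(self) -> None:
        assert self.augmented_total_nt == self.base_total_nt + self.unique_total_nt
        assert self.unique_total_nt <= self.donor_total_nt


def unique_donor_regions(
    base: Sequence[SeqRecord],
    donor: Sequence[SeqRecord],
    config: Optional[MapperConfig] = None,
    min_region: int = 76,
    unique_threshold: int = 10,
) -> Tuple[List[Tuple[str, Interval]], List[SeqRecord]]:
    """Donor intervals not covered by the base, as intervals and sequences.

    The base is the query set and the donor the subject set; per donor
    sequence the resolved hit coverage is subtracted from [0, len) and
    leftover intervals >= ``min_region`` are emitted as new records with ids
    ``donorid:start-end``.
    """
    if not base or not donor:
        raise ValidationError("both assemblies must be non-empty")
    config = config or MapperConfig()
    hits = map_sequences(base, donor, config)
    chains = resolve(hits, axis="subject", unique_threshold=unique_threshold)
    intervals: List[Tuple[str, Interval]] = []
    records: List[SeqRecord] = []
    for rec in donor:
        chain = chains.get(rec.id)
        covered = chain.covered if chain else []
        for s, e in subtract_intervals([(0, len(rec))], covered):
            if e - s >= min_region:
                intervals.append((rec.id, (s, e)))
                records.append(SeqRecord(f"{rec.id}:{s}-{e}", rec.sequence[s:e]))
    return intervals, records


def augment(
    base: Sequence[SeqRecord],
    unique: Sequence[SeqRecord],
    donor_total_nt: int = 0,
) -> Tuple[List[SeqRecord], AugmentationReport]:
    """Concatenate base and unique-region records; exact size conservation."""
    ids = [r.id for r in base] + [r.id for r in unique]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate ids between base and unique regions")
    augmented = list(base) + list(unique)
    base_total = sum(len(r) for r in base)
    unique_total = sum(len(r) for r in unique)
    report = AugmentationReport(
        base_total_nt=base_total,
        donor_total_nt=donor_total_nt,
        unique_region_count=len(unique),
        unique_total_nt=unique_total,
        augmented_total_nt=base_total + unique_total,
    )
    return augmented, report


def augment_assembly(
    base: Sequence[SeqRecord],
    donor: Sequence[SeqRecord],
    config: Optional[MapperConfig] = None,
    min_region: int = 76,
) -> Tuple[List[SeqRecord], AugmentationReport, List[Tuple[str, Interval]]]:
    """One-call convenience: find unique donor regions and merge them in."""
    intervals, records = unique_donor_regions(
        base, donor, config=config, min_region=min_region
    )
    donor_total = sum(len(r) for r in donor)
    augmented, report = augment(base, records, donor_total_nt=donor_total)
    return augmented, report, intervals
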