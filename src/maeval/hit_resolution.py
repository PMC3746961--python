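"""Greedy hit chaining: non-redundant coverage per query or per subject.

Raw hits are reduced per anchor (the query for misassembly statistics, the
subject for recovery statistics) by a greedy parser: candidates are visited
in descending anchor-axis length (ties: descending surrogate score, then
partner id, then anchor start) and retained only if they add strictly more
than ``unique_threshold`` (default 10) nt of new coverage on the anchor.
Nested hits add nothing and are always rejected; a partially overlapping hit
whose unique contribution is <= 10 nt is discarded.

The greedy parser is not a coverage optimizer: rare configurations exist
where a different subset covers more of the anchor.  That behaviour is
intentional and frozen by tests; the selection rule, not maximum coverage,
is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .formats_io import HitRow
from .intervals import Interval, add_interval, merge_intervals, new_coverage, total_length
from .model_assembly import DomainError

AXES = ("query", "subject")


@dataclass
class CoverageChain:
    """Retained hits and their disjoint coverage on one anchor sequence."""

    anchor_id: str
    axis: str
    hits: List[HitRow] = field(default_factory=list)
    covered: List[Interval] = field(default_factory=list)

    @property
    def covered_len(self) -> int:
        return total_length(self.covered)


def _anchor_interval(hit: HitRow, axis: str) -> Interval:
    return hit.q_interval if axis == "query" else hit.s_interval


def _partner_id(hit: HitRow, axis: str) -> str:
    return hit.subject_id if axis == "query" else hit.query_id


def _sort_key(axis: str):
    def key(hit: HitRow):
        s, e = _anchor_interval(hit, axis)
        return (-(e - s), -hit.score, _partner_id(hit, axis), s)

    return key


def resolve(
    hits: Iterable[HitRow],
    axis: str = "query",
    unique_threshold: int = 10,
    per_pair: bool = False,
) -> Dict[str, CoverageChain]:
    """Greedy chain selection per anchor; returns chains keyed by anchor id.

    With ``per_pair`` the greedy pass runs separately within each
    (anchor, partner) pair and the chain unions the per-pair selections;
    the default applies the rules globally per anchor.
    """
    if axis not in AXES:
        raise DomainError(f"axis must be one of {AXES}, got {axis!r}")

    grouped: Dict[str, List[HitRow]] = {}
    for hit in hits:
        anchor = hit.query_id if axis == "query" else hit.subject_id
        grouped.setdefault(anchor, []).append(hit)

    chains: Dict[str, CoverageChain] = {}
    for anchor in sorted(grouped):
        chain = CoverageChain(anchor_id=anchor, axis=axis)
        if per_pair:
            pairs: Dict[str, List[HitRow]] = {}
            for hit in grouped[anchor]:
                pairs.setdefault(_partner_id(hit, axis), []).append(hit)
            groups = [pairs[p] for p in sorted(pairs)]
        else:
            groups = [grouped[anchor]]
        for group in groups:
            covered: List[Interval] = []
            kept: List[HitRow] = []
            for hit in sorted(group, key=_sort_key(axis)):
                iv = _anchor_interval(hit, axis)
                if new_coverage(covered, iv) > unique_threshold:
                    covered = add_interval(covered, iv)
                    kept.append(hit)
            chain.hits.extend(kept)
            chain.covered = merge_intervals(chain.covered + covered)
        chains[anchor] = chain
    return chains


def best_single_source_fraction(
    chain: CoverageChain, query_length: int
) -> Tuple[float, Optional[str]]:
    """Largest fraction of the query covered by retained hits to one subject.

    An assembled fragment belongs to a single source when this fraction is
    >= 0.9; below that it is considered chimeric across sources.  Ties pick
    the lexicographically smallest subject id.  No hits: (0.0, None).
    """
    if chain.axis != "query":
        raise DomainError("best_single_source_fraction needs a query-axis chain")
    if query_length < 1:
        raise DomainError("query_length must be >= 1")
    per_subject: Dict[str, List[Interval]] = {}
    for hit in chain.hits:
        per_subject.setdefault(hit.subject_id, []).append(hit.q_interval)
    best: Tuple[float, Optional[str]] = (0.0, None)
    for subject in sorted(per_subject):
        frac = total_length(merge_intervals(per_subject[subject])) / query_length
        if frac > best[0]:
            best = (frac, subject)
    return best
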