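"""N50/N_MA50, recovery, misassembly categories, isoforms, shared regions, ROC."""

import numpy as np
import pytest

from maeval.formats_io import SeqRecord
from maeval.hit_resolution import CoverageChain, resolve
from maeval.mapping import MapperConfig, map_sequences, reverse_complement
from maeval.metrics import (
    MisassemblyRecord,
    RecoveryRecord,
    intersection_histogram,
    isoform_category,
    isoform_recovery,
    length_bin_label,
    length_recovery_table,
    misassembly_classify,
    n50,
    recovery_stats,
    roc_point,
    shared_unique_regions,
    summarize_assembly,
)
from maeval.model_assembly import DomainError, MAFragment

from conftest import random_seq


def oracle_n50(lengths, denom=None):
    """Independent cumulative-sum implementation via numpy."""
    arr = np.sort(np.asarray(lengths))[::-1]
    cum = np.cumsum(arr)
    target = (cum[-1] if denom is None else denom) / 2
    idx = np.searchsorted(cum, target, side="left")
    return int(arr[idx]) if idx < len(arr) else 0


def frag(tid="t1", start=0, end=100, bin="B1", excluded=False, pnc=1.0):
    return MAFragment(tid, start, end, read_count=1, pnc=pnc, bin=bin, excluded=excluded)


def subject_chain(ma_id, covered):
    chain = CoverageChain(anchor_id=ma_id, axis="subject")
    chain.covered = covered
    return chain


class TestN50:
    def test_worked_example(self):
        assert n50([8, 4, 3, 2, 2, 1]) == 4

    def test_ma_denominator_variant(self):
        assert n50([8, 4, 3, 2, 2, 1], denominator_total=40) == 1

    def test_singleton(self):
        assert n50([10]) == 10

    def test_undefined_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert n50([5, 5], denominator_total=100) == 0

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            n50([])

    def test_matches_cumulative_sum_oracle(self, rng):
        for _ in range(300):
            lengths = rng.integers(1, 5000, size=int(rng.integers(1, 60))).tolist()
            assert n50(lengths) == oracle_n50(lengths)
            denom = int(rng.integers(1, 2 * sum(lengths)))
            expected = oracle_n50(lengths, denom)
            if expected == 0:
                with pytest.warns(UserWarning):
                    assert n50(lengths, denom) == 0
            else:
                assert n50(lengths, denom) == expected


class TestSummary:
    def test_length_multiset_fields(self):
        recs = [SeqRecord(f"f{i}", "A" * n) for i, n in enumerate([76, 100, 200])]
        s = summarize_assembly(recs)
        assert (s.min_len, s.median_len, s.max_len, s.total_nt) == (76, 100.0, 200, 376)
        assert s.n_fragments == 3

    def test_exact_ma_copy_equal_n50s(self):
        recs = [SeqRecord(f"f{i}", "A" * n) for i, n in enumerate([300, 150, 90])]
        s = summarize_assembly(recs, ma_total=540)
        assert s.n50 == s.n_ma50

    def test_n_ma50_monotone_in_added_fragments(self, rng):
        ma_total = 10000
        lengths = [500, 400, 300]
        base = n50(lengths, ma_total) if sum(lengths) * 2 >= ma_total else 0
        for extra in [100, 600, 2000]:
            grown = lengths + [extra]
            if sum(grown) * 2 < ma_total:
                continue
            assert n50(grown, ma_total) >= base


class TestRecovery:
    def test_perfect_assembly_all_full(self):
        ma = [frag(end=100), frag(tid="t2", end=150, bin="B2")]
        chains = {
            "t1:0-100": subject_chain("t1:0-100", [(0, 100)]),
            "t2:0-150": subject_chain("t2:0-150", [(0, 150)]),
        }
        records, bins = recovery_stats(chains, ma)
        assert all(r.pct_recovered == 100.0 for r in records)
        assert bins == {"B1": 1, "B2": 1}

    def test_empty_assembly_all_zero(self):
        records, bins = recovery_stats({}, [frag(), frag(tid="t2")])
        assert all(r.recovered_len == 0 and not r.detected for r in records)
        assert bins == {}

    def test_excluded_fragments_skip_bin_counts(self):
        ma = [frag(excluded=True), frag(tid="t2")]
        chains = {f.ma_id: subject_chain(f.ma_id, [(0, 100)]) for f in ma}
        records, bins = recovery_stats(chains, ma)
        assert bins == {"B1": 1}
        assert all(r.detected for r in records)

    def test_intersection_histogram(self):
        hist = intersection_histogram(
            {"a": {"m1", "m2", "m3"}, "b": {"m2", "m3"}, "c": {"m3"}}
        )
        assert hist == {1: 1, 2: 1, 3: 1}


class TestLengthRecoveryTable:
    def test_default_bins_reproduce_categories(self):
        assert length_bin_label(76) == "<=76"
        assert length_bin_label(77) == "76-300"
        assert length_bin_label(300) == "76-300"
        assert length_bin_label(1500) == "1000-1500"
        assert length_bin_label(6500) == "5000-6500"
        assert length_bin_label(9000) == ">6500"

    def test_uniform_cell_no_outliers(self):
        records = [
            RecoveryRecord(f"t1:0-{i}00", "B1", 100, 100) for i in range(1, 6)
        ]
        (cell,) = length_recovery_table(records)
        assert cell["median"] == cell["q1"] == cell["q3"] == 100.0
        assert cell["n_outliers"] == 0

    def test_outliers_by_direct_iqr_formula(self):
        vals = [10, 20, 30, 40, 95]
        records = [
            RecoveryRecord(f"t1:0-{i}", "B1", 100, v)
            for i, v in enumerate(vals)
        ]
        (cell,) = length_recovery_table(records)
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        expected = sorted(v for v in vals if v < q1 - 1.5 * iqr or v > q3 + 1.5 * iqr)
        assert cell["outliers"] == [float(v) for v in expected]
        assert cell["whisker_high"] == max(v for v in vals if v <= q3 + 1.5 * iqr)


class TestMisassembly:
    @pytest.mark.parametrize(
        "fraction,category",
        [
            (0.95, "ge90"),
            (0.90, "ge90"),  # boundary goes up
            (0.70, "b60_90"),
            (0.60, "b60_90"),  # boundary goes up
            (0.50, "lt60"),
            (0.0, "lt60"),
        ],
    )
    def test_category_thresholds(self, fraction, category):
        rec = MisassemblyRecord("f", 100, fraction, "s")
        assert rec.category == category

    def test_counts_sum_to_fragment_number(self, rng):
        lengths = {f"f{i}": int(rng.integers(76, 800)) for i in range(20)}
        records, cells = misassembly_classify({}, lengths)
        assert len(records) == 20
        assert sum(cells.values()) == 20
        assert all(cat == "lt60" for (_, cat) in cells)


class TestIsoformRecovery:
    def test_categories(self):
        assert isoform_category(0.0) == "0%"
        assert isoform_category(15.0) == ">0-20%"
        assert isoform_category(20.0) == ">0-20%"
        assert isoform_category(20.5) == ">20-40%"
        assert isoform_category(80.5) == ">80-100%"
        assert isoform_category(100.0) == ">80-100%"

    def test_fully_recovered_isoform(self):
        records = [
            RecoveryRecord(f"iso1:exon{k}", "B3", 100, 100) for k in range(3)
        ]
        mapping = {f"iso1:exon{k}": "iso1" for k in range(3)}
        per_iso, med = isoform_recovery(records, mapping, {"iso1": 12.0})
        assert per_iso["iso1"][">80-100%"] == 3
        assert sum(per_iso["iso1"].values()) == 3
        assert med == {">80-100%": 12.0}

    def test_unrecovered_isoform_all_zero_category(self):
        records = [RecoveryRecord(f"iso1:exon{k}", "B1", 100, 0) for k in range(2)]
        mapping = {f"iso1:exon{k}": "iso1" for k in range(2)}
        per_iso, _ = isoform_recovery(records, mapping, {"iso1": 2.0})
        assert per_iso["iso1"]["0%"] == 2

    def test_median_pnc_tracks_expression_gradient(self):
        # isoforms with higher pnc recover better: medians must not decrease
        records, mapping, pnc = [], {}, {}
        for i, (p, rec_pct) in enumerate(
            [(1.0, 0), (2.0, 10), (5.0, 50), (12.0, 90), (25.0, 100)]
        ):
            eid = f"iso{i}:exon0"
            records.append(RecoveryRecord(eid, "B1", 100, rec_pct))
            mapping[eid] = f"iso{i}"
            pnc[f"iso{i}"] = p
        _, med = isoform_recovery(records, mapping, pnc)
        cats = ["0%", ">0-20%", ">40-60%", ">80-100%"]
        vals = [med[c] for c in cats]
        assert vals == sorted(vals)


class TestSharedUnique:
    def test_identical_transcripts_fully_shared(self, rng):
        seq = random_seq(rng, 200)
        regions = shared_unique_regions(
            [SeqRecord("a", seq), SeqRecord("b", seq)], MapperConfig()
        )
        assert regions["a"]["shared"] == [(0, 200)]
        assert regions["a"]["unique"] == []
        assert regions["b"]["shared"] == [(0, 200)]

    def test_unrelated_transcripts_fully_unique(self, rng):
        a, b = random_seq(rng, 200), random_seq(rng, 180)
        regions = shared_unique_regions(
            [SeqRecord("a", a), SeqRecord("b", b)], MapperConfig()
        )
        assert regions["a"]["unique"] == [(0, 200)]
        assert regions["b"]["unique"] == [(0, 180)]

    def test_single_transcript_all_unique(self, rng):
        regions = shared_unique_regions([SeqRecord("a", random_seq(rng, 150))])
        assert regions["a"]["unique"] == [(0, 150)]

    def test_planted_common_exon_recovered_within_edge_slack(self, rng):
        word = 28
        exon = random_seq(rng, 100)
        a = random_seq(rng, 150) + exon + random_seq(rng, 150)
        b = random_seq(rng, 80) + exon + random_seq(rng, 120)
        regions = shared_unique_regions(
            [SeqRecord("a", a), SeqRecord("b", b)], MapperConfig(word_size=word)
        )
        (sh,) = regions["a"]["shared"]
        assert abs(sh[0] - 150) <= word - 1
        assert abs(sh[1] - 250) <= word - 1


class TestRoc:
    def test_perfect_assembly(self):
        ma = [frag(end=100)]
        schains = {"t1:0-100": subject_chain("t1:0-100", [(0, 100)])}
        records, _ = recovery_stats(schains, ma)
        qchain = CoverageChain(anchor_id="f1", axis="query")
        qchain.covered = [(0, 100)]
        point = roc_point(records, 100, {"f1": qchain}, ["f1"])
        assert (point.tpr_percent, point.fpr_percent) == (100.0, 0.0)

    def test_unrelated_assembly(self):
        ma = [frag(end=100)]
        records, _ = recovery_stats({}, ma)
        point = roc_point(records, 100, {}, ["f1", "f2"])
        assert (point.tpr_percent, point.fpr_percent) == (0.0, 100.0)

    def test_recovered_never_exceeds_ma_total(self, rng):
        ma = [frag(end=100), frag(tid="t2", end=200)]
        chains = {
            f.ma_id: subject_chain(f.ma_id, [(0, int(rng.integers(1, f.length + 1)))])
            for f in ma
        }
        records, _ = recovery_stats(chains, ma)
        assert sum(r.recovered_len for r in records) <= 300
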