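"""Site statistics, indel-event counting, SV, and hotspot ranking."""

from __future__ import annotations

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastomma.align import Alignment
from plastomma.variability import (
    VariabilityResult,
    analyze_region,
    count_site_stats,
    detect_indel_events,
    indel_events_by_partition,
    rank_hotspots,
    sequence_variability,
)


def site_stats_oracle(rows: list[str]) -> tuple[int, int, int]:
    """Column-by-column recount with plain Python dictionaries."""
    s = m = pic = 0
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for ch in col:
            if ch in "ACGT":
                counts[ch] = counts.get(ch, 0) + 1
        k = len(counts)
        if k >= 2:
            s += 1
        if k >= 1:
            m += k - 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            pic += 1
    return s, m, pic


def indel_oracle(rows: list[str]) -> dict[tuple[int, int], int]:
    """Exhaustive enumeration of distinct maximal interior gap intervals."""
    n_cols = len(rows[0])
    intervals: dict[tuple[int, int], int] = {}
    for row in rows:
        for match in re.finditer(r"-+", row):
            s, e = match.span()
            if s == 0 or e == n_cols:
                continue
            intervals[(s, e)] = intervals.get((s, e), 0) + 1
    return intervals


aligned_rows = st.integers(2, 10).flatmap(
    lambda r: st.integers(2, 50).flatmap(
        lambda c: st.lists(
            st.text(alphabet="ACGTN-", min_size=c, max_size=c),
            min_size=r,
            max_size=r,
        )
    )
)


class TestSiteStats:
    def test_identical_rows(self):
        aln = Alignment(taxa=list("abcd"), rows=["ACGT"] * 4)
        assert count_site_stats(aln) == (0, 0, 0)

    @pytest.mark.parametrize(
        "column, expected",
        [
            ("AATG", (1, 2, 0)),  # tri-allelic: one site, two mutations, no PIC
            ("AATT", (1, 1, 1)),  # balanced biallelic: informative
            ("AAAT", (1, 1, 0)),  # singleton: not informative
            ("A--N", (0, 0, 0)),  # gaps and N never create variability
            ("----", (0, 0, 0)),
        ],
    )
    def test_single_column_definitions(self, column, expected):
        rows = [c + "G" for c in column]  # pad with an invariant column
        aln = Alignment(taxa=[f"t{i}" for i in range(len(rows))], rows=rows)
        assert count_site_stats(aln) == expected

    @settings(max_examples=60, derandomize=True)
    @given(aligned_rows)
    def test_matches_columnwise_oracle(self, rows):
        aln = Alignment(taxa=[f"t{i}" for i in range(len(rows))], rows=rows)
        assert count_site_stats(aln) == site_stats_oracle(aln.rows)

    def test_random_alignment_against_oracle(self):
        rng = np.random.default_rng(12)
        rows = [
            "".join(rng.choice(list("ACGT-N"), p=[0.22] * 4 + [0.08, 0.04], size=300))
            for _ in range(12)
        ]
        aln = Alignment(taxa=[f"t{i}" for i in range(12)], rows=rows)
        assert count_site_stats(aln) == site_stats_oracle(rows)


class TestIndelEvents:
    def test_gapless(self):
        aln = Alignment(taxa=["a", "b"], rows=["ACGTACGT", "ACGTACGT"])
        assert detect_indel_events(aln) == []

    def test_single_interior_gap(self):
        aln = Alignment(taxa=["a", "b"], rows=["AC-----T", "ACGTACGT"])
        events = detect_indel_events(aln)
        assert len(events) == 1
        assert (events[0].start, events[0].end) == (2, 7)

    def test_shared_gap_is_one_event(self):
        rows = ["AC-----TAA"] * 3 + ["ACGTACGTAA"] * 7
        aln = Alignment(taxa=[f"t{i}" for i in range(10)], rows=rows)
        events = detect_indel_events(aln)
        assert len(events) == 1
        assert len(events[0].members) == 3

    def test_terminal_gaps_excluded(self):
        aln = Alignment(taxa=["a", "b"], rows=["--GTAC--", "ACGTACGT"])
        assert detect_indel_events(aln) == []

    def test_nested_gaps_are_distinct_events(self):
        aln = Alignment(
            taxa=["a", "b", "c"],
            rows=["AC----GT", "ACA---GT", "ACAAAAGT"],
        )
        events = detect_indel_events(aln)
        assert {(e.start, e.end) for e in events} == {(2, 6), (3, 6)}

    @settings(max_examples=60, derandomize=True)
    @given(aligned_rows)
    def test_matches_enumeration_oracle(self, rows):
        aln = Alignment(taxa=[f"t{i}" for i in range(len(rows))], rows=rows)
        events = detect_indel_events(aln)
        expected = indel_oracle(aln.rows)
        assert {(e.start, e.end) for e in events} == set(expected)
        for event in events:
            assert len(event.members) == expected[(event.start, event.end)]


class TestSequenceVariability:
    @pytest.mark.parametrize(
        "l, m, i, expected",
        [(100, 0, 0, 0.0), (7, 3, 2, 100 * 5 / 12), (90, 10, 0, 10.0)],
    )
    def test_closed_form(self, l, m, i, expected):
        assert sequence_variability(l, m, i) == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            sequence_variability(0, 1, 1)

    @settings(max_examples=80, derandomize=True)
    @given(
        st.integers(1, 10_000),
        st.integers(0, 500),
        st.integers(0, 500),
    )
    def test_monotonicity(self, l, m, i):
        """SV increases in m and i, decreases in l."""
        sv = sequence_variability(l, m, i)
        assert 0 <= sv <= 100
        assert sequence_variability(l, m + 1, i) > sv
        assert sequence_variability(l, m, i + 1) > sv
        if m + i > 0:
            assert sequence_variability(l + 1, m, i) < sv
        assert (sv == 0) == (m + i == 0)

    def test_planted_counts_recovered_exactly(self):
        """An alignment with exactly m*=12 biallelic substitutions and
        i*=3 distinct interior deletions gives SV = 100*15/(l+15)."""
        rng = np.random.default_rng(42)
        l = 100
        base = "".join(rng.choice(list("ACGT"), l))
        rows = [list(base) for _ in range(10)]
        sub_cols = rng.choice(np.arange(2, l - 2), size=12, replace=False)
        for col in sub_cols:
            alt = next(b for b in "ACGT" if b != base[col])
            rows[int(rng.integers(0, 10))][col] = alt
        gap_intervals = [(10, 14), (40, 48), (70, 71)]
        for row_idx, (s, e) in zip((3, 5, 7), gap_intervals):
            for c in range(s, e):
                rows[row_idx][c] = "-"
        aln = Alignment(
            taxa=[f"t{k}" for k in range(10)], rows=["".join(r) for r in rows]
        )
        s_count, m, _ = count_site_stats(aln)
        events = detect_indel_events(aln)
        assert m == 12 and s_count == 12
        assert len(events) == 3
        sv = sequence_variability(aln.n_cols, m, len(events))
        assert sv == pytest.approx(100 * 15 / (100 + 15), abs=1e-12)

    def test_negative_control_identical_sequences(self):
        aln = Alignment(taxa=list("abcd"), rows=["ACGTAC" * 20] * 4)
        result = analyze_region("ctrl", aln)
        assert result.sv == 0.0
        assert result.mutations == result.indel_events == 0


class TestRankHotspots:
    def _results(self, svs, ms=None):
        ms = ms or [0] * len(svs)
        return [
            VariabilityResult(name=f"r{k}", sv=sv, mutations=m, length=100)
            for k, (sv, m) in enumerate(zip(svs, ms))
        ]

    def test_descending_top_k(self):
        ranked = rank_hotspots(self._results([30.0, 40.0, 20.0]), k=2)
        assert [r.sv for r in ranked] == [40.0, 30.0]

    def test_sv_tie_broken_by_mutations(self):
        ranked = rank_hotspots(self._results([10.0, 10.0], ms=[2, 5]), k=2)
        assert [r.mutations for r in ranked] == [5, 2]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(8)
        results = [
            VariabilityResult(
                name=f"reg{k:03d}",
                sv=float(rng.choice([5.0, 10.0, 15.0])),
                mutations=int(rng.integers(0, 4)),
                length=100,
            )
            for k in range(104)
        ]
        ranked = rank_hotspots(results, k=10)
        oracle = sorted(results, key=lambda r: (-r.sv, -r.mutations, r.name))[:10]
        assert [r.name for r in ranked] == [r.name for r in oracle]


class TestIndelEventsByPartition:
    REGIONS = [("LSC", 0, 50), ("SSC", 50, 80), ("IR", 80, 100)]

    def _pair(self, ref: str, query: str) -> Alignment:
        return Alignment(taxa=["ref", "qry"], rows=[ref, query])

    def test_planted_counts(self):
        ref = "A" * 100
        query = list(ref)
        for s, e in [(5, 8), (20, 24), (40, 42), (60, 65)]:  # 3 LSC + 1 SSC
            for c in range(s, e):
                query[c] = "-"
        counts = indel_events_by_partition(
            self._pair(ref, "".join(query)), "ref", self.REGIONS
        )
        assert (counts["LSC"], counts["SSC"], counts["IR"]) == (3, 1, 0)

    def test_boundary_midpoint_goes_left(self):
        """An event whose reference midpoint sits exactly on a region
        boundary belongs to the region ending there."""
        ref = "A" * 100
        query = list(ref)
        for c in range(49, 52):  # midpoint column 50 = LSC/SSC boundary
            query[c] = "-"
        counts = indel_events_by_partition(
            self._pair(ref, "".join(query)), "ref", self.REGIONS
        )
        assert counts["LSC"] == 1 and counts["SSC"] == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_totals_match_membership_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        ref = "".join(rng.choice(list("ACGT"), 100))
        query = list(ref)
        placed = []
        cursor = 2
        while cursor < 95:
            if rng.random() < 0.25:
                length = int(rng.integers(1, 5))
                end = min(cursor + length, 97)
                placed.append((cursor, end))
                for c in range(cursor, end):
                    query[c] = "-"
                cursor = end + 2
            else:
                cursor += 3
        pair = self._pair(ref, "".join(query))
        counts = indel_events_by_partition(pair, "ref", self.REGIONS)
        expected = {"LSC": 0, "SSC": 0, "IR": 0}
        for s, e in placed:
            mid = (s + e - 1) // 2  # query gap: columns = reference coords
            for name, lo, hi in self.REGIONS:
                if lo < mid <= hi or (mid == 0 and lo == 0):
                    expected[name] += 1
                    break
        assert counts == expected

    def test_requires_reference_in_alignment(self):
        with pytest.raises(ValueError):
            indel_events_by_partition(
                self._pair("AAAA", "AA-A"), "nope", self.REGIONS
            )


class TestFamilyWindows:
    def test_igs_window_statistics_match_truth(self, family):
        """m and i recovered exactly on every ancestor spacer window."""
        _, truth = family
        checked = 0
        for name, part, s, e in truth.igs_windows():
            if e - s < 150:
                continue
            aln = truth.region_alignment(part, s, e)
            _s, m, _pic = count_site_stats(aln)
            events = detect_indel_events(aln)
            assert m == truth.expected_substitutions(part, s, e), name
            assert len(events) == truth.expected_indel_events(part, s, e), name
            checked += 1
        assert checked > 20
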