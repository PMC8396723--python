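"""SSR scanning, cross-taxon polymorphism, and primer constraints."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastomma.align import Alignment
from plastomma.io import drop_one_ir
from plastomma.records import revcomp
from plastomma.ssr import (
    DEFAULT_MINIMA,
    HOTSPOT_PROFILE,
    SSR_PROFILE,
    PrimerCandidate,
    PrimerConstraints,
    canonical_rotation,
    contextualize,
    filter_primers,
    gc_tm,
    group_compound,
    motif_class,
    polymorphic_loci,
    scan_ssrs,
    wallace_tm,
)


def _primitive(motif: str) -> bool:
    return all(
        not (len(motif) % d == 0 and motif == motif[: d] * (len(motif) // d))
        for d in range(1, len(motif))
    )


def exhaustive_ssr_oracle(seq: str, minima=None) -> set[tuple[str, int, int, int]]:
    """Test every (position, unit) pair: greedy repeat extension with
    explicit left-maximality; reported under the primitive motif only."""
    minima = minima or DEFAULT_MINIMA
    found = set()
    n = len(seq)
    for unit, min_reps in minima.items():
        for i in range(n - unit * min_reps + 1):
            motif = seq[i : i + unit]
            if "N" in motif or not _primitive(motif):
                continue
            # left maximality: the position one before must break the period
            if i >= 1 and seq[i - 1] == seq[i - 1 + unit]:
                continue
            reps = 1
            while (
                i + (reps + 1) * unit <= n
                and seq[i + reps * unit : i + (reps + 1) * unit] == motif
            ):
                reps += 1
            if reps >= min_reps:
                found.add((motif, reps, i, i + reps * unit))
    return found


class TestScanner:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("AAAAAAAAAA", [("A", 10)]),  # exactly the mono minimum
            ("AAAAAAAAA", []),  # one repeat short
            ("ATATATATAT", [("AT", 5)]),  # shortest-period rule: di, not mono
            ("AGCAGCAGC", [("AGC", 3)]),
            ("ACGTACGTACG", []),  # tetra needs 3 full units
        ],
    )
    def test_threshold_examples(self, seq, expected):
        loci = scan_ssrs(seq)
        assert [(l.motif, l.reps) for l in loci] == expected

    def test_locus_embedded_with_flanks(self):
        seq = "GCGC" + "TA" * 6 + "GGCC"
        loci = scan_ssrs(seq)
        assert [(l.motif, l.reps, l.start, l.end) for l in loci] == [("TA", 6, 4, 16)]

    def test_rejects_bad_characters(self):
        with pytest.raises(ValueError):
            scan_ssrs("ACGTRYACGT")

    def test_n_breaks_repeats(self):
        assert scan_ssrs("AAAAANAAAAA") == []

    @settings(max_examples=80, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=120))
    def test_matches_exhaustive_oracle(self, seq):
        got = {(l.motif, l.reps, l.start, l.end) for l in scan_ssrs(seq)}
        assert got == exhaustive_ssr_oracle(seq)

    @pytest.mark.parametrize("seed", range(3))
    def test_oracle_on_5kb_random(self, seed):
        rng = np.random.default_rng(1000 + seed)
        # AT-rich so repeats actually occur
        seq = "".join(rng.choice(list("ACGT"), p=[0.36, 0.14, 0.14, 0.36], size=5000))
        got = {(l.motif, l.reps, l.start, l.end) for l in scan_ssrs(seq)}
        assert got == exhaustive_ssr_oracle(seq)

    def test_maximality(self):
        """No reported locus extends by one unit in either direction."""
        rng = np.random.default_rng(77)
        seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=3000))
        for locus in scan_ssrs(seq):
            u = locus.unit
            if locus.start >= u:
                assert seq[locus.start - u : locus.start] != locus.motif
            if locus.end + u <= len(seq):
                assert seq[locus.end : locus.end + u] != locus.motif

    def test_reverse_complement_mirror(self):
        """Scanning the reverse complement preserves the locus set: same
        count, reverse-complemented motifs, mirrored coordinates (up to
        the reporting phase within a partially-extended run)."""
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=3000))
        fwd = scan_ssrs(seq)
        rev = scan_ssrs(revcomp(seq))
        assert len(fwd) == len(rev)
        n = len(seq)
        original = [
            (canonical_rotation(l.motif), l.reps, l.start) for l in fwd
        ]
        for locus in rev:
            start = n - locus.end
            key = canonical_rotation(revcomp(locus.motif))
            assert any(
                k == key and reps == locus.reps and abs(s - start) < locus.unit
                for k, reps, s in original
            ), locus

    def test_compound_grouping_preserves_count(self):
        seq = "AAAAAAAAAAAA" + "GC" * 10 + "TTTTTTTTTTT" + "G" * 200
        loci = scan_ssrs(seq)
        groups = group_compound(loci, max_gap=100)
        assert sum(len(g) for g in groups) == len(loci)
        assert len(groups) < len(loci)  # nearby loci got grouped


class TestMotifClasses:
    def test_canonical_rotation(self):
        assert canonical_rotation("TAA") == "AAT"

    def test_complement_insensitive_class(self):
        assert motif_class("A") == "A/T"
        assert motif_class("AAG") == motif_class("CTT")
        assert motif_class("AT") == "AT"  # self-complementary class


class TestContextualize:
    def test_planted_contexts(self, small_family):
        records, truth = small_family
        rec = drop_one_ir(records[0])
        cds = rec.get_features("psbB", kind="CDS")[0]
        mono = "A" * 11
        pos = cds.segments[0][0] + 30
        seq = rec.sequence[:pos] + mono + rec.sequence[pos + 11 :]
        rec2 = rec.copy()
        rec2.sequence = seq
        loci = [l for l in scan_ssrs(seq) if l.start == pos]
        out = contextualize(loci, rec2)
        assert out and out[0].context == "CDS"
        assert out[0].region == "LSC"

    def test_igs_context(self, family):
        records, truth = family
        rec = drop_one_ir(records[0])
        loci = contextualize(scan_ssrs(rec.sequence), rec)
        expected = {
            (l.start, l.end) for l in truth.ssr_expected_loci(records[0].taxon)
        }
        planted = [l for l in loci if (l.start, l.end) in expected]
        assert planted and all(l.context == "IGS" for l in planted)

    def test_assignments_match_interval_oracle(self, family):
        records, _ = family
        rec = drop_one_ir(records[1])
        loci = contextualize(scan_ssrs(rec.sequence), rec)
        regions = rec.annotations["regions"]
        for locus in loci[:50]:
            mid = (locus.start + locus.end - 1) // 2
            expected = next(name for name, s, e in regions if s <= mid < e)
            assert locus.region == expected


class TestPolymorphicLoci:
    def test_planted_polymorphic_locus(self):
        """(AT)5 vs (AT)7 at homologous positions in 8 of 10 taxa."""
        taxa = [f"t{i}" for i in range(10)]
        lead, tail = "GCGGC", "CCGGA"
        rows, per_taxon = [], {}
        for idx, taxon in enumerate(taxa):
            if idx < 8:
                reps = 5 if idx % 2 else 7
                seq = lead + "AT" * reps + tail
                row = lead + "AT" * reps + "--" * (7 - reps) + tail
                per_taxon[taxon] = [
                    l for l in scan_ssrs(seq, {2: 5}) if l.motif in ("AT", "TA")
                ]
            else:
                row = lead + "GGCCAAGGCCAse"[:0] + "GGCCAATTCCGGAA"[: 14] + tail
                row = lead + "--" * 7 + tail
                per_taxon[taxon] = []
            rows.append(row)
        aln = Alignment(taxa=taxa, rows=rows)
        cross = polymorphic_loci(per_taxon, aln, min_presence=7)
        assert len(cross) == 1
        locus = cross[0]
        assert locus.presence == 8
        assert locus.polymorphic
        assert set(locus.reps.values()) == {5, 7}

    def test_monomorphic_locus_flagged(self):
        taxa = [f"t{i}" for i in range(8)]
        seq = "GGCGC" + "A" * 12 + "CGCGG"
        per_taxon = {t: scan_ssrs(seq) for t in taxa}
        aln = Alignment(taxa=taxa, rows=[seq] * 8)
        cross = polymorphic_loci(per_taxon, aln, min_presence=7)
        assert len(cross) == 1
        assert not cross[0].polymorphic

    def test_absent_taxon_raises(self):
        aln = Alignment(taxa=["a", "b"], rows=["ACGT" * 5, "ACGT" * 5])
        with pytest.raises(ValueError):
            polymorphic_loci({"zz": []}, aln)

    def test_family_truth_recall(self, family):
        """Every planted polymorphic locus is recovered with full presence
        and the planted repeat counts."""
        records, truth = family
        per_taxon = {
            r.taxon: scan_ssrs(drop_one_ir(r).sequence) for r in records
        }
        aln = truth.one_ir_alignment()
        cross = polymorphic_loci(per_taxon, aln, min_presence=7)
        found = 0
        for planted in truth.ssr_loci:
            motif = canonical_rotation(planted.motif)
            matches = [
                c
                for c in cross
                if c.motif == motif
                and set(planted.reps.items()) <= set(c.reps.items())
            ]
            assert matches, planted
            assert matches[0].polymorphic == planted.polymorphic
            found += 1
        assert found == len(truth.ssr_loci) == 20


class TestPrimerFiltering:
    def test_wallace_rule_window(self):
        primer = "GC" * 5 + "AT" * 5  # 10 G/C + 10 A/T -> Tm 60
        assert wallace_tm(primer) == 60.0
        cand = PrimerCandidate(forward=primer, reverse=primer, product_size=300)
        cand.evaluate(SSR_PROFILE)
        assert cand.checks["tm"] and cand.checks["gc"] and cand.passes

    def test_length_constraint(self):
        short = "GCATGCATGCATGCATG"  # 17-mer
        cand = PrimerCandidate(forward=short, reverse="GC" * 5 + "AT" * 5, product_size=300)
        cand.evaluate(SSR_PROFILE)
        assert not cand.checks["length"] and not cand.passes

    def test_profiles_differ_in_tm_and_product(self):
        fwd = "GC" * 5 + "AT" * 5  # 10 GC / 10 AT -> Tm 60
        rev = "GC" * 5 + "AT" * 4 + "GA"  # 11 GC / 9 AT -> Tm 62
        cand = PrimerCandidate(forward=fwd, reverse=rev, product_size=800)
        cand.evaluate(SSR_PROFILE)
        assert not cand.passes  # dTm 2 > 1 and product 800 > 500
        cand.evaluate(HOTSPOT_PROFILE)
        assert cand.passes

    def test_gc_formula_above_20mer(self):
        primer = "G" * 12 + "A" * 10  # 22-mer, 12 GC
        expected = 64.9 + 41 * (12 - 16.4) / 22
        assert gc_tm(primer) == pytest.approx(expected)

    def test_random_pool_matches_constraint_oracle(self):
        rng = np.random.default_rng(5)
        constraints = PrimerConstraints()
        pool = []
        for _ in range(300):
            lf, lr = rng.integers(15, 30, size=2)
            fwd = "".join(rng.choice(list("ACGT"), lf))
            rev = "".join(rng.choice(list("ACGT"), lr))
            pool.append(
                PrimerCandidate(
                    forward=fwd,
                    reverse=rev,
                    product_size=int(rng.integers(50, 1200)),
                )
            )
        passing = {id(c) for c in filter_primers(pool, constraints)}

        def tm(p):
            return (
                wallace_tm(p)
                if len(p) <= 20
                else 64.9 + 41 * ((p.count("G") + p.count("C")) - 16.4) / len(p)
            )

        for cand in pool:
            fwd, rev = cand.forward, cand.reverse
            expect = all(
                [
                    18 <= len(fwd) <= 27 and 18 <= len(rev) <= 27,
                    all(
                        0.2 <= (p.count("G") + p.count("C")) / len(p) <= 0.8
                        for p in (fwd, rev)
                    ),
                    all(57 <= tm(p) <= 63 for p in (fwd, rev)),
                    abs(tm(fwd) - tm(rev)) <= 1.0,
                    100 <= cand.product_size <= 500,
                ]
            )
            assert (id(cand) in passing) == expect

    def test_empty_pool(self):
        assert filter_primers([], SSR_PROFILE) == []
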