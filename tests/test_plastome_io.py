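"""GenBank round-trips, quadripartite detection, region extraction."""

from __future__ import annotations

import numpy as np
import pytest

from plastomma.io import (
    NoIRFoundError,
    detect_quadripartite,
    drop_one_ir,
    extract_regions,
    read_genbank,
    write_genbank,
)
from plastomma.records import Feature, GenomeRecord, revcomp


def brute_force_ir(seq: str, min_len: int):
    """Quadratic oracle: the longest disjoint reverse-complement interval
    pair, via diagonal runs between the sequence and its reverse
    complement (ties: leftmost first interval)."""
    n = len(seq)
    rc = revcomp(seq)
    best = None
    for d in range(-(n - 1), n):
        i = max(0, d)
        j = i - d
        run = 0
        while i <= n and j <= n:
            if i < n and j < n and seq[i] == rc[j]:
                run += 1
            else:
                if run >= min_len:
                    a = (i - run, i)
                    b = (n - j, n - j + run)
                    first, second = (a, b) if a[0] <= b[0] else (b, a)
                    if first[1] <= second[0]:
                        cand = (run, -first[0], first, second)
                        if best is None or cand[:2] > best[:2]:
                            best = cand
                run = 0
            i += 1
            j += 1
    return best and (best[2], best[3], best[0])


def _planted_ir_record(rng, lsc, ir, ssc):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    bases = np.array(list("ACGT"))
    lsc_s = "".join(rng.choice(bases, lsc))
    ir_s = "".join(rng.choice(bases, ir))
    ssc_s = "".join(rng.choice(bases, ssc))
    # pin the junction-flanking bases so the mirror is exactly the planted IR
    if ssc_s[0] == comp[ssc_s[-1]]:
        ssc_s = next(b for b in "ACGT" if b != comp[ssc_s[-1]]) + ssc_s[1:]
    if lsc_s[0] == comp[lsc_s[-1]]:
        lsc_s = next(b for b in "ACGT" if b != comp[lsc_s[-1]]) + lsc_s[1:]
    return GenomeRecord(taxon="planted", sequence=lsc_s + ir_s + ssc_s + revcomp(ir_s))


class TestGenBankRoundTrip:
    def test_minimal_minus_strand_gene(self, tmp_path):
        """A 30 bp minus-strand gene survives the 1-based/0-based boundary."""
        seq = "ACGT" * 20
        rec = GenomeRecord(
            taxon="mini",
            sequence=seq,
            features=[Feature("tiny", "gene", [(10, 40, -1)])],
        )
        path = tmp_path / "mini.gb"
        write_genbank(rec, path)
        back = read_genbank(path)
        assert back.sequence == seq
        assert back.features[0].segments == [(10, 40, -1)]
        assert back.features[0].name == "tiny"

    def test_round_trip_preserves_all_features(self, tmp_path, small_family):
        records, _ = small_family
        rec = records[0]
        path = tmp_path / "rec.gb"
        write_genbank(rec, path)
        back = read_genbank(path)
        assert back.sequence == rec.sequence
        original = sorted((f.name, f.kind, tuple(f.segments)) for f in rec.features)
        returned = sorted((f.name, f.kind, tuple(f.segments)) for f in back.features)
        assert returned == original

    def test_joined_cds_uses_join_syntax(self, tmp_path):
        rec = GenomeRecord(
            taxon="j",
            sequence="A" * 50 + "C" * 50,
            features=[Feature("two", "CDS", [(0, 30, 1), (60, 90, 1)])],
        )
        path = tmp_path / "join.gb"
        write_genbank(rec, path)
        assert "join(" in path.read_text()
        back = read_genbank(path)
        assert back.get_features("two")[0].segments == [(0, 30, 1), (60, 90, 1)]

    def test_pseudo_flag_round_trips(self, tmp_path):
        rec = GenomeRecord(
            taxon="p",
            sequence="ACGT" * 30,
            features=[Feature("brk", "gene", [(5, 50, 1)], pseudo=True)],
        )
        path = tmp_path / "p.gb"
        write_genbank(rec, path)
        assert read_genbank(path).features[0].pseudo

    def test_output_is_byte_stable(self, tmp_path):
        """Writing the same record twice gives identical bytes."""
        rng = np.random.default_rng(4)
        for k in range(5):
            rec = _planted_ir_record(rng, 300, 100, 80)
            rec.features.append(Feature(f"g{k}", "gene", [(10, 70, 1)]))
            p1, p2 = tmp_path / "a.gb", tmp_path / "b.gb"
            write_genbank(rec, p1)
            write_genbank(rec, p2)
            assert p1.read_bytes() == p2.read_bytes()

    def test_empty_sequence_rejected(self, tmp_path):
        path = tmp_path / "empty.gb"
        path.write_text("LOCUS       x 0 bp DNA circular PLN 01-JAN-2000\n//\n")
        with pytest.raises(ValueError):
            read_genbank(path)


class TestQuadripartiteDetection:
    def test_planted_structure_recovered(self):
        rng = np.random.default_rng(0)
        rec = _planted_ir_record(rng, 5000, 2000, 1000)
        part = detect_quadripartite(rec, min_ir_len=1000)
        assert (part.lsc_len, part.ir_len, part.ssc_len) == (5000, 2000, 1000)
        assert rec.sequence[slice(*part.irb)] == revcomp(rec.sequence[slice(*part.ira)])

    def test_no_ir_raises(self):
        rng = np.random.default_rng(1)
        rec = GenomeRecord(
            taxon="flat", sequence="".join(rng.choice(list("ACGT"), 3000))
        )
        with pytest.raises(NoIRFoundError):
            detect_quadripartite(rec, min_ir_len=500)

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_quadratic_oracle(self, seed):
        """Planted 150 bp IR in 600 bp: detection equals the brute-force
        longest reverse-complement repeat search."""
        rng = np.random.default_rng(100 + seed)
        rec = _planted_ir_record(rng, 200, 150, 100)
        oracle = brute_force_ir(rec.sequence, 60)
        part = detect_quadripartite(rec, min_ir_len=60)
        assert oracle is not None
        (a, b, length) = oracle
        assert part.ir_len == length
        assert (part.irb, part.ira) == (a, b)

    def test_relinearizes_rotated_genome(self):
        """A genome cut inside the LSC is rotated so the LSC starts at 0."""
        rng = np.random.default_rng(7)
        rec = _planted_ir_record(rng, 4000, 1500, 800)
        shift = 1200
        rotated = GenomeRecord(
            taxon="rot", sequence=rec.sequence[shift:] + rec.sequence[:shift]
        )
        part = detect_quadripartite(rotated, min_ir_len=800)
        assert (part.lsc_len, part.ir_len, part.ssc_len) == (4000, 1500, 800)
        assert part.lsc[0] == 0
        assert rotated.sequence == rec.sequence

    def test_generated_family_partitions(self, family):
        """Detection on generated records reproduces the construction."""
        records, _ = family
        for rec in records[:3]:
            fresh = rec.copy()
            fresh.partition = None
            part = detect_quadripartite(fresh, min_ir_len=10_000)
            assert part == rec.partition


class TestExtractRegions:
    def _two_gene_record(self, gap: bool):
        seq = "ACGT" * 100
        g2_start = 200 if gap else 100
        return GenomeRecord(
            taxon="t",
            sequence=seq,
            features=[
                Feature("g1", "gene", [(0, 100, 1)]),
                Feature("g2", "gene", [(g2_start, g2_start + 100, 1)]),
            ],
            annotations={"regions": [("LSC", 0, 400)]},
        )

    def test_igs_between_two_genes(self):
        regions = extract_regions(self._two_gene_record(gap=True))
        igs = [r for r in regions if r.category == "IGS"]
        assert len(igs) == 1
        assert igs[0].name == "g1-g2"
        assert (igs[0].start, igs[0].end) == (100, 200)
        assert len(igs[0].sequence) == 100

    def test_abutting_genes_give_no_igs(self):
        regions = extract_regions(self._two_gene_record(gap=False))
        assert [r for r in regions if r.category == "IGS"] == []

    def test_igs_never_overlaps_genes(self, small_family):
        """Region extraction refines the genome: IGSs avoid all genes."""
        records, _ = small_family
        rec = records[0]
        spans = [
            (f.start, f.end)
            for f in rec.features_of_kind("gene", "tRNA", "rRNA")
        ]
        for region in extract_regions(rec):
            if region.category != "IGS":
                continue
            for s, e in spans:
                assert region.end <= s or region.start >= e

    def test_intron_and_cds_extraction(self, small_family):
        records, truth = small_family
        rec = records[0]
        regions = {(r.name, r.category) for r in extract_regions(rec)}
        assert ("rpl16_intron1", "intron") in regions
        assert ("rps3", "CDS") in regions

    def test_min_len_filters_short_noncoding(self):
        regions = extract_regions(self._two_gene_record(gap=True), min_len=150)
        assert [r for r in regions if r.category == "IGS"] == []


class TestDropOneIR:
    def test_length_arithmetic(self):
        rng = np.random.default_rng(3)
        rec = _planted_ir_record(rng, 5000, 2000, 1000)
        detect_quadripartite(rec, min_ir_len=1000)
        dropped = drop_one_ir(rec)
        assert len(dropped) == len(rec) - 2000

    def test_study_scale_subtraction(self, family):
        """One-IR length equals total minus IR for every generated taxon."""
        records, _ = family
        for rec in records:
            dropped = drop_one_ir(rec)
            assert len(dropped) == len(rec) - rec.partition.ir_len

    def test_second_application_fails(self):
        rng = np.random.default_rng(3)
        rec = _planted_ir_record(rng, 5000, 2000, 1000)
        detect_quadripartite(rec, min_ir_len=1000)
        dropped = drop_one_ir(rec)
        with pytest.raises(ValueError):
            drop_one_ir(dropped)

    def test_ir_features_clipped_not_duplicated(self, small_family):
        records, _ = small_family
        rec = records[0]
        dropped = drop_one_ir(rec)
        # retained IRa copy: exactly one rrn16 left
        assert len(dropped.get_features("rrn16", "rRNA")) == 1
        assert dropped.sequence in rec.sequence[: rec.partition.irb[0]] + rec.sequence[rec.partition.irb[1]:]
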