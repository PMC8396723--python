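"""Synthetic plastome families with fully known truth.

The generator builds a circular quadripartite ancestor (LSC + IRb + SSC +
IRa, the IRs exact mirror copies) from a gene roster, then derives a
family of taxa by planting substitution events (infinite-sites: every
event at its own position), deletion events with known boundaries and
sharing patterns, SSR loci with cross-taxon repeat-count polymorphism,
and per-taxon ndh gene fates (complete / pseudogene via a 1 bp
frameshift deletion / lost via whole-gene deletion).  Because all edits
are deletions or point substitutions relative to the ancestor, the true
multiple alignment of any ancestor window is known exactly, and every
downstream statistic has a closed-form expectation.

Default structural parameters follow the Pleurothallidinae study system:
LSC ~84 kb, SSC ~16.5 kb, IR ~26 kb (~150 kb total), GC ~0.37, eleven
ndh genes of which seven sit in the SSC, ycf1 spanning the SSC/IRa
junction and rpl22 the LSC/IRb junction.

A separate neutral-coalescent simulator (via msprime, haploid samples,
infinite-sites mutations) calibrates the Tajima's D machinery:
E[segregating sites] = theta * a1 with a1 = sum_{i<n} 1/i.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import msprime
import numpy as np

from .align import Alignment
from .records import Feature, GenomeRecord, QuadripartitePartition, revcomp
from .ssr import DEFAULT_MINIMA, SSRLocus

PARTS = ("LSC", "IR", "SSC")

_SENSE_CODONS = None
_STOPS = ("TAA", "TAG", "TGA")


def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        import itertools

        _SENSE_CODONS = [
            "".join(c)
            for c in itertools.product("ACGT", repeat=3)
            if "".join(c) not in _STOPS
        ]
    return _SENSE_CODONS


# ---------------------------------------------------------------------------
# Gene rosters


@dataclass(frozen=True)
class GeneSpec:
    """One gene to place: spliced length, strand, optional single intron."""

    name: str
    kind: str  # CDS / tRNA / rRNA
    length: int  # spliced length (CDS length includes the stop codon)
    strand: int = 1
    intron: int = 0
    start_codon: str = "ATG"

    @property
    def genomic_length(self) -> int:
        return self.length + self.intron


def default_roster() -> dict[str, list[GeneSpec]]:
    """A realistic plastome roster (~80 genes; ndh genes in their usual
    regions: ndhB in the IR, ndhC/J/K in the LSC, the other seven in the
    SSC)."""
    C, T, R = "CDS", "tRNA", "rRNA"
    lsc = [
        GeneSpec("trnH", T, 75),
        GeneSpec("psbA", C, 1062, -1),
        GeneSpec("matK", C, 1530, -1, start_codon="ATT"),
        GeneSpec("rps16", C, 678, -1, intron=860),
        GeneSpec("psbK", C, 186),
        GeneSpec("psbI", C, 111),
        GeneSpec("trnS", T, 88, -1),
        GeneSpec("trnG", T, 71),
        GeneSpec("trnR", T, 72),
        GeneSpec("atpA", C, 1524, -1),
        GeneSpec("atpF", C, 555, -1, intron=700),
        GeneSpec("atpH", C, 246, -1),
        GeneSpec("atpI", C, 744, -1),
        GeneSpec("rps2", C, 711, -1, start_codon="ACG"),
        GeneSpec("rpoC2", C, 4140, -1),
        GeneSpec("rpoC1", C, 2043, -1, intron=738),
        GeneSpec("rpoB", C, 3213, -1),
        GeneSpec("trnC", T, 71),
        GeneSpec("petN", C, 90),
        GeneSpec("psbM", C, 105, -1),
        GeneSpec("trnD", T, 74, -1),
        GeneSpec("trnE", T, 73),
        GeneSpec("psbD", C, 1062),
        GeneSpec("psbC", C, 1386),
        GeneSpec("trnT", T, 72),
        GeneSpec("psbZ", C, 189),
        GeneSpec("trnW", T, 74, -1),
        GeneSpec("trnP", T, 74, -1),
        GeneSpec("rbcL", C, 1428),
        GeneSpec("accD", C, 1467),
        GeneSpec("psaI", C, 111),
        GeneSpec("ycf4", C, 555),
        GeneSpec("cemA", C, 690),
        GeneSpec("petA", C, 963),
        GeneSpec("psbJ", C, 123, -1),
        GeneSpec("psbL", C, 117, -1),
        GeneSpec("psbF", C, 120, -1),
        GeneSpec("psbE", C, 252, -1),
        GeneSpec("petL", C, 96),
        GeneSpec("petG", C, 114),
        GeneSpec("psaJ", C, 135),
        GeneSpec("rpl33", C, 201),
        GeneSpec("rps18", C, 306),
        GeneSpec("rpl20", C, 354, -1),
        GeneSpec("clpP", C, 591, -1, intron=790),
        GeneSpec("psbB", C, 1527),
        GeneSpec("psbT", C, 108),
        GeneSpec("psbN", C, 132, -1),
        GeneSpec("psbH", C, 222),
        GeneSpec("petB", C, 648, intron=753),
        GeneSpec("petD", C, 483, intron=742),
        GeneSpec("rpoA", C, 1014, -1),
        GeneSpec("rps11", C, 417, -1),
        GeneSpec("rpl36", C, 114, -1),
        GeneSpec("rps8", C, 405, -1),
        GeneSpec("rpl14", C, 369, -1),
        GeneSpec("rpl16", C, 408, -1, intron=1020),
        GeneSpec("rps3", C, 657, -1),
        GeneSpec("ndhC", C, 363, -1),
        GeneSpec("ndhK", C, 678, -1),
        GeneSpec("ndhJ", C, 477, -1),
        GeneSpec("rpl22", C, 420),  # protrudes into IRb
    ]
    ir = [
        GeneSpec("rps19", C, 279, -1, start_codon="GTG"),
        GeneSpec("rrn16", R, 1491),
        GeneSpec("trnI", T, 74),
        GeneSpec("trnA", T, 73),
        GeneSpec("rrn23", R, 2810),
        GeneSpec("rrn5", R, 121),
        GeneSpec("trnN", T, 72, -1),
        GeneSpec("ndhB", C, 1533, -1, intron=679),
        GeneSpec("ycf2", C, 6801),
    ]
    ssc = [
        GeneSpec("ndhF", C, 2220, -1),
        GeneSpec("rpl32", C, 174),
        GeneSpec("trnL", T, 80),
        GeneSpec("ccsA", C, 966),
        GeneSpec("ndhD", C, 1503, -1, start_codon="ACG"),
        GeneSpec("psaC", C, 246, -1),
        GeneSpec("ndhE", C, 306, -1),
        GeneSpec("ndhG", C, 531, -1),
        GeneSpec("ndhI", C, 543, -1),
        GeneSpec("ndhA", C, 1092, -1, intron=1080),
        GeneSpec("ndhH", C, 1182, -1),
        GeneSpec("rps15", C, 273),
        GeneSpec("ycf1", C, 5400),  # protrudes into IRa
    ]
    return {"LSC": lsc, "IR": ir, "SSC": ssc}


def mini_roster() -> dict[str, list[GeneSpec]]:
    """A reduced roster for small, fast genomes (~10-15 kb)."""
    C, T, R = "CDS", "tRNA", "rRNA"
    return {
        "LSC": [
            GeneSpec("psbA", C, 300, -1),
            GeneSpec("trnS", T, 75, -1),
            GeneSpec("psbB", C, 300),
            GeneSpec("psbT", C, 108),
            GeneSpec("rpl16", C, 300, -1, intron=200),
            GeneSpec("rps3", C, 300, -1),
            GeneSpec("rpl22", C, 300),
        ],
        "IR": [
            GeneSpec("rps19", C, 279, -1, start_codon="GTG"),
            GeneSpec("rrn16", R, 500),
            GeneSpec("ndhB", C, 300, -1, intron=150),
        ],
        "SSC": [
            GeneSpec("ndhF", C, 600, -1),
            GeneSpec("rpl32", C, 174),
            GeneSpec("ndhD", C, 300, -1, start_codon="ACG"),
            GeneSpec("ndhA", C, 300, -1, intron=200),
            GeneSpec("ndhH", C, 300, -1),
            GeneSpec("ycf1", C, 900),
        ],
    }


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class FamilyConfig:
    """Study conditions for a synthetic family.

    Rates are event densities per ancestor bp of the single-copy regions
    (the IR gets ``ir_rate_factor`` times the rate, reflecting its
    conservatism).  Defaults emulate the ten-plastome study system.
    """

    n_taxa: int = 10
    taxa: list[str] | None = None
    lsc_len: int = 84_000
    ir_len: int = 26_000
    ssc_len: int = 17_800
    gc: float = 0.37
    sub_rate: float = 0.08
    indel_rate: float = 0.018
    ir_rate_factor: float = 0.15
    indel_mean_len: float = 4.0
    n_ssr_loci: int = 20
    ssr_max_extra: int = 6
    ndh_pattern: dict[str, dict[str, str]] | None = None
    junction_type: str = "I"  # ancestor JSB layout: I, II, or III
    ycf1_ir_overlap: int = 1000
    rpl22_ir_overlap: int = 33
    ndhf_ir_overlap: int = 44
    ssc_pad: int = 60
    min_gap: int = 80
    roster: dict[str, list[GeneSpec]] | None = None

    def resolved_taxa(self) -> list[str]:
        if self.taxa is not None:
            return list(self.taxa)
        return [f"Taxon{i + 1:02d}" for i in range(self.n_taxa)]

    def resolved_roster(self) -> dict[str, list[GeneSpec]]:
        return self.roster if self.roster is not None else default_roster()

    def validate(self) -> None:
        if self.junction_type not in ("I", "II", "III"):
            raise ValueError("junction_type must be I, II, or III")
        if self.junction_type == "II" and self.ycf1_ir_overlap > 0:
            raise ValueError(
                "junction type II (ndhF across JSB) requires ycf1_ir_overlap == 0: "
                "the IRb end cannot mirror both gene tails"
            )
        roster = self.resolved_roster()
        for part, target in (
            ("LSC", self.lsc_len),
            ("IR", self.ir_len),
            ("SSC", self.ssc_len),
        ):
            genes = list(roster.get(part, ()))
            total = sum(g.genomic_length for g in genes)
            slack = target - total - (len(genes) + 1) * self.min_gap
            if slack < 0:
                raise ValueError(
                    f"{part} length {target} too small for its gene content "
                    f"({total} bp of genes)"
                )


NDH_GENES = [f"ndh{c}" for c in "ABCDEFGHIJK"]


def default_ndh_pattern(taxa: list[str], junction_type: str = "I") -> dict[str, dict[str, str]]:
    """A deterministic study-like fate pattern: two taxa with all ndh
    genes complete, one heavily eroded taxon (ndhF lost), the rest mixed."""
    pattern: dict[str, dict[str, str]] = {}
    for idx, taxon in enumerate(taxa):
        fates = {g: "complete" for g in NDH_GENES}
        if idx in (0, 1):
            pass  # fully intact
        elif idx == 2:
            for g in NDH_GENES:
                fates[g] = "lost"
            for g in ("ndhB", "ndhD", "ndhH", "ndhE", "ndhG"):
                fates[g] = "pseudogene"
        else:
            if idx % 2:
                fates["ndhA"] = "pseudogene"
                fates["ndhF"] = "pseudogene"
            if idx % 3 == 0:
                fates["ndhK"] = "lost"
                fates["ndhG"] = "pseudogene"
            if idx % 4 == 0:
                fates["ndhI"] = "lost"
        pattern[taxon] = fates
    return pattern


# ---------------------------------------------------------------------------
# Truth bookkeeping


@dataclass(frozen=True)
class Event:
    """One planted evolutionary event in ancestor part coordinates."""

    kind: str  # substitution / deletion
    part: str  # LSC / IR / SSC
    start: int
    end: int
    members: tuple[str, ...]
    base: str | None = None  # derived base for substitutions
    origin: str = "background"  # background / ssr / ndh_frameshift / ndh_loss

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PlantedSSR:
    """A planted SSR locus with per-taxon repeat counts."""

    part: str
    start: int  # ancestor part-relative start
    motif: str
    max_reps: int
    reps: dict[str, int] = field(default_factory=dict)

    @property
    def unit(self) -> int:
        return len(self.motif)

    @property
    def polymorphic(self) -> bool:
        return len(set(self.reps.values())) > 1


class FamilyTruth:
    """Everything needed to recompute every expected statistic exactly."""

    def __init__(
        self,
        config: FamilyConfig,
        taxa: list[str],
        part_seqs: dict[str, str],
        features: list[Feature],
        gap_windows: dict[str, list[tuple[int, int]]],
        events: list[Event],
        ssr_loci: list[PlantedSSR],
        ndh_status: dict[str, dict[str, str]],
    ) -> None:
        self.config = config
        self.taxa = taxa
        self.part_seqs = part_seqs  # ancestor LSC / IR (IRb orientation) / SSC
        self.features = features  # ancestor global coordinates (incl. IRa mirrors)
        self.gap_windows = gap_windows
        self.events = events
        self.ssr_loci = ssr_loci
        self.ndh_status = ndh_status
        self.part_len = {p: len(part_seqs[p]) for p in PARTS}
        self.part_offset = {
            "LSC": 0,
            "IR": self.part_len["LSC"],
            "SSC": self.part_len["LSC"] + self.part_len["IR"],
        }
        self.ancestor = (
            part_seqs["LSC"] + part_seqs["IR"] + part_seqs["SSC"] + revcomp(part_seqs["IR"])
        )
        self._del_cache: dict[str, dict[str, np.ndarray]] = {}

    # -- per-taxon event views ------------------------------------------

    def taxon_events(self, taxon: str, kind: str, part: str | None = None) -> list[Event]:
        return [
            e
            for e in self.events
            if e.kind == kind
            and taxon in e.members
            and (part is None or e.part == part)
        ]

    def _deletion_arrays(self, taxon: str, part: str) -> tuple[np.ndarray, np.ndarray]:
        key = f"{taxon}:{part}"
        if key not in self._del_cache:
            dels = sorted(
                (e.start, e.end) for e in self.taxon_events(taxon, "deletion", part)
            )
            starts = np.array([d[0] for d in dels], dtype=int)
            ends = np.array([d[1] for d in dels], dtype=int)
            self._del_cache[key] = {"starts": starts, "ends": ends}
        cache = self._del_cache[key]
        return cache["starts"], cache["ends"]

    def deleted_before(self, taxon: str, part: str, pos: int) -> int:
        """Deleted bp strictly before ``pos`` in a taxon's copy of a part."""
        starts, ends = self._deletion_arrays(taxon, part)
        clipped = np.minimum(ends, pos) - np.minimum(starts, pos)
        return int(np.maximum(clipped, 0).sum())

    def is_deleted(self, taxon: str, part: str, pos: int) -> bool:
        starts, ends = self._deletion_arrays(taxon, part)
        idx = np.searchsorted(starts, pos, side="right") - 1
        return idx >= 0 and pos < ends[idx]

    # -- alignments ------------------------------------------------------

    def _sub_arrays(self, taxon: str, part: str) -> tuple[np.ndarray, np.ndarray]:
        key = f"sub:{taxon}:{part}"
        if key not in self._del_cache:
            subs = sorted(
                (e.start, e.base)
                for e in self.taxon_events(taxon, "substitution", part)
            )
            pos = np.array([s[0] for s in subs], dtype=int)
            bases = np.array([s[1] for s in subs], dtype="S1")
            self._del_cache[key] = {"starts": pos, "ends": bases}
        cache = self._del_cache[key]
        return cache["starts"], cache["ends"]

    def region_alignment(
        self, part: str, start: int, end: int, taxa: list[str] | None = None
    ) -> Alignment:
        """True alignment of an ancestor part window across taxa."""
        taxa = taxa or self.taxa
        window = np.frombuffer(
            self.part_seqs[part][start:end].encode(), dtype="S1"
        )
        rows = []
        for taxon in taxa:
            arr = window.copy()
            pos, bases = self._sub_arrays(taxon, part)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            arr[pos[lo:hi] - start] = bases[lo:hi]
            dstarts, dends = self._deletion_arrays(taxon, part)
            clip_lo = np.clip(dstarts, start, end)
            clip_hi = np.clip(dends, start, end)
            for s, e in zip(clip_lo[clip_hi > clip_lo], clip_hi[clip_hi > clip_lo]):
                arr[s - start : e - start] = b"-"
            rows.append(arr.tobytes().decode())
        return Alignment(taxa=list(taxa), rows=rows)

    def one_ir_alignment(self, taxa: list[str] | None = None) -> Alignment:
        """True whole-genome alignment matching the one-IR-removed records
        (LSC + SSC + IRa, IRa being the mirror of the IRb part)."""
        taxa = taxa or self.taxa
        lsc = self.region_alignment("LSC", 0, self.part_len["LSC"], taxa)
        ssc = self.region_alignment("SSC", 0, self.part_len["SSC"], taxa)
        ir = self.region_alignment("IR", 0, self.part_len["IR"], taxa)
        rows = [
            lsc.rows[i] + ssc.rows[i] + revcomp(ir.rows[i]).replace("N", "N")
            for i in range(len(taxa))
        ]
        # gaps are strand-neutral: revcomp maps '-' to '-'
        return Alignment(taxa=list(taxa), rows=rows)

    def cds_alignment(self, gene: str, taxa: list[str] | None = None) -> Alignment:
        """True spliced, strand-corrected alignment of a CDS."""
        taxa = taxa or self.taxa
        feats = [f for f in self.features if f.name == gene and f.kind == "CDS"]
        if not feats:
            raise KeyError(f"gene {gene} not in ancestor roster")
        feat = feats[0]
        pieces = []
        for gs, ge, strand in feat.segments:
            part, rel_s, rel_e = self._to_part(gs, ge)
            aln = self.region_alignment(part, rel_s, rel_e, taxa)
            rows = [revcomp(r) for r in aln.rows] if strand == -1 else aln.rows
            pieces.append(rows)
        rows = ["".join(p[i] for p in pieces) for i in range(len(taxa))]
        return Alignment(taxa=list(taxa), rows=rows)

    def _to_part(self, gstart: int, gend: int) -> tuple[str, int, int]:
        for part in ("LSC", "IR", "SSC"):
            off = self.part_offset[part]
            if off <= gstart and gend <= off + self.part_len[part]:
                return part, gstart - off, gend - off
        raise ValueError(f"global window ({gstart}, {gend}) crosses part bounds")

    # -- expected statistics --------------------------------------------

    def expected_substitutions(self, part: str, start: int, end: int) -> int:
        return sum(
            1
            for e in self.events
            if e.kind == "substitution" and e.part == part and start <= e.start < end
        )

    def expected_indel_events(self, part: str, start: int, end: int) -> int:
        """Distinct deletion intervals strictly inside the window (events
        touching a window edge align as terminal gaps and are excluded)."""
        intervals = {
            (e.start, e.end)
            for e in self.events
            if e.kind == "deletion" and e.part == part and e.start > start and e.end < end
        }
        return len(intervals)

    def igs_windows(self) -> list[tuple[str, str, int, int]]:
        """Ancestor IGS windows: (name, part, rel start, rel end)."""
        out = []
        for part in PARTS:
            off = self.part_offset[part]
            plen = self.part_len[part]
            feats = sorted(
                {
                    (f.start, f.end, f.name)
                    for f in self.features
                    if f.kind in ("gene", "tRNA", "rRNA")
                    and off <= f.start and f.end <= off + plen
                }
            )
            prev_end, prev_name = None, None
            for fs, fe, name in feats:
                if prev_end is not None and fs > prev_end:
                    out.append(
                        (f"{prev_name}-{name}", part, prev_end - off, fs - off)
                    )
                if prev_end is None or fe > prev_end:
                    prev_end, prev_name = fe, name
        return out

    def intron_windows(self) -> list[tuple[str, str, int, int]]:
        """Ancestor intron windows: (name, part, rel start, rel end)."""
        out = []
        for part in PARTS:
            off = self.part_offset[part]
            plen = self.part_len[part]
            seen = set()
            for f in self.features:
                if f.kind != "gene" or len(f.segments) < 2 or f.name in seen:
                    continue
                if not (off <= f.start and f.end <= off + plen):
                    continue
                seen.add(f.name)
                segs = sorted((s, e) for s, e, _ in f.segments)
                for idx in range(len(segs) - 1):
                    s, e = segs[idx][1], segs[idx + 1][0]
                    if e > s:
                        out.append(
                            (f"{f.name}_intron{idx + 1}", part, s - off, e - off)
                        )
        return out

    def cds_genes(self) -> list[str]:
        """Gene names carrying a CDS annotation in the ancestor."""
        return sorted({f.name for f in self.features if f.kind == "CDS"})

    def analysis_alignments(
        self, min_len: int = 0
    ) -> dict[str, tuple[str, str, Alignment]]:
        """True alignments of every analysis region.

        Returns {name: (category, location, Alignment)} for all IGS and
        intron windows at least ``min_len`` columns wide, plus every CDS.
        """
        out: dict[str, tuple[str, str, Alignment]] = {}
        for name, part, s, e in self.igs_windows():
            if e - s >= min_len:
                out[name] = ("IGS", part, self.region_alignment(part, s, e))
        for name, part, s, e in self.intron_windows():
            if e - s >= min_len:
                out[name] = ("intron", part, self.region_alignment(part, s, e))
        for gene in self.cds_genes():
            try:
                aln = self.cds_alignment(gene)
            except ValueError:
                continue  # junction-spanning CDS crosses part bounds
            feat = next(f for f in self.features if f.name == gene and f.kind == "CDS")
            part = (
                "LSC"
                if feat.start < self.part_len["LSC"]
                else ("IR" if feat.start < self.part_offset["SSC"] else "SSC")
            )
            out[gene] = ("CDS", part, aln)
        return out

    def ssr_expected_loci(self, taxon: str) -> list[SSRLocus]:
        """Planted SSR loci in the taxon's one-IR-removed coordinates."""
        lsc_t = self.part_len["LSC"] - self.deleted_before(
            taxon, "LSC", self.part_len["LSC"]
        )
        offset = {"LSC": 0, "SSC": lsc_t}
        out = []
        for locus in self.ssr_loci:
            reps = locus.reps.get(taxon)
            if reps is None:
                continue
            start = (
                offset[locus.part]
                + locus.start
                - self.deleted_before(taxon, locus.part, locus.start)
            )
            out.append(
                SSRLocus(
                    motif=locus.motif,
                    reps=reps,
                    start=start,
                    end=start + reps * locus.unit,
                )
            )
        return sorted(out, key=lambda l: l.start)

    # -- serialization ---------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "taxa": self.taxa,
            "part_len": self.part_len,
            "events": [asdict(e) for e in self.events],
            "ssr_loci": [asdict(l) for l in self.ssr_loci],
            "ndh_status": self.ndh_status,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Ancestor construction


def _rand_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _rand_orf(rng: np.random.Generator, length: int, start_codon: str) -> str:
    if length % 3:
        raise ValueError("ORF length must be a multiple of 3")
    n_body = length // 3 - 2
    codons = rng.choice(_sense_codons(), size=n_body)
    stop = _STOPS[int(rng.integers(0, 3))]
    return start_codon + "".join(codons) + stop


def _gap_sizes(
    rng: np.random.Generator, n_gaps: int, total: int, min_gap: int
) -> list[int]:
    extra = total - n_gaps * min_gap
    if extra < 0:
        raise ValueError("not enough room for minimum gaps")
    props = rng.dirichlet(np.ones(n_gaps))
    sizes = (min_gap + np.floor(props * extra)).astype(int)
    sizes[-1] += total - int(sizes.sum())
    return sizes.tolist()


def _place_gene(
    rng: np.random.Generator,
    spec: GeneSpec,
    start: int,
    gc: float,
) -> tuple[str, list[tuple[int, int, int]]]:
    """Genomic sequence and (relative) CDS/exon segments for one gene.

    For minus-strand spliced genes the biological exon order runs against
    genome coordinates, so segments are listed right-to-left.
    """
    if spec.kind == "CDS":
        orf = _rand_orf(rng, spec.length, spec.start_codon)
    else:
        orf = _rand_seq(rng, spec.length, gc)
    if not spec.intron:
        seq = orf if spec.strand == 1 else revcomp(orf)
        return seq, [(start, start + spec.length, spec.strand)]
    half = (spec.length // 2) // 3 * 3 or 3
    e1, e2 = orf[:half], orf[half:]
    intron_seq = _rand_seq(rng, spec.intron, gc)
    if spec.strand == 1:
        seq = e1 + intron_seq + e2
        segs = [
            (start, start + len(e1), 1),
            (start + len(e1) + spec.intron, start + spec.genomic_length, 1),
        ]
    else:
        seq = revcomp(e2) + intron_seq + revcomp(e1)
        segs = [
            (start + len(e2) + spec.intron, start + spec.genomic_length, -1),
            (start, start + len(e2), -1),
        ]
    return seq, segs


# ---------------------------------------------------------------------------
# Ancestor construction


def _rand_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _rand_orf(rng: np.random.Generator, length: int, start_codon: str) -> str:
    if length % 3:
        raise ValueError("ORF length must be a multiple of 3")
    n_body = length // 3 - 2
    codons = rng.choice(_sense_codons(), size=n_body)
    stop = _STOPS[int(rng.integers(0, 3))]
    return start_codon + "".join(codons) + stop


def _gap_sizes(
    rng: np.random.Generator, n_gaps: int, total: int, min_gap: int
) -> list[int]:
    extra = total - n_gaps * min_gap
    if extra < 0:
        raise ValueError(
            "region too small for its gene content (not enough room for gaps)"
        )
    props = rng.dirichlet(np.ones(n_gaps))
    sizes = (min_gap + np.floor(props * extra)).astype(int)
    sizes[-1] += total - int(sizes.sum())
    return sizes.tolist()


def _place_gene(
    rng: np.random.Generator, spec: GeneSpec, start: int, gc: float
) -> tuple[str, list[tuple[int, int, int]]]:
    """Genomic sequence and relative exon segments for one gene.

    Segments are listed in biological (transcription) order, which for
    minus-strand spliced genes runs against genome coordinates.
    """
    if spec.kind == "CDS":
        orf = _rand_orf(rng, spec.length, spec.start_codon)
    else:
        orf = _rand_seq(rng, spec.length, gc)
    if not spec.intron:
        seq = orf if spec.strand == 1 else revcomp(orf)
        return seq, [(start, start + spec.length, spec.strand)]
    half = max((spec.length // 2) // 3 * 3, 3)
    e1, e2 = orf[:half], orf[half:]
    intron_seq = _rand_seq(rng, spec.intron, gc)
    if spec.strand == 1:
        seq = e1 + intron_seq + e2
        segs = [
            (start, start + len(e1), 1),
            (start + len(e1) + spec.intron, start + spec.genomic_length, 1),
        ]
    else:
        seq = revcomp(e2) + intron_seq + revcomp(e1)
        segs = [
            (start + len(e2) + spec.intron, start + spec.genomic_length, -1),
            (start, start + len(e2), -1),
        ]
    return seq, segs


def _layout_part(
    rng: np.random.Generator,
    genes: list[GeneSpec],
    target: int,
    lo: int,
    hi: int,
    start_protrude: int,
    end_protrude: int,
    gc: float,
    min_gap: int,
):
    """Place genes with random spacers into [lo, hi) of a part of length
    ``target``.  The first gene may protrude ``start_protrude`` bp before
    position lo and the last ``end_protrude`` bp past hi; protruding
    content is written into the neighbouring part by the caller."""
    arr = np.frombuffer(_rand_seq(rng, target, gc).encode(), dtype="S1").copy()
    if not genes:
        return arr, [], [(lo, hi)]
    inside = sum(g.genomic_length for g in genes) - start_protrude - end_protrude
    lead = 0 if start_protrude else 1
    trail = 0 if end_protrude else 1
    n_slots = (len(genes) - 1) + lead + trail
    sizes = _gap_sizes(rng, n_slots, hi - lo - inside, min_gap)
    gap_queue = list(sizes)
    feats: list[tuple[GeneSpec, list[tuple[int, int, int]], str]] = []
    windows: list[tuple[int, int]] = []
    pos = lo - start_protrude
    if lead:
        g = gap_queue.pop(0)
        windows.append((pos, pos + g))
        pos += g
    for idx, spec in enumerate(genes):
        seq, segs = _place_gene(rng, spec, pos, gc)
        clip_lo, clip_hi = max(pos, 0), min(pos + len(seq), target)
        if clip_hi > clip_lo:
            arr[clip_lo:clip_hi] = np.frombuffer(
                seq[clip_lo - pos : clip_hi - pos].encode(), dtype="S1"
            )
        feats.append((spec, segs, seq))
        pos += spec.genomic_length
        if idx < len(genes) - 1:
            g = gap_queue.pop(0)
            windows.append((pos, pos + g))
            pos += g
    if trail:
        g = gap_queue.pop(0)
        windows.append((pos, pos + g))
        pos += g
    assert pos == hi + end_protrude, "part layout arithmetic error"
    return arr, feats, windows


def _build_ancestor(config: FamilyConfig, rng: np.random.Generator):
    """Ancestor part sequences, global features, gap windows, overlaps."""
    roster = config.resolved_roster()
    lsc_len, ir_len, ssc_len = config.lsc_len, config.ir_len, config.ssc_len
    ov_r = config.rpl22_ir_overlap
    ov_y = config.ycf1_ir_overlap if config.junction_type != "II" else 0
    ov_f = config.ndhf_ir_overlap if config.junction_type == "II" else 0

    lsc_genes = list(roster.get("LSC", ()))
    ir_genes = list(roster.get("IR", ()))
    ssc_genes = list(roster.get("SSC", ()))
    if config.junction_type == "III":
        ssc_genes = [g for g in ssc_genes if g.name != "ndhF"]

    lsc_ep = ov_r if (lsc_genes and lsc_genes[-1].name == "rpl22") else 0
    ssc_sp = ov_f if (ssc_genes and ssc_genes[0].name == "ndhF") else 0
    ssc_ep = ov_y if (ssc_genes and ssc_genes[-1].name == "ycf1") else 0

    lsc_arr, lsc_feats, lsc_gaps = _layout_part(
        rng, lsc_genes, lsc_len, 0, lsc_len, 0, lsc_ep, config.gc, config.min_gap
    )
    ir_arr, ir_feats, ir_gaps = _layout_part(
        rng,
        ir_genes,
        ir_len,
        lsc_ep,
        ir_len - max(ov_y, ov_f),
        0,
        0,
        config.gc,
        config.min_gap,
    )
    ssc_arr, ssc_feats, ssc_gaps = _layout_part(
        rng,
        ssc_genes,
        ssc_len,
        0 if ssc_sp else config.ssc_pad,
        ssc_len,
        ssc_sp,
        ssc_ep,
        config.gc,
        config.min_gap,
    )

    # write junction-protruding gene content into the IR part
    for spec, segs, seq in lsc_feats:
        if spec.name == "rpl22" and lsc_ep:
            ir_arr[:lsc_ep] = np.frombuffer(seq[-lsc_ep:].encode(), dtype="S1")
    for spec, segs, seq in ssc_feats:
        if spec.name == "ycf1" and ssc_ep:
            # ycf1 tail occupies IRa start; IRb end carries its mirror
            ir_arr[ir_len - ssc_ep :] = np.frombuffer(
                revcomp(seq[-ssc_ep:]).encode(), dtype="S1"
            )
        if spec.name == "ndhF" and ssc_sp:
            ir_arr[ir_len - ssc_sp :] = np.frombuffer(
                seq[:ssc_sp].encode(), dtype="S1"
            )

    # break chance mirror extension across the IR junctions: the IR must
    # be exactly the constructed interval, so the flanking single-copy
    # bases must not complement each other
    comp = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A"}

    def _unmatch(arr, fix_index, other_index):
        if arr[fix_index] == comp[bytes(arr[other_index])]:
            arr[fix_index] = next(
                b.encode()
                for b in "ACGT"
                if b.encode() != comp[bytes(arr[other_index])]
            )

    _unmatch(lsc_arr, 0, -1)  # leading LSC gap base is free
    if ssc_sp:  # type II: SSC starts inside ndhF, adjust the free tail base
        _unmatch(ssc_arr, -1, 0)
    else:  # SSC starts with the free junction pad
        _unmatch(ssc_arr, 0, -1)

    part_seqs = {
        "LSC": lsc_arr.tobytes().decode(),
        "IR": ir_arr.tobytes().decode(),
        "SSC": ssc_arr.tobytes().decode(),
    }
    part_feats = {"LSC": lsc_feats, "IR": ir_feats, "SSC": ssc_feats}
    gap_windows = {"LSC": lsc_gaps, "IR": ir_gaps, "SSC": ssc_gaps}

    # global annotations: layout LSC + IRb + SSC + IRa
    off = {"LSC": 0, "IR": lsc_len, "SSC": lsc_len + ir_len}
    ira_off = lsc_len + ir_len + ssc_len
    n_total = ira_off + ir_len
    features: list[Feature] = []

    def add(spec: GeneSpec, segs: list[tuple[int, int, int]]) -> None:
        features.append(Feature(spec.name, "gene", list(segs)))
        kind = spec.kind
        if kind in ("CDS", "tRNA", "rRNA"):
            features.append(Feature(spec.name, kind, list(segs)))

    for part in PARTS:
        for spec, segs, _seq in part_feats[part]:
            segs_global = [(s + off[part], e + off[part], st) for s, e, st in segs]
            add(spec, segs_global)
            if part == "IR":  # exact mirrored copy in IRa
                mirrored = [
                    (ira_off + ir_len - e, ira_off + ir_len - s, -st)
                    for s, e, st in segs
                ]
                add(spec, mirrored)

    if lsc_ep:  # partial rpl22 copy at the IRa end (mirror of the IRb head)
        features.append(
            Feature("rpl22", "gene", [(n_total - lsc_ep, n_total, -1)], pseudo=True)
        )
    if ssc_ep:  # partial ycf1 copy at the IRb end (mirror of its IRa tail)
        features.append(
            Feature(
                "ycf1",
                "gene",
                [(off["IR"] + ir_len - ssc_ep, off["IR"] + ir_len, -1)],
                pseudo=True,
            )
        )
    if ssc_sp:  # partial ndhF copy at the IRa start (mirror of its IRb head)
        features.append(
            Feature("ndhF", "gene", [(ira_off, ira_off + ssc_sp, 1)], pseudo=True)
        )
    return part_seqs, part_feats, features, gap_windows, (lsc_ep, ssc_ep, ssc_sp)


# ---------------------------------------------------------------------------
# Family generation


_SSR_MOTIF_POOL = [
    ("A", 8), ("T", 8), ("AT", 2), ("TA", 2),
    ("AAG", 3), ("AAT", 3), ("ATT", 3), ("TTC", 2), ("AGA", 2), ("TAT", 2),
    ("AATT", 1), ("AATAT", 1),
]


def generate_family(
    config: FamilyConfig | None = None, seed: int = 0
) -> tuple[list[GenomeRecord], FamilyTruth]:
    """Generate an annotated plastome family plus its complete truth.

    Identical (config, seed) pairs give byte-identical output.
    """
    config = config if config is not None else FamilyConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    taxa = config.resolved_taxa()
    n_taxa = len(taxa)

    part_seqs, part_feats, features, gap_windows, (ov_r, ov_y, ov_f) = _build_ancestor(
        config, rng
    )
    part_len = {p: len(part_seqs[p]) for p in PARTS}
    arrs = {
        p: np.frombuffer(part_seqs[p].encode(), dtype="S1").copy() for p in PARTS
    }

    protected = {p: np.zeros(part_len[p], dtype=bool) for p in PARTS}
    del_zone = {p: np.zeros(part_len[p], dtype=bool) for p in PARTS}
    for p in PARTS:
        protected[p][:2] = True
        protected[p][-2:] = True
    protected["IR"][: ov_r + 2] = True
    tail = max(ov_y, ov_f)
    if tail:
        protected["IR"][-(tail + 2) :] = True
    if config.ssc_pad:
        protected["SSC"][: config.ssc_pad] = True

    events: list[Event] = []

    # -- ndh gene fates --------------------------------------------------
    gene_location: dict[str, tuple[str, int, int, list]] = {}
    for part in PARTS:
        for spec, segs, _seq in part_feats[part]:
            s = min(x[0] for x in segs)
            e = max(x[1] for x in segs)
            gene_location[spec.name] = (part, s, e, segs)
    pattern = (
        config.ndh_pattern
        if config.ndh_pattern is not None
        else default_ndh_pattern(taxa, config.junction_type)
    )
    ndh_status: dict[str, dict[str, str]] = {}
    for taxon in taxa:
        fates = pattern.get(taxon, {})
        ndh_status[taxon] = {
            g: (fates.get(g, "complete") if g in gene_location else "lost")
            for g in NDH_GENES
        }
    for gene in NDH_GENES:
        if gene not in gene_location:
            continue
        part, gs, ge, segs = gene_location[gene]
        span_lo, span_hi = max(gs, 0), min(ge, part_len[part])
        protected[part][max(span_lo - 2, 0) : span_hi + 2] = True
        pseudo_members = tuple(
            sorted(t for t in taxa if ndh_status[t][gene] == "pseudogene")
        )
        lost_members = tuple(sorted(t for t in taxa if ndh_status[t][gene] == "lost"))
        if pseudo_members:
            # 1 bp frameshift inside the first genome-order exon
            exon = min(segs, key=lambda x: x[0])
            pos = max(exon[0], 0) + (min(exon[1], part_len[part]) - max(exon[0], 0)) // 2
            events.append(
                Event("deletion", part, pos, pos + 1, pseudo_members, origin="ndh_frameshift")
            )
            del_zone[part][pos : pos + 1] = True
        if lost_members:
            events.append(
                Event("deletion", part, span_lo, span_hi, lost_members, origin="ndh_loss")
            )
            del_zone[part][span_lo:span_hi] = True

    # -- planted SSR loci ------------------------------------------------
    ssr_loci: list[PlantedSSR] = []
    if config.n_ssr_loci:
        motifs, weights = zip(*_SSR_MOTIF_POOL)
        weights = np.array(weights, dtype=float)
        weights /= weights.sum()
        candidates = [
            (p, s, e)
            for p in ("LSC", "SSC")
            for s, e in gap_windows[p]
            if e - s >= 80 and not protected[p][s:e].any()
        ]
        if len(candidates) < config.n_ssr_loci:
            raise ValueError("not enough spacer room for the requested SSR loci")
        order = rng.permutation(len(candidates))
        placed = 0
        for ci in order:
            if placed == config.n_ssr_loci:
                break
            p, ws, we = candidates[ci]
            motif = str(rng.choice(motifs, p=weights))
            unit = len(motif)
            min_reps = DEFAULT_MINIMA[unit]
            max_reps = min_reps + int(rng.integers(1, config.ssr_max_extra + 1))
            run = max_reps * unit
            if we - ws < run + 12:
                continue
            start = int(rng.integers(ws + 5, we - 5 - run))
            arrs[p][start : start + run] = np.frombuffer(
                (motif * max_reps).encode(), dtype="S1"
            )
            # break periodicity at both flanks so the run is exactly maximal
            left_bad, right_bad = motif[-1].encode(), motif[0].encode()
            if arrs[p][start - 1] == left_bad:
                arrs[p][start - 1] = next(
                    b.encode() for b in "CGAT" if b.encode() != left_bad
                )
            if arrs[p][start + run] == right_bad:
                arrs[p][start + run] = next(
                    b.encode() for b in "CGAT" if b.encode() != right_bad
                )
            reps = rng.integers(min_reps, max_reps + 1, size=n_taxa)
            if n_taxa > 1:
                reps[0] = max_reps  # anchor: at least one taxon keeps the full run
                reps[1] = min_reps  # and the locus is guaranteed polymorphic
            else:
                reps[0] = max_reps
            locus = PlantedSSR(
                part=p,
                start=start,
                motif=motif,
                max_reps=max_reps,
                reps={t: int(r) for t, r in zip(taxa, reps)},
            )
            ssr_loci.append(locus)
            for r in sorted(set(locus.reps.values())):
                if r == max_reps:
                    continue
                members = tuple(sorted(t for t in taxa if locus.reps[t] == r))
                events.append(
                    Event(
                        "deletion",
                        p,
                        start + r * unit,
                        start + run,
                        members,
                        origin="ssr",
                    )
                )
            del_zone[p][start : start + run] = True
            protected[p][max(start - unit - 1, 0) : start + run + unit + 1] = True
            placed += 1
        if placed < config.n_ssr_loci:
            raise ValueError("not enough spacer room for the requested SSR loci")

    # -- background indels ----------------------------------------------
    # indels are restricted to non-exonic positions (selection removes
    # frame-disrupting indels from real coding regions); substitutions
    # may fall anywhere outside the protected zones
    exon_blocked = {p: protected[p].copy() for p in PARTS}
    for part in PARTS:
        for _spec, segs, _seq in part_feats[part]:
            for s, e, _st in segs:
                exon_blocked[part][max(s, 0) : min(e, part_len[part])] = True
    if n_taxa > 1:
        for part in PARTS:
            rate = config.indel_rate * (
                config.ir_rate_factor if part == "IR" else 1.0
            )
            n_events = int(round(rate * part_len[part]))
            attempts = 0
            made = 0
            while made < n_events and attempts < 80 * max(n_events, 1):
                attempts += 1
                length = int(rng.geometric(1.0 / config.indel_mean_len))
                if length > part_len[part] // 8:
                    continue
                start = int(rng.integers(2, part_len[part] - 2 - length))
                zone = exon_blocked[part][start - 2 : start + length + 2]
                if zone.any():
                    continue
                k = int(rng.integers(1, n_taxa))
                members = tuple(
                    sorted(rng.choice(taxa, size=k, replace=False))
                )
                events.append(
                    Event("deletion", part, start, start + length, members)
                )
                exon_blocked[part][start - 2 : start + length + 2] = True
                del_zone[part][start : start + length] = True
                made += 1

        # -- background substitutions -----------------------------------
        for part in PARTS:
            rate = config.sub_rate * (
                config.ir_rate_factor if part == "IR" else 1.0
            )
            n_events = int(round(rate * part_len[part]))
            allowed = np.nonzero(~(protected[part] | del_zone[part]))[0]
            if n_events > len(allowed):
                raise ValueError(f"substitution rate too high for {part}")
            positions = rng.choice(allowed, size=n_events, replace=False)
            for pos in sorted(int(x) for x in positions):
                orig = arrs[part][pos].decode()
                base = str(rng.choice([b for b in "ACGT" if b != orig]))
                k = int(rng.integers(1, n_taxa))
                members = tuple(sorted(rng.choice(taxa, size=k, replace=False)))
                events.append(
                    Event("substitution", part, pos, pos + 1, members, base=base)
                )

    part_strings = {p: arrs[p].tobytes().decode() for p in PARTS}
    truth = FamilyTruth(
        config=config,
        taxa=taxa,
        part_seqs=part_strings,
        features=features,
        gap_windows=gap_windows,
        events=events,
        ssr_loci=ssr_loci,
        ndh_status=ndh_status,
    )
    records = [_assemble_taxon(truth, taxon, i) for i, taxon in enumerate(taxa)]
    return records, truth


def _assemble_taxon(truth: FamilyTruth, taxon: str, index: int) -> GenomeRecord:
    """Apply a taxon's substitutions and deletions to the ancestor."""
    cfg = truth.config
    lsc_len = truth.part_len["LSC"]
    ir_len = truth.part_len["IR"]
    ssc_len = truth.part_len["SSC"]
    ira_off = lsc_len + ir_len + ssc_len
    n_anc = ira_off + ir_len
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    arr = np.frombuffer(truth.ancestor.encode(), dtype="S1").copy()
    offset = truth.part_offset
    subs: list[tuple[int, str]] = []
    dels: list[tuple[int, int]] = []
    for ev in truth.events:
        if taxon not in ev.members:
            continue
        g_s = offset[ev.part] + ev.start
        g_e = offset[ev.part] + ev.end
        if ev.kind == "substitution":
            subs.append((g_s, ev.base))
            if ev.part == "IR":
                subs.append((ira_off + ir_len - 1 - ev.start, comp[ev.base]))
        else:
            dels.append((g_s, g_e))
            if ev.part == "IR":
                dels.append((ira_off + ir_len - ev.end, ira_off + ir_len - ev.start))
    for pos, base in subs:
        arr[pos] = base.encode()
    keep = np.ones(n_anc, dtype=bool)
    for s, e in dels:
        keep[s:e] = False
    sequence = arr[keep].tobytes().decode()

    dels.sort()
    del_starts = np.array([d[0] for d in dels], dtype=int)
    del_ends = np.array([d[1] for d in dels], dtype=int)

    def remap(pos: int) -> int:
        removed = int(
            np.maximum(np.minimum(del_ends, pos) - np.minimum(del_starts, pos), 0).sum()
        )
        return pos - removed

    new_features = []
    for feat in truth.features:
        segments = []
        for s, e, strand in feat.segments:
            ns, ne = remap(s), remap(e)
            if ne > ns:
                segments.append((ns, ne, strand))
        if segments:
            new_features.append(
                Feature(feat.name, feat.kind, segments, pseudo=feat.pseudo)
            )

    def removed_in(lo: int, hi: int) -> int:
        return int(
            np.maximum(
                np.minimum(del_ends, hi) - np.maximum(del_starts, lo), 0
            ).sum()
        )

    lsc_t = lsc_len - removed_in(0, lsc_len)
    irb_t = ir_len - removed_in(lsc_len, lsc_len + ir_len)
    ssc_t = ssc_len - removed_in(lsc_len + ir_len, ira_off)
    partition = QuadripartitePartition(
        lsc=(0, lsc_t),
        irb=(lsc_t, lsc_t + irb_t),
        ssc=(lsc_t + irb_t, lsc_t + irb_t + ssc_t),
        ira=(lsc_t + irb_t + ssc_t, lsc_t + 2 * irb_t + ssc_t),
    )
    return GenomeRecord(
        taxon=taxon,
        sequence=sequence,
        circular=True,
        features=new_features,
        partition=partition,
        annotations={"accession": f"SYN{index + 1:03d}"},
    )


def make_plastome(
    junction_type: str = "I",
    seed: int = 0,
    roster: dict[str, list[GeneSpec]] | None = None,
    **overrides,
) -> tuple[GenomeRecord, FamilyTruth]:
    """One synthetic plastome with a chosen JSB layout (for junction and
    structure tests).  Uses the mini roster and small regions by default."""
    defaults = dict(
        n_taxa=1,
        lsc_len=6_000,
        ir_len=3_000,
        ssc_len=4_200,
        n_ssr_loci=0,
        sub_rate=0.0,
        indel_rate=0.0,
        ycf1_ir_overlap=0 if junction_type == "II" else 400,
        rpl22_ir_overlap=33,
        ndhf_ir_overlap=44,
        min_gap=60,
    )
    defaults.update(overrides)
    config = FamilyConfig(
        junction_type=junction_type,
        roster=roster if roster is not None else mini_roster(),
        **defaults,
    )
    records, truth = generate_family(config, seed)
    return records[0], truth


# ---------------------------------------------------------------------------
# Neutral coalescent alignments


def simulate_neutral_alignment(
    n: int, theta: float, length: int = 1000, seed: int = 0
) -> Alignment:
    """A neutral-coalescent alignment under infinite-sites mutation.

    Simulates a haploid Kingman coalescent (msprime, population size 1)
    and drops mutations at rate theta/2 on the genealogy, so the expected
    number of segregating sites is theta * a1 (a1 = sum_{i=1}^{n-1} 1/i)
    and expected pairwise diversity is theta.  Variant sites are placed
    at distinct random columns; the ancestral base is A, derived T.
    """
    if n < 2 or theta <= 0:
        raise ValueError("need n >= 2 and theta > 0")
    rng = np.random.default_rng(seed)
    anc_seed = int(rng.integers(1, 2**31 - 1))
    mut_seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=1.0, random_seed=anc_seed
    )
    mts = msprime.sim_mutations(
        ts,
        rate=theta / 2.0,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=mut_seed,
    )
    n_sites = mts.num_sites
    if n_sites > length:
        raise ValueError(
            f"{n_sites} segregating sites exceed alignment length {length}"
        )
    mat = np.full((n, length), b"A", dtype="S1")
    if n_sites:
        cols = np.sort(rng.choice(length, size=n_sites, replace=False))
        geno = mts.genotype_matrix()  # sites x samples
        for k in range(n_sites):
            mat[geno[k] > 0, cols[k]] = b"T"
    rows = [mat[i].tobytes().decode() for i in range(n)]
    return Alignment(taxa=[f"sample{i + 1:02d}" for i in range(n)], rows=rows)


def save_family(records: list[GenomeRecord], truth: FamilyTruth, outdir) -> None:
    """Write GenBank + FASTA records and the truth table to a directory."""
    import os

    from .io import write_fasta, write_genbank

    os.makedirs(outdir, exist_ok=True)
    for rec in records:
        stem = rec.taxon.replace(" ", "_")
        write_genbank(rec, os.path.join(outdir, f"{stem}.gb"))
    write_fasta(
        {r.taxon: r.sequence for r in records}, os.path.join(outdir, "family.fasta")
    )
    truth.to_json(os.path.join(outdir, "truth.json"))
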