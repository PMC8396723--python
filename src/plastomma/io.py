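"""Reading/writing annotated plastome records and structural bookkeeping.

GenBank flat files are read and written through Biopython; internally all
coordinates are 0-based half-open (converted from GenBank's 1-based
inclusive at the boundary).  This module also detects the quadripartite
partition (the maximal exact inverted-repeat pair), extracts analysis
regions (IGS / intron / CDS), and removes one inverted repeat so
downstream statistics do not double-count the IR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .records import Feature, GenomeRecord, QuadripartitePartition, revcomp

log = logging.getLogger(__name__)

_GB_KINDS = {"gene": "gene", "CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


class NoIRFoundError(ValueError):
    """No inverted-repeat pair of the required length exists."""


# ---------------------------------------------------------------------------
# GenBank I/O


def read_genbank(path) -> GenomeRecord:
    """Read one annotated plastome from a GenBank flat file.

    Coordinates are converted to 0-based half-open; minus-strand features
    retain their strand; ``/pseudo`` and ``/pseudogene`` qualifiers set the
    pseudo flag.
    """
    try:
        seqrec = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise ValueError(f"cannot parse GenBank file {path}: {exc}") from exc
    sequence = str(seqrec.seq).upper()
    if not sequence:
        raise ValueError(f"{path}: empty sequence")
    features: list[Feature] = []
    for gbf in seqrec.features:
        if gbf.type not in _GB_KINDS:
            continue
        name = (
            gbf.qualifiers.get("gene", [None])[0]
            or gbf.qualifiers.get("locus_tag", [None])[0]
            or gbf.type
        )
        if gbf.location is None:
            raise ValueError(f"{path}: feature {name} has malformed location")
        segments = []
        for part in gbf.location.parts:
            strand = part.strand if part.strand in (1, -1) else 1
            segments.append((int(part.start), int(part.end), strand))
        if gbf.location.strand == -1:
            # Biopython lists parts in transcription order for minus-strand
            # joins; our convention is the same (biological order).
            pass
        pseudo = "pseudo" in gbf.qualifiers or "pseudogene" in gbf.qualifiers
        features.append(Feature(name=name, kind=gbf.type, segments=segments, pseudo=pseudo))
    circular = seqrec.annotations.get("topology", "circular") == "circular"
    taxon = seqrec.annotations.get("organism") or seqrec.id
    if taxon in (None, ".", "", "unknown"):
        taxon = seqrec.id
    return GenomeRecord(
        taxon=taxon,
        sequence=sequence,
        circular=circular,
        features=features,
        annotations={"accession": seqrec.id, "description": seqrec.description},
    )


def write_genbank(record: GenomeRecord, path) -> None:
    """Write a record as a GenBank flat file (re-readable to an equal record).

    Features are emitted sorted by (start, kind, name) so output is
    byte-stable for a given record.
    """
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.annotations.get("accession", record.taxon.replace(" ", "_"))[:16],
        name=record.taxon.replace(" ", "_")[:16],
        description=record.annotations.get("description", record.taxon),
    )
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = "circular" if record.circular else "linear"
    seqrec.annotations["organism"] = record.taxon
    for feat in sorted(record.features, key=lambda f: (f.start, f.kind, f.name)):
        locs = [SimpleLocation(s, e, strand) for s, e, strand in feat.segments]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        qualifiers = {"gene": [feat.name]}
        if feat.pseudo:
            qualifiers["pseudo"] = [None]
        seqrec.features.append(SeqFeature(location, type=feat.kind, qualifiers=qualifiers))
    with open(path, "w") as fh:
        SeqIO.write(seqrec, fh, "genbank")


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-)FASTA file into an ordered {label: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for label, seq in sequences.items():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Quadripartite detection


def _mirror_pairs(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal disjoint interval pairs (a0, b0, length) with
    seq[a0:a0+L] == revcomp(seq[b0:b0+L]) and L >= min_len, a0 < b0.

    Anchor k-mers shared between the sequence and its reverse complement
    are grouped by diagonal and extended to maximal runs.
    """
    n = len(seq)
    k = min(16, max(4, min_len))
    rc = revcomp(seq)
    index: dict[str, list[int]] = {}
    for p in range(0, n - k + 1):
        index.setdefault(rc[p : p + k], []).append(p)
    diagonals: dict[int, set[int]] = {}
    for i in range(0, n - k + 1):
        for p in index.get(seq[i : i + k], ()):
            diagonals.setdefault(i - p, set()).add(i)
    pairs = []
    seen = set()
    for d, anchors in diagonals.items():
        done: set[int] = set()
        for i in sorted(anchors):
            if i in done:
                continue
            p = i - d
            lo_i, lo_p = i, p
            while lo_i > 0 and lo_p > 0 and seq[lo_i - 1] == rc[lo_p - 1]:
                lo_i -= 1
                lo_p -= 1
            hi_i, hi_p = i + k, p + k
            while hi_i < n and hi_p < n and seq[hi_i] == rc[hi_p]:
                hi_i += 1
                hi_p += 1
            done.update(range(lo_i, hi_i - k + 1))
            length = hi_i - lo_i
            if length < min_len:
                continue
            a = (lo_i, hi_i)  # interval in seq
            b = (n - hi_p, n - lo_p)  # mirrored interval in seq
            first, second = (a, b) if a[0] <= b[0] else (b, a)
            if first[1] > second[0]:
                continue  # overlapping (palindromic) candidate, not an IR pair
            key = (first[0], second[0], length)
            if key not in seen:
                seen.add(key)
                pairs.append((first[0], second[0], length))
    return pairs


def detect_quadripartite(
    record: GenomeRecord, min_ir_len: int = 10_000
) -> QuadripartitePartition:
    """Locate the inverted-repeat pair and partition the genome.

    Finds the maximal pair of disjoint intervals whose sequences are exact
    reverse complements (ties broken by leftmost start).  The longer
    single-copy arc is the LSC, the shorter the SSC.  If the LSC does not
    already begin at coordinate 0 the record is relinearized in place to
    start at the LSC (features spanning the new origin are split).
    Returns the partition and stores it on the record.
    """
    n = len(record.sequence)
    pairs = _mirror_pairs(record.sequence, min_ir_len)
    if not pairs:
        raise NoIRFoundError(
            f"{record.taxon}: no inverted repeat of length >= {min_ir_len} found"
        )
    best_len = max(p[2] for p in pairs)
    a0, b0, ir_len = min(p for p in pairs if p[2] == best_len)
    a = (a0, a0 + ir_len)
    b = (b0, b0 + ir_len)
    mid_arc = (a[1], b[0])  # between the two IRs
    wrap_arc = (b[1], a[0] + n)  # through the origin (may be empty)
    mid_len = mid_arc[1] - mid_arc[0]
    wrap_len = wrap_arc[1] - wrap_arc[0]
    if mid_len >= wrap_len:
        lsc_start, lsc_len, ssc_len = mid_arc[0] % n, mid_len, wrap_len
    else:
        lsc_start, lsc_len, ssc_len = wrap_arc[0] % n, wrap_len, mid_len
    if lsc_start != 0:
        _rotate_record(record, lsc_start)
    partition = QuadripartitePartition(
        lsc=(0, lsc_len),
        irb=(lsc_len, lsc_len + ir_len),
        ssc=(lsc_len + ir_len, lsc_len + ir_len + ssc_len),
        ira=(lsc_len + ir_len + ssc_len, n),
    )
    partition.validate(n)
    irb_seq = record.sequence[partition.irb[0] : partition.irb[1]]
    ira_seq = record.sequence[partition.ira[0] : partition.ira[1]]
    if revcomp(ira_seq) != irb_seq:
        raise ValueError(f"{record.taxon}: IR mirror check failed after detection")
    record.partition = partition
    return partition


def _rotate_record(record: GenomeRecord, shift: int) -> None:
    """Relinearize a circular record to start at ``shift`` (in place)."""
    n = len(record.sequence)
    record.sequence = record.sequence[shift:] + record.sequence[:shift]
    for feat in record.features:
        segments = []
        for s, e, strand in feat.segments:
            ns, ne = (s - shift) % n, (e - shift) % n or n
            if ns < ne:
                segments.append((ns, ne, strand))
            else:  # feature segment now spans the origin: split
                segments.append((ns, n, strand))
                segments.append((0, ne, strand))
        feat.segments = segments
    record.partition = None


# ---------------------------------------------------------------------------
# Region extraction


@dataclass(frozen=True)
class ExtractedRegion:
    """One region extracted from a single record."""

    name: str
    category: str  # IGS / intron / CDS
    location: str  # LSC / SSC / IR
    start: int
    end: int
    sequence: str


def _location_class(record: GenomeRecord, midpoint: int) -> str:
    if record.partition is not None:
        return record.partition.region_of(midpoint)
    for name, s, e in record.annotations.get("regions", ()):
        if s <= midpoint < e:
            return name
    raise ValueError(f"{record.taxon}: no partition/region map for location class")


def extract_regions(record: GenomeRecord, min_len: int = 0) -> list[ExtractedRegion]:
    """Extract CDSs, introns, and intergenic spacers from one record.

    CDSs are spliced and strand-corrected; introns are the gaps between
    consecutive exon segments of multi-segment gene features; IGSs are the
    gaps between consecutive gene-bearing features on the linearized
    genome.  ``min_len`` drops IGS/intron candidates shorter than the
    threshold as measured on the unaligned extraction; the conventional
    150 bp cut is applied downstream on alignment length, so the default
    here keeps everything.
    """
    regions: list[ExtractedRegion] = []
    seq = record.sequence

    for feat in record.features_of_kind("CDS"):
        cds = feat.extract(seq)
        regions.append(
            ExtractedRegion(
                name=feat.name,
                category="CDS",
                location=_location_class(record, feat.midpoint),
                start=feat.start,
                end=feat.end,
                sequence=cds,
            )
        )

    gene_like = record.features_of_kind("gene", "tRNA", "rRNA")
    # deduplicate gene wrappers that shadow a tRNA/rRNA feature of same span
    spans: dict[tuple[int, int], Feature] = {}
    for feat in gene_like:
        spans.setdefault((feat.start, feat.end), feat)
    ordered = sorted(spans.values(), key=lambda f: (f.start, f.end))

    for feat in ordered:
        if len(feat.segments) < 2:
            continue
        segs = sorted((s, e) for s, e, _ in feat.segments)
        for idx in range(len(segs) - 1):
            s = segs[idx][1]
            e = segs[idx + 1][0]
            if e <= s:
                continue
            intron = seq[s:e] if feat.strand == 1 else revcomp(seq[s:e])
            if min_len and e - s < min_len:
                continue
            regions.append(
                ExtractedRegion(
                    name=f"{feat.name}_intron{idx + 1}",
                    category="intron",
                    location=_location_class(record, (s + e) // 2),
                    start=s,
                    end=e,
                    sequence=intron,
                )
            )

    prev = None
    for feat in ordered:
        if prev is not None:
            gap_s, gap_e = prev.end, feat.start
            if gap_e > gap_s:
                if not min_len or gap_e - gap_s >= min_len:
                    regions.append(
                        ExtractedRegion(
                            name=f"{prev.name}-{feat.name}",
                            category="IGS",
                            location=_location_class(record, (gap_s + gap_e) // 2),
                            start=gap_s,
                            end=gap_e,
                            sequence=seq[gap_s:gap_e],
                        )
                    )
            elif gap_e < gap_s:
                log.info(
                    "%s: overlapping genes %s/%s, no IGS emitted",
                    record.taxon,
                    prev.name,
                    feat.name,
                )
        if prev is None or feat.end > prev.end:
            prev = feat
    return regions


def collect_regions(per_taxon: dict[str, list[ExtractedRegion]]):
    """Group per-record extractions into cross-taxon RegionSequence objects.

    Regions are matched by (name, category); the location class is taken
    from the first taxon carrying the region.
    """
    from .records import RegionSequence

    grouped: dict[tuple[str, str], RegionSequence] = {}
    for taxon, regions in per_taxon.items():
        for reg in regions:
            key = (reg.name, reg.category)
            if key not in grouped:
                grouped[key] = RegionSequence(
                    name=reg.name, category=reg.category, location=reg.location
                )
            grouped[key].sequences[taxon] = reg.sequence
    return list(grouped.values())


# ---------------------------------------------------------------------------
# One-IR removal


def drop_one_ir(record: GenomeRecord) -> GenomeRecord:
    """Return a copy of the record with IRb removed (IRa copy retained).

    Features lying wholly in IRb are dropped; features straddling an IRb
    boundary are clipped to their retained portion.  The result carries a
    three-region map (LSC/SSC/IR) in ``annotations["regions"]`` instead of
    a quadripartite partition.
    """
    part = record.partition
    if part is None:
        raise ValueError(f"{record.taxon}: record has no quadripartite partition")
    lsc_s, lsc_e = part.lsc
    irb_s, irb_e = part.irb
    ssc_s, ssc_e = part.ssc
    ira_s, ira_e = part.ira
    ir_len = part.ir_len
    new_seq = (
        record.sequence[lsc_s:lsc_e]
        + record.sequence[ssc_s:ssc_e]
        + record.sequence[ira_s:ira_e]
    )

    new_features = []
    for feat in record.features:
        segments = []
        for s, e, strand in feat.segments:
            # keep the parts left of IRb (identity) and right of IRb
            # (shifted left by one IR length); the IRb overlap is dropped
            if min(e, irb_s) > s:
                segments.append((s, min(e, irb_s), strand))
            if e > max(s, irb_e):
                segments.append((max(s, irb_e) - ir_len, e - ir_len, strand))
        if segments:
            new_features.append(
                Feature(feat.name, feat.kind, segments, pseudo=feat.pseudo)
            )
    new_lsc = lsc_e - lsc_s
    new_ssc = ssc_e - ssc_s
    annotations = dict(record.annotations)
    annotations["regions"] = [
        ("LSC", 0, new_lsc),
        ("SSC", new_lsc, new_lsc + new_ssc),
        ("IR", new_lsc + new_ssc, new_lsc + new_ssc + ir_len),
    ]
    return GenomeRecord(
        taxon=record.taxon,
        sequence=new_seq,
        circular=False,
        features=new_features,
        partition=None,
        annotations=annotations,
    )
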