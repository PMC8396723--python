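"""Microsatellite (SSR) scanning, cross-taxon polymorphism, and primer
constraint filtering.

The scanner reports maximal *perfect* tandem repeats of 1-6 bp motifs
with the conventional plastid thresholds (>= 10 repeats for mono-, >= 5
for di-, >= 3 for tri- through hexanucleotide motifs).  A locus is
reported once, under its shortest period: motifs that are themselves a
repetition of a shorter motif are never emitted.  Loci closer than a
configurable distance are additionally grouped as compound, which does
not change the individual-locus count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .align import Alignment
from .records import GenomeRecord, revcomp

log = logging.getLogger(__name__)

DEFAULT_MINIMA = {1: 10, 2: 5, 3: 3, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class SSRLocus:
    """One perfect tandem repeat: motif, repeat count, and coordinates."""

    motif: str
    reps: int
    start: int
    end: int
    region: str = ""  # LSC / SSC / IR
    context: str = ""  # CDS / intron / IGS

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif) * self.reps:
            raise ValueError("locus span inconsistent with motif and repeat count")

    @property
    def unit(self) -> int:
        return len(self.motif)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end - 1) // 2


def _primitive(motif: str) -> bool:
    """True unless the motif is itself a repetition of a shorter motif."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_rotation(motif: str) -> str:
    """Lexicographically minimal cyclic rotation (cross-taxon identity)."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def motif_class(motif: str) -> str:
    """Strand- and rotation-insensitive motif class, e.g. A/T or AAG/CTT."""
    fwd = canonical_rotation(motif)
    rev = canonical_rotation(revcomp(motif))
    if fwd == rev:
        return fwd
    a, b = sorted((fwd, rev))
    return f"{a}/{b}"


def scan_ssrs(
    sequence: str,
    minima: dict[int, int] | None = None,
) -> list[SSRLocus]:
    """All maximal perfect tandem repeats meeting the repeat-count minima.

    Repeats containing N are not reported; non-ACGTN characters raise.
    Loci are sorted by (start, unit).
    """
    minima = dict(DEFAULT_MINIMA if minima is None else minima)
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    n = len(seq)
    loci: list[SSRLocus] = []
    for unit, min_reps in sorted(minima.items()):
        if min_reps is None:
            continue
        i = 0
        while i + unit * min_reps <= n:
            motif = seq[i : i + unit]
            if "N" in motif or not _primitive(motif):
                i += 1
                continue
            j = i + unit
            while j < n and seq[j] == seq[j - unit] and seq[j] != "N":
                j += 1
            reps = (j - i) // unit
            if reps >= min_reps:
                loci.append(
                    SSRLocus(motif=motif, reps=reps, start=i, end=i + reps * unit)
                )
                i = i + reps * unit
            else:
                # any start inside this periodic run hits the same break
                i = max(i + 1, j - unit + 1) if reps > 1 else i + 1
        # note: runs shorter than the threshold are simply skipped
    return sorted(loci, key=lambda l: (l.start, l.unit))


def group_compound(loci: list[SSRLocus], max_gap: int = 100) -> list[list[SSRLocus]]:
    """Group loci separated by less than ``max_gap`` bp as compound SSRs.

    Grouping is informational only; it never changes the locus count.
    """
    groups: list[list[SSRLocus]] = []
    for locus in sorted(loci, key=lambda l: (l.start, l.unit)):
        if groups and locus.start - groups[-1][-1].end < max_gap:
            groups[-1].append(locus)
        else:
            groups.append([locus])
    return groups


def contextualize(loci: list[SSRLocus], record: GenomeRecord) -> list[SSRLocus]:
    """Fill each locus's partition region and genomic context by midpoint.

    Context is CDS when the midpoint lies in an exon segment of any
    coding or structural-RNA feature, intron when it lies inside a gene
    span but between exons, and IGS otherwise.  A locus straddling a
    feature boundary follows its midpoint (logged).
    """
    if record.partition is not None:
        region_map = [
            ("IR" if name in ("IRa", "IRb") else name, s, e)
            for name, s, e in record.partition.named_intervals()
        ]
    else:
        region_map = list(record.annotations.get("regions", ()))
    exonic = record.features_of_kind("CDS", "tRNA", "rRNA")
    genic = record.features_of_kind("gene", "CDS", "tRNA", "rRNA")
    out = []
    for locus in loci:
        mid = locus.midpoint
        region = next((name for name, s, e in region_map if s <= mid < e), "")
        if any(f.contains(mid) for f in exonic):
            context = "CDS"
        elif any(f.span_contains(mid) for f in genic):
            context = "intron"
        else:
            context = "IGS"
        if any(
            f.span_contains(locus.start) != f.span_contains(locus.end - 1)
            for f in genic
        ):
            log.info(
                "%s: SSR %s at %d straddles a feature boundary; midpoint rule used",
                record.taxon,
                locus.motif,
                locus.start,
            )
        out.append(replace(locus, region=region, context=context))
    return out


# ---------------------------------------------------------------------------
# Cross-taxon polymorphic loci


@dataclass
class CrossTaxonLocus:
    """One SSR locus matched across taxa via the alignment."""

    motif: str  # canonical rotation
    aligned_start: int
    aligned_end: int
    reps: dict[str, int] = field(default_factory=dict)

    @property
    def presence(self) -> int:
        return len(self.reps)

    @property
    def polymorphic(self) -> bool:
        return len(set(self.reps.values())) > 1


def polymorphic_loci(
    per_taxon_loci: dict[str, list[SSRLocus]],
    alignment: Alignment,
    min_presence: int = 7,
) -> list[CrossTaxonLocus]:
    """Match SSR loci across taxa and report those present in at least
    ``min_presence`` taxa, flagged polymorphic when repeat counts differ.

    Loci from different taxa are the same cross-taxon locus iff their
    alignment-column intervals overlap and their motifs match up to
    cyclic rotation.  Locus coordinates must refer to the exact sequences
    present (ungapped) in the alignment.
    """
    items = []  # (canonical motif, aligned interval, taxon, reps)
    for taxon, loci in per_taxon_loci.items():
        if taxon not in alignment.taxa:
            raise ValueError(f"taxon {taxon} absent from alignment")
        coord_map = alignment.ungapped_to_aligned(taxon)
        for locus in loci:
            if locus.end > len(coord_map):
                raise ValueError(
                    f"{taxon}: locus at {locus.start} beyond aligned sequence"
                )
            a_start = int(coord_map[locus.start])
            a_end = int(coord_map[locus.end - 1]) + 1
            items.append((canonical_rotation(locus.motif), a_start, a_end, taxon, locus.reps))

    # union-find over overlapping same-motif intervals
    parent = list(range(len(items)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_motif: dict[str, list[int]] = {}
    for idx, item in enumerate(items):
        by_motif.setdefault(item[0], []).append(idx)
    for indices in by_motif.values():
        indices.sort(key=lambda i: items[i][1])
        chain_root, chain_end = indices[0], items[indices[0]][2]
        for idx in indices[1:]:
            if items[idx][1] < chain_end:  # overlaps the running cluster
                parent[find(idx)] = find(chain_root)
                chain_end = max(chain_end, items[idx][2])
            else:
                chain_root, chain_end = idx, items[idx][2]

    clusters: dict[int, CrossTaxonLocus] = {}
    for idx, (motif, a_start, a_end, taxon, reps) in enumerate(items):
        root = find(idx)
        if root not in clusters:
            clusters[root] = CrossTaxonLocus(
                motif=motif, aligned_start=a_start, aligned_end=a_end
            )
        cluster = clusters[root]
        cluster.aligned_start = min(cluster.aligned_start, a_start)
        cluster.aligned_end = max(cluster.aligned_end, a_end)
        if taxon in cluster.reps:
            cluster.reps[taxon] = max(cluster.reps[taxon], reps)
        else:
            cluster.reps[taxon] = reps
    return sorted(
        (c for c in clusters.values() if c.presence >= min_presence),
        key=lambda c: (c.aligned_start, c.motif),
    )


# ---------------------------------------------------------------------------
# Primer constraints


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C), for <= 20-mers."""
    seq = seq.upper()
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


def gc_tm(seq: str) -> float:
    """GC-fraction melting temperature: 64.9 + 41 (G+C - 16.4) / N."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def melting_temperature(seq: str, formula: str = "auto") -> float:
    """Primer Tm; 'auto' uses the Wallace rule up to 20-mers, else the
    GC formula. Explicit 'wallace' or 'gc' select one formula."""
    if formula == "wallace":
        return wallace_tm(seq)
    if formula == "gc":
        return gc_tm(seq)
    return wallace_tm(seq) if len(seq) <= 20 else gc_tm(seq)


@dataclass(frozen=True)
class PrimerConstraints:
    """Constraint profile for primer filtering.

    The SSR profile uses max_tm_diff 1 degC and product 100-500 bp; the
    hotspot profile relaxes to 2 degC and 100-1000 bp.
    """

    min_len: int = 18
    max_len: int = 27
    min_gc: float = 0.20
    max_gc: float = 0.80
    min_tm: float = 57.0
    max_tm: float = 63.0
    max_tm_diff: float = 1.0
    min_product: int = 100
    max_product: int = 500
    tm_formula: str = "auto"


SSR_PROFILE = PrimerConstraints()
HOTSPOT_PROFILE = PrimerConstraints(max_tm_diff=2.0, max_product=1000)


@dataclass
class PrimerCandidate:
    """A forward/reverse primer pair with per-constraint pass/fail."""

    forward: str
    reverse: str
    product_size: int
    target: str = ""
    checks: dict[str, bool] = field(default_factory=dict)

    def evaluate(self, constraints: PrimerConstraints) -> dict[str, bool]:
        fwd, rev = self.forward.upper(), self.reverse.upper()
        tm_f = melting_temperature(fwd, constraints.tm_formula)
        tm_r = melting_temperature(rev, constraints.tm_formula)

        def gc_frac(s: str) -> float:
            return (s.count("G") + s.count("C")) / len(s) if s else 0.0

        self.checks = {
            "length": all(
                constraints.min_len <= len(p) <= constraints.max_len for p in (fwd, rev)
            ),
            "gc": all(
                constraints.min_gc <= gc_frac(p) <= constraints.max_gc
                for p in (fwd, rev)
            ),
            "tm": all(constraints.min_tm <= t <= constraints.max_tm for t in (tm_f, tm_r)),
            "tm_diff": abs(tm_f - tm_r) <= constraints.max_tm_diff,
            "product": constraints.min_product
            <= self.product_size
            <= constraints.max_product,
        }
        return self.checks

    @property
    def passes(self) -> bool:
        return bool(self.checks) and all(self.checks.values())


def filter_primers(
    candidates: list[PrimerCandidate], constraints: PrimerConstraints
) -> list[PrimerCandidate]:
    """Candidates passing every constraint; each check recorded per pair."""
    passing = []
    for cand in candidates:
        cand.evaluate(constraints)
        if cand.passes:
            passing.append(cand)
    return passing


def design_primers(
    sequence: str,
    target_start: int,
    target_end: int,
    constraints: PrimerConstraints = SSR_PROFILE,
    flank: int = 200,
    target: str = "",
    max_candidates: int = 2000,
) -> list[PrimerCandidate]:
    """Enumerate sliding-window primer pairs around a target and filter.

    Candidate generation is plumbing: every window of an allowed length
    within ``flank`` bp of the target, paired across the target, is
    offered to :func:`filter_primers`.
    """
    n = len(sequence)
    left_lo = max(0, target_start - flank)
    right_hi = min(n, target_end + flank)

    def window_ok(primer: str) -> bool:
        gc = (primer.count("G") + primer.count("C")) / len(primer)
        tm = melting_temperature(primer, constraints.tm_formula)
        return (
            constraints.min_gc <= gc <= constraints.max_gc
            and constraints.min_tm <= tm <= constraints.max_tm
        )

    forwards = []  # (start, primer)
    reverses = []  # (end, primer)
    for length in range(constraints.min_len, constraints.max_len + 1):
        for fs in range(left_lo, target_start - length + 1):
            primer = sequence[fs : fs + length]
            if window_ok(primer):
                forwards.append((fs, primer))
        for re_ in range(target_end + length, right_hi + 1):
            primer = revcomp(sequence[re_ - length : re_])
            if window_ok(primer):
                reverses.append((re_, primer))
    candidates: list[PrimerCandidate] = []
    for fs, fwd in forwards:
        for re_, rev in reverses:
            candidates.append(
                PrimerCandidate(
                    forward=fwd, reverse=rev, product_size=re_ - fs, target=target
                )
            )
            if len(candidates) >= max_candidates:
                break
        if len(candidates) >= max_candidates:
            break
    return filter_primers(candidates, constraints)
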