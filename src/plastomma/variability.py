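"""Alignment variability statistics and mutational-hotspot ranking.

The central statistic is the sequence-variability percentage

    SV = 100 * (m + i) / (l + m + i)

where ``l`` is the alignment length in bp, ``m`` the total number of
mutations (extra alleles summed over columns, so a tri-allelic site
contributes 2), and ``i`` the number of indel *events* — maximal gap
intervals counted once even when shared identically by several rows,
which avoids the homoplasy inflation of counting gap columns as sites.
Segregating sites ``s`` (columns with >= 2 states) and parsimony-
informative characters (columns with >= 2 states each in >= 2 rows) are
computed alongside; ``m`` and ``s`` differ only at multi-allelic columns
and both are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import Alignment

log = logging.getLogger(__name__)

_BASES = (b"A", b"C", b"G", b"T")


@dataclass(frozen=True)
class IndelEvent:
    """A maximal gap interval (alignment columns, half-open) and the rows
    gapped over exactly this interval."""

    start: int
    end: int
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("indel event interval must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end - 1) // 2


@dataclass
class VariabilityResult:
    """Per-region variability summary."""

    name: str
    location: str = ""
    category: str = ""
    length: int = 0  # l: alignment length in bp
    mutations: int = 0  # m: total number of mutations
    segregating: int = 0  # s: segregating sites
    indel_events: int = 0  # i
    pic: int = 0  # parsimony-informative characters
    sv: float = 0.0
    gc: float = 0.0
    events: list[IndelEvent] = field(default_factory=list, repr=False)


def count_site_stats(aln: Alignment) -> tuple[int, int, int]:
    """Count (segregating sites, mutations, parsimony-informative sites).

    Gap and N characters never contribute alleles.  Per column with k
    distinct states the mutation count increases by k - 1 (multi-allelic
    sites count multiply); an all-gap column contributes nothing.
    """
    mat = aln.matrix
    counts = np.stack([(mat == b).sum(axis=0) for b in _BASES])  # 4 x cols
    k = (counts > 0).sum(axis=0)
    s = int((k >= 2).sum())
    m = int(np.maximum(k - 1, 0).sum())
    pic = int(((counts >= 2).sum(axis=0) >= 2).sum())
    return s, m, pic


def detect_indel_events(aln: Alignment) -> list[IndelEvent]:
    """Find indel events: distinct maximal gap intervals across rows.

    Maximal gap runs are located per row; runs with identical (start, end)
    in several rows merge into one event.  Terminal runs (touching the
    first or last column) are treated as missing data, not events.
    """
    n_cols = aln.n_cols
    intervals: dict[tuple[int, int], set[str]] = {}
    for taxon, row in zip(aln.taxa, aln.rows):
        arr = np.frombuffer(row.encode(), dtype="S1") == b"-"
        if not arr.any():
            continue
        padded = np.diff(np.concatenate(([0], arr.view(np.int8), [0])))
        starts = np.nonzero(padded == 1)[0]
        ends = np.nonzero(padded == -1)[0]
        for s, e in zip(starts, ends):
            if s == 0 or e == n_cols:
                continue  # terminal gap: missing data
            intervals.setdefault((int(s), int(e)), set()).add(taxon)
    return [
        IndelEvent(s, e, frozenset(members))
        for (s, e), members in sorted(intervals.items())
    ]


def sequence_variability(l: int, m: int, i: int) -> float:
    """SV = 100 (m + i) / (l + m + i); zero iff no mutations and no events."""
    if l <= 0:
        raise ValueError("alignment length must be positive")
    if m < 0 or i < 0:
        raise ValueError("mutation and indel counts must be non-negative")
    return 100.0 * (m + i) / (l + m + i)


def analyze_region(
    name: str,
    aln: Alignment,
    location: str = "",
    category: str = "",
) -> VariabilityResult:
    """Full variability summary of one aligned region."""
    s, m, pic = count_site_stats(aln)
    events = detect_indel_events(aln)
    i = len(events)
    mat = aln.matrix
    gc = int(((mat == b"G") | (mat == b"C")).sum())
    acgt = int(sum((mat == b).sum() for b in _BASES))
    return VariabilityResult(
        name=name,
        location=location,
        category=category,
        length=aln.n_cols,
        mutations=m,
        segregating=s,
        indel_events=i,
        pic=pic,
        sv=sequence_variability(aln.n_cols, m, i),
        gc=gc / acgt if acgt else 0.0,
        events=events,
    )


def rank_hotspots(
    results: list[VariabilityResult], k: int | None = 10
) -> list[VariabilityResult]:
    """Top-k regions by SV, descending; ties by larger m, then name."""
    if not results:
        raise ValueError("no variability results to rank")
    ordered = sorted(results, key=lambda r: (-r.sv, -r.mutations, r.name))
    return ordered if k is None else ordered[:k]


def export_concatenated(
    alignments: dict[str, Alignment], path, fmt: str = "nexus"
) -> None:
    """Write a concatenated supermatrix of region alignments with a
    partition block (NEXUS charsets) or as relaxed PHYLIP.

    Regions are concatenated in name order; a taxon missing from a
    region is filled with gaps for that block.
    """
    names = sorted(alignments)
    taxa = sorted({t for name in names for t in alignments[name].taxa})
    blocks: dict[str, list[str]] = {t: [] for t in taxa}
    charsets: list[tuple[str, int, int]] = []
    cursor = 0
    for name in names:
        aln = alignments[name]
        for taxon in taxa:
            if taxon in aln.taxa:
                blocks[taxon].append(aln.row(taxon))
            else:
                blocks[taxon].append("-" * aln.n_cols)
        charsets.append((name, cursor + 1, cursor + aln.n_cols))
        cursor += aln.n_cols
    rows = {t: "".join(parts) for t, parts in blocks.items()}
    safe = {t: t.replace(" ", "_") for t in taxa}
    with open(path, "w") as fh:
        if fmt == "nexus":
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(taxa)} NCHAR={cursor};\n")
            fh.write("  FORMAT DATATYPE=DNA MISSING=N GAP=-;\n  MATRIX\n")
            for taxon in taxa:
                fh.write(f"    {safe[taxon]}  {rows[taxon]}\n")
            fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
            for name, start, end in charsets:
                fh.write(f"  CHARSET {name.replace('-', '_')} = {start}-{end};\n")
            fh.write("END;\n")
        elif fmt == "phylip":
            fh.write(f" {len(taxa)} {cursor}\n")
            for taxon in taxa:
                fh.write(f"{safe[taxon]}  {rows[taxon]}\n")
        else:
            raise ValueError(f"unknown format {fmt!r} (use 'nexus' or 'phylip')")


def indel_events_by_partition(
    aln_pair: Alignment,
    reference: str,
    regions: list[tuple[str, int, int]],
) -> dict[str, int]:
    """Assign pairwise indel events to LSC/SSC/IR by reference midpoint.

    ``aln_pair`` is a pairwise alignment containing the reference taxon;
    ``regions`` lists (class, start, end) intervals in reference
    coordinates (class one of LSC/SSC/IR).  Each event goes to the region
    holding its reference-coordinate midpoint; an event whose midpoint
    falls exactly on a boundary belongs to the left region (the interval
    ending there), which the half-open interval arithmetic below yields
    directly for gap-in-reference events.
    """
    if reference not in aln_pair.taxa:
        raise ValueError(f"reference {reference} absent from alignment")
    if aln_pair.n_rows != 2:
        raise ValueError("indel_events_by_partition expects a pairwise alignment")
    ref_row = np.frombuffer(aln_pair.row(reference).encode(), dtype="S1")
    # reference coordinate of each alignment column (count of non-gap
    # reference chars strictly before the column)
    ref_coord = np.concatenate(([0], np.cumsum(ref_row != b"-")))[:-1]
    counts = {name: 0 for name, _, _ in regions}
    counts.setdefault("LSC", 0)
    counts.setdefault("SSC", 0)
    counts.setdefault("IR", 0)
    for event in detect_indel_events(aln_pair):
        pos = int(ref_coord[event.midpoint])
        assigned = None
        for name, s, e in regions:
            # boundary tie rule: a midpoint exactly on a region boundary
            # belongs to the left region (the interval ending there)
            if s < pos <= e or (pos == 0 and s == 0):
                assigned = name
                break
        if assigned is None:
            log.info("indel event %s outside region map, skipped", event)
            continue
        counts[assigned] += 1
    return counts
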