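"""Core domain types for annotated plastome records.

A plastome is a circular ~150 kb molecule with a quadripartite layout:
a large single-copy region (LSC), a small single-copy region (SSC), and
two identical inverted repeats (IRa/IRb) separating them.  All internal
coordinates are 0-based half-open on the linearized sequence; the GenBank
boundary (1-based inclusive) is handled in :mod:`plastomma.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction over unambiguous bases; 0.0 for empty input."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


@dataclass
class Feature:
    """A genome feature: gene, CDS, tRNA, or rRNA.

    ``segments`` is an ordered list of ``(start, end, strand)`` intervals
    (0-based half-open, strand +1/-1).  Multi-segment features keep their
    biological segment order (exon order for spliced genes), which for
    minus-strand features runs against genome coordinates.
    """

    name: str
    kind: str  # one of {"gene", "CDS", "tRNA", "rRNA"}
    segments: list[tuple[int, int, int]]
    pseudo: bool = False

    KINDS = ("gene", "CDS", "tRNA", "rRNA")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"feature {self.name}: unknown kind {self.kind!r}")
        if not self.segments:
            raise ValueError(f"feature {self.name}: no segments")
        for s, e, strand in self.segments:
            if not (0 <= s < e):
                raise ValueError(f"feature {self.name}: bad interval ({s}, {e})")
            if strand not in (1, -1):
                raise ValueError(f"feature {self.name}: bad strand {strand}")

    @property
    def start(self) -> int:
        return min(s for s, _, _ in self.segments)

    @property
    def end(self) -> int:
        return max(e for _, e, _ in self.segments)

    @property
    def strand(self) -> int:
        return self.segments[0][2]

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def spliced_length(self) -> int:
        return sum(e - s for s, e, _ in self.segments)

    def extract(self, sequence: str) -> str:
        """Spliced, strand-corrected sequence of the feature."""
        parts = []
        for s, e, strand in self.segments:
            seg = sequence[s:e]
            parts.append(revcomp(seg) if strand == -1 else seg)
        return "".join(parts)

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e, _ in self.segments)

    def span_contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class QuadripartitePartition:
    """The four arcs of the quadripartite layout on the linearized circle.

    Canonical order after relinearization is LSC, IRb, SSC, IRa; the two IR
    intervals have equal length and mirror-image (reverse-complement)
    sequence content.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]

    @property
    def lsc_len(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_len(self) -> int:
        return self.ssc[1] - self.ssc[0]

    @property
    def ir_len(self) -> int:
        return self.ira[1] - self.ira[0]

    def total(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len

    def named_intervals(self) -> list[tuple[str, int, int]]:
        return [
            ("LSC", *self.lsc),
            ("IRb", *self.irb),
            ("SSC", *self.ssc),
            ("IRa", *self.ira),
        ]

    def region_of(self, pos: int) -> str:
        """Region class ("LSC", "SSC", or "IR") holding a coordinate."""
        for name, s, e in self.named_intervals():
            if s <= pos < e:
                return "IR" if name in ("IRa", "IRb") else name
        raise ValueError(f"position {pos} outside partition")

    def validate(self, genome_length: int) -> None:
        intervals = sorted((s, e) for _, s, e in self.named_intervals())
        cursor = 0
        for s, e in intervals:
            if s != cursor:
                raise ValueError("partition intervals do not tile the genome")
            cursor = e
        if cursor != genome_length:
            raise ValueError("partition intervals do not tile the genome")
        if self.irb[1] - self.irb[0] != self.ira[1] - self.ira[0]:
            raise ValueError("IR intervals have unequal length")


@dataclass
class GenomeRecord:
    """One annotated plastome: sequence, features, optional partition."""

    taxon: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)
    partition: QuadripartitePartition | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.taxon}: non-ACGTN characters {sorted(bad)}")
        if self.partition is not None:
            self.partition.validate(len(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_fraction(self.sequence)

    def features_of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]

    def get_features(self, name: str, kind: str | None = None) -> list[Feature]:
        return [
            f
            for f in self.features
            if f.name == name and (kind is None or f.kind == kind)
        ]

    def copy(self) -> "GenomeRecord":
        return GenomeRecord(
            taxon=self.taxon,
            sequence=self.sequence,
            circular=self.circular,
            features=[replace(f, segments=list(f.segments)) for f in self.features],
            partition=self.partition,
            annotations=dict(self.annotations),
        )


@dataclass
class RegionSequence:
    """A named analysis region (IGS, intron, or CDS) across taxa.

    IGS names are formed ``"<left gene>-<right gene>"`` in linearized
    plus-strand gene order.  ``sequences`` maps taxon label to the
    unaligned extracted sequence.
    """

    name: str
    category: str  # one of {"IGS", "intron", "CDS"}
    location: str  # one of {"LSC", "SSC", "IR"}
    sequences: dict[str, str] = field(default_factory=dict)

    CATEGORIES = ("IGS", "intron", "CDS")

    def __post_init__(self) -> None:
        if self.category not in self.CATEGORIES:
            raise ValueError(f"region {self.name}: bad category {self.category}")

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)
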