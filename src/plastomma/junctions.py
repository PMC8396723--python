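"""IR/single-copy junction location, junction typing, and ndh status.

The four junctions of the quadripartite layout are JLB (LSC/IRb), JSB
(IRb/SSC), JSA (SSC/IRa), and JLA (IRa/LSC, at the circular origin).
The IRb/SSC junction is classified into three types by the fate of
*ndhF*: type I, *ndhF* wholly within the SSC; type II, *ndhF*
overlapping the junction; type III, *ndhF* deleted.  The JLB context is
reported as lying within *rpl22*, within *rps19*, or in the
*rpl22*-*rps19* spacer.

The 11 plastid NAD(P)H-dehydrogenase (*ndh*) genes are scored per taxon
as complete, pseudogene, or lost; *ndh* loss and pseudogenization are
rampant in orchids and drive SSC-size variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .records import Feature, GenomeRecord

log = logging.getLogger(__name__)

NDH_GENES = [f"ndh{c}" for c in "ABCDEFGHIJK"]

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODONS = ("ATG", "GTG", "ACG", "CTG", "ATT")

JUNCTION_NAMES = ("JLB", "JSB", "JSA", "JLA")


@dataclass
class JunctionGene:
    """A gene at a junction: name and bp lying on either side."""

    gene: str
    left_bp: int
    right_bp: int


@dataclass
class JunctionProfile:
    """Coordinates of the four junctions and the genes spanning them."""

    taxon: str
    coordinates: dict[str, int]
    genes: dict[str, list[JunctionGene]] = field(default_factory=dict)
    jsb_type: str = ""  # I / II / III / unclassified
    jlb_context: str = ""  # within rpl22 / within rps19 / rpl22-rps19 IGS

    def overlap(self, junction: str, gene: str) -> int:
        """IR-side bp of ``gene`` at ``junction`` (0 if not spanning)."""
        for jg in self.genes.get(junction, []):
            if jg.gene == gene:
                if junction in ("JLB", "JSA"):  # IR lies to the right
                    return jg.right_bp
                return jg.left_bp
        return 0


def locate_junctions(record: GenomeRecord, min_remnant: int = 1) -> JunctionProfile:
    """Report, for each junction, the genes containing it and the side split.

    A gene counts at a junction when its span strictly contains the
    junction coordinate and at least ``min_remnant`` bp lie on each side
    (any annotated remnant counts by default).  JLA sits at the circular
    origin; genes split across the origin into two segments are handled
    through their segment spans.
    """
    part = record.partition
    if part is None:
        raise ValueError(f"{record.taxon}: no partition; run detect_quadripartite")
    n = len(record.sequence)
    coords = {
        "JLB": part.lsc[1],
        "JSB": part.irb[1],
        "JSA": part.ssc[1],
        "JLA": part.ira[1] % n,  # == 0 on the linearized circle
    }
    profile = JunctionProfile(taxon=record.taxon, coordinates=coords)
    gene_like = {
        (f.name, f.start, f.end): f
        for f in record.features_of_kind("gene", "tRNA", "rRNA")
    }
    for junction, pos in coords.items():
        hits: list[JunctionGene] = []
        for feat in gene_like.values():
            left = sum(
                min(e, pos) - s for s, e, _ in feat.segments if s < pos
            )
            right = feat.spliced_length() - left
            if junction == "JLA" and pos == 0:
                # origin junction: a spanning gene has segments at both ends
                touches_end = any(e == n for _, e, _ in feat.segments)
                touches_start = any(s == 0 for s, _, _ in feat.segments)
                if touches_end and touches_start:
                    left = sum(e - s for s, e, _ in feat.segments if e == n)
                    right = feat.spliced_length() - left
                else:
                    continue
            elif not (feat.start < pos < feat.end):
                continue
            if left >= min_remnant and right >= min_remnant:
                hits.append(JunctionGene(feat.name, left, right))
        profile.genes[junction] = sorted(hits, key=lambda h: h.gene)
    profile.jlb_context = _jlb_context(profile)
    return profile


def _jlb_context(profile: JunctionProfile) -> str:
    spanning = {jg.gene for jg in profile.genes.get("JLB", [])}
    if "rpl22" in spanning:
        return "within rpl22"
    if "rps19" in spanning:
        return "within rps19"
    return "rpl22-rps19 IGS"


def classify_jsb(profile: JunctionProfile, record: GenomeRecord) -> str:
    """Type I (ndhF wholly in SSC), II (ndhF spans JSB), III (ndhF absent).

    An ndhF lying wholly within the IR cannot be typed and is flagged
    "unclassified" (logged).
    """
    ndhf = [
        f
        for f in record.features_of_kind("gene", "CDS")
        if f.name == "ndhF"
    ]
    if not ndhf:
        profile.jsb_type = "III"
        return "III"
    if any(jg.gene == "ndhF" for jg in profile.genes.get("JSB", [])):
        profile.jsb_type = "II"
        return "II"
    part = record.partition
    ssc = part.ssc
    feat = ndhf[0]
    if ssc[0] <= feat.start and feat.end <= ssc[1]:
        profile.jsb_type = "I"
        return "I"
    ir_only = all(
        (part.irb[0] <= s and e <= part.irb[1]) or (part.ira[0] <= s and e <= part.ira[1])
        for s, e, _ in feat.segments
    )
    if ir_only:
        log.warning("%s: ndhF lies wholly within the IR; unclassified", record.taxon)
        profile.jsb_type = "unclassified"
        return "unclassified"
    profile.jsb_type = "I"
    return "I"


def cds_is_intact(feature: Feature, sequence: str) -> bool:
    """Complete reading frame: allowed start, length divisible by 3,
    terminal stop, no internal stop, and not flagged pseudo."""
    if feature.pseudo:
        return False
    cds = feature.extract(sequence)
    if len(cds) % 3 or len(cds) < 6:
        return False
    if cds[:3] not in START_CODONS:
        return False
    if cds[-3:] not in STOP_CODONS:
        return False
    for k in range(3, len(cds) - 3, 3):
        if cds[k : k + 3] in STOP_CODONS:
            return False
    return True


def ndh_gene_status(record: GenomeRecord, gene: str) -> str:
    """Status of one ndh gene: complete / pseudogene / lost.

    For genes duplicated in the IR (ndhB) the retained/first copy that
    passes the completeness rule wins.
    """
    cds_feats = [f for f in record.features if f.name == gene and f.kind == "CDS"]
    any_feats = [f for f in record.features if f.name == gene]
    if not any_feats:
        return "lost"
    for feat in cds_feats:
        if cds_is_intact(feat, record.sequence):
            return "complete"
    return "pseudogene"


@dataclass
class NdhStatusMatrix:
    """Taxon x ndh-gene status matrix with per-taxon summary counts."""

    table: pd.DataFrame  # rows: taxa; columns: the 11 ndh genes
    present_counts: pd.Series
    complete_counts: pd.Series


def ndh_status_matrix(records: list[GenomeRecord]) -> NdhStatusMatrix:
    """Score all 11 ndh genes across records (absent gene => lost)."""
    rows = {}
    for record in records:
        rows[record.taxon] = {g: ndh_gene_status(record, g) for g in NDH_GENES}
    table = pd.DataFrame.from_dict(rows, orient="index", columns=NDH_GENES)
    present = (table != "lost").sum(axis=1)
    complete = (table == "complete").sum(axis=1)
    return NdhStatusMatrix(table=table, present_counts=present, complete_counts=complete)


def junction_report(profiles: list[JunctionProfile]) -> pd.DataFrame:
    """Long-form junction table: one row per (taxon, junction, gene)."""
    rows = []
    for prof in profiles:
        for junction in JUNCTION_NAMES:
            genes = prof.genes.get(junction, [])
            if not genes:
                rows.append(
                    {
                        "taxon": prof.taxon,
                        "junction": junction,
                        "coordinate": prof.coordinates[junction],
                        "gene": "",
                        "left_bp": 0,
                        "right_bp": 0,
                        "jsb_type": prof.jsb_type,
                    }
                )
            for jg in genes:
                rows.append(
                    {
                        "taxon": prof.taxon,
                        "junction": junction,
                        "coordinate": prof.coordinates[junction],
                        "gene": jg.gene,
                        "left_bp": jg.left_bp,
                        "right_bp": jg.right_bp,
                        "jsb_type": prof.jsb_type,
                    }
                )
    return pd.DataFrame(rows)
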