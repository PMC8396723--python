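"""Reproduction checks against the published ten-plastome results.

These helpers recompute the study-level summary numbers from a set of
annotated plastome records: the total SSR count under the standard
minima, the shared-gene breakdown (CDS / tRNA / rRNA), the number of
genes screened as under positive selection, and the variable-character
count of a named region alignment.  Run on the ten deposited
Pleurothallidinae records (GenBank MH979332, KJ566305 and companions)
the published targets are 1,290 SSRs, 102 shared genes (68 CDS / 30
tRNA / 4 rRNA), 13 genes under positive selection, and 370 variable
characters in the 12-taxon ndhF-rpl32 alignment; all four are sensitive
to annotation parsing and aligner version, so they are reported as
reproduction checks with tolerances, not hard gates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import Alignment
from .io import drop_one_ir
from .records import GenomeRecord
from .selection import screen_genes
from .ssr import scan_ssrs
from .variability import count_site_stats


@dataclass
class ReproductionReport:
    total_ssrs: int
    shared_genes: int
    shared_cds: int
    shared_trna: int
    shared_rrna: int
    positive_selection_genes: int
    region_variable_characters: int | None
    region_name: str | None


def total_ssr_count(
    records: list[GenomeRecord],
    minima: dict[int, int] | None = None,
    one_ir: bool = True,
) -> int:
    """Total SSR loci across records (one IR removed by default; both
    modes are supported because the published counting basis is
    ambiguous)."""
    total = 0
    for rec in records:
        target = drop_one_ir(rec) if (one_ir and rec.partition is not None) else rec
        total += len(scan_ssrs(target.sequence, minima))
    return total


def shared_gene_breakdown(records: list[GenomeRecord]) -> dict[str, int]:
    """Genes annotated in every record, broken down by kind."""
    per_kind: dict[str, set[str] | None] = {"CDS": None, "tRNA": None, "rRNA": None}
    for rec in records:
        for kind in per_kind:
            names = {f.name for f in rec.features_of_kind(kind)}
            per_kind[kind] = names if per_kind[kind] is None else per_kind[kind] & names
    counts = {kind: len(names or ()) for kind, names in per_kind.items()}
    counts["total"] = sum(counts.values())
    return counts


def reproduce_published_checks(
    records: list[GenomeRecord],
    gene_alignments: dict[str, Alignment],
    region_alignment: Alignment | None = None,
    region_name: str | None = None,
    minima: dict[int, int] | None = None,
) -> ReproductionReport:
    """Recompute all four published summary quantities from data.

    ``gene_alignments`` are the shared-CDS alignments for the selection
    screen; ``region_alignment`` is the marker-region alignment whose
    variable-character count is reported (the published check uses
    ndhF-rpl32).
    """
    shared = shared_gene_breakdown(records)
    _, summary = screen_genes(gene_alignments)
    var_chars = None
    if region_alignment is not None:
        s, _m, _pic = count_site_stats(region_alignment)
        var_chars = s
    return ReproductionReport(
        total_ssrs=total_ssr_count(records, minima=minima),
        shared_genes=shared["total"],
        shared_cds=shared["CDS"],
        shared_trna=shared["tRNA"],
        shared_rrna=shared["rRNA"],
        positive_selection_genes=summary["positive"],
        region_variable_characters=var_chars,
        region_name=region_name,
    )
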