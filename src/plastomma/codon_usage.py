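"""Codon counting, relative frequency (RF), RSCU, and start codons.

RSCU (relative synonymous codon usage) is a codon's count divided by the
mean count over its synonymous family under the plastid/bacterial genetic
code (NCBI table 11 by default): values above 1 mark codons used more
often than expected under uniform synonymous usage.  RF is count over
total codons; stop codons are included in RF by default (configurable)
and always excluded from RSCU families.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

log = logging.getLogger(__name__)

CODONS = ["".join(c) for c in itertools.product("TCAG", repeat=3)]

PLASTID_START_CODONS = ("ATG", "GTG", "ACG", "CTG", "ATT")


def _code_tables(table_id: int) -> tuple[dict[str, str], list[str]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), list(table.stop_codons)


def synonymous_families(table_id: int = 11) -> dict[str, list[str]]:
    """Amino acid -> list of codons (stop codons under key '*')."""
    forward, stops = _code_tables(table_id)
    families: dict[str, list[str]] = {}
    for codon in CODONS:
        aa = "*" if codon in stops else forward[codon]
        families.setdefault(aa, []).append(codon)
    return families


@dataclass
class CodonUsageTable:
    """Per-taxon codon counts with RF and RSCU columns.

    ``table`` has one row per codon with columns
    (codon, aa, count_<taxon>, rf_<taxon>, rscu_<taxon>, ...);
    ``ambiguous`` counts codons skipped for containing N;
    ``unobserved_families`` lists (taxon, aa) families never observed,
    whose RSCU is reported as 0.
    """

    table: pd.DataFrame
    ambiguous: dict[str, int] = field(default_factory=dict)
    unobserved_families: list[tuple[str, str]] = field(default_factory=list)
    aa_totals: pd.DataFrame | None = None

    def rf(self, taxon: str) -> pd.Series:
        return self.table.set_index("codon")[f"rf_{taxon}"]

    def rscu(self, taxon: str) -> pd.Series:
        return self.table.set_index("codon")[f"rscu_{taxon}"]

    @property
    def taxa(self) -> list[str]:
        return [c[len("count_"):] for c in self.table.columns if c.startswith("count_")]


def count_codons(cds_set: dict[str, str]) -> tuple[dict[str, int], int]:
    """Codon counts over a CDS set; returns (counts, ambiguous count).

    CDSs whose length is not a multiple of 3 are excluded with a warning;
    codons containing N are skipped but tallied.
    """
    counts = {c: 0 for c in CODONS}
    ambiguous = 0
    for gene, seq in cds_set.items():
        seq = seq.upper()
        if len(seq) % 3:
            log.warning("CDS %s length %d not divisible by 3; excluded", gene, len(seq))
            continue
        for k in range(0, len(seq), 3):
            codon = seq[k : k + 3]
            if codon in counts:
                counts[codon] += 1
            else:
                ambiguous += 1
    return counts, ambiguous


def usage_table(
    cds_sets: dict[str, dict[str, str]],
    table_id: int = 11,
    rf_includes_stops: bool = True,
) -> CodonUsageTable:
    """Build the codon-usage table for one or more per-taxon CDS sets.

    ``cds_sets`` maps taxon -> {gene: spliced CDS sequence}.  RSCU of a
    codon is count / (mean count over its synonymous family); families
    never observed in a taxon get RSCU 0 and are flagged.
    """
    forward, stops = _code_tables(table_id)
    families = synonymous_families(table_id)
    aa_of = {c: ("*" if c in stops else forward[c]) for c in CODONS}
    data: dict[str, list] = {"codon": CODONS, "aa": [aa_of[c] for c in CODONS]}
    ambiguous: dict[str, int] = {}
    unobserved: list[tuple[str, str]] = []
    aa_rows = {}
    for taxon, cds_set in cds_sets.items():
        counts, n_amb = count_codons(cds_set)
        ambiguous[taxon] = n_amb
        total = sum(counts.values())
        rf_total = total if rf_includes_stops else total - sum(
            counts[c] for c in stops
        )
        rscu = {}
        for aa, members in families.items():
            if aa == "*":
                for c in members:
                    rscu[c] = float("nan")
                continue
            fam_total = sum(counts[c] for c in members)
            if fam_total == 0:
                unobserved.append((taxon, aa))
                for c in members:
                    rscu[c] = 0.0
            else:
                mean = fam_total / len(members)
                for c in members:
                    rscu[c] = counts[c] / mean
        data[f"count_{taxon}"] = [counts[c] for c in CODONS]
        data[f"rf_{taxon}"] = [
            (counts[c] / rf_total if rf_total else 0.0)
            if (rf_includes_stops or c not in stops)
            else 0.0
            for c in CODONS
        ]
        data[f"rscu_{taxon}"] = [rscu[c] for c in CODONS]
        aa_rows[taxon] = {
            aa: sum(counts[c] for c in members) for aa, members in families.items()
        }
    table = pd.DataFrame(data)
    aa_totals = pd.DataFrame(aa_rows)
    return CodonUsageTable(
        table=table,
        ambiguous=ambiguous,
        unobserved_families=unobserved,
        aa_totals=aa_totals,
    )


def start_codon_inventory(cds_set: dict[str, str]) -> pd.DataFrame:
    """First codon of each (strand-corrected) CDS, with a canonical flag."""
    rows = []
    for gene in sorted(cds_set):
        start = cds_set[gene][:3].upper()
        rows.append(
            {
                "gene": gene,
                "start_codon": start,
                "canonical": start == "ATG",
                "allowed_alternative": start in PLASTID_START_CODONS,
            }
        )
    return pd.DataFrame(rows)


def at3_gc3_summary(cds_set: dict[str, str]) -> dict[str, float]:
    """Fraction of third codon positions ending in A/T vs G/C."""
    at3 = gc3 = 0
    for seq in cds_set.values():
        seq = seq.upper()
        for k in range(2, len(seq) - len(seq) % 3, 3):
            if seq[k] in "AT":
                at3 += 1
            elif seq[k] in "GC":
                gc3 += 1
    total = at3 + gc3
    return {
        "at3": at3 / total if total else 0.0,
        "gc3": gc3 / total if total else 0.0,
    }
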