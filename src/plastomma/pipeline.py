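"""End-to-end orchestration: records in, report tables out.

Stages run in order: structure (partition + one-IR removal) ->
junctions/ndh -> region alignments -> variability & hotspots -> SSRs &
polymorphic loci -> codon usage -> selection screen -> genome metrics &
correlations.  Every stage is a pure function of (inputs, config), and a
run manifest (config, stage list, output checksums) makes reruns
verifiable.

Alignments are consumed, not computed: supply them either precomputed
(a synthetic family's truth provides exact ones) or through an external
aligner shell hook (e.g. ``mafft --auto {input} > {output}``).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import subprocess
import tempfile
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .align import Alignment
from .codon_usage import start_codon_inventory, usage_table
from .io import drop_one_ir, read_genbank, write_fasta
from .junctions import (
    classify_jsb,
    junction_report,
    locate_junctions,
    ndh_status_matrix,
)
from .metrics import build_metric_table, correlation_suite
from .records import GenomeRecord
from .selection import screen_genes
from .ssr import (
    HOTSPOT_PROFILE,
    SSR_PROFILE,
    contextualize,
    design_primers,
    polymorphic_loci,
    scan_ssrs,
)
from .variability import (
    analyze_region,
    indel_events_by_partition,
    rank_hotspots,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study's stated values."""

    output_dir: str = "plastomma_out"
    min_region_len: int = 150
    min_ir_len: int = 10_000
    ssr_minima: dict[int, int] | None = None
    min_presence: int = 7
    hotspot_k: int = 10
    aligner_hook: str | None = None  # e.g. "mafft --auto {input} > {output}"
    reference: str | None = None  # reference taxon for pairwise indels
    design_hotspot_primers: bool = True
    design_ssr_primers: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_region_len", "min_ir_len", "min_presence", "hotspot_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ReportBundle:
    """All pipeline outputs as data frames, plus the manifest."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    hotspots: list = field(default_factory=list)

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        checksums = {}
        for name, frame in sorted(self.tables.items()):
            path = os.path.join(outdir, f"{name}.tsv")
            frame.to_csv(path, sep="\t", index=False)
            checksums[f"{name}.tsv"] = _sha256(path)
        self.manifest["checksums"] = checksums
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def align_with_hook(sequences: dict[str, str], hook: str) -> Alignment:
    """Run an external aligner via a shell command template.

    The template must contain ``{input}`` and ``{output}`` placeholders
    for FASTA paths.
    """
    with tempfile.TemporaryDirectory() as tmp:
        inp = os.path.join(tmp, "in.fasta")
        out = os.path.join(tmp, "out.fasta")
        write_fasta(sequences, inp)
        cmd = hook.format(input=inp, output=out)
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0 or not os.path.exists(out):
            raise RuntimeError(f"aligner hook failed: {cmd}\n{proc.stderr[-500:]}")
        return Alignment.from_fasta(out)


def pairwise_from_msa(msa: Alignment, taxon_a: str, taxon_b: str) -> Alignment:
    """Project two rows out of an MSA, dropping shared-gap columns."""
    row_a, row_b = msa.row(taxon_a), msa.row(taxon_b)
    kept = [
        (a, b) for a, b in zip(row_a, row_b) if not (a == "-" and b == "-")
    ]
    return Alignment(
        taxa=[taxon_a, taxon_b],
        rows=["".join(a for a, _ in kept), "".join(b for _, b in kept)],
    )


def load_records(paths: list[str], min_ir_len: int = 10_000) -> list[GenomeRecord]:
    """Read GenBank records and ensure each has a quadripartite partition."""
    from .io import detect_quadripartite

    records = []
    for path in paths:
        rec = read_genbank(path)
        if rec.partition is None:
            detect_quadripartite(rec, min_ir_len=min_ir_len)
        records.append(rec)
    return records


def run_all(
    records: list[GenomeRecord],
    config: RunConfig | None = None,
    region_alignments: dict[str, tuple[str, str, Alignment]] | None = None,
    genome_alignment: Alignment | None = None,
) -> ReportBundle:
    """Execute the full analysis over partitioned records.

    ``region_alignments`` maps region name -> (category, location,
    Alignment); ``genome_alignment`` is the one-IR-removed whole-genome
    MSA (used for polymorphic SSR loci and per-region indel counts).
    When either is missing and an aligner hook is configured, alignments
    are computed through the hook; otherwise the dependent stages abort.
    """
    config = config or RunConfig()
    config.validate()
    bundle = ReportBundle()
    stages: list[str] = []

    def fail(stage: str, msg: str):
        raise RuntimeError(f"pipeline stage '{stage}' failed: {msg}")

    # -- structure -------------------------------------------------------
    for rec in records:
        if rec.partition is None:
            fail("structure", f"{rec.taxon} has no partition")
    dropped = {rec.taxon: drop_one_ir(rec) for rec in records}
    stages.append("structure")

    # -- junctions and ndh status ---------------------------------------
    profiles = []
    for rec in records:
        prof = locate_junctions(rec)
        classify_jsb(prof, rec)
        profiles.append(prof)
    bundle.tables["junctions"] = junction_report(profiles)
    ndh = ndh_status_matrix(records)
    ndh_table = ndh.table.copy()
    ndh_table.insert(0, "taxon", ndh_table.index)
    ndh_table["ndh_present"] = ndh.present_counts.values
    ndh_table["ndh_complete"] = ndh.complete_counts.values
    bundle.tables["ndh_status"] = ndh_table.reset_index(drop=True)
    stages.append("junctions")

    # -- alignments ------------------------------------------------------
    if region_alignments is None:
        if config.aligner_hook is None:
            fail("alignments", "no region alignments and no aligner hook")
        region_alignments = _align_regions(dropped, config)
    if genome_alignment is None and config.aligner_hook is not None:
        genome_alignment = align_with_hook(
            {t: d.sequence for t, d in dropped.items()}, config.aligner_hook
        )
    stages.append("alignments")

    # -- variability and hotspots ---------------------------------------
    results = []
    for name, (category, location, aln) in sorted(region_alignments.items()):
        if category in ("IGS", "intron") and aln.n_cols < config.min_region_len:
            continue
        results.append(analyze_region(name, aln, location=location, category=category))
    noncoding = [r for r in results if r.category in ("IGS", "intron")]
    ranked = rank_hotspots(noncoding or results, k=None)
    bundle.hotspots = ranked[: config.hotspot_k]
    bundle.tables["variability"] = pd.DataFrame(
        {
            "region": r.name,
            "location": r.location,
            "category": r.category,
            "length_bp": r.length,
            "gc": round(r.gc, 4),
            "mutations": r.mutations,
            "segregating_sites": r.segregating,
            "indel_events": r.indel_events,
            "pic": r.pic,
            "sv_percent": round(r.sv, 2),
        }
        for r in ranked
    )
    stages.append("variability")

    # -- SSRs ------------------------------------------------------------
    per_taxon_loci = {}
    ssr_rows = []
    for taxon, drec in dropped.items():
        loci = contextualize(scan_ssrs(drec.sequence, config.ssr_minima), drec)
        per_taxon_loci[taxon] = loci
        for idx, locus in enumerate(loci, 1):
            ssr_rows.append(
                {
                    "taxon": taxon,
                    "ssr_nr": idx,
                    "type": f"p{locus.unit}",
                    "ssr": f"({locus.motif}){locus.reps}",
                    "size_bp": locus.end - locus.start,
                    "start": locus.start,
                    "end": locus.end,
                    "region": locus.region,
                    "context": locus.context,
                }
            )
    bundle.tables["ssr_loci"] = pd.DataFrame(ssr_rows)
    if genome_alignment is not None:
        cross = polymorphic_loci(
            per_taxon_loci, genome_alignment, min_presence=config.min_presence
        )
        poly = [c for c in cross if c.polymorphic]
        bundle.tables["ssr_polymorphic"] = pd.DataFrame(
            {
                "motif": c.motif,
                "aligned_start": c.aligned_start,
                "aligned_end": c.aligned_end,
                "presence": c.presence,
                "polymorphic": c.polymorphic,
                "reps": "/".join(
                    str(c.reps[t]) for t in sorted(c.reps)
                ),
            }
            for c in cross
        )
        if config.design_ssr_primers:
            bundle.tables["ssr_primers"] = _primers_for_loci(
                poly, per_taxon_loci, dropped
            )
    stages.append("ssr")

    # -- codon usage -----------------------------------------------------
    cds_sets = {}
    for taxon, drec in dropped.items():
        cds_sets[taxon] = {
            f.name: f.extract(drec.sequence)
            for f in drec.features_of_kind("CDS")
            if f.spliced_length() % 3 == 0
        }
    usage = usage_table(cds_sets)
    bundle.tables["codon_usage"] = usage.table
    starts = []
    for taxon, cds_set in cds_sets.items():
        inv = start_codon_inventory(cds_set)
        inv.insert(0, "taxon", taxon)
        starts.append(inv)
    bundle.tables["start_codons"] = pd.concat(starts, ignore_index=True)
    stages.append("codon")

    # -- selection -------------------------------------------------------
    shared = None
    for taxon, cds_set in cds_sets.items():
        names = set(cds_set)
        shared = names if shared is None else shared & names
    gene_alns = {
        name: aln
        for name, (cat, _loc, aln) in region_alignments.items()
        if cat == "CDS" and name in (shared or set())
    }
    tajima_results, tajima_summary = screen_genes(gene_alns)
    bundle.tables["tajima"] = pd.DataFrame(
        {
            "gene": r.gene,
            "n": r.n,
            "S": r.S,
            "pi": round(r.pi, 4),
            "D": round(r.D, 4) if r.D == r.D else "",
            "p_beta": round(r.p_beta, 4) if r.p_beta == r.p_beta else "",
            "class": r.selection_class,
        }
        for r in tajima_results
    )
    stages.append("selection")

    # -- metrics and correlations ---------------------------------------
    indel_frame = None
    if genome_alignment is not None:
        reference = config.reference or records[0].taxon
        ref_regions = dropped[reference].annotations["regions"]
        rows = {}
        for taxon in dropped:
            if taxon == reference:
                continue
            pair = pairwise_from_msa(genome_alignment, reference, taxon)
            counts = indel_events_by_partition(pair, reference, ref_regions)
            rows[taxon] = {
                "lsc_indels": counts.get("LSC", 0),
                "ssc_indels": counts.get("SSC", 0),
                "ir_indels": counts.get("IR", 0),
            }
        indel_frame = pd.DataFrame.from_dict(rows, orient="index")
        indel_frame.index.name = "taxon"
        out = indel_frame.reset_index()
        out["total"] = out[["lsc_indels", "ssc_indels", "ir_indels"]].sum(axis=1)
        bundle.tables["indels_by_region"] = out
    ndh_counts = ndh_table.set_index("taxon")[["ndh_present", "ndh_complete"]]
    metric = build_metric_table(
        records, ndh_counts=ndh_counts, region_indels=indel_frame
    )
    bundle.tables["metric_table"] = metric.table
    correlations, ranges = correlation_suite(metric)
    bundle.tables["correlations"] = correlations
    ranges_frame = ranges.rename("range_bp").reset_index()
    ranges_frame.columns = ["column", "range_bp"]
    bundle.tables["ranges"] = ranges_frame
    stages.append("metrics")

    # -- hotspot primers -------------------------------------------------
    if config.design_hotspot_primers and bundle.hotspots:
        bundle.tables["hotspot_primers"] = _primers_for_hotspots(
            bundle.hotspots, dropped, config
        )

    bundle.manifest = {
        "version": __version__,
        "stages": stages,
        "n_records": len(records),
        "taxa": [r.taxon for r in records],
        "config": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
    }
    return bundle


def _align_regions(
    dropped: dict[str, GenomeRecord], config: RunConfig
) -> dict[str, tuple[str, str, Alignment]]:
    """Extract analysis regions per taxon and align each through the hook."""
    from .io import collect_regions, extract_regions

    per_taxon = {t: extract_regions(d) for t, d in dropped.items()}
    out = {}
    for region in collect_regions(per_taxon):
        if len(region.sequences) < 2:
            continue
        aln = align_with_hook(region.sequences, config.aligner_hook)
        out[region.name] = (region.category, region.location, aln)
    return out


def _primers_for_loci(cross_loci, per_taxon_loci, dropped) -> pd.DataFrame:
    """Primer pairs for polymorphic SSR loci on a carrier taxon's genome."""
    rows = []
    for cross in cross_loci:
        carrier = sorted(cross.reps)[0]
        target = None
        for locus in per_taxon_loci[carrier]:
            from .ssr import canonical_rotation

            if canonical_rotation(locus.motif) == cross.motif:
                target = locus
                break
        if target is None:
            continue
        passing = design_primers(
            dropped[carrier].sequence,
            target.start,
            target.end,
            constraints=SSR_PROFILE,
            target=f"({cross.motif})",
            max_candidates=400,
        )
        if passing:
            best = passing[0]
            rows.append(
                {
                    "locus": f"({cross.motif}) at {cross.aligned_start}",
                    "forward": best.forward,
                    "reverse": best.reverse,
                    "product_bp": best.product_size,
                }
            )
    return pd.DataFrame(rows)


def _primers_for_hotspots(hotspots, dropped, config) -> pd.DataFrame:
    """Primer pairs flanking each top-ranked hotspot on a reference taxon."""
    from .io import extract_regions

    reference = config.reference or next(iter(dropped))
    regions = {r.name: r for r in extract_regions(dropped[reference])}
    rows = []
    for hs in hotspots:
        reg = regions.get(hs.name)
        if reg is None:
            continue
        passing = design_primers(
            dropped[reference].sequence,
            reg.start,
            reg.end,
            constraints=HOTSPOT_PROFILE,
            target=hs.name,
            max_candidates=400,
        )
        if passing:
            best = passing[0]
            rows.append(
                {
                    "hotspot": hs.name,
                    "sv_percent": round(hs.sv, 2),
                    "forward": best.forward,
                    "reverse": best.reverse,
                    "product_bp": best.product_size,
                }
            )
    return pd.DataFrame(rows)
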