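"""End-to-end orchestration: from alignments to the summary report.

`run_diagnose` chains the stages — fixed-difference detection per nuclear
locus and on the concatenated chloroplast system, additivity scoring of the
candidates, haplotype phasing and inventories, multilocus classification,
maternal assignment, clonality, and haplotype-network export — and writes
TSV/JSON reports under one output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .alignments import (
    CHLOROPLAST,
    NUCLEAR,
    AlignmentError,
    LocusAlignment,
    TaxonMap,
    concatenate_loci,
    load_dataset,
)
from .classify import (
    HybridCall,
    assess_clonality,
    assign_maternal,
    calls_to_frame,
    classify_sample,
    multilocus_genotype,
)
from .diagnostics import (
    additivity_to_frame,
    find_fixed_indels,
    find_fixed_substitutions,
    indels_to_frame,
    score_additivity,
    sites_to_frame,
    summarize_fixed_differences,
)
from .haplotypes import HaplotypeInventory, build_inventory, shared_haplotypes
from .network import (
    IndelEvent,
    annotate_network,
    build_mj_network,
    export_network,
    node_table,
    recode_matrix,
)

log = logging.getLogger("hybdiag")


@dataclass
class RunConfig:
    """Paths, parent labels and thresholds for one pipeline run."""

    locus_metadata: str | Path | None = None
    taxon_map: str | Path | None = None
    out_dir: str | Path = "hybdiag_out"
    parent_a: str | None = None  # taxon labels; default: roles in the taxon map
    parent_b: str | None = None
    min_per_taxon: int = 2
    missing_tolerance: float = 0.0
    phasing_cap: int = 16
    epsilon: int = 0
    other_tolerance: float = 0.0
    reference_2c: float | None = None
    reference_ploidy: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.parent_a is not None and self.parent_a == self.parent_b):
            raise AlignmentError("parentA and parentB taxa must differ")


@dataclass
class DiagnoseResult:
    sites: dict[str, list] = field(default_factory=dict)
    indels: dict[str, list] = field(default_factory=dict)
    reports: dict[str, dict] = field(default_factory=dict)  # sample -> locus -> report
    inventory: HaplotypeInventory | None = None
    calls: list[HybridCall] = field(default_factory=list)
    clone_summary = None
    summary: dict = field(default_factory=dict)
    cp_concat: LocusAlignment | None = None


def diagnose(alignments: list[LocusAlignment], taxa: TaxonMap,
             config: RunConfig | None = None,
             out_dir: str | Path | None = None) -> DiagnoseResult:
    """Run the full diagnostic pipeline on in-memory data.

    When ``out_dir`` is given all report files are written there.
    """
    cfg = config or RunConfig()
    taxa.validate_against(alignments)
    res = DiagnoseResult()
    nuclear = [a for a in alignments if a.compartment == NUCLEAR]
    cp = [a for a in alignments if a.compartment == CHLOROPLAST]
    if not nuclear:
        raise AlignmentError("pipeline needs at least one nuclear locus")

    units: list[LocusAlignment] = list(nuclear)
    if cp:
        res.cp_concat = concatenate_loci(cp, CHLOROPLAST)
        units.append(res.cp_concat)

    compartments = {}
    for aln in units:
        sites = find_fixed_substitutions(aln, taxa, cfg.min_per_taxon,
                                         cfg.missing_tolerance)
        indels = find_fixed_indels(aln, taxa, cfg.min_per_taxon)
        res.sites[aln.locus_id] = sites
        res.indels[aln.locus_id] = indels
        compartments[aln.locus_id] = aln.compartment
        log.info("locus %s: %d fixed substitutions, %d fixed indel events",
                 aln.locus_id, len(sites), len(indels))
    summary_df = summarize_fixed_differences(
        {k: (res.sites[k], res.indels[k]) for k in res.sites}, compartments)

    by_locus = {a.locus_id: a for a in units}
    candidates = taxa.samples_with_role("candidate")
    others = taxa.samples_with_role("other")
    for sample in candidates + others:
        res.reports[sample] = {}
        for aln in units:
            res.reports[sample][aln.locus_id] = score_additivity(
                res.sites[aln.locus_id], res.indels[aln.locus_id],
                by_locus, sample, taxa)

    inv_alignments = nuclear + ([res.cp_concat] if cp else [])
    indels_by_locus = {k: v for k, v in res.indels.items()}
    res.inventory = build_inventory(inv_alignments, taxa, max_het=cfg.phasing_cap,
                                    indels_by_locus=indels_by_locus)

    parent_a_taxon = cfg.parent_a or _role_taxon(taxa, "parentA")
    parent_b_taxon = cfg.parent_b or _role_taxon(taxa, "parentB")
    nuclear_ids = [a.locus_id for a in nuclear]
    cp_id = res.cp_concat.locus_id if cp else None
    for sample in candidates:
        call = classify_sample(sample,
                               {l: res.reports[sample][l] for l in nuclear_ids},
                               cfg.other_tolerance)
        if cp_id is not None:
            cp_hap = res.inventory.sample_haplotypes(sample, cp_id)[0]
            assign_maternal(call, cp_hap, res.inventory, cp_id,
                            parent_a_taxon, parent_b_taxon)
        res.calls.append(call)
    if len(res.calls) >= 2:
        genotypes = {}
        for c in res.calls:
            try:
                genotypes[c.sample_id] = multilocus_genotype(
                    res.inventory, c.sample_id, nuclear_ids, cp_id)
            except AlignmentError:
                # unphaseable somewhere: fall back to the raw consensus rows,
                # which are still byte-comparable between samples
                log.warning("sample %s not fully phased; clone grouping uses "
                            "raw consensus rows", c.sample_id)
                genotypes[c.sample_id] = ("unphased",) + tuple(
                    by_locus[l].row(c.sample_id) for l in by_locus)
        _, res.clone_summary = assess_clonality(res.calls, genotypes)

    shared = shared_haplotypes(res.inventory, parent_a_taxon, parent_b_taxon)
    nuclear_subs = sum(len(res.sites[l]) for l in nuclear_ids)
    cp_subs = len(res.sites[cp_id]) if cp_id else 0
    res.summary = {
        "version": __version__,
        "parentA": parent_a_taxon,
        "parentB": parent_b_taxon,
        "nuclear_fixed_subs": nuclear_subs,
        "cp_fixed_subs": cp_subs,
        "total_fixed_subs": nuclear_subs + cp_subs,
        "indel_events": sum(len(v) for v in res.indels.values()),
        "n_candidates": len(candidates),
        "classes": {c.sample_id: c.hybrid_class for c in res.calls},
        "maternal": {c.sample_id: c.maternal for c in res.calls},
        "n_clone_groups": (int(res.clone_summary["clone_group"].max())
                           if res.clone_summary is not None else 0),
        "shared_parental_haplotypes": {k: sorted(v) for k, v in shared.items()
                                       if v},
    }

    if out_dir is not None:
        _write_reports(res, units, taxa, Path(out_dir), cfg, summary_df)
    return res


def _role_taxon(taxa: TaxonMap, role: str) -> str:
    taxa_of_role = {taxa.taxon(s) for s in taxa.samples_with_role(role)}
    if len(taxa_of_role) != 1:
        raise AlignmentError(
            f"role {role!r} maps to {len(taxa_of_role)} taxa; pass an explicit label")
    return taxa_of_role.pop()


def _write_reports(res: DiagnoseResult, units, taxa, out: Path, cfg: RunConfig,
                   summary_df) -> None:
    out.mkdir(parents=True, exist_ok=True)
    all_sites = [s for sites in res.sites.values() for s in sites]
    all_indels = [e for evs in res.indels.values() for e in evs]
    sites_to_frame(all_sites).to_csv(out / "diagnostic_sites.tsv", sep="\t", index=False)
    indels_to_frame(all_indels).to_csv(out / "diagnostic_indels.tsv", sep="\t", index=False)
    summary_df.to_csv(out / "fixed_difference_summary.tsv", sep="\t", index=False)
    flat = [rep for per_locus in res.reports.values() for rep in per_locus.values()]
    merged = {}
    for sample, per_locus in res.reports.items():
        from .diagnostics import AdditivityReport
        m = AdditivityReport(sample)
        for rep in per_locus.values():
            m.site_verdicts.update(rep.site_verdicts)
            m.indel_verdicts.update(rep.indel_verdicts)
        merged[sample] = m
    additivity_to_frame(list(merged.values())).to_csv(
        out / "additivity.tsv", sep="\t", index=False)
    if res.inventory is not None:
        res.inventory.to_frame().to_csv(out / "haplotypes.tsv", sep="\t", index=False)
    if res.calls:
        calls_to_frame(res.calls).to_csv(out / "calls.tsv", sep="\t", index=False)
    if res.clone_summary is not None:
        res.clone_summary.to_csv(out / "clone_groups.tsv", sep="\t", index=False)
    for aln in units:
        net = locus_network(res, aln.locus_id, taxa, cfg.epsilon)
        if net is None:
            continue
        export_network(net, out / f"network_{aln.locus_id}.tsv", "tsv")
        export_network(net, out / f"network_{aln.locus_id}.dot", "dot")
        node_table(net).to_csv(out / f"network_{aln.locus_id}_nodes.tsv",
                               sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps(res.summary, indent=2) + "\n")


def locus_network(res: DiagnoseResult, locus_id: str, taxa: TaxonMap,
                  epsilon: int = 0):
    """Median-joining network over the distinct haplotypes of one locus."""
    if res.inventory is None:
        return None
    seqs: dict[str, str] = {}
    counts: dict[str, int] = {}
    taxa_comp: dict[str, dict[str, int]] = {}
    for (taxon, lid), haps in res.inventory.inventory.items():
        if lid != locus_id:
            continue
        for hap, count in haps:
            name = None
            for existing, seq in seqs.items():
                if seq == hap.sequence:
                    name = existing
            if name is None:
                name = f"{taxon}:{hap.label}"
                seqs[name] = hap.sequence
            counts[name] = counts.get(name, 0) + count
            taxa_comp.setdefault(name, {})
            taxa_comp[name][taxon] = taxa_comp[name].get(taxon, 0) + count
    if not seqs:
        return None
    # one mutational step per shared gap run, inferred from the haplotypes
    # themselves so private indels of non-parental taxa also count once
    from .network import infer_indel_events

    events = infer_indel_events(seqs, locus_id)
    matrix = recode_matrix(seqs, events)
    net = build_mj_network(matrix, epsilon=epsilon)
    annotate_network(net, counts, taxa_comp)
    return net


def run_diagnose(cfg: RunConfig) -> DiagnoseResult:
    """File-based entry point: load, diagnose, write reports."""
    if cfg.locus_metadata is None or cfg.taxon_map is None:
        raise AlignmentError("locus metadata and taxon map paths are required")
    for p in (cfg.locus_metadata, cfg.taxon_map):
        if not Path(p).exists():
            raise AlignmentError(f"input file not found: {p}")
    alignments, taxa = load_dataset(cfg.locus_metadata, cfg.taxon_map)
    return diagnose(alignments, taxa, cfg, out_dir=cfg.out_dir)
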