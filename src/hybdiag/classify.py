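"""Multilocus hybrid verdicts: class, maternal parent, and clone groups.

Per nuclear locus a candidate's genotype is classed AB (both parental allele
sets present), AA or BB (one parent only) or other.  The multilocus rule then
mirrors qualitative diagnostic-site reading of direct-sequencing data:

* all evaluable loci AB            -> F1
* AB mixed with AA only            -> backcross toward parent A
* AB mixed with BB only            -> backcross toward parent B
* all AA / all BB                  -> parental
* anything else                    -> complex

Dosage is deliberately not inferred: a consensus chromatogram cannot separate
AABB from ABBB in a tetraploid, so classes rest on allele presence/absence
alone, and generations beyond the first backcross are not distinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .alignments import AlignmentError
from .diagnostics import (
    ADDITIVE,
    HETEROZYGOUS,
    OTHER,
    PARENT_A_LIKE,
    PARENT_B_LIKE,
    AdditivityReport,
)
from .haplotypes import HaplotypeInventory

CLASSES = ("parentA", "parentB", "F1", "backcross_A", "backcross_B",
           "complex", "ambiguous")


@dataclass
class HybridCall:
    sample_id: str
    hybrid_class: str
    maternal: str = "unassigned"  # parentA | parentB | unassigned
    maternal_note: str = ""
    clone_group: int = 0
    evidence: dict[str, str] = field(default_factory=dict)  # locus -> AB/AA/BB/other


def locus_genotype_class(report: AdditivityReport, locus_id: str) -> str | None:
    """AB/AA/BB/other for one locus, or None when no diagnostic evidence.

    Indel verdicts count like site verdicts, with heterozygous treated as
    both-present.  Mixtures of additive and parental-like evidence within a
    locus are contradictory under a no-recombination reading and class as
    ``other``.
    """
    verdicts = [v for (loc, _), v in report.site_verdicts.items() if loc == locus_id]
    verdicts += [v for (loc, _, _), v in report.indel_verdicts.items() if loc == locus_id]
    if not verdicts:
        return None
    n_add = sum(1 for v in verdicts if v in (ADDITIVE, HETEROZYGOUS))
    n_a = sum(1 for v in verdicts if v == PARENT_A_LIKE)
    n_b = sum(1 for v in verdicts if v == PARENT_B_LIKE)
    n_other = sum(1 for v in verdicts if v == OTHER)
    if n_other:
        return OTHER
    if n_add and not n_a and not n_b:
        return "AB"
    if n_a and not n_add and not n_b:
        return "AA"
    if n_b and not n_add and not n_a:
        return "BB"
    return OTHER


def classify_sample(sample_id: str,
                    reports_by_locus: dict[str, AdditivityReport],
                    other_tolerance: float = 0.0) -> HybridCall:
    """Combine per-locus genotype classes into a multilocus verdict.

    ``reports_by_locus`` maps nuclear locus_id -> the candidate's additivity
    report restricted to that locus.  Loci without diagnostic evidence are
    dropped.  A fraction of ``other`` loci above ``other_tolerance`` yields
    ``ambiguous``.  Backcross calls need at least one AB and one homozygous-
    parental locus, so a single-locus dataset can never support one.
    """
    evidence: dict[str, str] = {}
    for locus_id, report in reports_by_locus.items():
        cls = locus_genotype_class(report, locus_id)
        if cls is not None:
            evidence[locus_id] = cls
    if not evidence:
        raise AlignmentError(
            f"sample {sample_id!r}: no evaluable nuclear locus with diagnostic sites")
    classes = list(evidence.values())
    n = len(classes)
    n_other = classes.count(OTHER)
    if n_other > other_tolerance * n:
        call_class = "ambiguous"
    else:
        informative = [c for c in classes if c != OTHER]
        n_ab = informative.count("AB")
        n_aa = informative.count("AA")
        n_bb = informative.count("BB")
        if n_ab == len(informative):
            call_class = "F1"
        elif n_aa == len(informative):
            call_class = "parentA"
        elif n_bb == len(informative):
            call_class = "parentB"
        elif n_ab and n_aa and not n_bb:
            call_class = "backcross_A"
        elif n_ab and n_bb and not n_aa:
            call_class = "backcross_B"
        else:
            call_class = "complex"
    return HybridCall(sample_id, call_class, evidence=evidence)


def assign_maternal(call: HybridCall, sample_cp: str,
                    inv: HaplotypeInventory, cp_locus: str,
                    parent_a_taxon: str, parent_b_taxon: str) -> HybridCall:
    """Assign the maternal parent by exact chloroplast haplotype match.

    Matching a haplotype carried by a single parental individual still
    assigns, with a rare-variant note; matching both parents (shared cp
    haplotype) is uninformative.
    """
    a_haps = {h.sequence: c for h, c in inv.haplotypes(parent_a_taxon, cp_locus)}
    b_haps = {h.sequence: c for h, c in inv.haplotypes(parent_b_taxon, cp_locus)}
    in_a, in_b = sample_cp in a_haps, sample_cp in b_haps
    if in_a and in_b:
        call.maternal = "unassigned"
        call.maternal_note = "uninformative: chloroplast haplotype shared by both parents"
    elif in_a or in_b:
        call.maternal = "parentA" if in_a else "parentB"
        carriers = a_haps[sample_cp] if in_a else b_haps[sample_cp]
        if carriers == 1:
            call.maternal_note = ("matches a rare parental chloroplast haplotype "
                                  "carried by a single individual")
    else:
        call.maternal = "unassigned"
        call.maternal_note = "novel chloroplast haplotype: matches neither parent"
    return call


def multilocus_genotype(inv: HaplotypeInventory, sample: str,
                        nuclear_loci: list[str], cp_locus: str | None) -> tuple:
    """Canonical full genotype: sorted haplotype pair per nuclear locus + cp."""
    parts = []
    for locus_id in nuclear_loci:
        haps = inv.sample_haplotypes(sample, locus_id)
        parts.append((locus_id, tuple(sorted(haps))))
    if cp_locus is not None:
        parts.append((cp_locus, inv.sample_haplotypes(sample, cp_locus)))
    return tuple(parts)


def assess_clonality(calls: list[HybridCall], genotypes: dict[str, tuple],
                     ) -> tuple[list[HybridCall], pd.DataFrame]:
    """Partition candidates into groups of identical multilocus genotypes.

    Clone-group ids are assigned 1..k in order of first appearance.  A single
    group covering every candidate is reported as consistent with one clonal
    (apomictic) lineage — identity of genotypes cannot by itself prove a
    single origin, so the wording stays "consistent with".
    """
    if len(calls) < 2:
        raise AlignmentError("clonality assessment needs at least two candidates")
    group_of: dict[tuple, int] = {}
    for call in calls:
        g = genotypes[call.sample_id]
        if g not in group_of:
            group_of[g] = len(group_of) + 1
        call.clone_group = group_of[g]
    sizes: dict[int, int] = {}
    for call in calls:
        sizes[call.clone_group] = sizes.get(call.clone_group, 0) + 1
    summary = pd.DataFrame(
        [{"clone_group": g, "n_samples": n,
          "single_clonal_lineage": len(sizes) == 1} for g, n in sorted(sizes.items())],
        columns=["clone_group", "n_samples", "single_clonal_lineage"])
    return calls, summary


def calls_to_frame(calls: list[HybridCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": c.sample_id, "class": c.hybrid_class, "maternal": c.maternal,
          "maternal_note": c.maternal_note, "clone_group": c.clone_group,
          "evidence": ";".join(f"{k}={v}" for k, v in sorted(c.evidence.items()))}
         for c in calls],
        columns=["sample_id", "class", "maternal", "maternal_note",
                 "clone_group", "evidence"])
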