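"""Synthetic dataset generator emulating a two-parent hybrid-zone study.

The generator produces the statistical structure the diagnostic pipeline
assumes: two parental taxa separated by configurable numbers of fixed
substitutions and fixed indels per locus, shallow within-taxon haplotype
diversity (variants one substitution from the taxon core haplotype), F1
hybrids whose consensus rows are column-wise IUPAC collapses of one haplotype
from each parent, apomictic clones (byte-identical genotypes), optional
first-generation backcrosses, maternally copied chloroplast haplotypes, and
two-peak flow-cytometry event streams.  Everything is driven by one seed:
identical configs give byte-identical outputs.

Parental individuals are emitted homozygous at nuclear loci.  The taxa being
emulated are predominantly selfing or apomictic shrubs with very low
within-population diversity, and homozygous parents make per-locus haplotype
counts exactly recoverable, which is what the truth table asserts.

Backcross gametes are drawn conditioned on yielding at least one heterozygous
and one homozygous-parental locus, i.e. on being *diagnosable* as
first-generation backcrosses; an unconditioned draw can by chance look purely
parental, which no presence/absence method could ever recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignments import (
    CHLOROPLAST,
    GAP,
    NUCLEAR,
    AlignmentError,
    HetIndel,
    LocusAlignment,
    TaxonMap,
    collapse_bases,
    write_locus_fasta,
    write_taxon_map,
)
from .ploidy import FlowEvents


@dataclass
class LocusSpec:
    locus_id: str
    compartment: str
    length: int
    n_substitutions: int
    indel_lengths: tuple[int, ...] = ()
    #: optional explicit 1-based diagnostic positions (drawn when None)
    substitution_positions: tuple[int, ...] | None = None
    #: optional explicit within-taxon variant positions per taxon
    variant_positions: dict[str, tuple[int, ...]] | None = None


@dataclass
class FlowSpec:
    """Per-taxon flow-cytometry simulation: 2C (pg), CV, events per run."""

    taxon_2c: dict[str, float]
    cv: float = 0.03
    n_events: int = 10_000
    standard_2c: float = 2.5
    gain: float = 100.0  # channel units per pg


@dataclass
class SimulationConfig:
    seed: int
    loci: list[LocusSpec]
    #: taxon -> number of sampled individuals (parental populations)
    sample_sizes: dict[str, int]
    parent_a: str = "taxonA"
    parent_b: str = "taxonB"
    #: taxon -> locus_id -> number of distinct haplotypes (default 1)
    haplotype_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    #: taxon -> number of distinct chloroplast haplotypes over the cp system
    cp_haplotype_counts: dict[str, int] = field(default_factory=dict)
    n_f1_clones: int = 0
    n_independent_f1: int = 0
    n_backcross_a: int = 0
    n_backcross_b: int = 0
    n_candidate_parentals_a: int = 0
    n_candidate_parentals_b: int = 0
    maternal: str = "parentB"  # maternal parent of every F1
    allele_dropout_rate: float = 0.0
    flow: FlowSpec | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise AlignmentError("simulation seed is mandatory")
        if self.maternal not in ("parentA", "parentB"):
            raise AlignmentError("maternal must be 'parentA' or 'parentB'")
        for spec in self.loci:
            if spec.substitution_positions is not None:
                subs = set(spec.substitution_positions)
                if len(subs) != spec.n_substitutions:
                    raise AlignmentError(
                        f"{spec.locus_id}: explicit positions disagree with count")
                if not all(1 <= p <= spec.length for p in subs):
                    raise AlignmentError(f"{spec.locus_id}: position outside locus")
                for taxon, positions in (spec.variant_positions or {}).items():
                    clash = subs & set(positions)
                    if clash:
                        raise AlignmentError(
                            f"{spec.locus_id}: diagnostic and intraspecific variant "
                            f"positions collide at {sorted(clash)}")


@dataclass
class SimulatedDataset:
    alignments: dict[str, LocusAlignment]
    taxa: TaxonMap
    truth: pd.DataFrame
    config: SimulationConfig
    flow_events: dict[str, FlowEvents] = field(default_factory=dict)

    @property
    def nuclear(self) -> list[LocusAlignment]:
        return [a for a in self.alignments.values() if a.compartment == NUCLEAR]

    @property
    def chloroplast(self) -> list[LocusAlignment]:
        return [a for a in self.alignments.values() if a.compartment == CHLOROPLAST]

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lines = ["locus_id\tcompartment\tfile"]
        for locus_id, aln in self.alignments.items():
            write_locus_fasta(aln, out / f"{locus_id}.fasta")
            lines.append(f"{locus_id}\t{aln.compartment}\t{locus_id}.fasta")
        (out / "loci.tsv").write_text("\n".join(lines) + "\n")
        write_taxon_map(self.taxa, out / "samples.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        return out


def _draw_positions(rng: np.random.Generator, spec: LocusSpec,
                    ) -> tuple[list[int], list[tuple[int, int]]]:
    """Diagnostic substitution positions and indel ranges, non-overlapping."""
    indel_ranges: list[tuple[int, int]] = []
    blocked: set[int] = set()
    for ln in spec.indel_lengths:
        if ln < 1 or ln + 2 > spec.length:
            raise AlignmentError(f"{spec.locus_id}: indel length {ln} does not fit")
        for _ in range(10_000):
            start = int(rng.integers(2, spec.length - ln))  # keep off the ends
            cols = set(range(start, start + ln))
            pad = set(range(start - 1, start + ln + 1))
            if not (pad & blocked):
                indel_ranges.append((start, start + ln - 1))
                blocked |= cols
                break
        else:
            raise AlignmentError(f"{spec.locus_id}: cannot place indel of length {ln}")
    if spec.substitution_positions is not None:
        subs = list(spec.substitution_positions)
        if set(subs) & blocked:
            raise AlignmentError(
                f"{spec.locus_id}: explicit diagnostic position inside an indel range")
    else:
        free = sorted(set(range(1, spec.length + 1)) - blocked)
        if len(free) < spec.n_substitutions:
            raise AlignmentError(f"{spec.locus_id}: locus too short for "
                                 f"{spec.n_substitutions} diagnostic sites")
        subs = sorted(int(p) for p in
                      rng.choice(free, size=spec.n_substitutions, replace=False))
    return subs, indel_ranges


def _simulate_locus(rng: np.random.Generator, spec: LocusSpec,
                    config: SimulationConfig,
                    ) -> tuple[dict[str, list[str]], list[int], list[tuple[int, int]]]:
    """Per-taxon haplotype sequence lists for one locus.

    Returns (haplotypes by taxon, diagnostic positions, indel ranges).
    Haplotype 0 is the taxon core; further haplotypes are single-substitution
    neighbours at non-diagnostic positions.
    """
    subs, indel_ranges = _draw_positions(rng, spec)
    bg = rng.choice(list("ACGT"), size=spec.length)
    core = {config.parent_a: list(bg), config.parent_b: list(bg)}
    for pos in subs:
        pair = rng.choice(len(_BASE_PAIRS))
        a, b = _BASE_PAIRS[pair]
        core[config.parent_a][pos - 1] = a
        core[config.parent_b][pos - 1] = b
    for k, (start, end) in enumerate(indel_ranges):
        gapped = config.parent_a if k % 2 == 0 else config.parent_b
        for i in range(start - 1, end):
            core[gapped][i] = GAP
    blocked = set(subs)
    for start, end in indel_ranges:
        blocked |= set(range(start, end + 1))
    haps: dict[str, list[str]] = {}
    for taxon in (config.parent_a, config.parent_b):
        n_haps = config.haplotype_counts.get(taxon, {}).get(spec.locus_id, 1)
        explicit = (spec.variant_positions or {}).get(taxon)
        seqs = ["".join(core[taxon])]
        used: set[int] = set()
        for v in range(1, n_haps):
            if explicit is not None:
                pos = explicit[v - 1]
                if pos in set(subs):
                    raise AlignmentError(
                        f"{spec.locus_id}: variant position {pos} collides with a "
                        "diagnostic site")
            else:
                free = sorted(set(range(1, spec.length + 1)) - blocked - used)
                pos = int(rng.choice(free))
            used.add(pos)
            variant = list(core[taxon])
            old = variant[pos - 1]
            if old == GAP:
                raise AlignmentError(f"{spec.locus_id}: variant inside indel range")
            variant[pos - 1] = str(rng.choice([b for b in "ACGT" if b != old]))
            seqs.append("".join(variant))
        haps[taxon] = seqs
    return haps, subs, indel_ranges


_BASE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


def _collapse_rows(h1: str, h2: str) -> tuple[str, list[tuple[int, int]]]:
    """IUPAC consensus of two haplotypes; gap-vs-base runs become het indels.

    The consensus row carries the full-length allele across het-indel runs
    (mirroring how a double-peaked trace is exported) and the runs are
    reported for the sidecar flags.
    """
    out = []
    het_runs: list[tuple[int, int]] = []
    run_start = None
    for i, (x, y) in enumerate(zip(h1, h2), start=1):
        if (x == GAP) != (y == GAP):
            out.append(x if x != GAP else y)
            if run_start is None:
                run_start = i
            continue
        if run_start is not None:
            het_runs.append((run_start, i - 1))
            run_start = None
        if x == GAP:
            out.append(GAP)
        else:
            out.append(x if x == y else collapse_bases({x, y}))
    if run_start is not None:
        het_runs.append((run_start, len(h1)))
    return "".join(out), het_runs


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate alignments, taxon map and truth table for one configuration."""
    rng = np.random.default_rng(config.seed)
    pa, pb = config.parent_a, config.parent_b
    nuclear_specs = [s for s in config.loci if s.compartment == NUCLEAR]
    cp_specs = [s for s in config.loci if s.compartment == CHLOROPLAST]
    if not nuclear_specs:
        raise AlignmentError("need at least one nuclear locus")

    # --- parental haplotype pools ---------------------------------------
    haps: dict[str, dict[str, list[str]]] = {}  # locus -> taxon -> sequences
    meta: dict[str, tuple[list[int], list[tuple[int, int]]]] = {}
    for spec in config.loci:
        haps[spec.locus_id], subs, indels = _simulate_locus(rng, spec, config)
        meta[spec.locus_id] = (subs, indels)
    # chloroplast system haplotypes: variants applied in the first cp locus
    cp_haps: dict[str, list[dict[str, str]]] = {pa: [], pb: []}
    if cp_specs:
        for taxon in (pa, pb):
            n_cp = config.cp_haplotype_counts.get(taxon, 1)
            base = {s.locus_id: haps[s.locus_id][taxon][0] for s in cp_specs}
            cp_haps[taxon].append(base)
            first = cp_specs[0]
            subs0, indels0 = meta[first.locus_id]
            blocked = set(subs0)
            for st, en in indels0:
                blocked |= set(range(st, en + 1))
            used: set[int] = set()
            for _ in range(1, n_cp):
                free = sorted(set(range(1, first.length + 1)) - blocked - used)
                pos = int(rng.choice(free))
                used.add(pos)
                variant = dict(base)
                seq = list(base[first.locus_id])
                old = seq[pos - 1]
                if old == GAP:
                    continue
                seq[pos - 1] = str(rng.choice([b for b in "ACGT" if b != old]))
                variant[first.locus_id] = "".join(seq)
                cp_haps[taxon].append(variant)

    samples: dict[str, tuple[str, str]] = {}
    rows: dict[str, dict[str, str]] = {s.locus_id: {} for s in config.loci}
    het_flags: list[HetIndel] = []
    truth_rows: list[dict] = []

    def add_sample(sid: str, taxon: str, role: str, true_class: str,
                   nuclear_pairs: dict[str, tuple[str, str]],
                   cp_hap: dict[str, str] | None, maternal_taxon: str) -> None:
        samples[sid] = (taxon, role)
        for spec in nuclear_specs:
            h1, h2 = nuclear_pairs[spec.locus_id]
            row, het_runs = _collapse_rows(h1, h2)
            if config.allele_dropout_rate > 0:
                row = _apply_dropout(rng, row, h1, h2, config.allele_dropout_rate)
            rows[spec.locus_id][sid] = row
            for st, en in het_runs:
                het_flags.append(HetIndel(sid, spec.locus_id, st, en))
        for spec in cp_specs:
            rows[spec.locus_id][sid] = (cp_hap or {})[spec.locus_id]
        truth_rows.append({
            "sample_id": sid, "taxon": taxon, "role": role,
            "true_class": true_class, "true_maternal": maternal_taxon,
            "genotype_key": _genotype_key(nuclear_pairs, cp_hap)})

    def _genotype_key(nuclear_pairs, cp_hap) -> str:
        bits = []
        for spec in nuclear_specs:
            bits.append("|".join(sorted(nuclear_pairs[spec.locus_id])))
        if cp_hap:
            bits.append("|".join(cp_hap[s.locus_id] for s in cp_specs))
        return ";".join(bits)

    # --- parental populations -------------------------------------------
    counter = 0
    for taxon, role in ((pa, "parentA"), (pb, "parentB")):
        n = config.sample_sizes.get(taxon, 0)
        if n < 1:
            raise AlignmentError(f"need at least one sample for {taxon}")
        for i in range(n):
            counter += 1
            sid = f"{taxon}_{i + 1:03d}"
            pairs = {}
            for spec in nuclear_specs:
                pool = haps[spec.locus_id][taxon]
                h = pool[i % len(pool)]  # round-robin: every haplotype observed
                pairs[spec.locus_id] = (h, h)
            cp_hap = None
            if cp_specs:
                pool_cp = cp_haps[taxon]
                cp_hap = pool_cp[i % len(pool_cp)]
            add_sample(sid, taxon, role, role, pairs, cp_hap, role)

    # --- candidates ------------------------------------------------------
    hybrid_taxon = "hybrid"
    maternal_taxon = pa if config.maternal == "parentA" else pb
    maternal_role = config.maternal

    def draw_f1(avoid: set[tuple] | None = None) -> tuple[dict, dict, tuple]:
        for _ in range(10_000):
            key_parts = []
            pairs = {}
            for spec in nuclear_specs:
                ia = int(rng.integers(len(haps[spec.locus_id][pa])))
                ib = int(rng.integers(len(haps[spec.locus_id][pb])))
                pairs[spec.locus_id] = (haps[spec.locus_id][pa][ia],
                                        haps[spec.locus_id][pb][ib])
                key_parts.append((ia, ib))
            icp = int(rng.integers(len(cp_haps[maternal_taxon]))) if cp_specs else -1
            key = (tuple(key_parts), icp)
            cp_hap = cp_haps[maternal_taxon][icp] if cp_specs else None
            if avoid is None or key not in avoid:
                return pairs, cp_hap, key
        raise AlignmentError(
            "cannot draw a distinct F1 genotype: parental haplotype diversity "
            "is too low for the requested number of independent F1s")

    founder_pairs = founder_cp = None
    drawn: set[tuple] = set()
    if config.n_f1_clones or config.n_backcross_a or config.n_backcross_b:
        founder_pairs, founder_cp, key = draw_f1()
        drawn.add(key)
    for i in range(config.n_f1_clones):
        sid = f"F1clone_{i + 1:03d}"
        add_sample(sid, hybrid_taxon, "candidate", "F1",
                   founder_pairs, founder_cp, maternal_role)
    for i in range(config.n_independent_f1):
        pairs, cp_hap, key = draw_f1(avoid=drawn)
        drawn.add(key)
        add_sample(f"F1indep_{i + 1:03d}", hybrid_taxon, "candidate", "F1",
                   pairs, cp_hap, maternal_role)

    for n_bc, recurrent, label in ((config.n_backcross_a, pa, "backcross_A"),
                                   (config.n_backcross_b, pb, "backcross_B")):
        for i in range(n_bc):
            pairs = _draw_backcross(rng, nuclear_specs, haps, founder_pairs,
                                    recurrent, pa)
            # the F1 is the seed parent of the backcross, so its chloroplast
            # (the original maternal taxon's) is transmitted
            add_sample(f"{label}_{i + 1:03d}", hybrid_taxon, "candidate", label,
                       pairs, founder_cp, maternal_role)

    for n_par, taxon, label in (
            (config.n_candidate_parentals_a, pa, "parentA"),
            (config.n_candidate_parentals_b, pb, "parentB")):
        for i in range(n_par):
            pairs = {}
            for spec in nuclear_specs:
                pool = haps[spec.locus_id][taxon]
                h = pool[int(rng.integers(len(pool)))]
                pairs[spec.locus_id] = (h, h)
            cp_hap = cp_haps[taxon][int(rng.integers(len(cp_haps[taxon])))] \
                if cp_specs else None
            add_sample(f"cand_{label}_{i + 1:03d}", taxon, "candidate", label,
                       pairs, cp_hap, label)

    # realized clone groups: identity partition of candidate genotypes
    truth = pd.DataFrame(truth_rows)
    group_of: dict[str, int] = {}
    clone_groups = []
    for _, r in truth.iterrows():
        if r["role"] != "candidate":
            clone_groups.append(0)
            continue
        key = r["genotype_key"]
        if key not in group_of:
            group_of[key] = len(group_of) + 1
        clone_groups.append(group_of[key])
    truth["true_clone_group"] = clone_groups
    truth = truth.drop(columns=["genotype_key"])

    alignments = {}
    order = list(samples)
    for spec in config.loci:
        alignments[spec.locus_id] = LocusAlignment(
            spec.locus_id, spec.compartment, tuple(order),
            {s: rows[spec.locus_id][s] for s in order})
    taxa = TaxonMap(dict(samples), tuple(het_flags))

    flow_events: dict[str, FlowEvents] = {}
    if config.flow is not None:
        flow_events = simulate_flow(config.flow, int(rng.integers(2**31)))
    return SimulatedDataset(alignments, taxa, truth, config, flow_events)


def _draw_backcross(rng, nuclear_specs, haps, founder_pairs, recurrent, parent_a):
    """Gametes for one F1 x recurrent-parent offspring.

    Redraws until at least one locus is heterozygous (F1 passed the
    non-recurrent allele) and one homozygous-parental (F1 passed the
    recurrent-taxon allele), the minimum evidence for a backcross call.
    """
    rec_idx = 0 if recurrent == parent_a else 1
    for _ in range(10_000):
        pairs = {}
        n_het = n_hom = 0
        for spec in nuclear_specs:
            from_f1 = founder_pairs[spec.locus_id][int(rng.integers(2))]
            pool = haps[spec.locus_id][recurrent]
            from_parent = pool[int(rng.integers(len(pool)))]
            pairs[spec.locus_id] = (from_f1, from_parent)
            if from_f1 == founder_pairs[spec.locus_id][rec_idx]:
                n_hom += 1
            else:
                n_het += 1
        if n_het and n_hom:
            return pairs
    raise AlignmentError("cannot draw a diagnosable backcross (needs >= 2 loci)")


def _apply_dropout(rng, row: str, h1: str, h2: str, rate: float) -> str:
    """Genotyping noise: at het sites one allele drops out with given rate."""
    out = list(row)
    for i, (x, y) in enumerate(zip(h1, h2)):
        if x != y and x != GAP and y != GAP and rng.random() < rate:
            out[i] = x if rng.random() < 0.5 else y
    return "".join(out)


def simulate_flow(spec: FlowSpec, seed: int) -> dict[str, FlowEvents]:
    """Two-peak event streams per taxon: internal standard plus sample nuclei."""
    rng = np.random.default_rng(seed)
    if spec.cv <= 0:
        raise AlignmentError("flow CV must be positive")
    if spec.n_events < 1000:
        raise AlignmentError("need at least 1000 flow events")
    out: dict[str, FlowEvents] = {}
    std_channel = spec.gain * spec.standard_2c
    for taxon, c2 in spec.taxon_2c.items():
        n_std = spec.n_events // 2
        n_sample = spec.n_events - n_std
        sample_channel = spec.gain * c2
        sample = rng.normal(sample_channel, spec.cv * sample_channel, n_sample)
        standard = rng.normal(std_channel, spec.cv * std_channel, n_std)
        values = np.clip(np.concatenate([sample, standard]), 1e-6, None)
        out[taxon] = FlowEvents(
            values, standard_2c=spec.standard_2c,
            standard_window=(std_channel * 0.9, std_channel * 1.1))
    return out


def study_config(seed: int, n_f1_clones: int = 30, n_independent_f1: int = 0,
                 n_backcross_a: int = 0, n_backcross_b: int = 0,
                 maternal: str = "parentB", flow: bool = True) -> SimulationConfig:
    """Configuration mirroring the default study design.

    Five nuclear loci carrying 14/4/6/5/7 fixed substitutions plus one 6-bp
    indel at the fifth locus, six chloroplast regions carrying 14 fixed
    substitutions and three fixed indels in total, parental sample sizes of
    18 and 26, within-taxon haplotype counts of (2,2,1,2,1)+1cp for the A
    parent and (1,3,2,1,1)+2cp for the B parent, 30 apomictic F1 clones with
    the B parent maternal, and two-peak flow streams at 2C = 2.05, 2.02 and
    1.09 pg against a 2.5 pg/2C internal standard.
    """
    loci = [
        LocusSpec("nuc1", NUCLEAR, 840, 14),
        LocusSpec("nuc2", NUCLEAR, 568, 4),
        LocusSpec("nuc3", NUCLEAR, 461, 6),
        LocusSpec("nuc4", NUCLEAR, 645, 5),
        LocusSpec("nuc5", NUCLEAR, 811, 7, indel_lengths=(6,)),
        LocusSpec("cp1", CHLOROPLAST, 1036, 2),
        LocusSpec("cp2", CHLOROPLAST, 891, 4),
        LocusSpec("cp3", CHLOROPLAST, 662, 2, indel_lengths=(1,)),
        LocusSpec("cp4", CHLOROPLAST, 648, 2, indel_lengths=(18,)),
        LocusSpec("cp5", CHLOROPLAST, 415, 2),
        LocusSpec("cp6", CHLOROPLAST, 316, 2, indel_lengths=(13,)),
    ]
    flow_spec = FlowSpec(taxon_2c={"taxonA": 2.05, "hybrid": 2.02, "taxonB": 1.09}) \
        if flow else None
    return SimulationConfig(
        seed=seed, loci=loci,
        sample_sizes={"taxonA": 18, "taxonB": 26},
        haplotype_counts={
            "taxonA": {"nuc1": 2, "nuc2": 2, "nuc3": 1, "nuc4": 2, "nuc5": 1},
            "taxonB": {"nuc1": 1, "nuc2": 3, "nuc3": 2, "nuc4": 1, "nuc5": 1},
        },
        cp_haplotype_counts={"taxonA": 1, "taxonB": 2},
        n_f1_clones=n_f1_clones, n_independent_f1=n_independent_f1,
        n_backcross_a=n_backcross_a, n_backcross_b=n_backcross_b,
        maternal=maternal, flow=flow_spec)
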