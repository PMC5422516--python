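"""Parsimony haplotype phasing and per-taxon haplotype inventories.

IUPAC consensus rows are phased into haplotype pairs by anchoring to parental
reference haplotypes: among all haplotype pairs consistent with the observed
genotype, the pair whose members lie closest (summed Hamming distance) to
their nearest parental haplotypes is chosen.  This is deterministic — when the
minimiser is not unique the sample is flagged unphaseable rather than guessed.
Chloroplast loci are uniparentally inherited and treated as haploid: one
haplotype per sample, ambiguity codes there are data errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .alignments import (
    GAP,
    AlignmentError,
    LocusAlignment,
    TaxonMap,
    collapse_bases,
    expand_iupac,
)
from .diagnostics import DiagnosticIndel

UNPHASEABLE = "unphaseable"


@dataclass(frozen=True)
class Haplotype:
    """One phased allelic sequence at a locus (no ambiguity codes)."""

    locus_id: str
    sequence: str
    label: str = ""

    def __post_init__(self) -> None:
        for ch in self.sequence:
            if ch not in "ACGTN" and ch != GAP:
                raise AlignmentError(
                    f"haplotype for locus {self.locus_id!r} contains ambiguity "
                    f"code {ch!r}; haplotypes must be fully resolved")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise AlignmentError("hamming distance of unequal-length sequences")
    return sum(1 for x, y in zip(a, b) if x != y)


def _het_columns(row: str) -> list[int]:
    """0-based indices of 2+-fold ambiguity columns."""
    out = []
    for i, ch in enumerate(row):
        if ch == GAP:
            continue
        if len(expand_iupac(ch)) > 1:
            out.append(i)
    return out


def phase_sample(row: str, parental_haplotypes: list[Haplotype] | list[str],
                 max_het: int = 12,
                 het_indels: list[DiagnosticIndel] | None = None,
                 ) -> tuple[str, str] | str:
    """Phase one genotype row against parental reference haplotypes.

    Returns the ordered pair of haplotype sequences minimising the summed
    Hamming distance of each member to its closest parental haplotype, or the
    string ``"unphaseable"`` when the minimum is not unique.  A homozygous row
    phases to (row, row).  Enumeration over k het columns costs 2**(k-1) pair
    evaluations and is refused above ``max_het``.

    ``het_indels`` lists indel events for which this sample is flagged
    heterozygous: the member closer to the gapped parental allele receives the
    gaps, its mate keeps the full-length allele.
    """
    refs = [h.sequence if isinstance(h, Haplotype) else h for h in parental_haplotypes]
    for r in refs:
        if len(r) != len(row):
            raise AlignmentError("parental haplotype length differs from genotype row")
    # columns inside het-indel runs are unresolved until the indel alleles are
    # assigned below, so they must not contribute to the anchoring distance
    excluded: set[int] = set()
    for ev in het_indels or ():
        excluded.update(range(ev.start - 1, ev.end))
    het = [i for i in _het_columns(row) if i not in excluded]
    k = len(het)
    if k > max_het:
        raise AlignmentError(
            f"{k} heterozygous columns exceeds the phasing cap of {max_het}; "
            "enumeration would be exponential")
    if k == 0:
        pair = (row, row)
    else:
        if not refs:
            return UNPHASEABLE
        choices = [sorted(expand_iupac(row[i])) for i in het]
        # distance of any consistent haplotype to a reference decomposes into
        # a fixed part over the homozygous columns plus the het-column part,
        # so enumeration works on k-character tuples, not full sequences
        het_set = set(het) | excluded
        base_dist = []
        for r in refs:
            base_dist.append(sum(1 for i, (x, y) in enumerate(zip(row, r))
                                 if i not in het_set and x != y))
        ref_het = [tuple(r[i] for i in het) for r in refs]

        def nearest(chars: tuple[str, ...]) -> int:
            return min(b + sum(1 for x, y in zip(chars, rh) if x != y)
                       for b, rh in zip(base_dist, ref_het))

        best_score: int | None = None
        best_pairs: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
        # fix the first het column's assignment to break the mirror symmetry
        for flips in product("01", repeat=k - 1):
            c1, c2 = [choices[0][0]], [choices[0][1]]
            for j in range(1, k):
                x, y = choices[j]
                if flips[j - 1] == "0":
                    c1.append(x)
                    c2.append(y)
                else:
                    c1.append(y)
                    c2.append(x)
            t1, t2 = tuple(c1), tuple(c2)
            score = nearest(t1) + nearest(t2)
            if best_score is None or score < best_score:
                best_score, best_pairs = score, [(t1, t2)]
            elif score == best_score:
                best_pairs.append((t1, t2))
        uniq = {frozenset(p) for p in best_pairs}
        if len(uniq) > 1:
            return UNPHASEABLE
        t1, t2 = best_pairs[0]
        h1, h2 = list(row), list(row)
        for j, i in enumerate(het):
            h1[i], h2[i] = t1[j], t2[j]
        pair = ("".join(h1), "".join(h2))
    if het_indels:
        gapped_refs = [r for r in refs if any(
            set(r[ev.start - 1:ev.end]) == {GAP} for ev in het_indels)]
        h1, h2 = pair
        # give the gapped allele to the member nearer a gap-carrying parent
        def gap_affinity(seq: str) -> int:
            if not gapped_refs:
                return 0
            return min(hamming(seq, r) for r in gapped_refs)

        carrier = 0 if gap_affinity(h1) <= gap_affinity(h2) else 1
        mutable = [list(h1), list(h2)]
        for ev in het_indels:
            for i in range(ev.start - 1, ev.end):
                mutable[carrier][i] = GAP
        pair = ("".join(mutable[0]), "".join(mutable[1]))
    return pair


@dataclass
class PhasedSample:
    sample_id: str
    locus_id: str
    haplotypes: tuple[str, ...]  # 2 sequences (nuclear) or 1 (chloroplast)
    flag: str = ""


@dataclass
class HaplotypeInventory:
    """Distinct haplotypes per (taxon, locus) with carrier counts."""

    #: (taxon, locus_id) -> list of (Haplotype, carrier count), most frequent first
    inventory: dict[tuple[str, str], list[tuple[Haplotype, int]]] = field(default_factory=dict)
    phased: list[PhasedSample] = field(default_factory=list)
    loci: tuple[str, ...] = ()

    def haplotypes(self, taxon: str, locus_id: str) -> list[tuple[Haplotype, int]]:
        return self.inventory.get((taxon, locus_id), [])

    def n_haplotypes(self, taxon: str, locus_id: str | None = None) -> int:
        if locus_id is not None:
            return len(self.haplotypes(taxon, locus_id))
        return sum(len(v) for (t, _), v in self.inventory.items() if t == taxon)

    def sample_haplotypes(self, sample: str, locus_id: str) -> tuple[str, ...]:
        for p in self.phased:
            if p.sample_id == sample and p.locus_id == locus_id:
                if p.flag:
                    raise AlignmentError(
                        f"sample {sample!r} at {locus_id!r} is {p.flag}")
                return p.haplotypes
        raise AlignmentError(f"no phased record for sample {sample!r} at {locus_id!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (taxon, locus_id), haps in sorted(self.inventory.items()):
            for hap, count in haps:
                rows.append({"taxon": taxon, "locus_id": locus_id,
                             "label": hap.label, "count": count,
                             "sequence": hap.sequence})
        return pd.DataFrame(rows, columns=["taxon", "locus_id", "label",
                                           "count", "sequence"])


def _label_haplotypes(counts: dict[str, int], locus_id: str) -> dict[str, Haplotype]:
    """Labels in order of descending frequency, ties lexicographic by sequence."""
    ordered = sorted(counts, key=lambda seq: (-counts[seq], seq))
    out = {}
    for i, seq in enumerate(ordered):
        # H_A, H_B, ... then H_27, ... beyond the alphabet
        label = f"H_{chr(ord('A') + i)}" if i < 26 else f"H_{i + 1}"
        out[seq] = Haplotype(locus_id, seq, label)
    return out


def build_inventory(alignments: list[LocusAlignment], taxa: TaxonMap,
                    parent_roles: tuple[str, str] = ("parentA", "parentB"),
                    max_het: int = 12,
                    indels_by_locus: dict[str, list[DiagnosticIndel]] | None = None,
                    ) -> HaplotypeInventory:
    """Phase every sample at every locus and tabulate distinct haplotypes.

    Nuclear loci are phased per sample; parental reference haplotypes are the
    homozygous rows observed in the two parental populations at that locus
    (a deliberately simple anchor set: in low-diversity, largely selfing or
    apomictic populations most parental individuals are homozygous).
    Chloroplast loci are concatenated by the caller or passed individually and
    treated as haploid.
    """
    from .alignments import CHLOROPLAST

    inv = HaplotypeInventory(loci=tuple(a.locus_id for a in alignments))
    for aln in alignments:
        indels = (indels_by_locus or {}).get(aln.locus_id, [])
        if aln.compartment == CHLOROPLAST:
            seqs: dict[str, tuple[str, ...]] = {}
            for s in aln.samples:
                row = aln.rows[s]
                if _het_columns(row):
                    raise AlignmentError(
                        f"ambiguity code in chloroplast row (sample={s!r}, "
                        f"locus={aln.locus_id!r}): chloroplast data are haploid")
                seqs[s] = (row,)
        else:
            refs: list[str] = []
            for role in parent_roles:
                for s in (x for x in aln.samples if taxa.role(x) == role):
                    row = aln.rows[s]
                    if not _het_columns(row) and row not in refs:
                        refs.append(row)
            seqs = {}
            memo: dict[tuple, tuple[str, str] | str] = {}
            for s in aln.samples:
                het_evs = [DiagnosticIndel(aln.locus_id, h.start, h.end, "parentA",
                                           aln.rows[s][h.start - 1:h.end])
                           for h in taxa.het_indels_for(s, aln.locus_id)]
                key = (aln.rows[s], tuple((e.start, e.end) for e in het_evs))
                if key in memo:
                    result = memo[key]
                else:
                    result = phase_sample(aln.rows[s], refs, max_het=max_het,
                                          het_indels=het_evs or None)
                    memo[key] = result
                if isinstance(result, str):
                    inv.phased.append(PhasedSample(s, aln.locus_id, (), flag=result))
                    continue
                seqs[s] = result
        # tabulate per taxon
        for taxon in taxa.taxa:
            counts: dict[str, int] = {}
            for s in taxa.samples_of_taxon(taxon):
                for hap_seq in seqs.get(s, ()):
                    counts[hap_seq] = counts.get(hap_seq, 0) + 1
            if counts:
                labelled = _label_haplotypes(counts, aln.locus_id)
                inv.inventory[(taxon, aln.locus_id)] = [
                    (labelled[seq], counts[seq])
                    for seq in sorted(counts, key=lambda q: (-counts[q], q))]
        for s, pair in seqs.items():
            inv.phased.append(PhasedSample(s, aln.locus_id, pair))
    return inv


def shared_haplotypes(inv: HaplotypeInventory, taxon1: str, taxon2: str,
                      ) -> dict[str, set[str]]:
    """Per-locus sets of haplotype sequences carried by both taxa."""
    out: dict[str, set[str]] = {}
    for locus_id in inv.loci:
        seqs1 = {h.sequence for h, _ in inv.haplotypes(taxon1, locus_id)}
        seqs2 = {h.sequence for h, _ in inv.haplotypes(taxon2, locus_id)}
        out[locus_id] = seqs1 & seqs2
    return out
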