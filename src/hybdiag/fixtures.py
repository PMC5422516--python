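"""Built-in case study: the Malipo *Cotoneaster* hybrid zone.

A deterministic reference dataset reconstructing, at desk scale, the
published multilocus diagnostics for the putative hybrid between
*C. dielsianus* (parent A, tetraploid) and *C. glaucophyllus* (parent B,
diploid), with *C. franchetii* as a third, independently additive taxon.

Five nuclear EPIC loci (DUF, NA1, NA2, UPF, WD) carry 14/4/6/5/7 fixed
substitutions respectively (36 in all) plus one fixed 6-bp indel in WD; the
six chloroplast regions carry 14 fixed substitutions and three fixed indels
between the parents.  The hybrid is IUPAC-additive at every nuclear
diagnostic site, heterozygous for the WD indel, and chloroplast-identical to
the *minor* of the two *C. glaucophyllus* chloroplast haplotypes.
*C. franchetii* is additive at 29 of the 36 nuclear sites and carries a
unique chloroplast haplotype.

Alignment columns not listed below are invariant across all taxa; the
invariant background is drawn from a fixed seed, so the fixture is
deterministic and versioned.  Chloroplast diagnostic positions are nominal:
only their per-locus distribution, states and event counts are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignments import (
    CHLOROPLAST,
    NUCLEAR,
    HetIndel,
    LocusAlignment,
    TaxonMap,
    write_locus_fasta,
    write_taxon_map,
)

_BACKGROUND_SEED = 20170509

DIELSIANUS = "C_dielsianus"      # parent A
GLAUCOPHYLLUS = "C_glaucophyllus"  # parent B
HYBRID = "putative_hybrid"
FRANCHETII = "C_franchetii"

#: aligned locus lengths (bp)
LOCUS_LENGTHS: dict[str, int] = {
    "DUF": 840, "NA1": 568, "NA2": 461, "UPF": 645, "WD": 811,
    "ndhF": 1036, "rpl16": 891, "rps16": 662,
    "trnC-ycf6": 648, "trnG-trnS": 415, "trnH-rpl2": 316,
}

NUCLEAR_LOCI = ("DUF", "NA1", "NA2", "UPF", "WD")
CP_LOCI = ("ndhF", "rpl16", "rps16", "trnC-ycf6", "trnG-trnS", "trnH-rpl2")

#: nuclear diagnostic sites: locus -> [(position, dielsianus, glaucophyllus,
#: hybrid, franchetii)]
NUCLEAR_SITES: dict[str, list[tuple[int, str, str, str, str]]] = {
    "DUF": [
        (66, "G", "C", "S", "S"), (117, "A", "T", "W", "A"),
        (266, "T", "C", "Y", "Y"), (285, "A", "T", "W", "W"),
        (412, "C", "T", "Y", "Y"), (454, "T", "C", "Y", "Y"),
        (532, "A", "G", "R", "R"), (571, "C", "T", "Y", "Y"),
        (581, "G", "C", "S", "S"), (607, "C", "T", "Y", "Y"),
        (649, "A", "G", "R", "R"), (672, "A", "T", "W", "T"),
        (766, "C", "T", "Y", "C"), (810, "G", "T", "K", "K"),
    ],
    "NA1": [
        (379, "C", "T", "Y", "Y"), (397, "T", "G", "K", "K"),
        (435, "A", "T", "W", "W"), (443, "G", "T", "K", "K"),
    ],
    # NA2 positions are nominal: the published labels (517-527) exceed the
    # locus's 461-bp aligned length, so the six sites are placed at 317-327
    # with the printed states and spacing preserved
    "NA2": [
        (317, "G", "A", "R", "R"), (320, "A", "G", "R", "R"),
        (321, "A", "G", "R", "R"), (325, "T", "A", "W", "W"),
        (326, "A", "T", "W", "W"), (327, "G", "A", "R", "R"),
    ],
    "UPF": [
        (149, "G", "A", "R", "R"), (215, "C", "T", "Y", "Y"),
        (268, "T", "G", "K", "K"), (340, "C", "G", "S", "S"),
        (408, "G", "A", "R", "R"),
    ],
    "WD": [
        (187, "C", "T", "Y", "C"), (195, "C", "T", "Y", "C"),
        (257, "A", "G", "R", "A"), (278, "T", "A", "W", "T"),
        (364, "A", "C", "M", "M"),
        (623, "G", "T", "K", "K"), (625, "G", "T", "K", "K"),
    ],
}

#: the fixed nuclear indel: WD 40-45, dielsianus gapped, glaucophyllus TCACAT;
#: hybrid and franchetii heterozygous (full-length row + sidecar het flag)
WD_INDEL = ("WD", 40, 45, "TCACAT")

#: chloroplast diagnostic sites (positions nominal): locus ->
#: [(position, dielsianus, glaucophyllus)]; hybrid == glaucophyllus minor
#: haplotype, franchetii from its own states below
CP_SITES: dict[str, list[tuple[int, str, str]]] = {
    "ndhF": [(379, "T", "A"), (716, "A", "C")],
    "rpl16": [(582, "T", "G"), (589, "G", "T"), (635, "A", "G"), (790, "C", "T")],
    "rps16": [(65, "C", "T"), (125, "T", "G")],
    "trnC-ycf6": [(93, "G", "A"), (344, "G", "C")],
    "trnG-trnS": [(109, "T", "G"), (195, "C", "T")],
    "trnH-rpl2": [(92, "C", "T"), (254, "T", "C")],
}

#: chloroplast fixed indels: (locus, start, end, bases carried by glaucophyllus);
#: dielsianus is gapped in every event
CP_INDELS: list[tuple[str, int, int, str]] = [
    ("rps16", 188, 188, "T"),
    ("trnC-ycf6", 191, 208, "TTTATTCCTTTTATTTTA"),
    ("trnH-rpl2", 79, 91, "ATAAATATTTAAT"),
]

#: the single-carrier minor glaucophyllus cp haplotype (H_A) differs from the
#: major one at this position; the hybrid's cp matches the minor haplotype
CP_MINOR_VARIANT = ("ndhF", 500)

#: franchetii private cp changes: substitutions + one private 10-bp deletion
CP_FRANCHETII_SUBS: list[tuple[str, int]] = [("ndhF", 12), ("trnG-trnS", 300),
                                             ("trnH-rpl2", 254)]
CP_FRANCHETII_GAP = ("rpl16", 400, 409)

#: flow-cytometry 2C values (pg, mean across 4 individuals +/- SD) and ploidy
FLOW_2C: dict[str, tuple[float, float, int]] = {
    DIELSIANUS: (2.05, 0.126, 4),
    HYBRID: (2.02, 0.023, 4),
    GLAUCOPHYLLUS: (1.09, 0.034, 2),
}
STANDARD_2C = 2.5

#: sampling design: (taxon, collecting number, sample indices, role)
SAMPLING = (
    (HYBRID, "13917", range(1, 31), "candidate"),
    (DIELSIANUS, "13916", range(31, 49), "parentA"),
    (FRANCHETII, "13915", range(49, 71), "other"),
    (GLAUCOPHYLLUS, "13949", range(71, 97), "parentB"),
)


def sample_ids(taxon: str) -> list[str]:
    for t, coll, idxs, _ in SAMPLING:
        if t == taxon:
            return [f"{coll}_{i:02d}" for i in idxs]
    raise KeyError(taxon)


@dataclass
class CaseStudyDataset:
    alignments: dict[str, LocusAlignment]
    taxa: TaxonMap

    @property
    def nuclear(self) -> list[LocusAlignment]:
        return [self.alignments[l] for l in NUCLEAR_LOCI]

    @property
    def chloroplast(self) -> list[LocusAlignment]:
        return [self.alignments[l] for l in CP_LOCI]


def _background(length: int, rng: np.random.Generator) -> list[str]:
    return list(rng.choice(list("ACGT"), size=length))


def _other_base(base: str, rng: np.random.Generator) -> str:
    return str(rng.choice([b for b in "ACGT" if b != base]))


def build_dataset() -> CaseStudyDataset:
    """Construct the full reference dataset in memory (deterministic)."""
    rng = np.random.default_rng(_BACKGROUND_SEED)
    alignments: dict[str, LocusAlignment] = {}
    all_samples: dict[str, tuple[str, str]] = {}
    het_flags: list[HetIndel] = []
    for taxon, coll, idxs, role in SAMPLING:
        for s in sample_ids(taxon):
            all_samples[s] = (taxon, role)

    for locus in NUCLEAR_LOCI:
        length = LOCUS_LENGTHS[locus]
        bg = _background(length, rng)
        rows_by_taxon: dict[str, list[str]] = {t: list(bg) for t, *_ in SAMPLING}
        for pos, a, b, h, f in NUCLEAR_SITES[locus]:
            rows_by_taxon[DIELSIANUS][pos - 1] = a
            rows_by_taxon[GLAUCOPHYLLUS][pos - 1] = b
            rows_by_taxon[HYBRID][pos - 1] = h
            rows_by_taxon[FRANCHETII][pos - 1] = f
        if locus == WD_INDEL[0]:
            _, start, end, inserted = WD_INDEL
            for i, ch in enumerate(inserted):
                rows_by_taxon[GLAUCOPHYLLUS][start - 1 + i] = ch
                rows_by_taxon[HYBRID][start - 1 + i] = ch
                rows_by_taxon[FRANCHETII][start - 1 + i] = ch
                rows_by_taxon[DIELSIANUS][start - 1 + i] = "-"
            for taxon in (HYBRID, FRANCHETII):
                for s in sample_ids(taxon):
                    het_flags.append(HetIndel(s, locus, start, end))
        rows = {}
        samples = []
        for taxon, *_ in SAMPLING:
            seq = "".join(rows_by_taxon[taxon])
            for s in sample_ids(taxon):
                samples.append(s)
                rows[s] = seq
        alignments[locus] = LocusAlignment(locus, NUCLEAR, tuple(samples), rows)

    for locus in CP_LOCI:
        length = LOCUS_LENGTHS[locus]
        bg = _background(length, rng)
        glauc_major = list(bg)
        diels = list(bg)
        for pos, a, b in CP_SITES[locus]:
            diels[pos - 1] = a
            glauc_major[pos - 1] = b
        for loc, start, end, inserted in CP_INDELS:
            if loc != locus:
                continue
            for i, ch in enumerate(inserted):
                glauc_major[start - 1 + i] = ch
                diels[start - 1 + i] = "-"
        glauc_minor = list(glauc_major)
        if CP_MINOR_VARIANT[0] == locus:
            pos = CP_MINOR_VARIANT[1]
            glauc_minor[pos - 1] = _other_base(glauc_major[pos - 1], rng)
        fran = list(glauc_major)
        for loc, pos in CP_FRANCHETII_SUBS:
            if loc == locus:
                fran[pos - 1] = _other_base(glauc_major[pos - 1], rng)
        if CP_FRANCHETII_GAP[0] == locus:
            for i in range(CP_FRANCHETII_GAP[1] - 1, CP_FRANCHETII_GAP[2]):
                fran[i] = "-"
        seqs = {DIELSIANUS: "".join(diels), FRANCHETII: "".join(fran)}
        rows = {}
        samples = []
        minor_seq, major_seq = "".join(glauc_minor), "".join(glauc_major)
        for taxon, *_ in SAMPLING:
            for k, s in enumerate(sample_ids(taxon)):
                samples.append(s)
                if taxon == HYBRID:
                    rows[s] = minor_seq  # maternal: glaucophyllus minor haplotype
                elif taxon == GLAUCOPHYLLUS:
                    rows[s] = minor_seq if k == 0 else major_seq
                else:
                    rows[s] = seqs[taxon]
        alignments[locus] = LocusAlignment(locus, CHLOROPLAST, tuple(samples), rows)

    taxa = TaxonMap(all_samples, tuple(het_flags))
    return CaseStudyDataset(alignments, taxa)


def write_dataset(out_dir: str | Path, dataset: CaseStudyDataset | None = None) -> Path:
    """Emit the fixture files (per-locus FASTA, taxon map, locus metadata)."""
    ds = dataset or build_dataset()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["locus_id\tcompartment\tfile"]
    for locus in NUCLEAR_LOCI + CP_LOCI:
        aln = ds.alignments[locus]
        fname = f"{locus}.fasta"
        write_locus_fasta(aln, out / fname)
        lines.append(f"{locus}\t{aln.compartment}\t{fname}")
    (out / "loci.tsv").write_text("\n".join(lines) + "\n")
    write_taxon_map(ds.taxa, out / "samples.tsv")
    return out
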