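"""Aligned-locus data model and IUPAC ambiguity algebra.

The pipeline works on per-locus multiple sequence alignments of IUPAC-coded
consensus sequences, as produced by direct (Sanger) sequencing of population
samples.  A heterozygous individual shows superimposed chromatogram peaks at a
polymorphic column, recorded as the two-fold IUPAC code for the pair of bases;
a hybrid between two taxa that are fixed for different bases therefore shows
the code for the union of the parental bases ("chromatogram additivity").

Coordinates are 1-based throughout, matching how diagnostic sites are reported
in the wet-lab literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

#: IUPAC code -> set of unambiguous bases.  Three-fold codes and N are accepted
#: on input (they can occur in real consensus exports) but can never satisfy a
#: two-parent additivity test; downstream they are classified as "other".
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

ALPHABET = frozenset(IUPAC_TO_BASES) | {GAP}

NUCLEAR = "nuclear"
CHLOROPLAST = "chloroplast"
COMPARTMENTS = (NUCLEAR, CHLOROPLAST)

ROLES = ("parentA", "parentB", "candidate", "other")


class AlignmentError(ValueError):
    """Raised for malformed alignments, unknown characters or bad metadata."""


def expand_iupac(code: str, *, sample: str | None = None,
                 locus: str | None = None, position: int | None = None) -> frozenset[str]:
    """Return the set of unambiguous bases denoted by a single IUPAC code.

    The gap character is a state, not a base, and is rejected here; callers
    that need to treat gaps do so explicitly.  The optional keyword context is
    used to produce an error message naming the offending sample/locus/column.
    """
    try:
        return IUPAC_TO_BASES[code]
    except KeyError:
        ctx = ""
        if sample is not None or locus is not None or position is not None:
            ctx = f" (sample={sample!r}, locus={locus!r}, column={position})"
        raise AlignmentError(f"not a nucleotide IUPAC code: {code!r}{ctx}") from None


def collapse_bases(bases: Iterable[str]) -> str:
    """Inverse of :func:`expand_iupac`: the IUPAC code for a set of bases."""
    key = frozenset(bases)
    if not key:
        raise AlignmentError("cannot collapse an empty base set")
    try:
        return BASES_TO_IUPAC[key]
    except KeyError:
        bad = key - frozenset("ACGT")
        raise AlignmentError(f"not a set of unambiguous bases: {sorted(key)!r}"
                             f" (offending: {sorted(bad)!r})") from None


@dataclass(frozen=True)
class LocusAlignment:
    """One aligned locus with per-sample IUPAC-coded consensus rows.

    Parameters
    ----------
    locus_id:
        Short locus name, e.g. ``"DUF"`` or ``"ndhF"``.
    compartment:
        ``"nuclear"`` or ``"chloroplast"``.
    samples:
        Ordered sample identifiers; one row each.
    rows:
        Mapping sample id -> aligned sequence string (upper case).
    """

    locus_id: str
    compartment: str
    samples: tuple[str, ...]
    rows: Mapping[str, str]
    #: for concatenated alignments: [(locus_id, start, end)] 1-based inclusive
    segments: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise AlignmentError(
                f"unknown compartment {self.compartment!r} for locus {self.locus_id!r}")
        if not self.samples:
            raise AlignmentError(f"locus {self.locus_id!r} has no samples")
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise AlignmentError(f"duplicate sample ids in locus {self.locus_id!r}: {dupes}")
        lengths = {len(self.rows[s]) for s in self.samples}
        if len(lengths) != 1:
            common = max(lengths, key=lambda n: sum(len(self.rows[s]) == n for s in self.samples))
            bad = [s for s in self.samples if len(self.rows[s]) != common]
            raise AlignmentError(
                f"ragged alignment at locus {self.locus_id!r}: samples {bad} differ "
                f"in length from the majority length {common}")
        if lengths == {0}:
            raise AlignmentError(f"locus {self.locus_id!r} has zero aligned columns")
        for s in self.samples:
            row = self.rows[s]
            for i, ch in enumerate(row, start=1):
                if ch not in ALPHABET:
                    raise AlignmentError(
                        f"invalid character {ch!r} (sample={s!r}, "
                        f"locus={self.locus_id!r}, column={i})")

    @property
    def length(self) -> int:
        return len(self.rows[self.samples[0]])

    def row(self, sample: str) -> str:
        try:
            return self.rows[sample]
        except KeyError:
            raise AlignmentError(
                f"sample {sample!r} absent from locus {self.locus_id!r}") from None

    def column(self, position: int) -> dict[str, str]:
        """Characters of every sample at a 1-based column."""
        if not 1 <= position <= self.length:
            raise AlignmentError(
                f"column {position} out of range 1..{self.length} "
                f"for locus {self.locus_id!r}")
        return {s: self.rows[s][position - 1] for s in self.samples}

    def subset(self, samples: Sequence[str]) -> "LocusAlignment":
        return LocusAlignment(self.locus_id, self.compartment, tuple(samples),
                              {s: self.row(s) for s in samples}, self.segments)

    def map_position(self, position: int) -> tuple[str, int]:
        """Map a concatenated 1-based column back to (locus_id, local position)."""
        segments = self.segments or ((self.locus_id, 1, self.length),)
        for locus_id, start, end in segments:
            if start <= position <= end:
                return locus_id, position - start + 1
        raise AlignmentError(f"column {position} outside all segments of {self.locus_id!r}")


@dataclass(frozen=True)
class HetIndel:
    """Sidecar flag: a sample is heterozygous for an indel at locus[start..end].

    Aligned FASTA cannot represent a double-peaked, frame-shifted indel
    heterozygote in one consensus string, so the row carries the full-length
    allele and this flag records that the gapped allele is also present.
    """

    sample: str
    locus_id: str
    start: int
    end: int


@dataclass
class TaxonMap:
    """Sample -> (taxon label, role) assignments plus het-indel sidecar flags."""

    assignments: dict[str, tuple[str, str]]
    het_indels: tuple[HetIndel, ...] = ()

    def __post_init__(self) -> None:
        for sample, (taxon, role) in self.assignments.items():
            if role not in ROLES:
                raise AlignmentError(
                    f"unknown role {role!r} for sample {sample!r}; expected one of {ROLES}")
        for need in ("parentA", "parentB"):
            if not self.samples_with_role(need):
                raise AlignmentError(f"taxon map has no sample with role {need!r}")

    def taxon(self, sample: str) -> str:
        return self.assignments[sample][0]

    def role(self, sample: str) -> str:
        return self.assignments[sample][1]

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s, (_, r) in self.assignments.items() if r == role]

    def samples_of_taxon(self, taxon: str) -> list[str]:
        return [s for s, (t, _) in self.assignments.items() if t == taxon]

    @property
    def taxa(self) -> list[str]:
        seen: list[str] = []
        for taxon, _ in self.assignments.values():
            if taxon not in seen:
                seen.append(taxon)
        return seen

    def taxon_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for taxon, _ in self.assignments.values():
            counts[taxon] = counts.get(taxon, 0) + 1
        return counts

    def het_indels_for(self, sample: str, locus_id: str) -> list[HetIndel]:
        return [h for h in self.het_indels
                if h.sample == sample and h.locus_id == locus_id]

    def validate_against(self, alignments: Iterable[LocusAlignment]) -> None:
        """Every sample of every alignment must carry exactly one assignment."""
        for aln in alignments:
            missing = [s for s in aln.samples if s not in self.assignments]
            if missing:
                raise AlignmentError(
                    f"samples without taxon assignment in locus {aln.locus_id!r}: {missing}")


def read_locus_fasta(path: str | Path, locus_id: str, compartment: str) -> LocusAlignment:
    """Read one aligned FASTA into a validated :class:`LocusAlignment`.

    Headers are sample ids; lower-case input is silently upper-cased.
    """
    samples: list[str] = []
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise AlignmentError(f"duplicate sample id {rec.id!r} in {path}")
        samples.append(rec.id)
        rows[rec.id] = str(rec.seq).upper()
    if not samples:
        raise AlignmentError(f"no FASTA records in {path}")
    return LocusAlignment(locus_id, compartment, tuple(samples), rows)


def write_locus_fasta(aln: LocusAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(aln.rows[s]), id=s, description="") for s in aln.samples]
    SeqIO.write(records, str(path), "fasta")


def read_taxon_map(path: str | Path) -> TaxonMap:
    """Read the sample map TSV: sample_id, taxon, role[, het_indels].

    The optional fourth column lists het-indel flags as
    ``locus:start-end`` joined by commas.
    """
    assignments: dict[str, tuple[str, str]] = {}
    flags: list[HetIndel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "sample_id":  # header
                continue
            if len(parts) < 3:
                raise AlignmentError(f"{path}:{lineno}: expected at least 3 columns")
            sample, taxon, role = parts[0], parts[1], parts[2]
            if sample in assignments:
                raise AlignmentError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = (taxon, role)
            if len(parts) > 3 and parts[3].strip():
                for token in parts[3].split(","):
                    locus, span = token.strip().split(":")
                    start, end = span.split("-")
                    flags.append(HetIndel(sample, locus, int(start), int(end)))
    return TaxonMap(assignments, tuple(flags))


def write_taxon_map(taxa: TaxonMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttaxon\trole\thet_indels\n")
        for sample, (taxon, role) in taxa.assignments.items():
            flags = ",".join(f"{h.locus_id}:{h.start}-{h.end}"
                             for h in taxa.het_indels if h.sample == sample)
            fh.write(f"{sample}\t{taxon}\t{role}\t{flags}\n")


def read_locus_metadata(path: str | Path) -> list[tuple[str, str, str]]:
    """Locus metadata TSV: locus_id, compartment, file (relative to the TSV)."""
    out: list[tuple[str, str, str]] = []
    base = Path(path).parent
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("locus_id\t"):
                continue
            locus_id, compartment, fname = line.split("\t")[:3]
            out.append((locus_id, compartment, str(base / fname)))
    return out


def load_dataset(metadata_path: str | Path, taxon_map_path: str | Path,
                 ) -> tuple[list[LocusAlignment], TaxonMap]:
    """Load all loci named in a metadata TSV plus the taxon map, validated."""
    alignments = [read_locus_fasta(fname, locus_id, compartment)
                  for locus_id, compartment, fname in read_locus_metadata(metadata_path)]
    taxa = read_taxon_map(taxon_map_path)
    taxa.validate_against(alignments)
    return alignments, taxa


def trim_end_gaps(aln: LocusAlignment) -> LocusAlignment:
    """Drop leading/trailing columns where any sample is gapped (missing flanks).

    How ragged sequencing ends were handled upstream is usually unknowable from
    a finished alignment; trimming to the common covered core is the
    conservative option and is exposed rather than silently applied.
    """
    n = aln.length
    start = 0
    while start < n and any(aln.rows[s][start] == GAP for s in aln.samples):
        start += 1
    end = n
    while end > start and any(aln.rows[s][end - 1] == GAP for s in aln.samples):
        end -= 1
    if start == 0 and end == n:
        return aln
    if end <= start:
        raise AlignmentError(f"locus {aln.locus_id!r}: nothing left after end-trimming")
    rows = {s: aln.rows[s][start:end] for s in aln.samples}
    return LocusAlignment(aln.locus_id, aln.compartment, aln.samples, rows)


def concatenate_loci(alignments: Sequence[LocusAlignment],
                     compartment: str | None = None) -> LocusAlignment:
    """Concatenate loci (optionally filtered by compartment) in the given order.

    All member alignments must share the same sample set.  Per-locus offsets
    are recorded so concatenated coordinates map back to (locus, position) via
    :meth:`LocusAlignment.map_position`.
    """
    members = [a for a in alignments
               if compartment is None or a.compartment == compartment]
    if not members:
        raise AlignmentError("no alignments to concatenate"
                             + (f" in compartment {compartment!r}" if compartment else ""))
    ref = set(members[0].samples)
    for a in members[1:]:
        if set(a.samples) != ref:
            raise AlignmentError(
                f"sample-set mismatch between {members[0].locus_id!r} and "
                f"{a.locus_id!r}: {sorted(ref ^ set(a.samples))}")
    if len(members) == 1:
        return members[0]
    samples = members[0].samples
    rows = {s: "".join(a.rows[s] for a in members) for s in samples}
    segments = []
    offset = 0
    for a in members:
        segments.append((a.locus_id, offset + 1, offset + a.length))
        offset += a.length
    joint_id = "+".join(a.locus_id for a in members)
    compartments = {a.compartment for a in members}
    if len(compartments) > 1:
        warnings.warn("concatenating across compartments; result labelled nuclear")
    comp = members[0].compartment if len(compartments) == 1 else NUCLEAR
    return LocusAlignment(joint_id, comp, samples, rows, tuple(segments))
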