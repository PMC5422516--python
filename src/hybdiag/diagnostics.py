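"""Fixed interspecific differences and additivity scoring.

A *fixed substitution* is an alignment column at which every sampled
individual of parent taxon A carries one unambiguous base and every individual
of parent taxon B a different unambiguous base.  A *fixed indel* is a maximal
run of columns at which one parental taxon is entirely gapped and the other
entirely ungapped; a run of two or more columns counts as a single mutational
event.  A candidate hybrid is scored at each diagnostic site: its consensus
character is *additive* when it is the IUPAC code for exactly the union of the
two parental bases, parental-like when it equals one parent's state, and
*other* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .alignments import (
    GAP,
    AlignmentError,
    IUPAC_TO_BASES,
    LocusAlignment,
    TaxonMap,
    expand_iupac,
)

ADDITIVE = "additive"
PARENT_A_LIKE = "parentA_like"
PARENT_B_LIKE = "parentB_like"
HETEROZYGOUS = "heterozygous"
OTHER = "other"


@dataclass(frozen=True, order=True)
class DiagnosticSite:
    """A column fixed-different between the two parental taxa."""

    locus_id: str
    position: int  # 1-based
    base_a: str
    base_b: str

    def __post_init__(self) -> None:
        if self.base_a == self.base_b:
            raise AlignmentError("diagnostic site with identical parental bases")
        for b in (self.base_a, self.base_b):
            if b not in "ACGT":
                raise AlignmentError(f"diagnostic site base must be unambiguous, got {b!r}")

    @property
    def additive_code(self) -> str:
        from .alignments import collapse_bases
        return collapse_bases({self.base_a, self.base_b})


@dataclass(frozen=True, order=True)
class DiagnosticIndel:
    """A maximal gap run fixed between the parental taxa (one event)."""

    locus_id: str
    start: int  # 1-based inclusive
    end: int
    present_in: str  # "parentA" | "parentB": the taxon carrying bases
    inserted_sequence: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise AlignmentError("indel with end < start")
        if self.present_in not in ("parentA", "parentB"):
            raise AlignmentError(f"present_in must name a parent, got {self.present_in!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AdditivityReport:
    """Per-candidate classification at every diagnostic site and indel."""

    sample_id: str
    site_verdicts: dict[tuple[str, int], str] = field(default_factory=dict)
    indel_verdicts: dict[tuple[str, int, int], str] = field(default_factory=dict)

    def _count(self, verdict: str) -> int:
        return sum(1 for v in self.site_verdicts.values() if v == verdict)

    @property
    def n_additive(self) -> int:
        return self._count(ADDITIVE)

    @property
    def n_A(self) -> int:
        return self._count(PARENT_A_LIKE)

    @property
    def n_B(self) -> int:
        return self._count(PARENT_B_LIKE)

    @property
    def n_other(self) -> int:
        return self._count(OTHER)

    @property
    def n_sites(self) -> int:
        return len(self.site_verdicts)


def _parental_samples(aln: LocusAlignment, taxa: TaxonMap, role: str,
                      min_per_taxon: int) -> list[str]:
    samples = [s for s in aln.samples if taxa.role(s) == role]
    if len(samples) < min_per_taxon:
        raise AlignmentError(
            f"locus {aln.locus_id!r}: only {len(samples)} samples with role {role!r}, "
            f"need at least {min_per_taxon}")
    if len(samples) <= 4:
        warnings.warn(
            f"locus {aln.locus_id!r}: only {len(samples)} {role} samples; fixed "
            "differences may be sampling artefacts", stacklevel=3)
    return samples


def _check_min(min_per_taxon: int) -> None:
    if min_per_taxon < 2:
        raise AlignmentError("min_per_taxon below 2 makes 'fixed' meaningless")


def _fixed_state(chars: list[str], missing_tolerance: float) -> str | None:
    """The single state shared by a parental population at one column.

    Returns the base or GAP when the population is monomorphic, else None.
    'N' is missing data: in strict mode (missing_tolerance=0, default) any N
    disqualifies the column; lenient mode ignores up to the given fraction.
    """
    n_missing = sum(1 for c in chars if c == "N")
    if n_missing and n_missing > missing_tolerance * len(chars):
        return None
    called = [c for c in chars if c != "N"]
    if not called:
        return None
    state = called[0]
    if any(c != state for c in called):
        return None
    return state


def find_fixed_substitutions(aln: LocusAlignment, taxa: TaxonMap,
                             min_per_taxon: int = 2,
                             missing_tolerance: float = 0.0,
                             ) -> list[DiagnosticSite]:
    """Columns where parentA and parentB are fixed for different bases.

    A column qualifies only when every parental sample carries the same
    unambiguous base within taxon, the two taxa differ, and no parental sample
    shows a gap or ambiguity code there.  Sorted by position.
    """
    _check_min(min_per_taxon)
    a_samples = _parental_samples(aln, taxa, "parentA", min_per_taxon)
    b_samples = _parental_samples(aln, taxa, "parentB", min_per_taxon)
    sites: list[DiagnosticSite] = []
    for pos in range(1, aln.length + 1):
        a_chars = [aln.rows[s][pos - 1] for s in a_samples]
        b_chars = [aln.rows[s][pos - 1] for s in b_samples]
        state_a = _fixed_state(a_chars, missing_tolerance)
        state_b = _fixed_state(b_chars, missing_tolerance)
        if state_a is None or state_b is None:
            continue
        if state_a in "ACGT" and state_b in "ACGT" and state_a != state_b:
            sites.append(DiagnosticSite(aln.locus_id, pos, state_a, state_b))
    return sites


def find_fixed_indels(aln: LocusAlignment, taxa: TaxonMap,
                      min_per_taxon: int = 2,
                      ) -> list[DiagnosticIndel]:
    """Maximal column runs where one parental taxon is gapped, the other not.

    Each maximal run is one mutational event regardless of its length.  The
    gap run must be identical across every individual of the gapped taxon and
    the other taxon must carry (possibly polymorphic) bases throughout.
    """
    _check_min(min_per_taxon)
    a_samples = _parental_samples(aln, taxa, "parentA", min_per_taxon)
    b_samples = _parental_samples(aln, taxa, "parentB", min_per_taxon)

    def col_status(pos: int, samples: list[str]) -> str:
        chars = {aln.rows[s][pos - 1] for s in samples}
        if chars == {GAP}:
            return "gap"
        if GAP not in chars:
            return "base"
        return "mixed"

    events: list[DiagnosticIndel] = []
    pos = 1
    while pos <= aln.length:
        a_st, b_st = col_status(pos, a_samples), col_status(pos, b_samples)
        fixed = (a_st == "gap" and b_st == "base") or (a_st == "base" and b_st == "gap")
        if not fixed:
            pos += 1
            continue
        gapped_is_a = a_st == "gap"
        start = pos
        while pos + 1 <= aln.length:
            a2, b2 = col_status(pos + 1, a_samples), col_status(pos + 1, b_samples)
            same = (a2 == "gap" and b2 == "base") if gapped_is_a else (a2 == "base" and b2 == "gap")
            if not same:
                break
            pos += 1
        end = pos
        # the run must be maximal *and* clean: a partially-gapped flanking
        # column in the gapped taxon means the gap run is not identical across
        # its individuals, so the event is not fixed
        gapped_samples = a_samples if gapped_is_a else b_samples
        flank_mixed = False
        for flank in (start - 1, end + 1):
            if 1 <= flank <= aln.length and col_status(flank, gapped_samples) == "mixed":
                flank_mixed = True
        if not flank_mixed:
            carrier = b_samples[0] if gapped_is_a else a_samples[0]
            events.append(DiagnosticIndel(
                aln.locus_id, start, end,
                present_in="parentB" if gapped_is_a else "parentA",
                inserted_sequence=aln.rows[carrier][start - 1:end]))
        pos += 1
    return events


def score_additivity(sites: list[DiagnosticSite], indels: list[DiagnosticIndel],
                     alignments: dict[str, LocusAlignment], sample: str,
                     taxa: TaxonMap | None = None) -> AdditivityReport:
    """Classify one candidate at every diagnostic site and indel.

    ``alignments`` maps locus_id -> LocusAlignment containing the candidate.
    The taxon map supplies het-indel sidecar flags; without it a candidate can
    only be scored parental-like or other at indels.
    """
    report = AdditivityReport(sample)
    for site in sites:
        aln = alignments.get(site.locus_id)
        if aln is None:
            raise AlignmentError(f"no alignment supplied for locus {site.locus_id!r}")
        ch = aln.row(sample)[site.position - 1]
        if ch == GAP:
            verdict = OTHER
        else:
            bases = expand_iupac(ch, sample=sample, locus=site.locus_id,
                                 position=site.position)
            if bases == {site.base_a, site.base_b}:
                verdict = ADDITIVE
            elif bases == {site.base_a}:
                verdict = PARENT_A_LIKE
            elif bases == {site.base_b}:
                verdict = PARENT_B_LIKE
            else:
                verdict = OTHER
        report.site_verdicts[(site.locus_id, site.position)] = verdict
    for ev in indels:
        aln = alignments.get(ev.locus_id)
        if aln is None:
            raise AlignmentError(f"no alignment supplied for locus {ev.locus_id!r}")
        row = aln.row(sample)
        segment = row[ev.start - 1:ev.end]
        all_gap = set(segment) == {GAP}
        no_gap = GAP not in segment
        het = False
        if taxa is not None:
            het = any(h.start == ev.start and h.end == ev.end
                      for h in taxa.het_indels_for(sample, ev.locus_id))
        gap_like = PARENT_A_LIKE if ev.present_in == "parentB" else PARENT_B_LIKE
        full_like = PARENT_A_LIKE if ev.present_in == "parentA" else PARENT_B_LIKE
        if het and no_gap:
            verdict = HETEROZYGOUS
        elif all_gap:
            verdict = gap_like
        elif no_gap:
            verdict = full_like
        else:
            verdict = OTHER
        report.indel_verdicts[(ev.locus_id, ev.start, ev.end)] = verdict
    return report


def summarize_fixed_differences(
        per_locus: dict[str, tuple[list[DiagnosticSite], list[DiagnosticIndel]]],
        compartments: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-locus, per-compartment and grand totals of fixed differences.

    Returns a tidy frame with one row per locus plus ``__<compartment>__`` and
    ``__total__`` summary rows.
    """
    rows = []
    comp_totals: dict[str, list[int]] = {}
    total_subs = total_indels = 0
    for locus_id, (sites, indels) in per_locus.items():
        comp = (compartments or {}).get(locus_id, "")
        rows.append({"locus_id": locus_id, "compartment": comp,
                     "n_substitutions": len(sites), "n_indel_events": len(indels)})
        total_subs += len(sites)
        total_indels += len(indels)
        if comp:
            comp_totals.setdefault(comp, [0, 0])
            comp_totals[comp][0] += len(sites)
            comp_totals[comp][1] += len(indels)
    for comp, (s, i) in sorted(comp_totals.items()):
        rows.append({"locus_id": f"__{comp}__", "compartment": comp,
                     "n_substitutions": s, "n_indel_events": i})
    rows.append({"locus_id": "__total__", "compartment": "",
                 "n_substitutions": total_subs, "n_indel_events": total_indels})
    return pd.DataFrame(rows, columns=["locus_id", "compartment",
                                       "n_substitutions", "n_indel_events"])


def sites_to_frame(sites: list[DiagnosticSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"locus_id": s.locus_id, "position": s.position,
          "base_a": s.base_a, "base_b": s.base_b} for s in sites],
        columns=["locus_id", "position", "base_a", "base_b"])


def indels_to_frame(indels: list[DiagnosticIndel]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"locus_id": e.locus_id, "start": e.start, "end": e.end,
          "length": e.length, "present_in": e.present_in,
          "inserted_sequence": e.inserted_sequence} for e in indels],
        columns=["locus_id", "start", "end", "length", "present_in", "inserted_sequence"])


def additivity_to_frame(reports: list[AdditivityReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": r.sample_id, "n_sites": r.n_sites, "n_additive": r.n_additive,
          "n_A": r.n_A, "n_B": r.n_B, "n_other": r.n_other} for r in reports],
        columns=["sample_id", "n_sites", "n_additive", "n_A", "n_B", "n_other"])
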