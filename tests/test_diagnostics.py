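"""Fixed-difference detection against a brute-force oracle, and additivity."""

import random
import warnings

import pytest

from hybdiag.alignments import LocusAlignment, TaxonMap, expand_iupac
from hybdiag.diagnostics import (
    ADDITIVE,
    AlignmentError,
    HETEROZYGOUS,
    OTHER,
    PARENT_A_LIKE,
    PARENT_B_LIKE,
    DiagnosticIndel,
    DiagnosticSite,
    find_fixed_indels,
    find_fixed_substitutions,
    score_additivity,
    summarize_fixed_differences,
)


def make_case(a_rows, b_rows, extra=None):
    rows = {}
    assignments = {}
    for i, r in enumerate(a_rows):
        rows[f"a{i}"] = r
        assignments[f"a{i}"] = ("spA", "parentA")
    for i, r in enumerate(b_rows):
        rows[f"b{i}"] = r
        assignments[f"b{i}"] = ("spB", "parentB")
    for name, r in (extra or {}).items():
        rows[name] = r
        assignments[name] = ("cand", "candidate")
    aln = LocusAlignment("L", "nuclear", tuple(rows), rows)
    return aln, TaxonMap(assignments)


def oracle_fixed_substitutions(aln, taxa):
    """Independent column scan: set comparison per column, no streaming logic."""
    a = [aln.rows[s] for s in aln.samples if taxa.role(s) == "parentA"]
    b = [aln.rows[s] for s in aln.samples if taxa.role(s) == "parentB"]
    out = []
    for pos in range(1, aln.length + 1):
        sa = {r[pos - 1] for r in a}
        sb = {r[pos - 1] for r in b}
        if (len(sa) == 1 and len(sb) == 1 and sa != sb
                and sa <= set("ACGT") and sb <= set("ACGT")):
            out.append((pos, sa.pop(), sb.pop()))
    return out


def oracle_fixed_indels(aln, taxa):
    """Enumerate runs by brute force over every (start, end) interval."""
    a = [aln.rows[s] for s in aln.samples if taxa.role(s) == "parentA"]
    b = [aln.rows[s] for s in aln.samples if taxa.role(s) == "parentB"]

    def is_event(start, end):
        for gapped, full in ((a, b), (b, a)):
            if all(set(r[start - 1:end]) == {"-"} for r in gapped) \
                    and all("-" not in r[start - 1:end] for r in full):
                # maximality + clean flanks within the gapped taxon
                for flank in (start - 1, end + 1):
                    if 1 <= flank <= aln.length:
                        g = {r[flank - 1] for r in gapped}
                        f = {r[flank - 1] for r in full}
                        if g == {"-"} and "-" not in f:
                            return False  # run continues: not maximal
                        if "-" in g and g != {"-"}:
                            return False  # ragged gap boundary
                return True
        return False

    return sorted((s, e) for s in range(1, aln.length + 1)
                  for e in range(s, aln.length + 1) if is_event(s, e))


def test_single_fixed_substitution():
    aln, taxa = make_case(["ACGT", "ACGT"], ["ACCT", "ACCT"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sites = find_fixed_substitutions(aln, taxa)
    assert sites == [DiagnosticSite("L", 3, "G", "C")]


def test_parental_ambiguity_disqualifies():
    aln, taxa = make_case(["ACGT", "ARGT"], ["GCGT", "GCGT"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sites = find_fixed_substitutions(aln, taxa)
    assert [s.position for s in sites] == [1]  # column 2 disqualified by 'R'


def test_parental_n_strict_vs_lenient():
    a = ["ACGT"] * 4 + ["NCGT"]
    b = ["GCGT"] * 5
    aln, taxa = make_case(a, b)
    strict = find_fixed_substitutions(aln, taxa)
    assert [s.position for s in strict] == []
    lenient = find_fixed_substitutions(aln, taxa, missing_tolerance=0.25)
    assert [s.position for s in lenient] == [1]


def test_min_per_taxon_refusal():
    aln, taxa = make_case(["ACGT"], ["GCGT"])
    with pytest.raises(AlignmentError, match="need at least"):
        find_fixed_substitutions(aln, taxa, min_per_taxon=2)
    with pytest.raises(AlignmentError, match="meaningless"):
        find_fixed_substitutions(aln, taxa, min_per_taxon=1)


def test_fixed_indel_single_event():
    aln, taxa = make_case(["AC------GT", "AC------GT"],
                          ["ACTCACATGT", "ACTCACATGT"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        evs = find_fixed_indels(aln, taxa)
    assert len(evs) == 1
    ev = evs[0]
    assert (ev.start, ev.end, ev.length) == (3, 8, 6)
    assert ev.present_in == "parentB"
    assert ev.inserted_sequence == "TCACAT"


def test_ragged_gap_run_is_not_fixed():
    # one parentA sample is gapped at 3-7 only: the run is not identical
    aln, taxa = make_case(["AC-----TGT", "AC------GT"],
                          ["ACTCACATGT", "ACTCACATGT"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        evs = find_fixed_indels(aln, taxa)
    assert evs == oracle_events_as_diagnostics(aln, taxa) == []


def oracle_events_as_diagnostics(aln, taxa):
    return [(s, e) for s, e in oracle_fixed_indels(aln, taxa)]


def test_gap_free_alignment_no_indels():
    aln, taxa = make_case(["ACGT", "ACGT"], ["ACCT", "ACCT"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert find_fixed_indels(aln, taxa) == []


@pytest.mark.parametrize("seed", range(25))
def test_random_alignments_match_oracle(seed):
    """Streaming detectors agree with brute-force scans on small alignments."""
    rng = random.Random(seed)
    length = rng.randint(5, 50)
    n_a, n_b = rng.randint(2, 4), rng.randint(2, 4)

    def rand_row():
        return "".join(rng.choice("ACGT-" if rng.random() < 0.4 else "ACGT")
                       for _ in range(length))

    base_a, base_b = rand_row(), rand_row()

    def mutate(base):
        row = list(base)
        for _ in range(rng.randint(0, 3)):
            row[rng.randrange(length)] = rng.choice("ACGTRYN-")
        return "".join(row)

    aln, taxa = make_case([mutate(base_a) for _ in range(n_a)],
                          [mutate(base_b) for _ in range(n_b)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sites = find_fixed_substitutions(aln, taxa)
        indels = find_fixed_indels(aln, taxa)
    assert [(s.position, s.base_a, s.base_b) for s in sites] \
        == oracle_fixed_substitutions(aln, taxa)
    assert [(e.start, e.end) for e in indels] == oracle_fixed_indels(aln, taxa)


def test_parent_label_swap_symmetry():
    rng = random.Random(99)
    length = 30
    rows_a = ["".join(rng.choice("ACGT-") for _ in range(length))] * 3
    rows_b = ["".join(rng.choice("ACGT-") for _ in range(length))] * 3
    aln, taxa = make_case(rows_a, rows_b)
    swapped = TaxonMap({s: (t, {"parentA": "parentB", "parentB": "parentA"}[r])
                        for s, (t, r) in taxa.assignments.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fwd = find_fixed_substitutions(aln, taxa)
        rev = find_fixed_substitutions(aln, swapped)
    assert [(s.position, s.base_a, s.base_b) for s in fwd] \
        == [(s.position, s.base_b, s.base_a) for s in rev]


def test_additivity_monotone_in_parental_sampling():
    """Adding parental samples can only remove fixed sites, never add them."""
    rng = random.Random(5)
    length = 40
    base_a = "".join(rng.choice("ACGT") for _ in range(length))
    base_b = "".join(rng.choice("ACGT") for _ in range(length))

    def mutate(base):
        row = list(base)
        for _ in range(rng.randint(0, 2)):
            row[rng.randrange(length)] = rng.choice("ACGT")
        return "".join(row)

    prev = None
    for n in (2, 4, 8):
        aln, taxa = make_case([mutate(base_a) for _ in range(n)],
                              [mutate(base_b) for _ in range(n)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            count = len(find_fixed_substitutions(aln, taxa))
        if prev is not None:
            assert count <= prev
        prev = count


def test_score_additivity_verdicts():
    aln, taxa = make_case(["ACGT", "ACGT"], ["GCCT", "GCCT"],
                          extra={"hyb": "RCST", "pa": "ACGT", "odd": "TCNT"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sites = find_fixed_substitutions(aln, taxa)
    by_locus = {"L": aln}
    rep = score_additivity(sites, [], by_locus, "hyb", taxa)
    assert rep.n_additive == 2 and rep.n_other == 0
    rep_pa = score_additivity(sites, [], by_locus, "pa", taxa)
    assert rep_pa.n_A == 2 and rep_pa.n_additive == 0
    rep_odd = score_additivity(sites, [], by_locus, "odd", taxa)
    assert rep_odd.n_other == 2
    assert rep.n_additive + rep.n_A + rep.n_B + rep.n_other == len(sites)
    with pytest.raises(AlignmentError):
        score_additivity(sites, [], by_locus, "missing", taxa)


def test_indel_verdicts_require_sidecar_for_het():
    aln, taxa = make_case(["AC------GT", "AC------GT"],
                          ["ACTCACATGT", "ACTCACATGT"],
                          extra={"h1": "ACTCACATGT", "g1": "AC------GT"})
    from hybdiag.alignments import HetIndel
    taxa.het_indels = (HetIndel("h1", "L", 3, 8),)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        evs = find_fixed_indels(aln, taxa)
    rep = score_additivity([], evs, {"L": aln}, "h1", taxa)
    assert rep.indel_verdicts[("L", 3, 8)] == HETEROZYGOUS
    rep2 = score_additivity([], evs, {"L": aln}, "g1", taxa)
    assert rep2.indel_verdicts[("L", 3, 8)] == PARENT_A_LIKE


def test_summary_totals():
    per_locus = {
        "n1": ([DiagnosticSite("n1", i, "A", "C") for i in range(1, 37)],
               [DiagnosticIndel("n1", 40, 45, "parentB", "TCACAT")]),
        "cp": ([DiagnosticSite("cp", i, "A", "G") for i in range(1, 15)],
               [DiagnosticIndel("cp", j, j, "parentB", "T") for j in (5, 9, 13)]),
    }
    df = summarize_fixed_differences(per_locus, {"n1": "nuclear", "cp": "chloroplast"})
    total = df[df.locus_id == "__total__"].iloc[0]
    assert total.n_substitutions == 50 and total.n_indel_events == 4
    empty = summarize_fixed_differences({})
    assert empty[empty.locus_id == "__total__"].iloc[0].n_substitutions == 0
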