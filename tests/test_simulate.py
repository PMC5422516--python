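"""Synthetic-data generator: determinism, structure, truth-table coherence."""

import pytest

from hybdiag.alignments import CHLOROPLAST, NUCLEAR, AlignmentError
from hybdiag.fixtures import (
    CP_LOCI,
    LOCUS_LENGTHS,
    NUCLEAR_LOCI,
    build_dataset,
    sample_ids,
    write_dataset,
    DIELSIANUS,
    GLAUCOPHYLLUS,
    HYBRID,
)
from hybdiag.simulate import (
    FlowSpec,
    LocusSpec,
    SimulationConfig,
    simulate_dataset,
    study_config,
)


def small_config(seed, **kw):
    loci = [
        LocusSpec("n1", NUCLEAR, 200, 4, indel_lengths=(4,)),
        LocusSpec("n2", NUCLEAR, 180, 3),
        LocusSpec("c1", CHLOROPLAST, 220, 3),
    ]
    defaults = dict(
        seed=seed, loci=loci, sample_sizes={"taxonA": 4, "taxonB": 4},
        haplotype_counts={"taxonA": {"n1": 2}, "taxonB": {"n2": 2}},
        cp_haplotype_counts={"taxonA": 1, "taxonB": 2},
        n_f1_clones=3)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_same_seed_byte_identical(tmp_path):
    d1 = simulate_dataset(small_config(42))
    d2 = simulate_dataset(small_config(42))
    for locus in d1.alignments:
        assert d1.alignments[locus].rows == d2.alignments[locus].rows
    p1, p2 = tmp_path / "run1", tmp_path / "run2"
    d1.write(p1)
    d2.write(p2)
    for f in sorted(p1.iterdir()):
        assert f.read_bytes() == (p2 / f.name).read_bytes()


def test_different_seed_differs():
    d1 = simulate_dataset(small_config(1))
    d2 = simulate_dataset(small_config(2))
    assert any(d1.alignments[l].rows != d2.alignments[l].rows
               for l in d1.alignments)


def test_zero_candidates_parental_only():
    ds = simulate_dataset(small_config(3, n_f1_clones=0))
    roles = {r for _, r in ds.taxa.assignments.values()}
    assert roles == {"parentA", "parentB"}
    assert (ds.truth.role != "candidate").all()


def test_f1_rows_are_iupac_collapses():
    ds = simulate_dataset(small_config(4))
    truth = ds.truth.set_index("sample_id")
    f1 = [s for s in truth.index if truth.loc[s, "true_class"] == "F1"][0]
    aln = ds.alignments["n1"]
    # F1 row must contain at least one two-fold ambiguity code (het site)
    assert any(c in "RYSWKM" for c in aln.rows[f1])
    # clones are byte-identical
    clones = [s for s in truth.index if s.startswith("F1clone")]
    assert len({ds.alignments["n1"].rows[s] for s in clones}) == 1


def test_chloroplast_copied_from_maternal_parent():
    ds = simulate_dataset(small_config(5, maternal="parentB"))
    truth = ds.truth.set_index("sample_id")
    f1 = [s for s in truth.index if s.startswith("F1clone")][0]
    b_rows = {ds.alignments["c1"].rows[s]
              for s in ds.taxa.samples_of_taxon("taxonB")}
    assert ds.alignments["c1"].rows[f1] in b_rows


def test_independent_f1s_get_distinct_genotypes():
    ds = simulate_dataset(small_config(6, n_f1_clones=2, n_independent_f1=2))
    cand = ds.truth[ds.truth.role == "candidate"]
    assert cand.true_clone_group.nunique() == 3  # clones + two singletons


def test_no_shared_parental_haplotypes():
    ds = simulate_dataset(small_config(7))
    for locus, aln in ds.alignments.items():
        a = {aln.rows[s] for s in ds.taxa.samples_of_taxon("taxonA")}
        b = {aln.rows[s] for s in ds.taxa.samples_of_taxon("taxonB")}
        assert not a & b


def test_config_validation():
    with pytest.raises(AlignmentError, match="collide"):
        SimulationConfig(
            seed=1, sample_sizes={"taxonA": 2, "taxonB": 2},
            loci=[LocusSpec("n1", NUCLEAR, 100, 2,
                            substitution_positions=(10, 20),
                            variant_positions={"taxonA": (20,)})])
    with pytest.raises(AlignmentError, match="maternal"):
        SimulationConfig(seed=1, loci=[], sample_sizes={}, maternal="aunt")
    with pytest.raises(AlignmentError, match="disagree"):
        SimulationConfig(
            seed=1, sample_sizes={"taxonA": 2, "taxonB": 2},
            loci=[LocusSpec("n1", NUCLEAR, 100, 3,
                            substitution_positions=(10, 20))])


def test_backcross_needs_multiple_loci():
    cfg = SimulationConfig(
        seed=1, sample_sizes={"taxonA": 3, "taxonB": 3},
        loci=[LocusSpec("n1", NUCLEAR, 150, 4)],
        n_f1_clones=1, n_backcross_a=1)
    with pytest.raises(AlignmentError, match="backcross"):
        simulate_dataset(cfg)


def test_explicit_positions_are_respected():
    cfg = SimulationConfig(
        seed=2, sample_sizes={"taxonA": 3, "taxonB": 3},
        loci=[LocusSpec("n1", NUCLEAR, 120, 2, substitution_positions=(11, 57))])
    ds = simulate_dataset(cfg)
    a = ds.alignments["n1"].rows["taxonA_001"]
    b = ds.alignments["n1"].rows["taxonB_001"]
    diffs = [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]
    assert diffs == [11, 57]


def test_study_config_shape():
    cfg = study_config(seed=1)
    assert len(cfg.loci) == 11
    nuc = [s for s in cfg.loci if s.compartment == NUCLEAR]
    assert sum(s.n_substitutions for s in nuc) == 36
    cp = [s for s in cfg.loci if s.compartment == CHLOROPLAST]
    assert sum(s.n_substitutions for s in cp) == 14
    assert sum(len(s.indel_lengths) for s in cfg.loci) == 4


# ------------------------------------------------- built-in case study

def test_case_study_locus_lengths(case_study):
    for locus, length in LOCUS_LENGTHS.items():
        assert case_study.alignments[locus].length == length


def test_case_study_diagnostic_column_states(case_study):
    duf = case_study.alignments["DUF"]
    col = duf.column(66)
    assert {col[s] for s in sample_ids(DIELSIANUS)} == {"G"}
    assert {col[s] for s in sample_ids(GLAUCOPHYLLUS)} == {"C"}
    assert {col[s] for s in sample_ids(HYBRID)} == {"S"}


def test_case_study_wd_indel_and_sidecar(case_study):
    wd = case_study.alignments["WD"]
    d = sample_ids(DIELSIANUS)[0]
    g = sample_ids(GLAUCOPHYLLUS)[0]
    h = sample_ids(HYBRID)[0]
    assert wd.rows[d][39:45] == "------"
    assert wd.rows[g][39:45] == "TCACAT"
    assert wd.rows[h][39:45] == "TCACAT"
    flags = case_study.taxa.het_indels_for(h, "WD")
    assert [(f.start, f.end) for f in flags] == [(40, 45)]


def test_case_study_round_trips_through_files(tmp_path, case_study):
    from hybdiag.alignments import load_dataset

    out = write_dataset(tmp_path, case_study)
    alignments, taxa = load_dataset(out / "loci.tsv", out / "samples.tsv")
    assert len(alignments) == 11
    by_id = {a.locus_id: a for a in alignments}
    for locus in NUCLEAR_LOCI + CP_LOCI:
        assert by_id[locus].rows == case_study.alignments[locus].rows
    assert taxa.assignments == case_study.taxa.assignments
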