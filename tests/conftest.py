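import warnings

import pytest

from hybdiag.alignments import concatenate_loci
from hybdiag.diagnostics import find_fixed_indels, find_fixed_substitutions
from hybdiag.fixtures import CP_LOCI, NUCLEAR_LOCI, build_dataset
from hybdiag.pipeline import RunConfig, diagnose


@pytest.fixture(scope="session")
def case_study():
    """The built-in Cotoneaster reference dataset (built once per session)."""
    return build_dataset()


@pytest.fixture(scope="session")
def case_nuclear_diagnostics(case_study):
    """Per-locus fixed substitutions and indels for the five nuclear genes."""
    sites, indels = {}, {}
    for locus in NUCLEAR_LOCI:
        aln = case_study.alignments[locus]
        sites[locus] = find_fixed_substitutions(aln, case_study.taxa)
        indels[locus] = find_fixed_indels(aln, case_study.taxa)
    return sites, indels


@pytest.fixture(scope="session")
def case_cp_concat(case_study):
    return concatenate_loci([case_study.alignments[l] for l in CP_LOCI],
                            "chloroplast")


@pytest.fixture(scope="session")
def case_result(case_study):
    """Full pipeline run on the reference dataset."""
    alns = [case_study.alignments[l] for l in NUCLEAR_LOCI + CP_LOCI]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return diagnose(alns, case_study.taxa, RunConfig(phasing_cap=16))
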