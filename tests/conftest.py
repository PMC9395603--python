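import pytest

from cubkit import (
    SyntheticCohortSpec,
    generate_cohort,
    load_reference_table,
)
from cubkit.synthetic import write_cohort


@pytest.fixture(scope="session")
def human_ref():
    return load_reference_table("human")


@pytest.fixture(scope="session")
def cohort47():
    """A 47-gene synthetic cohort under the study's compositional conditions."""
    spec = SyntheticCohortSpec(n_genes=47, seed=11)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def cohort47_fasta(cohort47, tmp_path_factory):
    spec, genes = cohort47
    d = tmp_path_factory.mktemp("cohort")
    path = d / "cohort.fasta"
    write_cohort(genes, spec, path, d / "manifest.json")
    return path
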