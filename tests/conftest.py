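import pytest

from prophagekit.curation import curate_chromosome
from prophagekit.lm41 import build_lm41_fixture
from prophagekit.model import filter_promoters


@pytest.fixture(scope="session")
def lm41():
    return build_lm41_fixture()


@pytest.fixture(scope="session")
def lm41_curated(lm41):
    return curate_chromosome(
        lm41.chromosome, hits=lm41.hits, completeness=lm41.completeness
    )


@pytest.fixture(scope="session")
def lm41_confirmed(lm41_curated):
    return {rec.name: rec for rec in lm41_curated if rec.confirmed}


@pytest.fixture(scope="session")
def lm41_promoters(lm41):
    return filter_promoters(lm41.promoters)


@pytest.fixture(scope="session")
def lm41_files(lm41, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("lm41_bundle")
    return lm41.write(outdir)
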