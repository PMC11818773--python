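import pytest
from hypothesis import HealthCheck, settings

import lamaspectrum as ls

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_rows():
    """The packaged 75-variant national-cohort table."""
    return ls.load_fixture()


@pytest.fixture(scope="session")
def fixture_variants(fixture_rows):
    return [
        ls.describe_variant(r.cdna, r.protein, r.region_label)
        for r in fixture_rows.itertuples()
    ]


@pytest.fixture(scope="session")
def fixture_spectrum(fixture_rows):
    return ls.build_spectrum(fixture_rows, n_patients=90)


@pytest.fixture()
def toy_model():
    """Two-exon toy transcript: exon 1 = 1..100, exon 2 = 101..250."""
    return ls.GeneModel("toy", ((1, 1, 100), (2, 101, 250)))
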