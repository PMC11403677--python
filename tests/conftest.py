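import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table_series():
    """All 27 measured tension-concentration series, keyed (plastic, pollutant)."""
    from bilayermech.synthetic import table_fixtures

    return table_fixtures()


@pytest.fixture(scope="session")
def table_fits(table_series):
    """Per-series stretching-model fits of all 27 packaged series."""
    from bilayermech.stretching import fit_tension_series

    return {key: fit_tension_series(s) for key, s in table_series.items()}
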