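import pytest
from hypothesis import HealthCheck, settings

from castevar import SimulationConfig, generate_reference
from castevar.selection import build_coding_table
from castevar.simulate import prepare_sites

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    """A desk-sized study: 40 short transcripts, 2000 variants/library."""
    return SimulationConfig(
        n_transcripts=40,
        orf_codons_range=(30, 80),
        utr_len_range=(5, 40),
        variants_per_library=2000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """(reference, design, coding_table, site prep) for the small config."""
    reference, design = generate_reference(small_config)
    coding_table = build_coding_table(reference)
    prep = prepare_sites(reference, small_config, coding_table)
    return reference, design, coding_table, prep
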