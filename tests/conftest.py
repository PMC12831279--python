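"""Shared fixtures and hypothesis configuration for the test suite."""
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from buildaudit.syngen import GenerationConfig, simulate  # noqa: E402


def small_config(**over) -> GenerationConfig:
    base = dict(
        counts={"multi_exon": 8, "true_intronless": 3, "cds_intronless": 3,
                "selenoprotein": 3, "readthrough_parent": 2},
        cds_codons=(80, 200),
        intron_len=(120, 800),
        intergenic_len=(500, 1500),
    )
    base.update(over)
    return GenerationConfig(**base)


@pytest.fixture(scope="session")
def small_truth():
    """A 19-gene truth set covering every generated gene class."""
    return simulate(small_config(), 7)
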