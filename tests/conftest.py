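import pytest
from hypothesis import HealthCheck, settings

from qrsqtc import load_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort():
    """The packaged 16-case series."""
    return load_cohort("packaged")


@pytest.fixture(scope="session")
def ratio_groups(cohort):
    """Printed-precision QRS/QTc values split by VT/VF outcome (yes, no)."""
    yes, no = cohort.split_by_outcome()
    return (
        yes.values("ratio", printed_precision=True),
        no.values("ratio", printed_precision=True),
    )
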