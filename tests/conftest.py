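from hypothesis import HealthCheck, settings
import pytest

from costcontrol import CostOfControlModel, load_reference_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_dataset():
    """SUSTAIN 7 responder shares + SISMED 2021 prices, as packaged."""
    return load_reference_dataset()


@pytest.fixture(scope="session")
def base_results(reference_dataset):
    """Fitted base case under the table-reproducing conventions."""
    return CostOfControlModel(reference_dataset).fit()
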