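import pytest
from hypothesis import HealthCheck, settings as hsettings

from ceatree import DecisionModel, calibrated_acl_model

hsettings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
hsettings.load_profile("default")


@pytest.fixture(scope="session")
def acl():
    """Calibrated ACL model: (tree, params, settings)."""
    return calibrated_acl_model()


@pytest.fixture(scope="session")
def acl_model(acl):
    tree, params, settings = acl
    return DecisionModel(tree, settings), params
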