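import pytest

from sealpatch import BehaviorParams
from sealpatch.synthetic import default_params

BEHAVIORS = ("stop", "rolling", "flapping", "sliding")


def noiseless_params(label: str, noise_sd_v: float = 0.0) -> BehaviorParams:
    """Default params for a label with the noise level overridden."""
    p = default_params(label)
    return BehaviorParams(
        label=p.label,
        carrier_freq_hz=p.carrier_freq_hz,
        amplitude_v=p.amplitude_v,
        baseline_v=p.baseline_v,
        noise_sd_v=noise_sd_v,
        dvdt_shape=p.dvdt_shape,
    )


@pytest.fixture(params=BEHAVIORS)
def behavior_label(request):
    return request.param
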