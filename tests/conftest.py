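import numpy as np
import pytest

from tmdscreen import DoseResponseSeries, HillParams

STANDARD_DOSES = (0.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0)


@pytest.fixture
def true_params() -> HillParams:
    return HillParams(c=1.0, k=50.0, g=3.0)


@pytest.fixture
def noiseless_series(true_params) -> DoseResponseSeries:
    y = true_params.predict(np.array(STANDARD_DOSES))
    return DoseResponseSeries(
        pair_id="GpA_+1/GpA_+1",
        replicate_id="rep1",
        concentrations=STANDARD_DOSES,
        responses=tuple(y),
    )


def make_noisy_series(true: HillParams, seed: int, noise_sd: float = 0.05,
                      pair_id: str = "sim", replicate_id: str = "rep1"):
    rng = np.random.default_rng(seed)
    x = np.array(STANDARD_DOSES)
    y = np.clip(true.predict(x) + rng.normal(0.0, noise_sd, x.shape), 0.0, None)
    return DoseResponseSeries(
        pair_id=pair_id, replicate_id=replicate_id,
        concentrations=STANDARD_DOSES, responses=tuple(y),
    )
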