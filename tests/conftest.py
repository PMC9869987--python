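import numpy as np
import pytest

import ciberlite as cl


@pytest.fixture(scope="session")
def instrument():
    return cl.raa_instrument("not drinking any coffee at all in the next month")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230119)


@pytest.fixture(scope="session")
def small_dataset(instrument):
    """Moderate-n single-behavior Likert dataset with real structure."""
    corr = cl.raa_latent_corr(instrument, det_target_r={"attitude": 0.5, "perceived_norm": 0.3, "pbc": 0.15})
    cond = cl.BehaviorCondition(
        label="coffee",
        item_means={i: 3.0 for i in instrument.item_ids},
        latent_corr=corr,
    )
    spec = cl.SyntheticResponseSpec(
        n_respondents=400, instrument=instrument, behaviors=(cond,), seed=42
    )
    return cl.simulate_responses(spec)


@pytest.fixture(scope="session")
def expert_set():
    cells = tuple((f"b{i}", d) for i in range(8) for d in ("attitude", "perceived_norm", "pbc"))
    spec = cl.SyntheticExpertSpec(
        n_experts=45,
        cells=cells,
        true_means=tuple([3.0] * 24),
        sds=tuple([1.0] * 24),
        seed=7,
    )
    return cl.simulate_expert_estimates(spec)
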