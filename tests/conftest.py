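import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240521)


@pytest.fixture(scope="session")
def small_pair():
    """One deterministic synthetic pair at 32^3 with a known true field."""
    from voxreg import PhantomParams, make_registration_pair

    return make_registration_pair(
        PhantomParams(shape=(32, 32, 32), noise_sd=0.02, seed=7), amplitude=2.0
    )


@pytest.fixture(scope="session")
def trained_runs():
    """Two scaled-down training runs (lambda=1 and lambda=0) sharing seeds.

    Study conditions: 8 synthetic 32^3 pairs with peak displacement 3 voxels,
    one validation pair, one held-out evaluation pair, 30 epochs of Adam at
    learning rate 1e-4, batch size 1.  Shared across the end-to-end tests
    because each run takes minutes of CPU.
    """
    from voxreg import (
        DeformableRegistration,
        LossConfig,
        PhantomParams,
        make_registration_pair,
    )

    seed = 42
    held_out = make_registration_pair(
        PhantomParams(shape=(32, 32, 32), seed=seed + 100 * 9), amplitude=3.0
    )
    results = {}
    for lam in (1.0, 0.0):
        model = DeformableRegistration.from_synthetic(
            n_pairs=8,
            n_val=1,
            shape=(32, 32, 32),
            amplitude=3.0,
            seed=seed,
            loss_config=LossConfig(lambda_reg=lam),
        )
        results[lam] = model.fit(epochs=30, seed=seed)
    return {"results": results, "held_out": held_out, "seed": seed}
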