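import numpy as np
import pytest

import hteyield as hy
from hteyield.model import ModelConfig


@pytest.fixture(scope="session")
def tiny_spec():
    """A 2 x 2 x 2 x 1 combinatorial screen with an ABSENT ligand option."""
    return hy.FixtureSpec(
        roles={
            "halide": ["Clc1ccccn1", "Brc1ccccn1"],
            "additive": ["Cc1ccon1", "c1cc(on1)C"],
            "ligand": ["c1ccc(P(c2ccccc2)c2ccccc2)cc1", "none"],
            "base": ["CCN(CC)CC"],
        },
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_ds(tiny_spec):
    ds, _ = hy.generate_fixture(tiny_spec)
    return ds


@pytest.fixture(scope="session")
def additive_ds():
    """400-reaction zero-noise purely additive fixture plus its truth."""
    return hy.generate_fixture(hy.small_additive_spec(noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def bhc_ds():
    """BHC-shaped 15 x 22 x 4 x 3 = 3960 reaction fixture."""
    ds, _ = hy.generate_fixture(hy.bhc_like_spec(seed=0))
    return ds


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down architecture for fast tests."""
    return ModelConfig(
        d_embed=16,
        d_hidden=16,
        L=2,
        N=1,
        n_heads=2,
        d_mlp=16,
        dropout=0.0,
        lr=3e-3,
        batch_size=16,
        max_epochs=30,
        patience=30,
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_ds, small_cfg):
    """A model trained briefly on the tiny fixture (shared, read-only)."""
    import dataclasses

    cfg = dataclasses.replace(small_cfg, max_epochs=5, patience=5)
    return hy.train_model(tiny_ds, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
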