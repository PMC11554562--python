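import numpy as np
import pytest

from discell import (
    Attribute,
    AttributePlan,
    AttributeSchema,
    CellDataset,
    DisentanglementModel,
    LatentSpec,
    SyntheticConfig,
    generate,
)


@pytest.fixture
def tiny_schema():
    return AttributeSchema((
        Attribute("cell_type", "categorical", categories=("typeA", "typeB")),
        Attribute("dose", "ordered", dim=1),
    ))


@pytest.fixture
def tiny_ds(tiny_schema):
    x = np.array([[1.0, 0.0, 3.0],
                  [2.0, 5.0, 0.0],
                  [0.0, 1.0, 1.0],
                  [4.0, 2.0, 2.0]])
    return CellDataset(
        x=x,
        schema=tiny_schema,
        attribute_values={
            "cell_type": np.array(["typeA", "typeB", "typeA", "typeB"], dtype=object),
            "dose": np.array([[0.0], [0.5], [1.0], [0.5]]),
        },
        cell_ids=["c1", "c2", "c3", "c4"],
        feature_names=["g1", "g2", "g3"],
    )


def small_config(seed=3, **kw):
    defaults = dict(
        n=300,
        m=60,
        attributes=[
            AttributePlan("status", "categorical", range(0, 15), 1.0,
                          categories=("control", "perturbed")),
            AttributePlan("dose", "ordered", range(15, 30), 0.8),
        ],
        seed=seed,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


def small_spec(**kw):
    defaults = dict(n_latent_attr=8, n_latent_u=8, encoder_width=32,
                    decoder_width=64, family="zinb")
    defaults.update(kw)
    return LatentSpec(**defaults)


@pytest.fixture(scope="session")
def small_data():
    return generate(small_config())


@pytest.fixture(scope="session")
def small_results(small_data):
    ds, _ = small_data
    return DisentanglementModel(ds, small_spec()).fit(epochs=120, batch_size=128,
                                                      seed=0)
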