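import numpy as np
import pytest

from mnporigin.chem_io import LabeledDataset
from mnporigin.encoder import EncoderConfig, finetune, pretrain
from mnporigin.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def ds_small():
    """120 separable molecules (60/30/30), fixed seed."""
    return generate_dataset(SyntheticSpec(n_per_class={0: 60, 1: 30, 2: 30}, seed=3))


@pytest.fixture(scope="session")
def ds_medium():
    """400 separable molecules (200/100/100), fixed seed."""
    return generate_dataset(SyntheticSpec(n_per_class={0: 200, 1: 100, 2: 100}, seed=7))


@pytest.fixture(scope="session")
def small_config():
    return EncoderConfig(hidden_dim=32, epochs=12, seed=11)


@pytest.fixture(scope="session")
def pretrained_model(ds_small, small_config):
    animalia = ds_small.select_label(0)
    pool = LabeledDataset([r for r in ds_small if r.label != 0])
    return pretrain(animalia, pool, small_config)


@pytest.fixture(scope="session")
def tuned_model(pretrained_model, ds_small):
    return finetune(pretrained_model, ds_small)
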