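import numpy as np
import pytest

from dtakit.interaction_model import CrossAttentionRegressor, ModelConfig
from dtakit.presets import (
    desk_scale_model_config,
    desk_scale_training_config,
    interpretability_benchmark_spec,
)
from dtakit.splits import make_entity_cold_split
from dtakit.synthetic_data import SyntheticSpec, generate_benchmark
from dtakit.training import train_model


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark (seed 0): records, dictionaries, truth."""
    return generate_benchmark(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def tiny_model():
    """Small untrained model in inference mode for contract tests."""
    model = CrossAttentionRegressor(
        ModelConfig(d_model=16, n_heads=2, head_widths=(16,), dropout=0.0, seed=7)
    )
    model.eval()
    return model


@pytest.fixture(scope="session")
def trained_benchmark_model():
    """Desk-scale model trained on the entity-rich planted-motif benchmark
    under a protein-cold split, so it must carry the transferable motif
    feature; shared by the interpretability and screening recovery tests."""
    records, dicts, truth = generate_benchmark(interpretability_benchmark_spec(0))
    split = make_entity_cold_split(records, dicts, "protein", seed=0)
    model = CrossAttentionRegressor(desk_scale_model_config(0))
    model, history = train_model(
        model, records, dicts, split, desk_scale_training_config(0)
    )
    return {
        "model": model,
        "records": records,
        "dicts": dicts,
        "truth": truth,
        "split": split,
        "history": history,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
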