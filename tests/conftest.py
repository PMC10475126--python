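import numpy as np
import pytest

from beoff.deepmodel import ModelConfig, PairDataset, group_kfold, train_model
from beoff.synthetic_data import GeneratorConfig, benchmark_dataset, generate_screen


@pytest.fixture(scope="session")
def small_screen(tmp_path_factory):
    """A small synthetic screen with reads: 6 groups, 5% barcode corruption."""
    outdir = tmp_path_factory.mktemp("screen")
    config = GeneratorConfig(seed=3, n_groups=6, barcode_corruption_rate=0.05)
    art = generate_screen(config, outdir=outdir)
    art["config"] = config
    return art


@pytest.fixture(scope="session")
def trained_benchmark():
    """The synthetic parameter-recovery benchmark: 250 groups, one held-out
    fold, the reduced model trained to convergence. Shared session-wide
    because training dominates the suite's runtime."""
    gen = GeneratorConfig(seed=1, n_groups=250)
    pairs, eff = benchmark_dataset(gen)
    dataset = PairDataset(pairs, eff["off_on_ratio"].to_numpy(),
                          groups=eff["group_id"].to_numpy())
    train_idx, test_idx = group_kfold(dataset.groups, n_splits=10, seed=0)[0]
    config = ModelConfig.small(seed=0)
    model, log = train_model(dataset, (train_idx, test_idx), config)
    return {
        "generator_config": gen,
        "dataset": dataset,
        "efficiencies": eff,
        "split": (train_idx, test_idx),
        "model": model,
        "log": log,
    }
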