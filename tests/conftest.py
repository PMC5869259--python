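import numpy as np
import pandas as pd
import pytest

from rifnet import de as de_mod
from rifnet.normalize import (
    compute_rpkm,
    extract_normalized,
    fit_mixed_model,
    log2_transform,
)
from rifnet.simulate import SimulationConfig, simulate_experiment


def run_normalization(cfg: SimulationConfig, tissue: str = "t1"):
    """Simulate -> RPKM -> log2 -> mixed model -> normalized values."""
    cm, design, tfs, truth = simulate_experiment(cfg)
    y = log2_transform(compute_rpkm(cm))
    fit = fit_mixed_model(y, design)
    norm = extract_normalized(fit, design, tissue)
    return cm, design, tfs, truth, fit, norm


@pytest.fixture(scope="session")
def small_experiment():
    """One mid-sized seeded experiment shared by read-only tests."""
    cfg = SimulationConfig(
        n_genes=120, n_tf=20, prop_de=0.2, de_effect=2.0, n_tissues=2,
        n_libraries=28, n_planted_regulators=2, wiring_shift=1.0, seed=42,
    )
    cm, design, tfs, truth, fit, norm = run_normalization(cfg)
    de_table = de_mod.build_de_table(norm)
    return {
        "config": cfg, "counts": cm, "design": design, "tf_list": tfs,
        "truth": truth, "fit": fit, "norm": norm, "de_table": de_table,
    }


def make_normalized(values: pd.DataFrame, states: dict):
    """Assemble a NormalizedExpression directly from a value matrix."""
    from rifnet.normalize import NormalizedExpression

    animal_states = pd.Series(states)
    state_means = pd.DataFrame(
        {
            s: values.loc[:, animal_states.index[animal_states == s]].mean(axis=1)
            for s in ("pre", "post")
        }
    )
    return NormalizedExpression(
        values=values, animal_states=animal_states,
        state_means=state_means, tissue="t1",
    )


def random_correlation(n: int, n_samples: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(n, n_samples))
    r = np.clip(np.corrcoef(data), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    ids = [f"n{i:03d}" for i in range(n)]
    return pd.DataFrame(r, index=ids, columns=ids)
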