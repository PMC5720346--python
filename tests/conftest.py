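import numpy as np
import pandas as pd
import pytest

from replisig import ExpressionStudy, SimConfig, generate_two_studies


@pytest.fixture(scope="session")
def planted_pair():
    """Small two-study simulation with a planted shared signal."""
    cfg = SimConfig(
        n_genes=600,
        n_cases=(40, 40),
        n_controls=(40, 40),
        n_shared_de=60,
        n_specific_de=(15, 15),
        seed=11,
    )
    s1, s2, truth = generate_two_studies(cfg)
    return s1, s2, truth, cfg


@pytest.fixture()
def toy_study():
    """Deterministic 8-sample study builder for design/scoring tests."""

    def build(expression: np.ndarray, gene_ids=None, n_cases=4, **meta_overrides):
        expression = np.atleast_2d(np.asarray(expression, dtype=float))
        n_genes, n = expression.shape
        gene_ids = gene_ids or [f"g{i}" for i in range(1, n_genes + 1)]
        sample_ids = [f"s{j}" for j in range(1, n + 1)]
        rng = np.random.default_rng(1234)
        batch = np.tile([1, 2], (n + 1) // 2)[:n]
        sex = np.where(rng.integers(0, 2, n) == 1, "female", "male")
        anxiety = rng.integers(0, 2, n)
        meta = pd.DataFrame(
            {
                "group": ["case"] * n_cases + ["control"] * (n - n_cases),
                "batch": batch,
                "sex": sex,
                "age": np.linspace(25, 60, n),
                "anxiety": anxiety,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        for key, val in meta_overrides.items():
            meta[key] = val
        return ExpressionStudy(
            pd.DataFrame(expression, index=gene_ids, columns=sample_ids),
            meta,
            name="toy",
        )

    return build
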