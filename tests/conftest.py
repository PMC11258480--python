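import numpy as np
import pandas as pd
import pytest

from epistax.diffexpr import ContrastResult
from epistax.simulate import CountMatrix, InteractionModel, simulate_counts, simulate_effects


@pytest.fixture
def null_counts():
    """3v3v3v3 genotype design with all true effects zero (BCV 0.1)."""
    model = InteractionModel("additive", noise_sd=0.0)
    effects = simulate_effects(model, 400, 1.0, seed=42)
    effects.beta_a[:] = 0.0
    effects.beta_b[:] = 0.0
    effects.beta_ab[:] = 0.0
    return simulate_counts(effects, n_reps=3, depth_mean=200.0, bcv=0.1, seed=43)


@pytest.fixture
def toy_counts():
    """Tiny hand-checkable count matrix with WT/A singleton samples."""
    counts = pd.DataFrame(
        {
            "WT_r1": [10, 100, 40, 5],
            "A_r1": [10, 50, 10, 5],
        },
        index=pd.Index([f"g{i}" for i in range(4)], name="feature"),
    )
    meta = pd.DataFrame(
        {"genotype": ["WT", "A"], "replicate": [1, 1], "batch": ["b0", "b0"]},
        index=pd.Index(["WT_r1", "A_r1"], name="sample"),
    )
    return CountMatrix(counts=counts, sample_meta=meta)


def make_contrast(feature_ids, beta=None, p=None, q=None):
    """ContrastResult with sensible defaults for fields a test ignores."""
    n = len(feature_ids)
    beta = np.zeros(n) if beta is None else np.asarray(beta, float)
    p = np.full(n, 0.5) if p is None else np.asarray(p, float)
    q = p.copy() if q is None else np.asarray(q, float)
    return ContrastResult(
        feature_ids=list(feature_ids),
        beta=beta,
        se=np.ones(n),
        p=p,
        q=q,
        is_deg=np.zeros(n, bool),
    )
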