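import numpy as np
import pandas as pd
import pytest

from mccrewire import synthetic
from mccrewire.data import ExpressionMatrix
from mccrewire.signature import build_signature, marker_correlation_scores


def make_expr(values, genes=None, samples=None, condition="A", time_hours=None):
    """Tiny ExpressionMatrix builder for hand-computed toys."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    meta = pd.DataFrame({
        "condition": [condition] * len(samples),
        "time_hours": time_hours if time_hours is not None else [0] * len(samples),
        "replicate": list(range(1, len(samples) + 1)),
    }, index=pd.Index(samples, name="sample"))
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta)


@pytest.fixture(scope="session")
def cohort():
    return synthetic.gen_cohort(seed=0)


@pytest.fixture(scope="session")
def cohort_signature(cohort):
    expr, _ = cohort
    scores = marker_correlation_scores(expr, list(synthetic.DEFAULT_MARKERS))
    return build_signature(scores, n_per_tail=500)


@pytest.fixture(scope="session")
def timecourse():
    return synthetic.gen_timecourse(seed=21)


@pytest.fixture(scope="session")
def small_priors():
    cfg = synthetic.PriorConfig(n_tfs=5, n_genes=40)
    return synthetic.gen_network_priors(cfg, seed=5)
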