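import numpy as np
import pandas as pd
import pytest

import dielgate as dg


@pytest.fixture(scope="session")
def strong_sim():
    """Default strong-effect simulation (2,000 genes, 4 reps/group), filtered."""
    cfg = dg.SimulationConfig(seed=1)
    cm, truth = dg.simulate_experiment(cfg)
    cm = dg.filter_low_counts(cm, 10)
    return cm, truth.loc[cm.genes]


@pytest.fixture(scope="session")
def strong_de(strong_sim):
    """All three analyses on the strong-effect simulation."""
    cm, _ = strong_sim
    factors = dg.size_factors(cm)
    disp = dg.estimate_dispersions(cm, factors)
    kw = dict(factors=factors, dispersions=disp)
    return {
        "de1": dg.run_analysis1(cm, **kw),
        "de2": dg.run_analysis2(cm, **kw),
        "de3": dg.run_analysis3(cm, **kw),
    }


@pytest.fixture
def tiny_counts():
    """2-gene x 4-sample CountMatrix with a hand-written sample sheet."""
    counts = pd.DataFrame(
        {
            "s1": [5, 0],
            "s2": [7, 1],
            "s3": [6, 2],
            "s4": [8, 3],
        },
        index=["geneA", "geneB"],
    )
    samples = pd.DataFrame(
        {
            "time": ["AM", "AM", "PM", "PM"],
            "condition": ["control", "heat", "control", "heat"],
            "replicate": [1, 1, 1, 1],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )
    return dg.CountMatrix(counts, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
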