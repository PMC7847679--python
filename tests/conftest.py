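import numpy as np
import pandas as pd
import pytest

import cnacircuits as cc


def small_config(seed=5, **overrides):
    """A scaled-down study for fast structural tests: 24 tumors + 4 normals,
    2 chromosomes, 4 planted peaks, 2 circuits."""
    kwargs = dict(
        n_per_grade={"II": 8, "III": 8, "IV": 8},
        n_normal=4,
        n_chrom=2,
        n_enhancers=30,
        n_genes=50,
        n_tfs=4,
        n_peaks=4,
        n_circuits=2,
        n_prognostic=2,
    )
    kwargs.update(overrides)
    return cc.default_config(seed=seed, **kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return cc.generate_cohort(small_config(seed=5))


@pytest.fixture(scope="session")
def strong_cohort():
    """The default strong-effect study used for planted-truth recovery."""
    return cc.generate_cohort(cc.default_config(seed=11))


@pytest.fixture(scope="session")
def strong_results(strong_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("strong_run")
    cfg = cc.PipelineConfig(seed=11)
    results = cc.run_pipeline(strong_cohort, cfg, out)
    report = cc.evaluate_run(strong_cohort, results, permutation_B=2000, seed=11)
    return results, report


def expression_matrix(values, samples=None, grades=None, features=None):
    """Helper to build an ExpressionMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    features = features or [f"F{i}" for i in range(n_feat)]
    samples = samples or [f"S{i}" for i in range(n_samp)]
    grades = grades or ["II"] * n_samp
    return cc.ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples),
        pd.Series(grades, index=samples),
    )
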