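import numpy as np
import pandas as pd
import pytest

from raven import effects, regmap, synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.CohortConfig(
        seed=7,
        n_cases=150,
        n_controls=150,
        n_variants=1500,
        n_genes=40,
        n_peaks=150,
    )


@pytest.fixture(scope="session")
def cohort(small_config):
    return synthetic.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def effect_calls(cohort):
    thresholds, calls = effects.classify_effect_variants(cohort.scores)
    return thresholds, calls


@pytest.fixture(scope="session")
def assignment(cohort):
    abc = regmap.compute_abc_links(cohort.scaffold.peaks, cohort.scaffold.genes)
    empty = pd.DataFrame(columns=["peak_id", "gene_id", "tier", "score", "fdr"])
    return regmap.assign_target_genes(
        cohort.scaffold.peaks, abc, empty, cohort.scaffold.peaks,
        cohort.scaffold.genes,
    )


@pytest.fixture(scope="session")
def triplets(cohort, effect_calls, assignment):
    _, calls = effect_calls
    return regmap.map_variants_to_genes(
        calls, cohort.variants, cohort.scaffold.peaks, assignment
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
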