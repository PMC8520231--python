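import numpy as np
import pandas as pd
import pytest

from bemkit.containers import CountMatrix
from bemkit.synthdata import RefSimConfig, StudyMixConfig, gen_reference_counts, gen_study_counts


@pytest.fixture(scope="session")
def low_noise_reference():
    """2000-gene two-population reference with 100+100 planted genes at FC 4."""
    cfg = RefSimConfig(
        n_genes=2000, n_sig_a=100, n_sig_b=100, effect_fc=4.0, dispersion=0.05, seed=101
    )
    return gen_reference_counts(cfg)


@pytest.fixture(scope="session")
def study_with_mixture(low_noise_reference):
    """Four-group study whose engrafted group blends both reference profiles."""
    _, truth = low_noise_reference
    study, cfg = gen_study_counts(truth, StudyMixConfig(dispersion=0.05, seed=202))
    return study, cfg, truth


def make_counts(values: dict[str, list[float]], groups: dict[str, str]) -> CountMatrix:
    """Tiny hand-built count matrix; values keyed by sample id."""
    df = pd.DataFrame(values)
    df.index = pd.Index([f"g{i}" for i in range(len(df))], name="gene_id")
    return CountMatrix(df, pd.Series(groups))


def reorder_samples(cm: CountMatrix, sample_order: list[str]) -> CountMatrix:
    return CountMatrix(cm.values[sample_order], cm.sample_groups.loc[sample_order])
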