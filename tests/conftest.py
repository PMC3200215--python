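import numpy as np
import pandas as pd
import pytest

from lfqpipe import PipelineConfig, SyntheticConfig, load_table_fixtures
from lfqpipe import normalization as N
from lfqpipe import quantify as Q
from lfqpipe.synthetic import generate_peptide_table


@pytest.fixture(scope="session")
def fixtures():
    return load_table_fixtures()


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated study with defaults: 8 vs 5 samples, 2 replicates."""
    cfg = SyntheticConfig(n_proteins=60, frac_changed=0.2, seed=123)
    table, truth = generate_peptide_table(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def quantified(small_dataset):
    """Results of the normalize -> rollup -> ANOVA chain on small_dataset."""
    _, table, truth = small_dataset
    matrix = N.peptide_table_to_matrix(table)
    design = Q.StudyDesign(N.injection_design(table))
    normed = N.quantile_normalize(N.log2_transform(matrix))
    protein = Q.rollup_protein(normed)
    results = Q.quantify_proteins(protein, design)
    return results, truth, design, protein
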