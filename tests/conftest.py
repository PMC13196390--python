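import logging

import numpy as np
import pandas as pd
import pytest

from pepwire import (AnalysisConfig, IntensityMatrix, SampleDesign,
                     SimulationConfig, simulate_study)
from pepwire.pipeline import run_differential

logging.getLogger("pepwire").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def design():
    return SampleDesign.default()


@pytest.fixture(scope="session")
def analysis():
    return AnalysisConfig()


def small_sim_config(**overrides) -> SimulationConfig:
    """A reduced study: 3 motifs per mechanism, a few hundred background
    features — fast enough for per-test regeneration."""
    defaults = dict(n_background_nodes=30, n_motifs_per_mechanism=3,
                    n_background_peptides=200, n_background_phospho_peptides=10,
                    n_background_proteins=80, n_background_phosphosites=120,
                    n_planted_taas=10, n_decoy_shared=15, n_cta_proteins=3,
                    rng_seed=11)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_sim_config())


@pytest.fixture(scope="session")
def noiseless_study():
    """Zero replicate noise and no missingness: planted effects are exact."""
    return simulate_study(small_sim_config(replicate_noise_sd=0.0,
                                           missing_p_max=0.0, rng_seed=13))


@pytest.fixture(scope="session")
def noiseless_diffs(noiseless_study, analysis):
    results, _ = run_differential(noiseless_study.matrices, analysis, seed=13)
    return results


def build_matrix(values, design: SampleDesign, layer="immunopeptidome",
                 scale="log2", feature_ids=None) -> IntensityMatrix:
    """Matrix from a 2-D array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    if feature_ids is None:
        feature_ids = [f"F{i}" for i in range(values.shape[0])]
    data = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                        columns=list(design.sample_ids))
    return IntensityMatrix(layer=layer, data=data, design=design, scale=scale)
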