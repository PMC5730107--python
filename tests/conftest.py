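import numpy as np
import pandas as pd
import pytest

from sleepsweep.panel import AlleleCountPanel
from sleepsweep.simulate import (ExperimentConfig, MafSpectrum,
                                 generate_founder_panel)
from sleepsweep.simulate.experiment import simulate_experiment


@pytest.fixture(scope="session")
def small_panel():
    return generate_founder_panel(
        n_lines=10, n_sites_per_chrom=40, chrom_labels=["2L", "X"],
        maf_spectrum=MafSpectrum("uniform", 0.2, 0.8), seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_panel):
    cfg = ExperimentConfig(
        n_generations=13, n_measured_per_sex=30, census=60,
        selection_fraction=0.25, coverage_mean=80.0, env_sd=60.0,
        qtl_effects={0: 25.0, 45: -25.0}, seed=5)
    return simulate_experiment(small_panel, cfg)


@pytest.fixture
def toy_counts():
    """Tiny hand-built count panel: 3 sites, one population, 2 sexes x 2 gens."""
    sites = pd.DataFrame({
        "chrom": ["2L", "2L", "X"], "pos": [100, 200, 50],
        "ref": ["A", "C", "G"], "alt": ["T", "G", "A"],
    })
    samples = pd.DataFrame({
        "population": ["C1"] * 4,
        "scheme": ["control"] * 4,
        "replicate": [1] * 4,
        "sex": ["F", "M", "F", "M"],
        "generation": [0, 0, 12, 12],
    })
    ref = np.array([[90, 80, 40, 45],
                    [50, 55, 52, 48],
                    [100, 90, 5, 8]])
    alt = np.array([[10, 20, 60, 55],
                    [50, 45, 48, 52],
                    [0, 10, 95, 92]])
    return AlleleCountPanel(sites=sites, samples=samples, ref_count=ref,
                            alt_count=alt)
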