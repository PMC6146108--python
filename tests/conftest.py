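import numpy as np
import pytest

from nsip.config import AnalysisConfig, SimConfig
from nsip.io import Treatment
from nsip.synth import otu_ids, simulate_community, simulate_experiment

LABELED_NH4 = Treatment("NH4", "15N", "50")
CONTROLS = [Treatment(s, "14N_control", "50") for s in ("NH4", "NO3", "urea")]


@pytest.fixture
def sim_config():
    """Small, fast simulation setup for unit tests."""
    return SimConfig(seed=42, reads_per_fraction=5000)


@pytest.fixture
def analysis_config():
    return AnalysisConfig()


@pytest.fixture
def small_experiment(sim_config):
    """30 OTUs, 6 of them assimilating the labeled ammonium at atom
    fraction 0.5; one labeled gradient plus three pooled controls."""
    ids = otu_ids(30)
    true = ids[:6]
    community = simulate_community(
        30, sim_config, {LABELED_NH4: true}, atom_fraction=0.5)
    gradients, counts, otus, truth = simulate_experiment(
        community, [LABELED_NH4] + CONTROLS, sim_config)
    return {
        "community": community, "gradients": gradients, "counts": counts,
        "otus": otus, "truth": truth, "true_ids": true,
    }
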