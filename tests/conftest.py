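import numpy as np
import pytest

from rhizovar.io import SampleDesign, rotation_for_plot, species_for_plot
from rhizovar.simulate import (
    AsvClass,
    SimulationConfig,
    SubgroupSpec,
    enumerate_design,
    simulate_counts,
    simulate_phylogeny_and_sequences,
)


@pytest.fixture(scope="session")
def full_design():
    return enumerate_design()


@pytest.fixture(scope="session")
def small_dataset():
    """A small but full-design simulated dataset shared across tests."""
    cfg = SimulationConfig(seed=7, n_genera=6, asvs_per_genus=(5, 10))
    designs = enumerate_design()
    tree, seqs, tax = simulate_phylogeny_and_sequences(cfg)
    table, truth = simulate_counts(designs, cfg, tree=tree, taxonomy=tax)
    return {
        "cfg": cfg, "designs": designs, "tree": tree, "seqs": seqs,
        "tax": tax, "table": table, "truth": truth,
    }


def one_factor_designs(levels_per_sample, factor="plot"):
    """Designs varying only one factor; helper for small layouts."""
    out = []
    for i, level in enumerate(levels_per_sample):
        kw = dict(year="Y1", month="June", nitrogen="stdN", block="B1",
                  plot="M", subsample="R1", compartment="rhizosphere")
        kw[factor] = level
        kw["species"] = species_for_plot(kw["plot"], kw["year"])
        kw["rotation"] = rotation_for_plot(kw["plot"])
        out.append(SampleDesign(sample_id=f"s{i:03d}", **kw))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
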