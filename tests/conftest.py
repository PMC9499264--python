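import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_otu_table():
    """3 taxa × 2 samples with column sums [10, 10]."""
    from rhizorank.io import LINEAGE_RANKS, OtuTable, parse_lineage

    counts = pd.DataFrame(
        {"s1": [5, 3, 2], "s2": [8, 1, 1]},
        index=pd.Index(["otu1", "otu2", "otu3"], name="otu_id"))
    lineages = pd.DataFrame(
        [parse_lineage("Bacteria;Proteobacteria"),
         parse_lineage("Bacteria;Bacteroidetes"),
         parse_lineage("Bacteria;Actinobacteria")],
        index=counts.index, columns=list(LINEAGE_RANKS))
    return OtuTable(counts=counts, lineages=lineages)


@pytest.fixture
def noise_free_ct():
    """Synthetic Ct records with planted fold changes and zero noise."""
    from rhizorank.simulate import SimConfig, simulate_ct_table

    cfg = SimConfig(
        crop="maize", seed=3, hk_ct_sd=0.0, tech_rep_sd=0.0,
        planted_fc={
            "pgk": {"Char_MC-C_AMF": {"21DAS": 4.0}},
            "pgd": {"Char_MC-C_AMF": {"21DAS": 2.0, "60DAS": 0.5}},
            "oy1": {"Char": {"21DAS": 3.0}, "AMF": {"60DAS": 0.25}},
        })
    return cfg, simulate_ct_table(cfg)
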