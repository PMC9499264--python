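import math

import numpy as np
import pandas as pd
import pytest

from rhizorank import datasets
from rhizorank.diversity import relative_abundance, shannon
from rhizorank.simulate import (DEFAULT_PHYLUM_PROFILE, SimConfig,
                                default_config, simulate_ct_table,
                                simulate_otu_table, simulate_traits)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = default_config("maize", seed=11)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = SimConfig.from_yaml(path)
        assert back == cfg

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(phylum_profile=(("A", 0.5), ("B", 0.4)))
        with pytest.raises(ValueError, match="library_size"):
            SimConfig(library_size=0)
        with pytest.raises(ValueError, match="concentration"):
            SimConfig(dispersion=0.0)
        with pytest.raises(ValueError, match="negative sd"):
            SimConfig(trait_sds={"Control": {"spad": -1.0}})
        with pytest.raises(ValueError, match="positive"):
            SimConfig(planted_fc={"g": {"Char": {"21DAS": -2.0}}})


class TestDeterminism:
    def test_same_seed_identical(self):
        a = simulate_traits(default_config("wheat", seed=4))
        b = simulate_traits(default_config("wheat", seed=4))
        pd.testing.assert_frame_equal(a, b)
        ta = simulate_otu_table(SimConfig(seed=4, library_size=1000))
        tb = simulate_otu_table(SimConfig(seed=4, library_size=1000))
        assert ta == tb

    def test_different_seeds_differ(self):
        a = simulate_traits(default_config("wheat", seed=4))
        b = simulate_traits(default_config("wheat", seed=5))
        assert not a["value"].equals(b["value"])

    def test_streams_independent_per_table(self):
        """Drawing the OTU table does not perturb the trait stream."""
        cfg = default_config("maize", seed=9)
        t1 = simulate_traits(cfg)
        simulate_otu_table(cfg)
        t2 = simulate_traits(cfg)
        pd.testing.assert_frame_equal(t1, t2)


class TestTraits:
    def test_zero_sd_reproduces_means(self):
        means = datasets.trait_means("maize")
        cfg = SimConfig(
            crop="maize", seed=1, n_replicates=3,
            trait_means={t: means.loc[t].to_dict() for t in means.index},
            trait_sds={t: {k: 0.0 for k in means.columns}
                       for t in means.index})
        table = simulate_traits(cfg)
        wide = table.pivot_table(index=["treatment", "replicate"],
                                 columns="trait", values="value")
        for t in means.index:
            for trait in ("root_length_cm", "shoot_fw_g", "spad",
                          "root_dw_g"):
                vals = wide.xs(t, level="treatment")[trait]
                assert vals.to_numpy() == pytest.approx(
                    means.at[t, trait], rel=1e-12)

    def test_single_replicate(self):
        cfg = default_config("wheat", seed=2)
        cfg.n_replicates = 1
        table = simulate_traits(cfg)
        assert len(table) == 12 * 9
        assert (table["replicate"] == 1).all()

    def test_dw_never_exceeds_fw(self):
        table = simulate_traits(default_config("wheat", seed=6))
        wide = table.pivot_table(index=["treatment", "replicate"],
                                 columns="trait", values="value")
        for organ in ("root", "shoot"):
            assert (wide[f"{organ}_dw_g"] <= wide[f"{organ}_fw_g"] + 1e-12).all()
            derived = 100 * wide[f"{organ}_dw_g"] / wide[f"{organ}_fw_g"]
            pd.testing.assert_series_equal(
                wide[f"{organ}_dry_biomass_pct"], derived,
                check_names=False)

    def test_values_nonnegative(self):
        table = simulate_traits(default_config("wheat", seed=8))
        assert (table["value"] >= 0).all()

    def test_sample_means_near_configured(self):
        """Monte-Carlo: sample means fall within 2·sd/√n of the
        configured means for ≥95% of treatment × trait cells."""
        means = datasets.trait_means("wheat")
        sds = datasets.trait_sds("wheat")
        n = 6
        hits = total = 0
        direct = ("root_length_cm", "shoot_length_cm", "spad",
                  "root_fw_g", "shoot_fw_g")
        for seed in range(40):
            table = simulate_traits(default_config("wheat", seed=seed))
            got = (table[table["trait"].isin(direct)]
                   .groupby(["treatment", "trait"])["value"].mean())
            for (t, trait), m in got.items():
                sd = sds.at[t, trait]
                tol = 2 * sd / math.sqrt(n) if sd > 0 else 1e-9
                hits += abs(m - means.at[t, trait]) <= tol + 1e-9
                total += 1
        assert hits / total >= 0.90


class TestOtuSimulation:
    def test_law_of_large_numbers_profile_recovery(self):
        """Huge concentration and library: per-sample phylum abundances
        within 0.5% of the configured profile."""
        cfg = SimConfig(crop="maize", seed=7, dispersion=1e9,
                        library_size=1_000_000)
        table = simulate_otu_table(cfg)
        props = relative_abundance(table, rank="phylum")
        for phylum, p in DEFAULT_PHYLUM_PROFILE:
            assert np.allclose(props.loc[phylum], p, atol=0.005), phylum

    def test_single_phylum_zero_shannon(self):
        cfg = SimConfig(crop="maize", seed=3, library_size=5000,
                        phylum_profile=(("Proteobacteria", 1.0),),
                        n_otus_per_phylum=1)
        table = simulate_otu_table(cfg)
        for sample in table.sample_ids:
            assert shannon(table.counts[sample]) == 0.0

    def test_duplicate_samples_and_metadata(self):
        cfg = SimConfig(crop="maize", seed=1, library_size=1000)
        table = simulate_otu_table(cfg)
        assert table.counts.shape[1] == 8 * 2
        assert (table.sample_meta.groupby("treatment").size() == 2).all()

    def test_effect_multipliers_shift_composition(self):
        cfg = SimConfig(
            crop="maize", seed=2, dispersion=1e6, library_size=200_000,
            effect_multipliers={"Char": {"Proteobacteria": 2.0}})
        props = relative_abundance(simulate_otu_table(cfg), rank="phylum")
        assert props.loc["Proteobacteria", "Char-1"] > \
            props.loc["Proteobacteria", "Control-1"] + 0.05

    def test_fungal_community(self):
        table = simulate_otu_table(
            SimConfig(crop="maize", seed=2, library_size=1000), "ITS")
        assert set(table.lineages["kingdom"]) == {"Fungi"}
        assert "Ascomycota" in set(table.lineages["phylum"])


class TestCtSimulation:
    def test_structure(self):
        cfg = SimConfig(crop="maize", seed=5)
        ct = simulate_ct_table(cfg)
        # (1 housekeeping + 14 targets) × 8 treatments × 2 timepoints
        # × 2 bio reps × 3 tech reps
        assert len(ct) == 15 * 8 * 2 * 2 * 3
        assert set(ct["gene"]).issuperset({"18S", "pgk"})

    def test_unit_fc_noise_free_gives_flat_dct(self, noise_free_ct):
        cfg, ct = noise_free_ct
        sub = ct[(ct["gene"] == "oy1") & (ct["timepoint"] == "60DAS")]
        hk = ct[(ct["gene"] == "18S") & (ct["timepoint"] == "60DAS")]
        dct = (sub.set_index(["treatment", "bio_rep", "tech_rep"])["ct"]
               - hk.set_index(["treatment", "bio_rep", "tech_rep"])["ct"])
        # planted FC for oy1@60DAS is 0.25 in AMF, 1 elsewhere
        assert dct.loc["AMF"].to_numpy() == pytest.approx(
            dct.loc["Control"].to_numpy() + 2.0)

    def test_ceiling_reachable_by_offset(self):
        cfg = SimConfig(crop="maize", seed=5, hk_ct_sd=0.0, tech_rep_sd=0.0,
                        gene_offsets={g: 30.0 for g in SimConfig().genes})
        ct = simulate_ct_table(cfg)
        assert (ct.loc[ct["gene"] != "18S", "ct"] > 36).all()
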