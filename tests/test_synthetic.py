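"""Ground-truth generator: determinism, biases, kinetics, recoverability."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from microprot.constants import AA_ORDER
from microprot.quant import quant_share, quantify
from microprot.synthetic import (
    ConfigError,
    GrowthParams,
    SimConfig,
    component_shares,
    simulate_batch,
    simulate_events,
    simulate_proteome,
    simulate_psm_tables,
    toy_go_graph,
    write_dataset,
)


class TestConfigValidation:
    def test_component_without_bias_rejected(self):
        cfg = SimConfig(components=("ribosome", "nucleoid"))
        with pytest.raises(ConfigError, match="nucleoid"):
            cfg.validate()

    def test_negative_bias_rejected(self):
        cfg = SimConfig()
        cfg.aa_bias["ribosome"] = -np.ones(20)
        with pytest.raises(ConfigError, match="ribosome"):
            cfg.validate()

    def test_non_positive_ks_rejected(self):
        cfg = SimConfig(growth=GrowthParams(ks_c=0.0))
        with pytest.raises(ConfigError, match="half-saturation"):
            simulate_batch(cfg, "carbon")

    def test_allocation_outside_unit_interval_rejected(self):
        cfg = SimConfig(alloc_intercept=0.9, alloc_slope=0.5)
        with pytest.raises(ConfigError, match="phi_ribo"):
            cfg.validate()

    def test_zero_psm_budget_rejected(self):
        cfg = SimConfig(psm_budget=0)
        with pytest.raises(ConfigError, match="budget"):
            simulate_psm_tables(cfg, [0.1])

    def test_unknown_panel_and_limitation_rejected(self):
        cfg = SimConfig()
        with pytest.raises(ConfigError, match="panel"):
            simulate_events(cfg, "SYPRO")
        with pytest.raises(ConfigError, match="limitation"):
            simulate_batch(cfg, "phosphorus")


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(seed=99, n_proteins_per_component=10)
        for sub in ("a", "b"):
            write_dataset(cfg, tmp_path / sub, mus=(0.1, 0.3), limitations=("carbon",), panels=("SG",))
        for name in (
            "proteome.fasta",
            "ontology.obo",
            "annotations.tsv",
            "truth_components.tsv",
            "psm_tables.csv",
            "series_carbon.csv",
            "events_SG.csv",
            "events_SG.json",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        p1 = simulate_proteome(SimConfig(seed=1, n_proteins_per_component=5))
        p2 = simulate_proteome(SimConfig(seed=2, n_proteins_per_component=5))
        assert any(
            p1.db[p].sequence != p2.db[p].sequence for p in p1.db.records
        )


class TestProteomeGeneration:
    def test_toy_dag_contains_reference_roots(self):
        g = toy_go_graph()
        for root in ("GO:0110165", "GO:0032991", "GO:0005840"):
            assert root in g

    def test_degenerate_bias_gives_poly_ala(self):
        cfg = SimConfig(seed=0, n_proteins_per_component=3)
        ala_only = np.zeros(20)
        ala_only[AA_ORDER.index("A")] = 1.0
        cfg.aa_bias = {c: ala_only for c in cfg.components}
        prot = simulate_proteome(cfg)
        assert all(set(r.sequence) == {"A"} for r in prot.db)

    def test_lysine_enrichment_within_binomial_error(self):
        cfg = SimConfig(seed=6, n_proteins_per_component=50)
        bias = np.ones(20)
        bias[AA_ORDER.index("K")] = 1.5
        cfg.aa_bias = dict(cfg.aa_bias, ribosome=bias)
        prot = simulate_proteome(cfg)
        seqs = [prot.db[p].sequence for p in prot.proteins_of("ribosome")]
        n_res = sum(len(s) for s in seqs)
        assert n_res >= 10_000
        k_freq = sum(s.count("K") for s in seqs) / n_res
        p_expected = 1.5 / (19 + 1.5)
        sd = np.sqrt(p_expected * (1 - p_expected) / n_res)
        assert abs(k_freq - p_expected) < 3 * sd

    def test_unannotated_proteins_have_no_terms(self, proteome):
        for pid in proteome.proteins_of("unannotated"):
            assert pid not in proteome.annotations


class TestBatchSimulation:
    def test_mu_at_saturation_approaches_mu_max(self):
        cfg = replace(SimConfig(seed=1), noise_cv={"default": 0.0})
        cfg.growth.c0, cfg.growth.n0 = 50.0, 5.0  # both >> Ks throughout
        cfg.growth.t_end = 4.0
        run = simulate_batch(cfg, "carbon")
        assert (run.data["mu_true"] > 0.999 * cfg.growth.mu_max).all()

    def test_nitrogen_limitation_exhausts_n_before_c(self):
        cfg = replace(SimConfig(seed=1), noise_cv={"default": 0.0})
        run = simulate_batch(cfg, "nitrogen").data
        assert run["nh4_g_l"].iloc[-1] < 1e-3
        assert run["cod_g_l"].iloc[-1] > 0.5

    def test_carbon_limitation_exhausts_c_before_n(self):
        cfg = replace(SimConfig(seed=1), noise_cv={"default": 0.0})
        run = simulate_batch(cfg, "carbon").data
        assert run["cod_g_l"].iloc[-1] < 1e-2
        assert run["nh4_g_l"].iloc[-1] > 1e-3

    def test_step_halving_convergence(self):
        cfg = replace(SimConfig(seed=1), noise_cv={"default": 0.0})
        coarse = simulate_batch(cfg, "carbon", dt=0.01).data["cdw_g_l"].iloc[-1]
        fine = simulate_batch(cfg, "carbon", dt=0.001).data["cdw_g_l"].iloc[-1]
        assert abs(coarse - fine) / fine < 1e-3

    def test_all_observables_non_negative(self):
        for seed in range(3):
            cfg = SimConfig(seed=seed)
            for limitation in ("carbon", "nitrogen", "dual"):
                data = simulate_batch(cfg, limitation).data
                numeric = data.select_dtypes("number")
                assert (numeric.to_numpy() >= 0).all()

    def test_storage_signal_rises_under_nitrogen_limitation(self):
        cfg = replace(SimConfig(seed=1), noise_cv={"default": 0.0})
        run = simulate_batch(cfg, "nitrogen").data
        abundant = run[run["phase_true"] == "abundant"]["pha_au"]
        limiting = run[run["phase_true"] == "limiting"]["pha_au"]
        assert limiting.min() > abundant.max()


class TestPsmTables:
    def test_noise_free_shares_recover_growth_law_exactly(self, noise_free_config, proteome):
        mus = [0.05, 0.20, 0.35]
        tables = simulate_psm_tables(noise_free_config, mus, proteome=proteome, noise="off")
        for mu, table in zip(mus, tables):
            sq = quantify(table, proteome.db)
            share = quant_share(sq, proteome.proteins_of("ribosome"))
            assert share == pytest.approx(noise_free_config.phi_ribo(mu), abs=1e-12)

    def test_shared_peptides_still_exact_noise_free(self, config, proteome):
        table = simulate_psm_tables(config, [0.2], proteome=proteome, noise="off")[0]
        assert any(len(r.protein_ids) > 1 for r in table.rows)
        sq = quantify(table, proteome.db)
        share = quant_share(sq, proteome.proteins_of("ribosome"))
        assert share == pytest.approx(config.phi_ribo(0.2), abs=1e-12)

    def test_higher_mu_has_larger_ribosomal_share(self, config, proteome):
        low = component_shares(config, 0.05)["ribosome"]
        high = component_shares(config, 0.35)["ribosome"]
        assert high > low
        tables = simulate_psm_tables(config, [0.05, 0.35], proteome=proteome, noise="off")
        shares = [
            quant_share(quantify(t, proteome.db), proteome.proteins_of("ribosome"))
            for t in tables
        ]
        assert shares[1] > shares[0]

    def test_poisson_counts_are_integers(self, config, proteome):
        table = simulate_psm_tables(config, [0.2], proteome=proteome, noise="poisson")[0]
        assert all(float(r.psm_count).is_integer() for r in table.rows)
        assert table.total_psms() > 0


class TestEventSimulation:
    def test_metadata_defaults(self):
        events = simulate_events(SimConfig(seed=0), "SG")
        assert events.volume_ml == pytest.approx(0.075)
        assert events.dilution == 1.0
        assert events.panel == "SG"

    def test_population_fractions_drawn_correctly(self):
        cfg = SimConfig(seed=8)
        cfg.cytometry.doublet_fraction = 0.0
        cfg.cytometry.damaged_fraction = 0.4
        events = simulate_events(cfg, "SGPI")
        frac = (events.events["population"] == "damaged").mean()
        se = np.sqrt(0.4 * 0.6 / len(events))
        assert abs(frac - 0.4) < 3 * se

    def test_doublet_area_height_signature(self):
        cfg = SimConfig(seed=8)
        cfg.cytometry.doublet_fraction = 0.1
        events = simulate_events(cfg, "SG").events
        doublets = events[events["population"] == "doublet"]
        singlets = events[events["population"] != "doublet"]
        assert (doublets["BL1-A"] / doublets["BL1-H"]).median() > 1.5
        assert (singlets["BL1-A"] / singlets["BL1-H"]).median() == pytest.approx(1.0, abs=0.05)
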