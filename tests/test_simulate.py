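"""Generator construction, determinism and the deterministic signal model."""

import numpy as np
import pandas as pd
import pytest

import endomir as em
from endomir.errors import ContractError
from endomir.simulate import POOLS

from conftest import spearman_oracle


class TestGenerateWorld:
    def test_overlap_design_is_exact(self):
        cfg = em.GeneratorConfig(n_mirnas=60, n_int_only=10, n_sec_only=10, n_shared=20, seed=3)
        w = em.generate_world(cfg)
        assert len(w.int_support & w.sec_support) == 20
        assert len(w.int_support - w.sec_support) == 10
        assert len(w.sec_support - w.int_support) == 10

    def test_profiles_are_simplex_vectors(self, small_world):
        for name, prof in small_world.profiles.items():
            assert prof.min() >= 0
            assert abs(prof.sum() - 1.0) < 1e-9, name

    def test_mixture_weights_are_simplex(self, small_world):
        for key, w in small_world.mixture_weights.items():
            assert w.min() >= 0 and abs(w.sum() - 1.0) < 1e-9

    def test_same_seed_gives_identical_world(self, small_config):
        w1 = em.generate_world(small_config)
        w2 = em.generate_world(small_config)
        assert w1.mirna_ids == w2.mirna_ids
        for k in w1.profiles:
            np.testing.assert_array_equal(w1.profiles[k], w2.profiles[k])
        np.testing.assert_array_equal(w1.slopes, w2.slopes)
        np.testing.assert_array_equal(w1.trend_direction, w2.trend_direction)

    def test_nonlinear_fraction_realized_exactly(self):
        cfg = em.GeneratorConfig(
            n_mirnas=1000, n_int_only=250, n_sec_only=300, n_shared=450, seed=5
        )
        w = em.generate_world(cfg)
        assert len(w.nonlinear_probe_ids()) == 27  # 2.7% of 1000

    def test_overlap_exceeding_universe_rejected(self):
        with pytest.raises(ContractError, match="overlap"):
            em.GeneratorConfig(n_mirnas=10, n_int_only=5, n_sec_only=5, n_shared=5)

    def test_trend_counts_assigned_within_secretory_support(self):
        cfg = em.GeneratorConfig(
            n_mirnas=150, n_int_only=50, n_sec_only=40, n_shared=60,
            trend_counts=(39, 7), seed=2,
        )
        w = em.generate_world(cfg)
        truth = w.trend_truth()
        assert (truth == "increasing").sum() == 39
        assert (truth == "decreasing").sum() == 7
        trending = set(truth.index[truth != "unchanged"])
        assert trending <= w.sec_support


class TestSimulateArrays:
    def test_determinism_bit_identical(self, small_world):
        sheet = em.preset_designs("blood_panel", small_world.config)
        m1 = em.simulate_arrays(small_world, sheet, seed=7)
        m2 = em.simulate_arrays(small_world, sheet, seed=7)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_blank_medium_is_intercept_plus_background(self, noiseless_world):
        sheet = em.preset_designs("huvec_grid", noiseless_world.config)
        m = em.simulate_arrays(noiseless_world, sheet, seed=0)
        blank = m.values["blank-MCDB"]
        expected = noiseless_world.intercepts + noiseless_world.background_level
        np.testing.assert_allclose(blank.to_numpy(), expected)

    def test_dilution_proportionality_for_linear_probes(self, noiseless_world):
        sheet = em.preset_designs("dilution_series", noiseless_world.config)
        m = em.simulate_arrays(noiseless_world, sheet, seed=0)
        lin = noiseless_world.linear
        icpt = noiseless_world.intercepts[lin]
        c50 = m.values["dil-50ng"].to_numpy()[lin] - icpt
        c100 = m.values["dil-100ng"].to_numpy()[lin] - icpt
        np.testing.assert_allclose(c100, 2.0 * c50, rtol=1e-12)

    def test_pure_compartment_fractions_recover_profile(self):
        # equal slopes, no intercept/background/noise, all probes linear:
        # fraction normalization of a pure cell sample is the profile itself
        cfg = em.GeneratorConfig(
            n_mirnas=80, n_int_only=20, n_sec_only=20, n_shared=20,
            noise_sd=0.0, slope_log_sd=0.0, nonlinear_probe_fraction=0.0,
            donor_effect_sd=0.0, medium_effect_sd=0.0, background_level=0.0,
            seed=4,
        )
        w = em.generate_world(cfg)
        sheet = em.SampleSheet(pd.DataFrame(
            {"sample_id": ["c"], "compartment": ["cell"], "donor": ["1302"],
             "culture_medium": ["MCDB"]}
        ))
        m = em.simulate_arrays(w, sheet, seed=0)
        frac = em.normalize_total(m).table["c"].to_numpy()
        np.testing.assert_allclose(frac, w.profiles["endothelial_intracellular"], atol=1e-12)

    def test_pure_secretory_serum_matches_sec_profile(self):
        # serum with full weight on the endothelial-secretory pool: after
        # fraction normalization over detected probes, Spearman rho = 1
        # against the secretory profile (oracle: the signal model is a
        # monotone per-probe transform of the profile)
        cfg = em.GeneratorConfig(
            n_mirnas=100, n_int_only=25, n_sec_only=25, n_shared=25,
            noise_sd=0.0, serum_weights=(1.0, 0.0, 0.0, 0.0),
            nonlinear_probe_fraction=0.0, seed=9,
        )
        w = em.generate_world(cfg)
        sheet = em.SampleSheet(pd.DataFrame(
            {"sample_id": ["s"], "compartment": ["serum"], "donor": ["bd1"]}
        ))
        m = em.simulate_arrays(w, sheet, seed=0)
        det = em.call_detection(m, 1e-12)
        frac = em.normalize_total(m, mask=det)
        x = frac.table["s"]
        y = pd.Series(
            w.profiles["endothelial_secretory"] * w.donor_effects["bd1"] * w.slopes,
            index=w.mirna_ids,
        )
        detected = x[x > 0].index
        rho = spearman_oracle(x[detected].tolist(), y[detected].tolist())
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_unknown_donor_rejected(self, small_world):
        sheet = em.SampleSheet(pd.DataFrame(
            {"sample_id": ["x"], "compartment": ["cell"], "donor": ["nobody"],
             "culture_medium": ["MCDB"]}
        ))
        with pytest.raises(ContractError, match="nobody"):
            em.simulate_arrays(small_world, sheet, seed=0)

    def test_flags_reflect_deterministic_signal(self, small_world):
        sheet = em.preset_designs("dilution_series", small_world.config)
        m, flags = em.simulate_arrays(small_world, sheet, seed=3, with_flags=True)
        assert flags.shape == m.values.shape
        # flags are noise-free: identical across seeds
        _, flags2 = em.simulate_arrays(small_world, sheet, seed=99, with_flags=True)
        pd.testing.assert_frame_equal(flags, flags2)


class TestPresets:
    def test_huvec_grid_has_32_samples_plus_blanks(self):
        sheet = em.preset_designs("huvec_grid")
        assert len(sheet.table) == 36
        assert (sheet.table["compartment"] == "blank_medium").sum() == 4

    def test_dilution_series_is_increasing_with_six_points(self):
        sheet = em.preset_designs("dilution_series")
        d = sheet.dilution_samples()
        assert len(d) == 6
        assert d["input_ng"].is_monotonic_increasing
        assert d["input_ng"].iloc[0] == 12.5 and d["input_ng"].iloc[-1] == 150.0

    def test_blood_panel_paired_serum_plasma(self):
        sheet = em.preset_designs("blood_panel")
        assert (sheet.table["compartment"] == "serum").sum() == 4
        assert (sheet.table["compartment"] == "plasma").sum() == 4

    def test_timecourse_layout(self):
        cfg = em.GeneratorConfig()
        sheet = em.preset_designs("timecourse", cfg)
        tc = sheet.table[sheet.table["time_min"].notna()]
        assert len(tc) == len(cfg.time_grid) * cfg.replicates * 2

    def test_unknown_preset(self):
        with pytest.raises(ContractError, match="unknown preset"):
            em.preset_designs("bulk_rnaseq")

    def test_concat_sheets_rejects_duplicates(self):
        s = em.preset_designs("blood_panel")
        with pytest.raises(ContractError):
            em.concat_sheets(s, s)
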