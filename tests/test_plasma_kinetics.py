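"""Interval-wise Steele-equation kinetics: hand arithmetic, identities, recovery."""

import numpy as np
import pytest

from aaflux import (
    ConcentrationSeries,
    EnrichmentSeries,
    Pool,
    SimulationConfig,
    Tracer,
    TrialConfig,
    cumulative_exo_appearance,
    kinetics_table,
    phe_plasma_percent,
    recovery_report,
)
from aaflux.errors import AlignmentError, ConfigError, DomainError, PrecursorError
from aaflux import plasma_kinetics as pk


class TestScalarForms:
    def test_total_ra_steady_state_is_f_over_e(self):
        assert pk.total_ra(0.060, 0.125, 60.0, 0.0, 0.075) == pytest.approx(0.800)

    def test_total_ra_non_steady_state_hand_value(self):
        # falling IV enrichment adds pool-drain correction: (0.060 + 0.125*60*1e-4)/0.05
        assert pk.total_ra(0.060, 0.125, 60.0, -1e-4, 0.05) == pytest.approx(1.215)

    def test_total_ra_requires_positive_enrichment(self):
        with pytest.raises(PrecursorError):
            pk.total_ra(0.06, 0.125, 60.0, 0.0, 0.0)

    def test_exo_ra_hand_value_and_placebo(self):
        assert pk.exo_ra(1.0, 0.0316, 0.0, 60.0, 0.125, 0.316) == pytest.approx(0.100)
        assert pk.exo_ra(1.0, 0.0, 0.0, 60.0, 0.125, 0.0) == 0.0

    def test_exo_ra_nonzero_plasma_without_protein_enrichment_is_config_error(self):
        with pytest.raises(ConfigError):
            pk.exo_ra(1.0, 0.01, 0.0, 60.0, 0.125, 0.0)

    def test_endo_ra_identity(self):
        assert pk.endo_ra(1.20, 0.30, 0.06) == pytest.approx(0.84)
        assert pk.endo_ra(0.80, 0.0, 0.06) == pytest.approx(0.74)

    def test_total_rd_hand_value_and_flat_limit(self):
        assert pk.total_rd(1.0, 0.125, 0.2) == pytest.approx(0.975)
        assert pk.total_rd(0.8, 0.125, 0.0) == pytest.approx(0.8)


class TestKineticsTable:
    def test_steady_state_closed_form(self, flat_series, trial_config):
        conc, e_iv, e_oral = flat_series
        table = kinetics_table(conc, e_iv, e_oral, trial_config)
        assert len(table) == len(conc.times) - 1
        np.testing.assert_allclose(table["total_ra"], 0.060 / 0.075, rtol=1e-14)
        np.testing.assert_allclose(table["total_rd"], table["total_ra"], rtol=1e-14)
        np.testing.assert_allclose(table["exo_ra"], 0.0, atol=1e-15)

    def test_placebo_table_exo_all_zero(self, trial_config):
        times = np.arange(0.0, 721.0, 60.0)
        conc = ConcentrationSeries("phe", times, 60 + 2 * np.sin(times / 200))
        e_iv = EnrichmentSeries(Tracer.D5_PHE, Pool.PLASMA, times, 7.5 + 0.2 * np.cos(times / 300))
        cfg = TrialConfig(protein_dose_g=0.0)
        table = kinetics_table(conc, e_iv, None, cfg)
        np.testing.assert_array_equal(table["exo_ra"], 0.0)
        np.testing.assert_array_equal(table["exo_rd"], 0.0)
        np.testing.assert_allclose(
            table["total_ra"], table["endo_ra"] + cfg.f_phe_iv, rtol=1e-12
        )

    def test_conservation_identities_on_noisy_simulation(self, noisy_sim_25g):
        sim = noisy_sim_25g
        table = kinetics_table(
            sim.concentrations["phe"],
            sim.enrichments[Tracer.D5_PHE],
            sim.enrichments[Tracer.C13_PHE],
            sim.config.trial,
        )
        assert np.max(np.abs(table["ra_identity_resid"])) < 1e-10
        assert np.max(np.abs(table["rd_identity_resid"])) < 1e-10
        np.testing.assert_allclose(
            table["endo_rd"], table["total_rd"] - table["exo_rd"], atol=1e-12
        )

    def test_misaligned_grids_raise_with_offenders(self, trial_config):
        conc = ConcentrationSeries("phe", [0, 60, 120], [60, 61, 62])
        e_iv = EnrichmentSeries(Tracer.D5_PHE, Pool.PLASMA, [0, 90, 120], [7, 7, 7])
        e_oral = EnrichmentSeries(Tracer.C13_PHE, Pool.PLASMA, [0, 60, 120], [0, 1, 2])
        with pytest.raises(AlignmentError) as err:
            kinetics_table(conc, e_iv, e_oral, trial_config)
        assert set(err.value.offending_times) == {60.0, 90.0}

    def test_two_point_series_matches_hand_interval(self, trial_config):
        # one 30-min interval, C 58->62, E_iv 5.2%->4.8%, E_oral 2.8%->3.2%
        conc = ConcentrationSeries("phe", [0, 30], [58.0, 62.0])
        e_iv = EnrichmentSeries(Tracer.D5_PHE, Pool.PLASMA, [0, 30], [5.2, 4.8])
        e_oral = EnrichmentSeries(Tracer.C13_PHE, Pool.PLASMA, [0, 30], [2.8, 3.2])
        row = kinetics_table(conc, e_iv, e_oral, trial_config).iloc[0]
        c_mean, e_iv_mean = 60.0, 0.05
        de_iv = (0.048 - 0.052) / 30
        ra = (0.060 - 0.125 * c_mean * de_iv) / e_iv_mean
        assert row["total_ra"] == pytest.approx(ra, rel=1e-12)
        de_or = (0.032 - 0.028) / 30
        exo = (ra * 0.030 + 0.125 * c_mean * de_or) / 0.316
        assert row["exo_ra"] == pytest.approx(exo, rel=1e-12)
        assert row["total_rd"] == pytest.approx(ra - 0.125 * 4 / 30, rel=1e-12)

    def test_pre_drink_samples_are_excluded(self, trial_config):
        times = np.array([-150.0, -60.0, 0.0, 60.0, 120.0])
        conc = ConcentrationSeries("phe", times, np.full(5, 60.0))
        e_iv = EnrichmentSeries(Tracer.D5_PHE, Pool.PLASMA, times, np.full(5, 7.5))
        e_oral = EnrichmentSeries(Tracer.C13_PHE, Pool.PLASMA, times, np.zeros(5))
        table = kinetics_table(conc, e_iv, e_oral, trial_config)
        assert table["t_start"].iloc[0] == 0.0
        assert len(table) == 2


class TestCumulativeAvailability:
    def test_constant_rate_hand_value(self, trial_config):
        times = np.arange(0.0, 721.0, 60.0)
        table_like = kinetics_table(
            ConcentrationSeries("phe", times, np.full_like(times, 60.0)),
            EnrichmentSeries(Tracer.D5_PHE, Pool.PLASMA, times, np.full_like(times, 5.0)),
            EnrichmentSeries(Tracer.C13_PHE, Pool.PLASMA, times, np.full_like(times, 3.16)),
            trial_config,
        )
        # flat enrichments: exo_ra = total_ra * E_p,oral / E_oral = 1.2 * 0.1
        np.testing.assert_allclose(table_like["exo_ra"], 0.12, rtol=1e-12)
        auc = cumulative_exo_appearance(table_like)
        assert auc == pytest.approx(0.12 * 720, rel=1e-12)

    def test_phe_plasma_percent_hand_value(self, trial_config):
        import pandas as pd

        table = pd.DataFrame({"t_start": [0.0], "t_end": [720.0], "exo_ra": [0.1]})
        pct = phe_plasma_percent(table, 7265.0, 75.0)
        assert pct == pytest.approx(74.33, abs=0.01)

    def test_zero_length_window_is_zero(self, trial_config):
        import pandas as pd

        table = pd.DataFrame({"t_start": [0.0], "t_end": [720.0], "exo_ra": [0.1]})
        assert cumulative_exo_appearance(table, 100.0, 100.0) == 0.0

    def test_placebo_percent_undefined(self):
        import pandas as pd

        table = pd.DataFrame({"t_start": [0.0], "t_end": [720.0], "exo_ra": [0.0]})
        with pytest.raises(DomainError):
            phe_plasma_percent(table, 0.0, 75.0)

    def test_negative_rates_clamped_only_when_asked(self):
        import pandas as pd

        table = pd.DataFrame(
            {"t_start": [0.0, 60.0], "t_end": [60.0, 120.0], "exo_ra": [0.2, -0.1]}
        )
        assert cumulative_exo_appearance(table) == pytest.approx(0.2 * 60)
        assert cumulative_exo_appearance(table, clamp_negative=False) == pytest.approx(0.1 * 60)


class TestOracleRecovery:
    def test_grid_refinement_reduces_release_error(self):
        errs = []
        for dt in (30.0, 15.0, 5.0, 1.0):
            cfg = SimulationConfig(
                noise_cv_enrichment=0.0, noise_cv_concentration=0.0, sampling_dt_min=dt
            )
            rep = recovery_report(cfg, stages=("kinetics",)).set_index("quantity")
            errs.append(rep.loc["release_percent", "rel_error"])
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_exogenous_curve_recovered_on_fine_grid(self, oracle_sim_25g):
        cfg = oracle_sim_25g.config
        rep = recovery_report(cfg, sim=oracle_sim_25g, stages=("kinetics",)).set_index(
            "quantity"
        )
        assert rep.loc["exo_ra_rel_l2", "estimate"] < 0.02
        assert rep.loc["release_percent", "rel_error"] < 0.02
        assert rep.loc["endo_ra_mean", "rel_error"] < 0.02
        assert rep.loc["total_rd_mean", "rel_error"] < 0.02
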