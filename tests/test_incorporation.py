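"""Precursor-product FSR, de novo incorporation, and exo/endo partitioning."""

import numpy as np
import pytest

from aaflux import (
    BiopsyRecord,
    EnrichmentSeries,
    Pool,
    SimulationConfig,
    Tracer,
    exo_endo_contribution,
    fsr,
    fsr_table,
    mps_denovo,
    pp_denovo,
    recovery_report,
    weighted_precursor_mean,
)
from aaflux.errors import DomainError, PrecursorError


class TestPrecursorMean:
    def test_flat_series_returns_the_constant(self):
        s = EnrichmentSeries(Tracer.C13_LEU, Pool.PLASMA, [0, 300, 720], [8.0, 8.0, 8.0])
        assert weighted_precursor_mean(s, 0, 720) == pytest.approx(8.0)

    def test_linear_ramp_averages_to_midpoint(self):
        s = EnrichmentSeries(Tracer.D5_PHE, Pool.PLASMA, [0, 720], [0.0, 10.0])
        assert weighted_precursor_mean(s, 0, 720) == pytest.approx(5.0)

    def test_piecewise_series_matches_hand_trapezoid(self):
        s = EnrichmentSeries(Tracer.D5_PHE, Pool.PLASMA, [0, 120, 720], [6.0, 8.0, 7.0])
        hand = (0.5 * (6 + 8) * 120 + 0.5 * (8 + 7) * 600) / 720
        assert weighted_precursor_mean(s, 0, 720) == pytest.approx(hand)

    def test_window_outside_data_rejected(self):
        s = EnrichmentSeries(Tracer.D5_PHE, Pool.PLASMA, [0, 720], [6.0, 7.0])
        with pytest.raises(DomainError):
            weighted_precursor_mean(s, -60, 720)


class TestFsr:
    def test_zero_incorporation_gives_zero(self):
        assert fsr(0.0, 8.0, 4.0) == 0.0

    def test_hand_value(self):
        assert fsr(0.012, 8.0, 4.0) == pytest.approx(0.0375)

    def test_scale_invariance_mpe_vs_fraction(self):
        assert fsr(0.012, 8.0, 4.0) == pytest.approx(fsr(0.00012, 0.08, 4.0))

    def test_inverse_scaling_with_window_length(self):
        assert fsr(0.012, 8.0, 8.0) == pytest.approx(fsr(0.012, 8.0, 4.0) / 2)

    @pytest.mark.parametrize("prec, hours", [(0.0, 4.0), (8.0, 0.0), (-1.0, 4.0)])
    def test_degenerate_inputs_rejected(self, prec, hours):
        with pytest.raises((PrecursorError, DomainError)):
            fsr(0.01, prec, hours)


class TestDeNovo:
    def test_mps_denovo_hand_value(self):
        assert mps_denovo(30_000.0, 0.01, 31.6) == pytest.approx(1.899, abs=2e-3)

    def test_mps_denovo_zero_gain(self):
        assert mps_denovo(30_000.0, 0.0, 31.6) == 0.0

    def test_pp_denovo_hand_value_and_linearity(self):
        assert pp_denovo(75.0, 0.158, 31.6) == pytest.approx(1.010, abs=2e-3)
        assert pp_denovo(150.0, 0.158, 31.6) == pytest.approx(2 * pp_denovo(75.0, 0.158, 31.6))

    def test_zero_oral_enrichment_rejected(self):
        with pytest.raises(DomainError):
            mps_denovo(30_000.0, 0.01, 0.0)
        with pytest.raises(DomainError):
            pp_denovo(75.0, 0.1, 0.0)


class TestExoEndoContribution:
    def test_equal_normalized_incorporation_is_all_exogenous(self):
        exo, endo = exo_endo_contribution(0.316, 31.6, 0.05, 5.0)
        assert exo == pytest.approx(100.0)
        assert endo == pytest.approx(0.0)

    def test_hand_value_and_complement(self):
        exo, endo = exo_endo_contribution(0.01, 31.6, 0.06, 5.0)
        assert exo == pytest.approx(2.64, abs=0.01)
        assert exo + endo == 100.0

    def test_zero_exogenous_gain(self):
        exo, endo = exo_endo_contribution(0.0, 31.6, 0.06, 5.0)
        assert (exo, endo) == (0.0, 100.0)

    def test_zero_iv_gain_undefined(self):
        with pytest.raises(DomainError):
            exo_endo_contribution(0.01, 31.6, 0.0, 5.0)

    def test_out_of_range_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capping"):
            exo, endo = exo_endo_contribution(0.4, 31.6, 0.05, 5.0)
        assert exo == 100.0 and endo == 0.0


class TestFsrTable:
    def _biopsies(self):
        recs = []
        for t in (0.0, 240.0, 480.0, 720.0):
            bound = {Tracer.D5_PHE: 0.075 * 0.05 / 60 * t}  # linear accrual
            free = {Tracer.D5_PHE: 0.65 * 7.5}
            recs.append(BiopsyRecord(t, "myofibrillar", bound, free))
        return recs

    def test_linear_accrual_at_plateau_precursor_recovers_rate(self):
        precursor = EnrichmentSeries(
            Tracer.D5_PHE, Pool.PLASMA, [0.0, 720.0], [7.5, 7.5]
        )
        table = fsr_table(self._biopsies(), {Tracer.D5_PHE: precursor})
        plasma = table[table.precursor_pool == "plasma"]
        # delta_E per window = 0.075% of precursor per hour worth of label
        np.testing.assert_allclose(plasma["fsr_pct_per_h"], 0.05, rtol=1e-12)

    def test_consecutive_windows_sum_to_full_window_gain(self):
        precursor = EnrichmentSeries(Tracer.D5_PHE, Pool.PLASMA, [0.0, 720.0], [7.5, 7.5])
        table = fsr_table(self._biopsies(), {Tracer.D5_PHE: precursor})
        plasma = table[table.precursor_pool == "plasma"].set_index(["t_start", "t_end"])
        gains = {
            w: r["fsr_pct_per_h"] * r["precursor_mean_mpe"] * (w[1] - w[0]) / 60
            for w, r in plasma.iterrows()
        }
        partial = gains[(0.0, 240.0)] + gains[(240.0, 480.0)] + gains[(480.0, 720.0)]
        assert partial == pytest.approx(gains[(0.0, 720.0)], rel=1e-12)

    def test_muscle_free_precursor_uses_bounding_biopsies(self):
        precursor = EnrichmentSeries(Tracer.D5_PHE, Pool.PLASMA, [0.0, 720.0], [7.5, 7.5])
        table = fsr_table(self._biopsies(), {Tracer.D5_PHE: precursor})
        free = table[table.precursor_pool == "muscle_free"]
        np.testing.assert_allclose(free["precursor_mean_mpe"], 0.65 * 7.5, rtol=1e-12)
        # lower (diluted) precursor -> proportionally higher FSR
        np.testing.assert_allclose(free["fsr_pct_per_h"], 0.05 / 0.65, rtol=1e-12)


class TestSimulatedRecovery:
    @pytest.mark.parametrize("true_fsr", [0.02, 0.05, 0.10])
    def test_programmed_fsr_recovered_within_one_percent(self, true_fsr):
        cfg = SimulationConfig(
            noise_cv_enrichment=0.0,
            noise_cv_concentration=0.0,
            true_fsr_pct_per_h={"myofibrillar": true_fsr},
        )
        rep = recovery_report(cfg, stages=("fsr",)).set_index("quantity")
        assert rep.loc["fsr_myofibrillar", "rel_error"] < 0.01
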