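"""Closed-form steady states: relay ratio, nucleotide pools, calibration table."""

import math

import numpy as np
import pytest

from caulomsg import (GUANINE_TOTAL, NutrientSignal, SpoTSplit,
                      cdg_steady_state, full_equilibrium,
                      nucleotide_equilibrium, pep_pyr_sweep, pts_equilibrium,
                      reproduce_table4, spot_split)


class TestPtsEquilibrium:
    def test_rich_condition_pools(self, params, rich):
        eq = pts_equilibrium(rich, params)
        assert eq.r == pytest.approx(0.0556, abs=2e-4)
        assert eq.NPrP == pytest.approx(1.58, abs=0.01)
        assert eq.EIIAP == pytest.approx(1.58, abs=0.01)
        assert eq.EIP_tot == pytest.approx(0.527, abs=0.005)

    def test_carbon_limited_pools(self, params, carbon_limited):
        eq = pts_equilibrium(carbon_limited, params)
        assert eq.r == pytest.approx(0.19743, abs=2e-4)
        assert eq.NPrP == pytest.approx(4.95, abs=0.02)

    def test_no_pep_means_no_phosphorylation(self, params):
        eq = pts_equilibrium(NutrientSignal(100, 0, 800), params)
        assert eq.r == 0.0
        assert eq.EIP_tot == eq.NPrP == eq.EIIAP == 0.0

    def test_no_pyr_is_fully_phosphorylated_limit(self, params):
        eq = pts_equilibrium(NutrientSignal(100, 300, 0), params)
        assert math.isinf(eq.r)
        assert eq.NPrP == params.NPr_T

    def test_no_donor_nor_acceptor_is_undefined(self, params):
        with pytest.raises(ValueError):
            pts_equilibrium(NutrientSignal(100, 0, 0), params)

    def test_pools_linear_in_totals_r_invariant(self, params, rich):
        a = pts_equilibrium(rich, params)
        b = pts_equilibrium(rich, params, EI_T=20.0, NPr_T=60.0, EIIA_T=3.0)
        assert b.r == a.r
        assert b.EIP_tot == pytest.approx(2 * a.EIP_tot)
        assert b.NPrP == pytest.approx(2 * a.NPrP)
        assert b.EIIAP == pytest.approx(0.1 * a.EIIAP)

    def test_r_monotone_decreasing_in_gln(self, params):
        glns = [0, 1, 10, 100, 1000, 10000]
        rs = [pts_equilibrium(NutrientSignal(g, 300, 1500), params).r for g in glns]
        assert all(b < a for a, b in zip(rs, rs[1:]))


class TestCdgSteadyState:
    def test_balances_synthesis_and_degradation(self, params):
        c = cdg_steady_state(1221.0, 1.4579, 0.561, params)
        syn = (params.k_s_cdG * 1.4579 * params.K1**2 / (params.K1**2 + c**2)
               * 1221.0**2 / (1221.0**2 + params.Km1**2))
        deg = params.k_d_cdG * 0.561 * c / (c + params.Km2)
        assert syn == pytest.approx(deg, rel=1e-10)

    def test_increasing_in_gtp_and_dgc(self, params):
        lo = cdg_steady_state(400.0, 1.4579, 0.561, params)
        hi = cdg_steady_state(1221.0, 1.4579, 0.561, params)
        assert hi > lo
        assert cdg_steady_state(1221.0, 2.0, 0.561, params) > hi

    def test_zero_gtp_gives_zero(self, params):
        assert cdg_steady_state(0.0, 1.4579, 0.561, params) == 0.0


class TestNucleotideEquilibrium:
    def test_rich_split_reproduces_printed_pools(self, params):
        split = spot_split(1.5796, 1.5796, params)
        nuc = nucleotide_equilibrium(split, GUANINE_TOTAL, params)
        assert nuc.GTP == pytest.approx(1221, abs=2)
        assert nuc.ppGpp == pytest.approx(118, abs=2)
        assert nuc.GMP == pytest.approx(81, abs=1)

    def test_starved_split_reproduces_printed_pools(self, params, nitrogen_starved):
        relay = pts_equilibrium(nitrogen_starved, params)
        split = spot_split(relay.NPrP, relay.EIIAP, params)
        assert split.f_sd == pytest.approx(0.4914, abs=5e-4)
        nuc = nucleotide_equilibrium(split, GUANINE_TOTAL, params)
        assert nuc.GTP == pytest.approx(452, abs=2)
        assert nuc.ppGpp == pytest.approx(939, abs=2)
        assert nuc.ppGpp / nuc.GTP == pytest.approx(2.1, abs=0.05)

    def test_hydrolysis_only_limit(self, params):
        nuc = nucleotide_equilibrium(SpoTSplit(0.0, 0.0, 1.0), GUANINE_TOTAL, params)
        assert nuc.ppGpp == 0.0
        # all guanine in GTP/GMP at the 15:1 interconversion ratio
        assert nuc.GMP == pytest.approx(nuc.GTP / 15 + 2 * 0.0, abs=0.05)
        assert nuc.GTP == pytest.approx((15 / 16) * GUANINE_TOTAL, rel=0.01)

    def test_pure_synthetase_has_no_equilibrium(self, params):
        with pytest.raises(ValueError):
            nucleotide_equilibrium(SpoTSplit(math.inf, 1.0, 0.0), GUANINE_TOTAL, params)

    @pytest.mark.parametrize("f_sd", [0.05, 0.0872, 0.27, 0.4914])
    def test_conservation_closure(self, params, f_sd):
        split = SpoTSplit(f_sd / (1 - f_sd), f_sd, 1 - f_sd)
        nuc = nucleotide_equilibrium(split, GUANINE_TOTAL, params)
        closure = nuc.GTP + nuc.GMP + nuc.ppGpp + 2 * nuc.cdG
        assert closure == pytest.approx(GUANINE_TOTAL, rel=1e-8)


class TestFullEquilibrium:
    def test_guanine_total_matches_every_printed_column(self, params):
        """Printed pools in every nutrient condition sum to the same conserved
        total fixed by the initial conditions (1420.6 µM)."""
        for gln, pep, pyr in [(10000, 300, 1500), (1, 300, 1500), (1000, 2800, 900)]:
            eq = full_equilibrium(NutrientSignal(gln, pep, pyr), params)
            total = 2 * eq.cdG + eq.GTP + eq.GMP + eq.ppGpp
            assert total == pytest.approx(GUANINE_TOTAL, rel=1e-8)


class TestReproduceTable4:
    # (EI_T, NPr_T) -> printed simulated EI~P+NPr~P
    @pytest.mark.parametrize("ei_t, npr_t, printed", [
        (0.157, 24.4, 6.8),
        (0.3125, 24.4, 6.9),
        (0.729, 24.4, 7.0),
        (1.57, 24.4, 7.2),
        (0.729, 0.0, 0.2),
        (0.729, 12.2, 3.6),
        (0.729, 36.6, 10.5),
    ])
    def test_printed_simulation_column(self, params, ei_t, npr_t, printed):
        assert reproduce_table4(ei_t, npr_t, params) == pytest.approx(printed, abs=0.1)

    def test_sum_proportional_to_totals(self, params):
        base = reproduce_table4(0.729, 24.4, params)
        assert reproduce_table4(2 * 0.729, 2 * 24.4, params) == pytest.approx(2 * base)

    def test_gln_zero_overpredicts(self, params):
        """With the glutamine factor released (Gln=0) the predicted sums are
        several-fold larger than the printed column — the reason the
        calibration defaults to the nutrient-rich factor."""
        assert reproduce_table4(0.729, 24.4, params, Gln=0.0) > 2 * 7.0


class TestPepPyrSweep:
    def test_r_strictly_increasing_in_ratio(self, params):
        df = pep_pyr_sweep([0.05, 0.1, 0.2, 0.5, 1, 2, 5], params)
        assert (np.diff(df["r"]) > 0).all()
        assert (np.diff(df["f_sd"]) > 0).all()

    def test_linear_regime_r_doubles_with_ratio(self, params):
        # far below both Kd's the ratio enters linearly
        df = pep_pyr_sweep([1e-3, 2e-3], params, Gln=1000.0, fixed_pyr=1.0)
        assert df["r"][1] / df["r"][0] == pytest.approx(2.0, rel=1e-3)

    def test_product_anchor(self, params):
        df = pep_pyr_sweep([0.5, 2.0], params, pep_pyr_product=300.0 * 1500.0)
        assert np.allclose(df["PEP"] * df["Pyr"], 300.0 * 1500.0)
        assert (np.diff(df["r"]) > 0).all()

    def test_matched_gln_columns(self, params):
        """At Gln=1000 the relay rises from NPr~P 2.4 (high carbon) to 4.9
        (limited carbon) across the two nutrient-grid PEP:Pyr settings."""
        hi_c = pts_equilibrium(NutrientSignal(1000, 300, 1500), params)
        lo_c = pts_equilibrium(NutrientSignal(1000, 2800, 900), params)
        assert hi_c.NPrP == pytest.approx(2.4, abs=0.1)
        assert lo_c.NPrP == pytest.approx(4.9, abs=0.1)

    def test_nonpositive_ratio_rejected(self, params):
        with pytest.raises(ValueError):
            pep_pyr_sweep([0.5, -1.0], params)
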