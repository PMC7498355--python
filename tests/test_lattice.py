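"""Core lattice model: state enumeration, weights, partition function and
occupancy observables, cross-checked against closed forms and the
transfer-matrix oracle."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aplbind import (
    BindingParameters,
    LatticeState,
    apparent_kd,
    convert_scale,
    derived_constants,
    enumerate_states,
    fraction_free,
    occupancy_profile,
    parse_config,
    partition_function,
    promoter_occupancy,
    relative_expression,
    state_weight,
    transfer_matrix_Z,
)
from aplbind.lattice import ENUMERATION_CAP


class TestParseConfig:
    def test_wild_type_string(self):
        lat = parse_config("00111111100", pR_active=True, pL_active=True)
        assert lat.n_sites == 11
        assert lat.specific_indices == (3, 4, 5, 6, 7, 8, 9)
        assert lat.pR_footprint == frozenset({1, 2, 3, 4})
        assert lat.pL_footprint == frozenset({9, 10, 11})

    def test_minimal_single_site(self):
        lat = parse_config("1")
        assert lat.n_sites == 1 and lat.in_vitro
        assert lat.pR_footprint == frozenset()

    def test_scrambled_construct(self):
        lat = parse_config("00110001100")
        assert lat.specific_indices == (3, 4, 8, 9)

    def test_non_binary_character_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            parse_config("01x10")

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            parse_config("")

    def test_label_preserved(self):
        assert parse_config("111", label="attP3").label == "attP3"

    def test_default_footprint_needs_room(self):
        with pytest.raises(ValueError, match="footprint"):
            parse_config("111", pR_active=True)


class TestEnumeration:
    def test_in_vitro_state_count(self, wt_invitro):
        assert len(enumerate_states(wt_invitro)) == 2 ** 11

    def test_in_vivo_state_count_and_sector_decomposition(self, wt_invivo):
        states = enumerate_states(wt_invivo)
        assert len(states) == 2448
        pR_only = sum(s.rnap_pR and not s.rnap_pL for s in states)
        pL_only = sum(s.rnap_pL and not s.rnap_pR for s in states)
        both = sum(s.rnap_pR and s.rnap_pL for s in states)
        assert (pR_only, pL_only, both) == (128, 256, 16)

    def test_single_site_two_states(self):
        assert len(enumerate_states(parse_config("1"))) == 2

    def test_rnap_states_respect_footprints(self, wt_invivo):
        for s in enumerate_states(wt_invivo):
            if s.rnap_pR:
                assert all(s.occupancy[i - 1] == 0 for i in wt_invivo.pR_footprint)
            if s.rnap_pL:
                assert all(s.occupancy[i - 1] == 0 for i in wt_invivo.pL_footprint)

    def test_cap_refuses_large_lattice(self, params_eu):
        big = parse_config("1" * (ENUMERATION_CAP + 1))
        with pytest.raises(ValueError, match="transfer_matrix"):
            enumerate_states(big)
        # transfer matrix still handles it
        assert transfer_matrix_Z(big, params_eu, 100.0) > 1


class TestStateWeight:
    def test_empty_state_has_unit_weight(self, wt_invitro, params_eu):
        s = LatticeState((0,) * 11)
        assert state_weight(s, wt_invitro, params_eu, 1234.0) == 1.0

    def test_single_specific_site(self, params_eu):
        # c * (B + U) = 1000 * 5.54e-5
        lat = parse_config("1")
        w = state_weight(LatticeState((1,)), lat, params_eu, 1000.0)
        assert w == pytest.approx(0.0554, rel=1e-12)

    def test_adjacent_pair_gains_cooperativity(self, params_eu):
        lat = parse_config("11")
        w = state_weight(LatticeState((1, 1)), lat, params_eu, 1000.0)
        assert w == pytest.approx(0.0554 ** 2 * 50.7, rel=1e-12)

    def test_b_only_mode(self, params_eu):
        p = replace(params_eu, specific_weight_mode="B_only")
        lat = parse_config("1")
        w = state_weight(LatticeState((1,)), lat, p, 1000.0)
        assert w == pytest.approx(1000.0 * params_eu.B, rel=1e-12)

    def test_negative_concentration_rejected(self, params_eu):
        with pytest.raises(ValueError):
            state_weight(LatticeState((0,)), parse_config("1"), params_eu, -1.0)

    def test_rnap_on_occupied_footprint_rejected(self, wt_invivo, params_eu):
        bad = LatticeState((1,) + (0,) * 10, rnap_pR=True)
        with pytest.raises(ValueError):
            state_weight(bad, wt_invivo, params_eu, 10.0)


class TestPartitionFunction:
    def test_zero_concentration_in_vitro(self, wt_invitro, params_eu):
        assert partition_function(wt_invitro, params_eu, 0.0).Z == pytest.approx(1.0)

    def test_zero_concentration_in_vivo_closed_form(self, wt_invivo, params_eu):
        # only RNAP species contribute: (1 + R)(1 + L)
        Z = partition_function(wt_invivo, params_eu, 0.0).Z
        assert Z == pytest.approx((1 + 6.88) * (1 + 0.29), rel=1e-12)
        assert Z == pytest.approx(10.1652, rel=1e-12)

    def test_probabilities_normalised(self, wt_invivo, params_eu):
        ens = partition_function(wt_invivo, params_eu, 800.0)
        assert ens.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(ens.weights >= 0)

    def test_deterministic(self, wt_invivo, params_eu):
        a = partition_function(wt_invivo, params_eu, 321.0)
        b = partition_function(wt_invivo, params_eu, 321.0)
        assert np.array_equal(a.log_weights, b.log_weights)

    def test_extreme_parameters_stay_finite_in_log_space(self):
        p = BindingParameters(B=1.0, U=0.5, F=1e6)
        ens = partition_function(parse_config("1" * 15), p, 1e6)
        assert np.isfinite(ens.log_Z)
        assert ens.probabilities.sum() == pytest.approx(1.0, abs=1e-9)


class TestTransferMatrixOracle:
    def test_single_site_closed_form(self, params_eu):
        lat = parse_config("1")
        c = 500.0
        expected = 1 + c * (params_eu.B + params_eu.U)
        assert transfer_matrix_Z(lat, params_eu, c) == pytest.approx(expected, rel=1e-12)

    def test_zero_concentration(self, params_eu):
        assert transfer_matrix_Z(parse_config("10101"), params_eu, 0.0) == 1.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        config=st.text(alphabet="01", min_size=1, max_size=12),
        logB=st.floats(-8, -2), logU=st.floats(-8, -2),
        logF=st.floats(0, 3), logc=st.floats(0, 4),
        mode=st.sampled_from(["B_plus_U", "B_only"]),
    )
    def test_matches_enumeration_in_vitro(self, config, logB, logU, logF, logc, mode):
        p = BindingParameters(B=10 ** logB, U=10 ** logU, F=10 ** logF,
                              specific_weight_mode=mode)
        lat = parse_config(config)
        Z_enum = partition_function(lat, p, 10 ** logc).Z
        Z_tm = transfer_matrix_Z(lat, p, 10 ** logc)
        assert Z_tm == pytest.approx(Z_enum, rel=1e-10)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(logB=st.floats(-7, -3), logU=st.floats(-7, -3),
           logF=st.floats(0, 3), R=st.floats(0.01, 50), L=st.floats(0.01, 50),
           logc=st.floats(0, 3.5))
    def test_matches_enumeration_with_rnap_sectors(self, logB, logU, logF, R, L, logc):
        p = BindingParameters(B=10 ** logB, U=10 ** logU, F=10 ** logF, R=R, L=L)
        lat = parse_config("00111111100", pR_active=True, pL_active=True)
        Z_enum = partition_function(lat, p, 10 ** logc).Z
        Z_tm = transfer_matrix_Z(lat, p, 10 ** logc)
        assert Z_tm == pytest.approx(Z_enum, rel=1e-10)


class TestPromoterObservables:
    def test_zero_apl_occupancy_closed_form(self, wt_invivo, params_eu):
        assert promoter_occupancy(wt_invivo, params_eu, 0.0, "pR") == pytest.approx(
            6.88 / 7.88, rel=1e-12)
        assert promoter_occupancy(wt_invivo, params_eu, 0.0, "pL") == pytest.approx(
            0.29 / 1.29, rel=1e-12)

    def test_saturating_apl_clears_promoters(self, wt_invivo, params_eu):
        assert promoter_occupancy(wt_invivo, params_eu, 1e8, "pR") < 1e-6

    def test_inactive_promoter_rejected(self, wt_invitro, params_eu):
        with pytest.raises(ValueError):
            promoter_occupancy(wt_invitro, params_eu, 10.0, "pR")

    def test_matches_brute_force_state_sum(self, wt_invivo, params_eu):
        c = 1500.0
        states = enumerate_states(wt_invivo)
        w = np.array([state_weight(s, wt_invivo, params_eu, c) for s in states])
        brute = w[[s.rnap_pR for s in states]].sum() / w.sum()
        assert promoter_occupancy(wt_invivo, params_eu, c, "pR") == pytest.approx(
            brute, rel=1e-10)

    def test_relative_expression_is_one_at_zero(self, wt_invivo, params_eu):
        assert relative_expression(wt_invivo, params_eu, 0.0, "pR") == 1.0

    def test_relative_expression_non_increasing(self, wt_invivo, params_eu):
        grid = np.linspace(0, 3000, 40)
        vals = [relative_expression(wt_invivo, params_eu, c, "pR") for c in grid]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_nonspecific_binding_strengthens_repression(self, wt_invivo, params_eu):
        """Removing non-specific binding (U = 0) weakens repression at every c."""
        p_noU = replace(params_eu, U=0.0)
        for c in np.linspace(100, 3000, 12):
            with_U = relative_expression(wt_invivo, params_eu, c, "pR")
            without_U = relative_expression(wt_invivo, p_noU, c, "pR")
            assert without_U >= with_U - 1e-12


class TestFractionFree:
    def test_one_at_zero(self, wt_invitro, params_eu):
        assert fraction_free(wt_invitro, params_eu, 0.0) == 1.0

    def test_single_site_closed_form(self, params_eu):
        lat = parse_config("1")
        c = 700.0
        expected = 1 / (1 + c * (params_eu.B + params_eu.U))
        assert fraction_free(lat, params_eu, c) == pytest.approx(expected, rel=1e-12)

    def test_rejects_active_promoters(self, wt_invivo, params_eu):
        with pytest.raises(ValueError):
            fraction_free(wt_invivo, params_eu, 100.0)

    def test_non_increasing_and_matches_enumeration(self, params_nM):
        lat = parse_config("1111111")
        grid = np.array([0, 50, 100, 200, 400, 800, 1600], dtype=float)
        vals = np.array([fraction_free(lat, params_nM, c) for c in grid])
        assert np.all(np.diff(vals) <= 0)
        for c, v in zip(grid, vals):
            ens = partition_function(lat, params_nM, c)
            assert v == pytest.approx(ens.probabilities[0], rel=1e-10)


class TestOccupancyProfile:
    def test_zero_concentration(self, wt_invitro, params_eu):
        prof = occupancy_profile(wt_invitro, params_eu, 0.0)
        assert np.all(prof.site_occupancy == 0)
        assert prof.stoichiometry[0] == 1.0

    @pytest.mark.parametrize("c", [50.0, 400.0, 2000.0])
    def test_normalisation_and_mean_consistency(self, params_nM, c):
        lat = parse_config("001111100")
        prof = occupancy_profile(lat, params_nM, c)
        assert prof.stoichiometry.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((prof.site_occupancy >= 0) & (prof.site_occupancy <= 1))
        mean_bound = (np.arange(prof.stoichiometry.size) * prof.stoichiometry).sum()
        assert prof.site_occupancy.sum() == pytest.approx(mean_bound, abs=1e-10)


class TestApparentKd:
    def test_single_site_closed_form(self, params_eu):
        kd = apparent_kd(parse_config("1"), params_eu)
        assert kd == pytest.approx(1 / (params_eu.B + params_eu.U), rel=1e-7)

    def test_decreases_with_operator_count(self, params_nM):
        kds = [apparent_kd(parse_config("1" * n), params_nM) for n in range(3, 8)]
        assert np.all(np.diff(kds) < 0)

    def test_scrambled_sites_bind_weaker(self, params_nM):
        kd_111 = apparent_kd(parse_config("111"), params_nM)
        for cfg in ["101", "1101", "10101"]:
            assert apparent_kd(parse_config(cfg), params_nM) > kd_111

    def test_half_occupancy_criterion_exceeds_free_dna_criterion(self, params_nM):
        # half-filling all operators takes more protein than shifting half
        # the molecules off the free band
        lat = parse_config("111")
        assert apparent_kd(lat, params_nM, "half_occupancy") > apparent_kd(lat, params_nM)

    def test_unknown_criterion(self, params_nM):
        with pytest.raises(ValueError):
            apparent_kd(parse_config("111"), params_nM, criterion="nope")


class TestDerivedConstants:
    def test_no_cooperativity_means_zero_free_energy(self):
        p = BindingParameters(B=1e-5, U=1e-6, F=1.0)
        assert derived_constants(p)["dG_coop_kcal_mol"] == 0.0

    def test_cooperativity_free_energy(self, params_eu):
        dG = derived_constants(params_eu, temperature=310.0)["dG_coop_kcal_mol"]
        assert dG == pytest.approx(-2.418, abs=5e-3)

    def test_single_operator_kd(self, params_eu):
        out = derived_constants(params_eu)
        assert out["kd_specific"] == pytest.approx(1 / 4.55e-5, rel=1e-12)
        assert out["kd_specific"] == pytest.approx(22000, rel=0.005)

    def test_molar_quantities_only_on_nM_scale(self, params_eu, params_nM):
        assert "dG_specific_kcal_mol" not in derived_constants(params_eu)
        out = derived_constants(params_nM, temperature=310.0)
        assert out["B_per_M"] == pytest.approx(79625, rel=1e-12)
        assert out["kd_nonspecific_M"] == pytest.approx(58e-6, rel=0.005)

    def test_invalid_temperature(self, params_eu):
        with pytest.raises(ValueError):
            derived_constants(params_eu, temperature=0.0)


class TestConvertScale:
    def test_identity_with_unit_factor(self, params_eu):
        p = convert_scale(params_eu, d=1.0, direction="to_nM")
        assert (p.B, p.U) == (params_eu.B, params_eu.U)
        assert p.scale == "per_nM"

    def test_printed_calibration(self, params_eu):
        p = convert_scale(params_eu, d=1.75, direction="to_nM")
        assert p.B * 1e9 == pytest.approx(79700, rel=0.005)
        assert p.U * 1e9 == pytest.approx(17300, rel=0.005)

    def test_round_trip_identity(self, params_eu):
        back = convert_scale(convert_scale(params_eu, direction="to_nM"),
                             direction="to_expression_units")
        assert back == params_eu

    def test_observables_scale_invariant(self, params_eu, params_nM):
        """c*B weights are invariant, so every observable is identical when
        concentrations are converted consistently (c_nM = c_EU / d)."""
        lat = parse_config("1111111")
        d = params_eu.d
        for c_eu in [100.0, 800.0, 2500.0]:
            assert fraction_free(lat, params_nM, c_eu / d) == pytest.approx(
                fraction_free(lat, params_eu, c_eu), rel=1e-10)
        prof_eu = occupancy_profile(lat, params_eu, 1000.0)
        prof_nm = occupancy_profile(lat, params_nM, 1000.0 / d)
        np.testing.assert_allclose(prof_eu.site_occupancy, prof_nm.site_occupancy,
                                   rtol=1e-10)

    def test_unknown_direction(self, params_eu):
        with pytest.raises(ValueError):
            convert_scale(params_eu, direction="sideways")

    def test_double_conversion_rejected(self, params_nM):
        with pytest.raises(ValueError):
            convert_scale(params_nM, direction="to_nM")
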