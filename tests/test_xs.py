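"""Cross-section data model: validation, interpolation, probabilities, I/O."""
import logging

import numpy as np
import pytest

from iortmc import transport, xs
from iortmc.constants import IP_LIQUID_EV

from conftest import make_single_channel_xs


class TestDefaultSet:
    def test_all_nine_channels_present_and_valid(self, xs_default):
        assert set(xs_default.channels) == set(xs.CHANNEL_NAMES)
        for ch in xs_default.channels.values():
            assert np.all(np.diff(ch.grid) > 0)
            assert np.all(ch.sigma >= 0)

    def test_sigma_zero_below_threshold(self, xs_default):
        # vibrational excitation opens at 0.2 eV
        assert xs_default.sigma("vibrational", 0.1) == 0.0
        assert xs_default.sigma("electronic_excitation", 2.0) == 0.0
        assert xs_default.sigma("single_ionization", 5.0) == 0.0

    def test_interpolation_exact_at_grid_nodes(self, xs_default):
        for name in ("elastic", "single_ionization", "attachment"):
            ch = xs_default.channels[name]
            got = ch.sigma_at(ch.grid)
            mask = ch.grid >= ch.threshold
            assert np.array_equal(got[mask], ch.sigma[mask])

    def test_total_inelastic_bounds_components(self, xs_default):
        E = np.geomspace(0.03, 9.9e3, 40)
        tot = xs_default.sigma_total_inelastic(E)
        for name in xs.CHANNEL_NAMES:
            if name != "elastic":
                assert np.all(tot >= xs_default.sigma(name, E) - 1e-12)

    def test_attachment_confined_to_resonance_window(self, xs_default):
        assert xs_default.sigma("attachment", 3.0) == 0.0
        assert xs_default.sigma("attachment", 8.2) > 0.0
        assert xs_default.sigma("attachment", 50.0) == 0.0

    def test_stopping_proxy_matches_bethe_at_10kev(self, xs_default, density):
        # n * sum_i sigma_i <dE>_i at the track-structure ceiling vs the
        # Born-limit collision stopping power of water
        n = xs_default.medium.number_density
        s_proxy = density.stopping_cs[-1] * n * 1e-16 / 1e6  # MeV/cm
        s_bethe = transport.collision_stopping_mev_cm(0.01)
        assert abs(s_proxy - s_bethe) / s_bethe < 0.25


class TestValidation:
    def test_negative_sigma_rejected(self):
        grid = np.array([1.0, 10.0, 100.0])
        with pytest.raises(ValueError, match="negative"):
            xs.InteractionChannel(
                "elastic", 0.0, False, grid, np.array([1.0, -1.0, 1.0]),
                xs.EnergyLossModel("kinematic"),
            )

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            xs.InteractionChannel(
                "elastic", 0.0, False, np.array([1.0, 0.5, 2.0]),
                np.ones(3), xs.EnergyLossModel("kinematic"),
            )

    def test_missing_channel_named_in_error(self, xs_default, tmp_path):
        path = tmp_path / "xs.csv"
        xs.write_xs_file(xs_default, path)
        text = path.read_text()
        lines = [
            ln for ln in text.splitlines() if not ln.startswith("attachment,")
        ]
        path.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="attachment"):
            xs.read_xs_file(path)

    def test_extrapolation_above_range_forbidden(self, xs_default):
        with pytest.raises(ValueError, match="extrapolation"):
            xs_default.sigma("elastic", 2e4)

    def test_medium_consistency(self):
        with pytest.raises(ValueError, match="number_density"):
            xs.MediumProperties(mass_density=1.0, number_density=4e22)
        m = xs.MediumProperties()
        derived = 1.0 * 6.02214076e23 / 18.015
        assert abs(m.number_density - derived) / derived < 1e-3
        assert m.ionization_potential_liquid < 12.8


class TestRoundTrip:
    def test_write_read_preserves_tables_and_metadata(self, xs_default, tmp_path):
        path = tmp_path / "xs.csv"
        xs.write_xs_file(xs_default, path)
        back = xs.read_xs_file(path)
        for name, ch in xs_default.channels.items():
            assert np.array_equal(back.channels[name].grid, ch.grid)
            assert np.array_equal(back.channels[name].sigma, ch.sigma)
            assert back.channels[name].threshold == ch.threshold
            assert back.channels[name].dissociative == ch.dissociative
            assert back.channels[name].energy_loss_model.kind == ch.energy_loss_model.kind
        assert back.medium.ionization_potential_liquid == IP_LIQUID_EV


class TestChannelProbabilities:
    def test_sub_excitation_energy_opens_only_elastic_and_rotational(self, xs_default):
        probs = xs.channel_probabilities(xs_default, 0.1)
        open_channels = {c for c, p in probs.items() if p > 0}
        assert open_channels == {"elastic", "rotational"}
        assert abs(sum(probs.values()) - 1.0) < 1e-12

    def test_ionization_dominates_excitation_at_1kev(self, xs_default):
        probs = xs.channel_probabilities(xs_default, 1000.0)
        assert probs["single_ionization"] > probs["electronic_excitation"]

    @pytest.mark.parametrize("energy", [0.05, 1.0, 15.0, 200.0, 5e3])
    def test_probabilities_normalized(self, xs_default, energy):
        probs = xs.channel_probabilities(xs_default, energy)
        assert abs(sum(probs.values()) - 1.0) < 1e-12
        assert all(p >= 0 for p in probs.values())

    def test_out_of_range_energy_directs_to_high_energy_stage(self, xs_default):
        with pytest.raises(ValueError, match="condensed-history"):
            xs.channel_probabilities(xs_default, 5e4)


class TestMeanFreePath:
    def test_hand_evaluated_value(self):
        # n = 3.34e22 cm^-3 and sigma_total = 1e-16 cm^2 -> 2.994e-7 cm
        rho = 3.34e22 * 18.015 / 6.02214076e23
        data = make_single_channel_xs(sigma_elastic=1.0, mass_density=rho)
        lam = xs.mean_free_path(data, 100.0)
        assert lam == pytest.approx(2.994e-7, rel=1e-3)

    def test_doubling_density_halves_path(self):
        a = make_single_channel_xs(mass_density=0.5)
        b = make_single_channel_xs(mass_density=1.0)
        assert xs.mean_free_path(a, 10.0) == pytest.approx(
            2.0 * xs.mean_free_path(b, 10.0), rel=1e-12
        )

    def test_positive_on_whole_grid(self, xs_default):
        for E in np.geomspace(0.03, 9.5e3, 30):
            assert xs.mean_free_path(xs_default, float(E)) > 0

    def test_no_open_channel_errors(self):
        data = make_single_channel_xs(sigma_elastic=0.0)
        with pytest.raises(ValueError, match="no open channel"):
            xs.mean_free_path(data, 10.0)


class TestNeutralDissociationByDifference:
    def test_simple_difference(self):
        grid = np.array([10.0, 20.0])
        out = xs.neutral_dissociation_by_difference(
            grid, np.array([10.0, 10.0]), {"a": np.array([9.0, 9.0])}
        )
        assert np.allclose(out, [1.0, 1.0])

    def test_clip_with_warning(self, caplog):
        grid = np.array([10.0, 20.0])
        with caplog.at_level(logging.WARNING, logger="iortmc.xs"):
            out = xs.neutral_dissociation_by_difference(
                grid, np.array([10.0, 10.0]), {"a": np.array([11.0, 9.0])}
            )
        assert np.allclose(out, [0.0, 1.0])
        assert any("clipped" in rec.message for rec in caplog.records)

    def test_components_equal_total_gives_zero(self):
        grid = np.array([1.0, 2.0, 3.0])
        tot = np.array([5.0, 6.0, 7.0])
        out = xs.neutral_dissociation_by_difference(grid, tot, {"a": tot})
        assert np.all(out == 0.0)

    def test_grid_mismatch_errors(self):
        with pytest.raises(ValueError, match="common grid"):
            xs.neutral_dissociation_by_difference(
                np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]), {}
            )
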