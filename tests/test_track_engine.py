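"""Cascade engine: stepping semantics, conservation laws, oracle equivalence."""
import numpy as np
import pytest
from scipy import stats

from iortmc import track, xs
from iortmc.xs import CHANNEL_NAMES, ELECTRONIC_LEVEL_CHANNELS


def _electron(energy, z=0.0):
    return track.ElectronState(
        np.array([0.0, 0.0, z]), np.array([0.0, 0.0, 1.0]), energy
    )


class TestStep:
    def test_sub_thermal_electron_thermalizes_without_collision(self, xs_default):
        rng = np.random.default_rng(1)
        e = _electron(0.020)
        outcome, secs = track.step(e, xs_default, track.TrackGeometry.infinite(), rng)
        assert outcome == "thermalized"
        assert e.status == "thermalized"
        assert secs == []

    def test_dead_electron_cannot_step(self, xs_default):
        rng = np.random.default_rng(2)
        e = _electron(0.020)
        track.step(e, xs_default, track.TrackGeometry.infinite(), rng)
        with pytest.raises(ValueError):
            track.step(e, xs_default, track.TrackGeometry.infinite(), rng)

    def test_energy_ledger_per_step(self, xs_default):
        # E_before = E_after + deposited + secondary energy, exactly
        rng = np.random.default_rng(3)
        geom = track.TrackGeometry.infinite()
        for E0 in (0.5, 5.0, 50.0, 500.0, 5e3):
            for _ in range(60):
                e = _electron(E0)
                before = e.energy
                outcome, secs = track.step(e, xs_default, geom, rng)
                if not isinstance(outcome, track.CollisionEvent):
                    continue
                sec_energy = sum(s.energy for s in secs)
                if outcome.channel == "attachment":
                    deposited = before
                elif outcome.channel == "single_ionization":
                    deposited = outcome.energy_loss - sec_energy
                elif outcome.channel in ("double_ionization", "kshell_ionization"):
                    deposited = outcome.energy_loss - sec_energy
                else:
                    deposited = outcome.energy_loss
                balance = e.energy + deposited + sec_energy
                assert balance == pytest.approx(before, rel=1e-9)

    def test_attachment_terminates_with_status(self, xs_default):
        rng = np.random.default_rng(4)
        geom = track.TrackGeometry.infinite()
        seen = False
        for _ in range(4000):
            e = _electron(8.2)  # inside the attachment resonance window
            outcome, _ = track.step(e, xs_default, geom, rng)
            if isinstance(outcome, track.CollisionEvent) and outcome.channel == "attachment":
                assert e.status == "attached"
                assert e.energy == 0.0
                seen = True
                break
        assert seen, "no attachment sampled inside the resonance window"

    def test_geometry_region_lookup_errors_outside_slab(self):
        geom = track.TrackGeometry(np.array([0.0, 10.0]), ["layer"])
        with pytest.raises(ValueError, match="outside"):
            geom.region_at(11.0)


class TestRunTracks:
    def test_identical_seed_gives_bit_identical_tally(self, xs_default):
        a = track.run_tracks(300.0, 25, xs_default, seed=7)
        b = track.run_tracks(300.0, 25, xs_default, seed=7)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.deposited_energy, b.deposited_energy)
        assert a.n_secondaries == b.n_secondaries

    def test_electron_number_closure(self, cascade_1kev):
        t = cascade_1kev
        assert (
            t.n_thermalized + t.n_attached + t.n_escaped
            == t.n_primaries + t.n_secondaries
        )

    def test_cascade_energy_conservation(self, cascade_1kev):
        t = cascade_1kev
        out = t.deposited_energy.sum() + t.energy_escaped
        assert abs(out - t.energy_in) / t.energy_in < 1e-6

    def test_escape_through_thin_slab(self, xs_default):
        geom = track.TrackGeometry(np.array([0.0, 5.0]), ["film"])  # 5 nm
        t = track.run_tracks(
            5e3, 30, xs_default, geometry=geom, seed=8,
            start_position=(0.0, 0.0, 1.0),
        )
        assert t.n_escaped > 0
        assert t.energy_escaped > 0

    def test_channel_frequencies_match_sigma_ratios(self, xs_default):
        # chi-squared on n = 1e5 single-collision channel selections at 100 eV
        tables = track._XsTables(xs_default)
        rng = np.random.default_rng(9)
        E = np.full(100_000, 100.0)
        idx = tables.index(E)
        u = rng.random(E.size)
        picks = (u[:, None] > tables.cum_prob[idx]).sum(1)
        observed = np.bincount(picks, minlength=len(CHANNEL_NAMES))
        probs = xs.channel_probabilities(xs_default, float(tables.grid[idx[0]]))
        expected = E.size * np.array([probs[c] for c in CHANNEL_NAMES])
        keep = expected > 5
        p = stats.chisquare(observed[keep], expected[keep]).pvalue
        assert p > 0.01

    def test_mean_secondary_energy_tracks_continuum_mean(self, cascade_1kev):
        # the ionization continuum mean is 12.5 eV; cascade secondaries include
        # double/K-shell ejections but remain in the same range
        assert 8.0 < cascade_1kev.mean_secondary_energy() < 16.0


class TestOracleEquivalence:
    def test_cascade_counts_match_degradation_estimator(
        self, xs_default, density, cascade_1kev
    ):
        """Monte Carlo cascade counts at 1 keV vs the deterministic
        degradation-spectrum estimator, within 10%."""
        n = cascade_1kev.n_primaries
        per = {c: v / n for c, v in cascade_1kev.channel_totals().items()}
        exp = density.counts(1000.0)
        for c in CHANNEL_NAMES:
            if exp[c] >= 5.0:  # channels with enough statistics at n = 80
                assert per[c] == pytest.approx(exp[c], rel=0.10), c
        mc_elec = sum(per[c] for c in ELECTRONIC_LEVEL_CHANNELS)
        est_elec = sum(exp[c] for c in ELECTRONIC_LEVEL_CHANNELS)
        assert mc_elec == pytest.approx(est_elec, rel=0.10)


class TestExpectedCollisionCounts:
    def test_zero_below_all_inelastic_thresholds(self, xs_default, density):
        counts = track.expected_collision_counts(0.02, xs_default, density)
        assert all(v == 0.0 for v in counts.values())

    def test_monotone_nondecreasing_in_energy(self, density):
        energies = [10.0, 100.0, 1e3, 1e4, 1e5, 1e6, 6e6]
        prev = None
        for E0 in energies:
            counts = density.counts(E0)
            if prev is not None:
                for c in CHANNEL_NAMES:
                    assert counts[c] >= prev[c] - 1e-9
            prev = counts

    def test_6mev_slowdown_budget(self, density):
        """A 6 MeV electron suffers ~2e5 electronic-level inelastic
        collisions, ~80% of which ionize the molecule."""
        summary = track.electronic_level_summary(density.counts(6.0e6))
        assert summary["electronic_level_total"] == pytest.approx(2.0e5, rel=0.30)
        assert summary["ionizing_fraction"] == pytest.approx(0.80, rel=0.30)
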