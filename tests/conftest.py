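"""Shared fixtures: expensive simulation products are built once per session."""
from __future__ import annotations

import numpy as np
import pytest

from iortmc import beamfit, fixtures, pipeline, track, transport, xs


@pytest.fixture(scope="session")
def xs_default():
    return xs.default_cross_sections()


@pytest.fixture(scope="session")
def density(xs_default):
    return track.CollisionDensity(xs_default)


@pytest.fixture(scope="session")
def cascade_1kev(xs_default):
    """A seeded 1 keV cascade run shared by engine and acceptance tests."""
    return track.run_tracks(1000.0, 80, xs_default, seed=3)


@pytest.fixture(scope="session")
def mono_pdds():
    """Monoenergetic depth-dose curves at three energies (seeded)."""
    return {
        e: transport.compute_pdd(e, n_primaries=2500, seed=21 + i)
        for i, e in enumerate((2.0, 4.0, 6.0))
    }


@pytest.fixture(scope="session")
def nominal_pdd():
    """Simulated PDD of the bundled nominal-6 MeV spectrum."""
    return transport.compute_pdd(
        beamfit.nominal_6mev_spectrum(), n_primaries=6000, seed=3
    )


@pytest.fixture(scope="session")
def measured_pdd():
    """The synthetic measured-like nominal PDD (R50 pinned to 24.2 mm)."""
    return fixtures.synthetic_measured_pdd(seed=0, n_primaries=6000)


@pytest.fixture(scope="session")
def basis():
    return beamfit.build_basis(
        beamfit.default_energy_grid(), n_primaries=1200, seed=42
    )


@pytest.fixture(scope="session")
def pipeline_report():
    cfg = pipeline.RunConfig(
        positions_mm=(15.3, 24.0, 30.0),
        n_primaries_transport=4000,
        n_interface_secondaries=1500,
        seed=1,
        outdir="scratch_unused",
    )
    return pipeline.run_pipeline(cfg, write=False)


def make_single_channel_xs(sigma_elastic: float = 1.0, mass_density: float = 1.0):
    """A degenerate nine-channel set where only elastic is non-zero: lets
    tests control sigma_total exactly for mean-free-path arithmetic."""
    grid = np.geomspace(0.025, 1e4, 16)
    medium = xs.MediumProperties(mass_density=mass_density)
    channels = {}
    for name in xs.CHANNEL_NAMES:
        sig = np.full_like(grid, sigma_elastic if name == "elastic" else 0.0)
        loss = (
            xs.EnergyLossModel("kinematic")
            if name == "elastic"
            else xs.EnergyLossModel("constant", {"value": 0.015})
        )
        channels[name] = xs.InteractionChannel(name, 0.0, False, grid, sig, loss)
    return xs.CrossSectionSet(channels, medium, (0.025, 1e4))
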