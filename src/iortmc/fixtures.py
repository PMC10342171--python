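"""Deterministic synthetic inputs emulating the study's measured data.

No deposited datasets exist for this experiment, so tests and examples run
on synthetic stand-ins generated here: a measured-like nominal-6 MeV
percentage depth-dose curve (R50 = 24.2 mm), two-component beam spectra,
clonogenic survival series from the linear depth-response model, and a
reduced toy cross-section table for fast I/O tests.  Everything regenerates
bit-identically for a fixed seed.
"""
from __future__ import annotations

import os

import numpy as np

from . import beamfit, survival, transport, xs

FIXTURE_KINDS = ("pdd", "spectrum", "sf_series", "xs_toy")


def synthetic_measured_pdd(seed: int = 0, n_primaries: int = 6000) -> transport.PDDCurve:
    """A measured-like nominal-6 MeV PDD (synthetic).

    Simulates the bundled nominal spectrum at moderate statistics and applies
    one affine depth rescale so the interpolated distal 50% depth is exactly
    24.2 mm — emulating a scanned ionization-chamber curve for a beam whose
    R50 is known.
    """
    spec = beamfit.nominal_6mev_spectrum()
    curve = transport.compute_pdd(
        spec, n_primaries=n_primaries, seed=seed, label="synthetic measured 6 MeV"
    )
    measured_r50 = transport.r50(curve)
    scale = 24.2 / measured_r50
    return transport.PDDCurve(
        curve.depth_mm * scale, curve.dose_percent, curve.label
    )


def two_component_spectrum(
    main=(5.0, 0.7), secondary=(3.5, 0.3), grid=None
) -> beamfit.BeamSpectrum:
    """A two-line test spectrum (energies in MeV with weights)."""
    if grid is None:
        grid = beamfit.default_energy_grid()
    grid = np.asarray(grid, float)
    w = np.zeros_like(grid)
    for e, wt in (main, secondary):
        j = int(np.argmin(np.abs(grid - e)))
        w[j] += wt
    return beamfit.BeamSpectrum(grid, w, label="two-component")


def toy_cross_sections(n_grid: int = 36) -> xs.CrossSectionSet:
    """A coarsened copy of the bundled cross-section set for fast tests."""
    full = xs.default_cross_sections()
    channels = {}
    for name, ch in full.channels.items():
        take = np.unique(
            np.concatenate(
                [
                    np.linspace(0, ch.grid.size - 1, n_grid).astype(int),
                    [0, ch.grid.size - 1],
                ]
            )
        )
        channels[name] = xs.InteractionChannel(
            name,
            ch.threshold,
            ch.dissociative,
            ch.grid[take],
            ch.sigma[take],
            ch.energy_loss_model,
        )
    return xs.CrossSectionSet(channels, full.medium, full.energy_range)


def make_fixtures(kind: str, seed: int = 0, outdir: str = ".") -> list:
    """Write deterministic fixture files; returns the paths written."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    os.makedirs(outdir, exist_ok=True)
    paths = []
    if kind == "pdd":
        curve = synthetic_measured_pdd(seed=seed)
        path = os.path.join(outdir, "pdd_nominal6MeV_synthetic.csv")
        curve.to_csv(path)
        paths.append(path)
    elif kind == "spectrum":
        for name, spec in (
            ("nominal6MeV", beamfit.nominal_6mev_spectrum()),
            ("two_component", two_component_spectrum()),
        ):
            path = os.path.join(outdir, f"spectrum_{name}.csv")
            spec.to_csv(path)
            paths.append(path)
    elif kind == "sf_series":
        series = survival.generate_synthetic_sf(seed=seed)
        path = os.path.join(outdir, "sf_series_synthetic.csv")
        series.to_csv(path)
        paths.append(path)
    elif kind == "xs_toy":
        path = os.path.join(outdir, "xs_water_toy.csv")
        xs.write_xs_file(toy_cross_sections(), path)
        paths.append(path)
    return paths
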