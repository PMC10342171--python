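"""Molecular-damage accounting: absorbed dose per region, scaling to a target
dose, dissociative-event counting and relative damage across positions.

Molecular damage is quantified as the number of dissociative inelastic
events (ionization, electronic excitation including neutral dissociation,
vibrational excitation and attachment) induced per incident electron in the
cell layer, scaled to the number of electrons required to deliver a fixed
absorbed dose (5 Gy by default).  Elastic scattering and rotational
excitation shape the tracks and heat the medium but cannot dissociate the
molecule and are never counted.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import JOULE_PER_MEV
from .track import Tally
from .transport import SlabGeometry
from .xs import CHANNEL_NAMES, DISSOCIATIVE_CHANNELS

REFERENCE_AREA_CM2 = 1.0  # mass normalisation area; per-primary results are
# area independent, the area only fixes the primaries-per-cm^2 figure


@dataclass
class DoseReport:
    """Per-region energy, mass and dose per primary, plus dose scaling."""

    regions: list
    energy_per_primary_mev: dict
    mass_g_per_cm2: dict
    dose_per_primary_gy: dict
    target_dose_gy: float
    scaling_region: str
    scale_factor: float  # multiply per-primary quantities by this for target
    n_primaries_required: float

    def total_energy_mev(self) -> float:
        return float(sum(self.energy_per_primary_mev.values()))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "region": self.regions,
                "energy_per_primary_MeV": [
                    self.energy_per_primary_mev[r] for r in self.regions
                ],
                "mass_g_cm2": [self.mass_g_per_cm2[r] for r in self.regions],
                "dose_per_primary_Gy": [
                    self.dose_per_primary_gy[r] for r in self.regions
                ],
            }
        )


@dataclass
class DamageSummary:
    """Dissociative-event accounting for one irradiation position."""

    position_mm: float
    counts_per_primary: float
    dose_per_primary_gy: float
    target_dose_gy: float
    n_primaries_required: float
    counts_at_target_dose: float
    uncertainty_fraction: float = 0.10
    relative_damage: float = float("nan")
    detail: dict = field(default_factory=dict)


def dissociative_count(
    tally_or_counts,
    channel_flags: dict | None = None,
    regions=None,
) -> float:
    """Total dissociative events in a tally or a channel->count map.

    ``channel_flags`` overrides which channels count as dissociative
    (default: ionization channels, electronic excitation incl. neutral
    dissociation, vibrational excitation and attachment; never elastic or
    rotational).
    """
    if channel_flags is None:
        flags = {c: (c in DISSOCIATIVE_CHANNELS) for c in CHANNEL_NAMES}
    else:
        flags = {c: bool(channel_flags.get(c, False)) for c in CHANNEL_NAMES}
    flags["elastic"] = False
    flags["rotational"] = False

    if isinstance(tally_or_counts, Tally):
        tally = tally_or_counts
        total = 0.0
        for i, region in enumerate(tally.regions):
            if regions is not None and region not in regions:
                continue
            for j, ch in enumerate(CHANNEL_NAMES):
                if flags[ch]:
                    total += float(tally.counts[i, j])
        return total
    counts = tally_or_counts
    return float(sum(v for c, v in counts.items() if flags.get(c, False)))


def region_masses_g_per_cm2(geometry: SlabGeometry) -> dict:
    """Areal mass of each region (thickness x density, per cm^2 of field)."""
    return {
        r.name: r.thickness_mm / 10.0 * r.density * REFERENCE_AREA_CM2
        for r in geometry.regions
    }


def dose_in_region(
    energy_per_primary_mev: dict,
    geometry: SlabGeometry,
    target_dose_gy: float = 5.0,
    scaling_region: str = "cell_layer",
) -> DoseReport:
    """Convert per-region energy per primary into dose and dose scaling.

    dose/primary = E[MeV] * 1.602e-13 J/MeV / mass[kg]; the number of
    primaries (per cm^2) required for the target dose follows from
    n = D * m / (E_per_primary * 1.602e-13).
    """
    masses = region_masses_g_per_cm2(geometry)
    dose = {}
    for name in masses:
        e = energy_per_primary_mev.get(name, 0.0)
        mass_kg = masses[name] / 1000.0
        dose[name] = e * JOULE_PER_MEV / mass_kg
    if scaling_region not in masses:
        raise ValueError(f"unknown scaling region {scaling_region!r}")
    if dose[scaling_region] <= 0.0:
        raise ValueError(
            f"no energy deposited in scaling region {scaling_region!r}"
        )
    scale = target_dose_gy / dose[scaling_region]
    return DoseReport(
        regions=list(masses),
        energy_per_primary_mev={n: float(energy_per_primary_mev.get(n, 0.0)) for n in masses},
        mass_g_per_cm2=masses,
        dose_per_primary_gy=dose,
        target_dose_gy=target_dose_gy,
        scaling_region=scaling_region,
        scale_factor=scale,
        n_primaries_required=scale,
    )


def relative_damage(summaries: list) -> list:
    """Normalize scaled damage counts to the first (shallowest) position."""
    if not summaries:
        return summaries
    ordered = sorted(summaries, key=lambda s: s.position_mm)
    ref = ordered[0].counts_at_target_dose
    if ref <= 0:
        raise ValueError("zero damage count at the reference position")
    for s in ordered:
        s.relative_damage = s.counts_at_target_dose / ref
    return ordered


def combine_uncertainty(statistical_percent: float, systematic_percent: float) -> float:
    """Quadrature combination of statistical and systematic uncertainties (%)."""
    if statistical_percent < 0 or systematic_percent < 0:
        raise ValueError("uncertainties must be non-negative")
    return float(np.hypot(statistical_percent, systematic_percent))
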