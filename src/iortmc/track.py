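"""Event-by-event Monte Carlo transport of electrons (<=10 keV) in liquid water.

Every single collision is sampled: exponential free paths from the total
cross section, channel selection proportional to the partial cross sections,
energy losses from per-channel distributions, angular deflection from a
screened-Rutherford elastic shape raised to the power (1 - dE/E) for
inelastic events, and explicit secondary-electron cascades for the
ionization channels.  Electrons terminate by thermalization (below 25 meV),
attachment, or escape from the slab.

Two engines share the same physics: a scalar :func:`step` that advances one
electron by one event (used for inspection and unit tests), and the batched
:func:`run_tracks` that advances the whole alive population one event per
iteration with numpy array operations.

:func:`expected_collision_counts` is the deterministic companion: a
continuous-slowing-down degradation-spectrum estimator of per-channel event
counts for a full slowdown, applied recursively to the secondary population.
It serves as the fast oracle for cascade counts and as the events-per-eV
bridge used by the pipeline when fast (condensed-history) electrons cross
the scoring layers.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .constants import (
    ELECTRON_MASS_U,
    THERMAL_CUTOFF_EV,
    WATER_MOLAR_MASS,
)
from .xs import CHANNEL_NAMES, CrossSectionSet, IONIZING_CHANNELS

# kinematic factor 2 m_e M / (m_e + M)^2 for elastic recoil on a water molecule
_KIN_FACTOR = (
    2.0
    * ELECTRON_MASS_U
    * WATER_MOLAR_MASS
    / (ELECTRON_MASS_U + WATER_MOLAR_MASS) ** 2
)

_CH_INDEX = {name: i for i, name in enumerate(CHANNEL_NAMES)}


# ---------------------------------------------------------------------------
# States, events, tallies
# ---------------------------------------------------------------------------
@dataclass
class ElectronState:
    """A transported electron: position (nm), unit direction, energy (eV)."""

    position: np.ndarray
    direction: np.ndarray
    energy: float
    generation: int = 0
    status: str = "alive"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        self.direction = np.asarray(self.direction, float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.energy < 0:
            raise ValueError("energy must be non-negative")


@dataclass
class CollisionEvent:
    channel: str
    energy_loss: float
    scatter_angle: float
    azimuth: float
    region: str
    secondary_energy: float | None = None


@dataclass
class Tally:
    """Per-region, per-channel event counts and deposited energy (eV)."""

    regions: list
    counts: np.ndarray  # (n_regions, n_channels)
    deposited_energy: np.ndarray  # (n_regions,)
    n_primaries: int = 0
    n_secondaries: int = 0
    n_thermalized: int = 0
    n_attached: int = 0
    n_escaped: int = 0
    energy_in: float = 0.0
    energy_escaped: float = 0.0
    secondary_energy_sum: float = 0.0
    manifest: dict = field(default_factory=dict)

    @classmethod
    def empty(cls, regions) -> "Tally":
        regions = list(regions)
        return cls(
            regions,
            np.zeros((len(regions), len(CHANNEL_NAMES))),
            np.zeros(len(regions)),
        )

    # -- views --------------------------------------------------------------
    def counts_per_primary(self) -> dict:
        """Region -> channel -> averaged events per primary electron."""
        n = max(self.n_primaries, 1)
        return {
            region: {
                ch: float(self.counts[i, j]) / n
                for j, ch in enumerate(CHANNEL_NAMES)
            }
            for i, region in enumerate(self.regions)
        }

    def channel_totals(self) -> dict:
        return {
            ch: float(self.counts[:, j].sum()) for j, ch in enumerate(CHANNEL_NAMES)
        }

    def mean_secondary_energy(self) -> float:
        return self.secondary_energy_sum / max(self.n_secondaries, 1)

    def to_json_dict(self) -> dict:
        return {
            "regions": {
                region: {
                    "counts": {
                        ch: float(self.counts[i, j])
                        for j, ch in enumerate(CHANNEL_NAMES)
                    },
                    "deposited_energy_eV": float(self.deposited_energy[i]),
                }
                for i, region in enumerate(self.regions)
            },
            "n_primaries": self.n_primaries,
            "n_secondaries": self.n_secondaries,
            "n_thermalized": self.n_thermalized,
            "n_attached": self.n_attached,
            "n_escaped": self.n_escaped,
            "energy_in_eV": self.energy_in,
            "energy_escaped_eV": self.energy_escaped,
            "manifest": self.manifest,
        }

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, region in enumerate(self.regions):
            for j, ch in enumerate(CHANNEL_NAMES):
                rows.append(
                    {"region": region, "channel": ch, "count": float(self.counts[i, j])}
                )
        return pd.DataFrame(rows)


@dataclass
class TrackGeometry:
    """1-D slab scoring geometry along z (nm): boundaries and region names."""

    boundaries: np.ndarray  # (n_regions + 1,), strictly increasing, nm
    regions: list

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, float)
        if not np.all(np.diff(self.boundaries) > 0):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.regions) != self.boundaries.size - 1:
            raise ValueError("need exactly one region name per slab")

    @classmethod
    def infinite(cls, half_width_nm: float = 1e9, name: str = "medium") -> "TrackGeometry":
        return cls(np.array([-half_width_nm, half_width_nm]), [name])

    def region_index(self, z) -> np.ndarray:
        idx = np.searchsorted(self.boundaries, z, side="right") - 1
        return idx  # -1 below, n_regions above: caller handles escapes

    def region_at(self, z: float) -> str:
        i = int(self.region_index(z))
        if i < 0 or i >= len(self.regions):
            raise ValueError(f"no region at z = {z} nm (outside the slab)")
        return self.regions[i]


# ---------------------------------------------------------------------------
# Elementary sampling operations
# ---------------------------------------------------------------------------
def screening_parameter(energy_ev) -> np.ndarray:
    """Screened-Rutherford screening eta(E); large at eV energies (quasi-
    isotropic elastic scattering), small and forward-peaked at keV."""
    E = np.asarray(energy_ev, float)
    return 5.0 / np.maximum(E, 1e-6) + 1e-5


def elastic_dcs(energy_ev: float, theta: np.ndarray) -> np.ndarray:
    """Normalized elastic angular density per solid angle at energy E."""
    eta = screening_parameter(energy_ev)
    a = 1.0 + 2.0 * eta
    f = 1.0 / (a - np.cos(theta)) ** 2
    # normalization over solid angle: int f dOmega = 2 pi * 2/((a-1)(a+1))
    norm = 4.0 * math.pi / ((a - 1.0) * (a + 1.0))
    return f / norm


def mean_cos_deficit(energy_ev) -> np.ndarray:
    """<1 - cos(theta)> of the screened-Rutherford elastic distribution."""
    eta = screening_parameter(energy_ev)
    return 2.0 * eta * (1.0 + eta) * np.log((1.0 + eta) / eta) - 2.0 * eta


def sample_free_path(xs: CrossSectionSet, energy: float, rng) -> float:
    """Exponential free path s = -lambda ln(u) in cm."""
    from .xs import mean_free_path

    lam = mean_free_path(xs, energy)
    return -lam * math.log(max(rng.random(), 1e-300))


def elastic_energy_transfer(energy: float, theta, target_mass: float = WATER_MOLAR_MASS):
    """Recoil energy transfer of an elastic collision (eV)."""
    kin = (
        2.0 * ELECTRON_MASS_U * target_mass / (ELECTRON_MASS_U + target_mass) ** 2
    )
    return energy * kin * (1.0 - np.cos(theta))


def sample_scatter_cos(energy, energy_loss, rng_or_u) -> np.ndarray:
    """Sample cos(theta) from the inelastic angular law.

    The angular density is the elastic screened-Rutherford density raised to
    the power (1 - dE/E): identical to elastic for dE = 0, isotropic for
    dE = E.  Closed-form inverse CDF of (a - x)^(-2p).
    """
    E = np.atleast_1d(np.asarray(energy, float))
    dE = np.atleast_1d(np.asarray(energy_loss, float))
    if np.any(dE > E * (1 + 1e-12)):
        raise ValueError("energy loss exceeds projectile energy")
    u = (
        rng_or_u.random(E.shape)
        if isinstance(rng_or_u, np.random.Generator)
        else np.atleast_1d(np.asarray(rng_or_u, float))
    )
    eta = screening_parameter(E)
    a = 1.0 + 2.0 * eta
    p = 1.0 - dE / np.maximum(E, 1e-300)
    q = 2.0 * p - 1.0
    x = np.empty_like(E)
    log_branch = np.abs(q) < 1e-6
    # general: (a-x)^(-q) interpolates between the endpoint values
    with np.errstate(over="ignore"):
        qa = q[~log_branch]
        aa = a[~log_branch]
        ua = u[~log_branch]
        lo = (aa + 1.0) ** (-qa)
        hi = (aa - 1.0) ** (-qa)
        x[~log_branch] = aa - (lo + ua * (hi - lo)) ** (-1.0 / qa)
    if np.any(log_branch):
        ab = a[log_branch]
        ub = u[log_branch]
        x[log_branch] = ab - (ab + 1.0) * ((ab - 1.0) / (ab + 1.0)) ** ub
    return np.clip(x, -1.0, 1.0)


def inelastic_angle_pdf(
    elastic_table: tuple,
    energy_loss: float,
    energy: float,
) -> tuple:
    """Discretized normalized angular density for an inelastic collision.

    ``elastic_table`` is (theta_grid, elastic density per solid angle at E).
    Returns (theta_grid, density per solid angle) with
    integral density dOmega = 1.
    """
    if energy_loss > energy:
        raise ValueError("energy loss exceeds projectile energy")
    theta, dcs = (np.asarray(a, float) for a in elastic_table)
    p = 1.0 - energy_loss / energy
    f = dcs**p
    norm = np.trapezoid(f * 2.0 * math.pi * np.sin(theta), theta)
    return theta, f / norm


def sample_energy_loss(channel, energy: float, rng) -> float:
    """Draw one energy loss (eV) for an open channel at energy E."""
    if channel.sigma_at(energy) <= 0:
        raise ValueError(
            f"channel {channel.name} is closed at E = {energy:.4g} eV"
        )
    return float(channel.energy_loss_model.sample(np.array([energy]), rng)[0])


def rotate_directions(d: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors ``d`` by polar angle acos(cos_t), azimuth phi."""
    d = np.atleast_2d(d)
    cos_t = np.atleast_1d(cos_t)
    phi = np.atleast_1d(phi)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 0.0))
    # orthonormal frame (u, v, d)
    small = np.abs(d[:, 2]) > 0.999999
    ref = np.where(small[:, None], np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]))
    u = np.cross(ref, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    out = (
        sin_t[:, None] * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v)
        + cos_t[:, None] * d
    )
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


def spawn_secondary(
    energy_loss: float,
    ionization_potential: float,
    primary_out: ElectronState,
    rng,
    primary_scatter: tuple | None = None,
) -> ElectronState:
    """Create the ejected electron of an ionizing collision.

    Its kinetic energy is dE - IP.  The ejection azimuth is opposite to the
    scattered primary and the polar angle balances the transverse momentum
    of the two outgoing electrons (non-relativistic binary-encounter
    convention; the residual longitudinal momentum is absorbed by the
    molecule).
    """
    if energy_loss <= ionization_potential:
        raise ValueError("energy loss does not exceed the ionization potential")
    w = energy_loss - ionization_potential
    if primary_scatter is None:
        theta_p, phi_p = 0.0, rng.random() * 2.0 * math.pi
    else:
        theta_p, phi_p = primary_scatter
    # transverse balance: p2 sin(theta_e) = p1 sin(theta_p), p ~ sqrt(E)
    p1 = math.sqrt(max(primary_out.energy, 0.0))
    p2 = math.sqrt(w)
    sin_e = min(1.0, p1 * math.sin(theta_p) / p2) if p2 > 0 else 0.0
    cos_e = math.sqrt(max(1.0 - sin_e**2, 0.0))
    phi_e = phi_p + math.pi
    direction = rotate_directions(
        primary_out.direction[None, :], np.array([cos_e]), np.array([phi_e])
    )[0]
    return ElectronState(
        primary_out.position.copy(),
        direction,
        w,
        generation=primary_out.generation + 1,
    )


# ---------------------------------------------------------------------------
# Scalar single-event step (reference implementation)
# ---------------------------------------------------------------------------
def step(
    electron: ElectronState,
    xs: CrossSectionSet,
    geometry: TrackGeometry,
    rng,
):
    """Advance one electron by one sampled event.

    Returns ``(outcome, secondaries)`` where outcome is a
    :class:`CollisionEvent`, or one of the strings ``"escaped"`` /
    ``"thermalized"``; ``secondaries`` is a (possibly empty) list of new
    :class:`ElectronState`.  Energy bookkeeping per step is exact:
    E_before = E_after + deposited + secondary energy.
    """
    if electron.status != "alive":
        raise ValueError("electron is not alive")
    E0 = electron.energy
    if E0 < xs.medium.thermal_cutoff:
        electron.status = "thermalized"
        return "thermalized", []

    s_cm = sample_free_path(xs, E0, rng)
    electron.position = electron.position + electron.direction * (s_cm * 1e7)
    z = electron.position[2]
    if z < geometry.boundaries[0] or z > geometry.boundaries[-1]:
        electron.status = "escaped"
        return "escaped", []
    region = geometry.region_at(z)

    from .xs import channel_probabilities

    probs = channel_probabilities(xs, E0)
    names = list(probs)
    channel = names[
        int(np.searchsorted(np.cumsum([probs[n] for n in names]), rng.random()))
    ]
    ch = xs.channels[channel]
    phi = rng.random() * 2.0 * math.pi
    secondaries: list[ElectronState] = []

    if channel == "attachment":
        electron.status = "attached"
        electron.energy = 0.0
        return CollisionEvent(channel, E0, 0.0, phi, region), []

    if channel == "elastic":
        cos_t = float(sample_scatter_cos(E0, 0.0, rng)[0])
        d_e = float(elastic_energy_transfer(E0, math.acos(cos_t)))
        sec_energy = None
    else:
        d_e = float(ch.energy_loss_model.sample(np.array([E0]), rng)[0])
        d_e = min(d_e, E0)
        cos_t = float(sample_scatter_cos(E0, d_e, rng)[0])
        sec_energy = None

    theta = math.acos(max(-1.0, min(1.0, cos_t)))
    electron.energy = E0 - d_e
    electron.direction = rotate_directions(
        electron.direction[None, :], np.array([cos_t]), np.array([phi])
    )[0]

    if channel == "single_ionization":
        sec = spawn_secondary(
            d_e, xs.medium.ionization_potential_liquid, electron, rng, (theta, phi)
        )
        secondaries.append(sec)
        sec_energy = sec.energy
    elif channel == "double_ionization":
        pool = max(d_e - 2.0 * xs.medium.ionization_potential_liquid, 0.0)
        split = rng.random()
        for frac, opposite in ((split, True), (1.0 - split, False)):
            w = pool * frac
            phi_e = phi + math.pi if opposite else rng.random() * 2 * math.pi
            cos_e = 1.0 - 2.0 * rng.random()
            direction = rotate_directions(
                electron.direction[None, :], np.array([cos_e]), np.array([phi_e])
            )[0]
            secondaries.append(
                ElectronState(
                    electron.position.copy(), direction, w, electron.generation + 1
                )
            )
        sec_energy = pool
    elif channel == "kshell_ionization" and d_e > xs.medium.kshell_binding:
        sec = spawn_secondary(d_e, xs.medium.kshell_binding, electron, rng, (theta, phi))
        secondaries.append(sec)
        sec_energy = sec.energy

    if electron.energy < xs.medium.thermal_cutoff:
        electron.status = "thermalized"

    return CollisionEvent(channel, d_e, theta, phi, region, sec_energy), secondaries


# ---------------------------------------------------------------------------
# Batched cascade engine
# ---------------------------------------------------------------------------
class _XsTables:
    """Pre-gridded per-channel data for the batched engine."""

    def __init__(self, xs: CrossSectionSet, n_grid: int = 700):
        lo, hi = xs.energy_range
        self.grid = np.geomspace(lo, hi, n_grid)
        self.log_grid = np.log(self.grid)
        sig = np.stack([xs.channels[c].sigma_at(self.grid) for c in CHANNEL_NAMES], 1)
        self.sigma = sig  # (n_grid, 9), 1e-16 cm^2
        self.sigma_tot = sig.sum(1)
        self.lam_cm = 1.0 / (xs.medium.number_density * self.sigma_tot * 1e-16)
        with np.errstate(invalid="ignore"):
            self.cum_prob = np.cumsum(sig, 1) / self.sigma_tot[:, None]
        self.xs = xs

    def index(self, energy: np.ndarray) -> np.ndarray:
        i = np.searchsorted(self.grid, energy, side="right") - 1
        return np.clip(i, 0, self.grid.size - 1)


def _sample_lines(lines, weights, E, rng):
    lines = np.asarray(lines, float)
    weights = np.asarray(weights, float)
    allowed = lines[None, :] <= E[:, None]
    w = np.where(allowed, weights[None, :], 0.0)
    wsum = w.sum(1, keepdims=True)
    # if nothing is allowed (shouldn't happen for open channels) take min line
    w = np.where(wsum > 0, w / np.maximum(wsum, 1e-300), 0.0)
    cum = np.cumsum(w, 1)
    u = rng.random(E.shape)
    pick = (u[:, None] > cum).sum(1)
    pick = np.clip(pick, 0, lines.size - 1)
    out = lines[pick]
    return np.minimum(out, E)


def _trunc_gauss(mu, sd, lo, hi, rng, n):
    a = (lo - mu) / sd
    b = (np.maximum(hi, lo + 1e-9) - mu) / sd
    u = rng.random(n)
    return truncnorm.ppf(u, a, b, loc=mu, scale=sd)


def run_tracks(
    source,
    n_primaries: int,
    xs: CrossSectionSet,
    geometry: TrackGeometry | None = None,
    seed: int = 0,
    start_position=None,
    direction=(0.0, 0.0, 1.0),
    tables: _XsTables | None = None,
) -> Tally:
    """Full cascade transport of ``n_primaries`` electrons and all secondaries.

    ``source`` is a fixed energy in eV, a ``(energies, weights)`` pair, or a
    callable ``f(rng, n) -> energies``.  Runs are reproducible bit-for-bit
    for a fixed seed.
    """
    if geometry is None:
        geometry = TrackGeometry.infinite()
    if tables is None:
        tables = _XsTables(xs)
    rng = np.random.default_rng(seed)
    medium = xs.medium
    ip = medium.ionization_potential_liquid
    cut = medium.thermal_cutoff

    if callable(source):
        E = np.asarray(source(rng, n_primaries), float)
    elif isinstance(source, tuple):
        energies, weights = (np.asarray(a, float) for a in source)
        E = rng.choice(energies, size=n_primaries, p=weights / weights.sum())
    else:
        E = np.full(n_primaries, float(source))
    np.clip(E, cut, xs.energy_range[1], out=E)

    if start_position is None:
        z0 = 0.5 * (geometry.boundaries[0] + geometry.boundaries[-1])
        start_position = (0.0, 0.0, z0)
    pos = np.tile(np.asarray(start_position, float), (n_primaries, 1))
    dvec = np.asarray(direction, float)
    dvec = dvec / np.linalg.norm(dvec)
    d = np.tile(dvec, (n_primaries, 1))
    gen = np.zeros(n_primaries, dtype=int)

    tally = Tally.empty(geometry.regions)
    tally.n_primaries = n_primaries
    tally.energy_in = float(E.sum())
    tally.manifest = {"seed": seed, "n_primaries": n_primaries}
    n_regions = len(geometry.regions)

    loss_models = {c: xs.channels[c].energy_loss_model for c in CHANNEL_NAMES}
    vib = loss_models["vibrational"].params
    exc = loss_models["electronic_excitation"].params
    nd = loss_models["neutral_dissociation"].params
    rot_loss = loss_models["rotational"].params["value"]
    w_mean = loss_models["single_ionization"].params["mean"]
    dbl = loss_models["double_ionization"].params
    ksh = loss_models["kshell_ionization"].params
    kbind = medium.kshell_binding

    max_iters = 2_000_000
    for _ in range(max_iters):
        n = E.size
        if n == 0:
            break
        # free path and new position
        i = tables.index(E)
        s_nm = -tables.lam_cm[i] * np.log(1.0 - rng.random(n)) * 1e7
        pos = pos + d * s_nm[:, None]
        z = pos[:, 2]
        escaped = (z < geometry.boundaries[0]) | (z > geometry.boundaries[-1])
        if escaped.any():
            tally.n_escaped += int(escaped.sum())
            tally.energy_escaped += float(E[escaped].sum())
            keep = ~escaped
            pos, d, E, gen, i = pos[keep], d[keep], E[keep], gen[keep], i[keep]
            n = E.size
            if n == 0:
                break
        region = np.clip(
            np.searchsorted(geometry.boundaries, pos[:, 2], side="right") - 1,
            0,
            n_regions - 1,
        )

        # channel selection
        u = rng.random(n)
        cidx = (u[:, None] > tables.cum_prob[i]).sum(1)
        cidx = np.clip(cidx, 0, len(CHANNEL_NAMES) - 1)
        np.add.at(tally.counts, (region, cidx), 1.0)

        d_e = np.zeros(n)
        deposit = np.zeros(n)
        phi = rng.random(n) * 2.0 * math.pi
        cos_t = np.ones(n)
        new_E, new_pos, new_d, new_gen = [], [], [], []
        dead = np.zeros(n, dtype=bool)

        def _mask(name):
            return cidx == _CH_INDEX[name]

        m = _mask("elastic")
        if m.any():
            c = sample_scatter_cos(E[m], np.zeros(m.sum()), rng.random(m.sum()))
            cos_t[m] = c
            loss = E[m] * _KIN_FACTOR * (1.0 - c)
            d_e[m] = loss
            deposit[m] = loss

        m = _mask("rotational")
        if m.any():
            loss = np.minimum(rot_loss, E[m])
            d_e[m] = loss
            deposit[m] = loss
            cos_t[m] = sample_scatter_cos(E[m], loss, rng.random(m.sum()))

        for name, params in (
            ("vibrational", vib),
            ("electronic_excitation", exc),
            ("neutral_dissociation", nd),
        ):
            m = _mask(name)
            if m.any():
                loss = _sample_lines(params["energies"], params["weights"], E[m], rng)
                d_e[m] = loss
                deposit[m] = loss
                cos_t[m] = sample_scatter_cos(E[m], loss, rng.random(m.sum()))

        m = _mask("single_ionization")
        if m.any():
            k = int(m.sum())
            wmax = np.maximum((E[m] - ip) / 2.0, 1e-12)
            w = -w_mean * np.log1p(-rng.random(k) * (1.0 - np.exp(-wmax / w_mean)))
            loss = ip + w
            d_e[m] = loss
            deposit[m] = ip
            c = sample_scatter_cos(E[m], loss, rng.random(k))
            cos_t[m] = c
            # transverse-balance ejection
            e_after = E[m] - loss
            sin_p = np.sqrt(np.maximum(1.0 - c**2, 0.0))
            sin_e = np.minimum(
                1.0, np.sqrt(np.maximum(e_after, 0.0) / np.maximum(w, 1e-12)) * sin_p
            )
            cos_e = np.sqrt(np.maximum(1.0 - sin_e**2, 0.0))
            sec_dir = rotate_directions(d[m], cos_e, phi[m] + math.pi)
            new_E.append(w)
            new_pos.append(pos[m].copy())
            new_d.append(sec_dir)
            new_gen.append(gen[m] + 1)
            tally.secondary_energy_sum += float(w.sum())

        m = _mask("double_ionization")
        if m.any():
            k = int(m.sum())
            loss = _trunc_gauss(
                dbl["mean"], dbl["sd"], dbl["lo"], np.minimum(dbl["hi"], E[m]), rng, k
            )
            loss = np.minimum(loss, E[m])
            d_e[m] = loss
            deposit[m] = 2.0 * ip
            pool = np.maximum(loss - 2.0 * ip, 0.0)
            split = rng.random(k)
            cos_t[m] = sample_scatter_cos(E[m], loss, rng.random(k))
            for frac, opp in ((split, True), (1.0 - split, False)):
                w = pool * frac
                phi_e = phi[m] + math.pi if opp else rng.random(k) * 2 * math.pi
                cos_e = 1.0 - 2.0 * rng.random(k)
                new_E.append(w)
                new_pos.append(pos[m].copy())
                new_d.append(rotate_directions(d[m], cos_e, phi_e))
                new_gen.append(gen[m] + 1)
            tally.secondary_energy_sum += float(pool.sum())

        m = _mask("kshell_ionization")
        if m.any():
            k = int(m.sum())
            loss = _trunc_gauss(
                ksh["mean"], ksh["sd"], ksh["lo"], np.minimum(ksh["hi"], E[m]), rng, k
            )
            loss = np.minimum(loss, E[m])
            d_e[m] = loss
            ejects = loss > kbind
            w = np.where(ejects, loss - kbind, 0.0)
            deposit[m] = np.where(ejects, kbind, loss)
            c = sample_scatter_cos(E[m], loss, rng.random(k))
            cos_t[m] = c
            if ejects.any():
                sub = np.flatnonzero(m)[ejects]
                sin_p = np.sqrt(np.maximum(1.0 - c[ejects] ** 2, 0.0))
                e_after = E[sub] - loss[ejects]
                sin_e = np.minimum(
                    1.0,
                    np.sqrt(np.maximum(e_after, 0.0) / np.maximum(w[ejects], 1e-12))
                    * sin_p,
                )
                cos_e = np.sqrt(np.maximum(1.0 - sin_e**2, 0.0))
                new_E.append(w[ejects])
                new_pos.append(pos[sub].copy())
                new_d.append(rotate_directions(d[sub], cos_e, phi[sub] + math.pi))
                new_gen.append(gen[sub] + 1)
                tally.secondary_energy_sum += float(w[ejects].sum())

        m = _mask("attachment")
        if m.any():
            d_e[m] = E[m]
            deposit[m] = E[m]
            dead[m] = True
            tally.n_attached += int(m.sum())

        np.add.at(tally.deposited_energy, region, deposit)
        E = E - d_e
        d = rotate_directions(d, cos_t, phi)

        # thermalization: residual deposited locally
        therm = (~dead) & (E < cut)
        if therm.any():
            np.add.at(tally.deposited_energy, region[therm], E[therm])
            tally.n_thermalized += int(therm.sum())
            dead |= therm
        E = np.where(dead, 0.0, E)

        keep = ~dead
        pos, d, E, gen = pos[keep], d[keep], E[keep], gen[keep]
        if new_E:
            add_E = np.concatenate(new_E)
            tally.n_secondaries += add_E.size
            E = np.concatenate([E, add_E])
            pos = np.concatenate([pos, np.concatenate(new_pos)])
            d = np.concatenate([d, np.concatenate(new_d)])
            gen = np.concatenate([gen, np.concatenate(new_gen)])
            # newborn below the cutoff thermalize on the spot
            low = E < cut
            if low.any():
                zlow = np.clip(
                    np.searchsorted(geometry.boundaries, pos[low, 2], side="right") - 1,
                    0,
                    n_regions - 1,
                )
                np.add.at(tally.deposited_energy, zlow, E[low])
                tally.n_thermalized += int(low.sum())
                keep = ~low
                pos, d, E, gen = pos[keep], d[keep], E[keep], gen[keep]
    else:
        raise RuntimeError("cascade did not terminate within the iteration cap")

    return tally


# ---------------------------------------------------------------------------
# Degradation-spectrum estimator
# ---------------------------------------------------------------------------
class CollisionDensity:
    """Deterministic continuous-slowing-down collision accounting.

    ``counts(E0)`` returns the expected number of events per channel for the
    full slowdown (primary plus recursively all secondaries) of an electron
    starting at E0 (eV).  Below the tabulated 10 keV ceiling the integrand
    uses the exact per-channel cross sections and truncated mean losses; for
    higher energies the per-eV event densities are frozen at their 10 keV
    values, which is the first-Born regime where the channel-to-stopping
    ratios become energy independent.
    """

    def __init__(self, xs: CrossSectionSet, n_grid: int = 400, n_quad: int = 12):
        self.xs = xs
        lo, hi = xs.energy_range
        self.grid = np.geomspace(lo * 1.0000001, hi, n_grid)
        self.n_quad = n_quad
        self._build()

    def _mean_loss(self, name: str, E: float) -> float:
        ch = self.xs.channels[name]
        if name == "elastic":
            return float(E * _KIN_FACTOR * mean_cos_deficit(E))
        return ch.energy_loss_model.mean(E)

    def _build(self) -> None:
        xs = self.xs
        g = self.grid
        nG = g.size
        nC = len(CHANNEL_NAMES)
        sigma = np.stack([xs.channels[c].sigma_at(g) for c in CHANNEL_NAMES], 1)
        mean_loss = np.zeros((nG, nC))
        for j, c in enumerate(CHANNEL_NAMES):
            for k in range(nG):
                if sigma[k, j] > 0:
                    mean_loss[k, j] = self._mean_loss(c, g[k])
        s_cs = (sigma * mean_loss).sum(1)  # stopping cross section (eV 1e-16 cm^2)
        self.sigma = sigma
        self.mean_loss = mean_loss
        self.stopping_cs = s_cs

        ip = xs.medium.ionization_potential_liquid
        kbind = xs.medium.kshell_binding
        w_mean = xs.channels["single_ionization"].energy_loss_model.params["mean"]
        dbl = xs.channels["double_ionization"].energy_loss_model.params
        ksh = xs.channels["kshell_ionization"].energy_loss_model.params

        y = np.zeros((nG, nC))  # cumulative expected counts for slowdown from g[k]
        uq = (np.arange(self.n_quad) + 0.5) / self.n_quad

        def y_at(energy: np.ndarray, upto: int) -> np.ndarray:
            """Interpolate y (rows 0..upto) at arbitrary energies below g[upto]."""
            e = np.clip(energy, g[0], g[upto])
            idx = np.searchsorted(g[: upto + 1], e) - 1
            idx = np.clip(idx, 0, upto - 1)
            t = (np.log(e) - np.log(g[idx])) / (np.log(g[idx + 1]) - np.log(g[idx]))
            t = np.clip(t, 0.0, 1.0)[:, None]
            return (1 - t) * y[idx] + t * y[idx + 1]

        j_ion = _CH_INDEX["single_ionization"]
        j_dbl = _CH_INDEX["double_ionization"]
        j_ksh = _CH_INDEX["kshell_ionization"]

        j_att = _CH_INDEX["attachment"]

        def _loss_quadrature(name: str, em: float):
            """(losses, weights) of the channel's loss distribution at em."""
            ch = xs.channels[name]
            model = ch.energy_loss_model
            if model.kind == "constant":
                return np.array([model.params["value"]]), np.array([1.0])
            if model.kind == "discrete_lines":
                lines = np.asarray(model.params["energies"], float)
                weights = np.asarray(model.params["weights"], float)
                ok = lines <= em
                if not ok.any():
                    return np.array([em]), np.array([1.0])
                w = weights[ok] / weights[ok].sum()
                return lines[ok], w
            if model.kind == "offset_exp":
                off = model.params["offset"]
                w0 = model.params["mean"]
                wmax = max((em - off) / 2.0, 1e-12)
                wq = -w0 * np.log1p(-uq * (1.0 - math.exp(-min(wmax / w0, 50.0))))
                return off + wq, np.full(uq.size, 1.0 / uq.size)
            if model.kind == "gaussian":
                mu, sd = model.params["mean"], model.params["sd"]
                a = (model.params.get("lo", 0.0) - mu) / sd
                b = (min(model.params.get("hi", np.inf), em) - mu) / sd
                if b <= a:
                    return np.array([min(mu, em)]), np.array([1.0])
                q4 = (np.arange(4) + 0.5) / 4.0
                dq = truncnorm.ppf(q4, a, b, loc=mu, scale=sd)
                return np.minimum(dq, em), np.full(4, 0.25)
            if model.kind == "capture":
                return np.array([em]), np.array([1.0])
            raise ValueError(model.kind)

        def _secondary_y(j: int, name: str, em: float, upto: int) -> np.ndarray:
            """Expected cascade counts of the secondaries of one event."""
            if name == "single_ionization":
                wmax = max((em - ip) / 2.0, 1e-12)
                wq = -w_mean * np.log1p(
                    -uq * (1.0 - math.exp(-min(wmax / w_mean, 50.0)))
                )
                return y_at(wq, upto).mean(0)
            if name == "double_ionization":
                losses, wts = _loss_quadrature(name, em)
                pool = max(float((losses * wts).sum()) - 2 * ip, 0.0)
                if pool <= 0:
                    return np.zeros(nC)
                return 2.0 * y_at(pool * uq, upto).mean(0)
            if name == "kshell_ionization":
                a = (ksh["lo"] - ksh["mean"]) / ksh["sd"]
                b = (min(ksh["hi"], em) - ksh["mean"]) / ksh["sd"]
                if b <= a:
                    return np.zeros(nC)
                p_eject = float(
                    truncnorm.sf(kbind, a, b, loc=ksh["mean"], scale=ksh["sd"])
                )
                if p_eject <= 0:
                    return np.zeros(nC)
                dq = truncnorm.ppf(
                    1 - p_eject * (1 - uq), a, b, loc=ksh["mean"], scale=ksh["sd"]
                )
                return p_eject * y_at(np.maximum(dq - kbind, g[0]), upto).mean(0)
            return np.zeros(nC)

        # Spencer–Fano-style hybrid recursion: channels whose losses are small
        # against the slice width are integrated continuously (CSDA); larger
        # discrete losses are point events with explicit landing energies, so
        # jumps across structured regions (e.g. the attachment window) and
        # terminal events (attachment, sub-cutoff landings) are respected.
        for k in range(nG - 1):
            em = math.sqrt(g[k] * g[k + 1])
            h = g[k + 1] - g[k]
            sig_m = np.array(
                [float(xs.channels[c].sigma_at(np.array([em]))[0]) for c in CHANNEL_NAMES]
            )
            ml_m = np.array(
                [
                    self._mean_loss(c, em) if sig_m[j] > 0 else 0.0
                    for j, c in enumerate(CHANNEL_NAMES)
                ]
            )
            if sig_m.sum() <= 0:
                y[k + 1] = y[k]
                continue
            hard = (sig_m > 0) & (ml_m > 2.0 * h)
            hard[_CH_INDEX["elastic"]] = False
            hard[j_att] = sig_m[j_att] > 0  # capture is always terminal
            soft = (sig_m > 0) & ~hard
            s_soft = float((sig_m[soft] * ml_m[soft]).sum())
            if s_soft <= 0:  # no continuous channel: force the dominant soft
                soft[_CH_INDEX["elastic"]] = sig_m[_CH_INDEX["elastic"]] > 0
                s_soft = max(float((sig_m[soft] * ml_m[soft]).sum()), 1e-30)

            sig_hard = float(sig_m[hard].sum())
            lam = sig_hard * h / s_soft
            p_hard = -math.expm1(-lam) if lam > 0 else 0.0
            slid = h * (p_hard / lam) if lam > 1e-12 else h

            contrib = np.zeros(nC)
            # continuous (soft) events over the energy actually slid
            for j in np.flatnonzero(soft):
                n_ev = sig_m[j] * slid / s_soft
                contrib[j] += n_ev
                if CHANNEL_NAMES[j] in IONIZING_CHANNELS:
                    contrib += n_ev * _secondary_y(j, CHANNEL_NAMES[j], em, k)
            # discrete (hard) events: one event, then the cascade from the
            # landing energy; attachment terminates the electron
            continuation = (1.0 - p_hard) * y[k]
            if p_hard > 0:
                for j in np.flatnonzero(hard):
                    pc = p_hard * sig_m[j] / sig_hard
                    contrib[j] += pc
                    name = CHANNEL_NAMES[j]
                    if name in IONIZING_CHANNELS:
                        contrib += pc * _secondary_y(j, name, em, k)
                    if j != j_att:
                        losses, wts = _loss_quadrature(name, em)
                        landing = np.maximum(em - losses, g[0])
                        continuation = continuation + pc * (
                            wts[:, None] * y_at(landing, k)
                        ).sum(0)
            y[k + 1] = contrib + continuation
        self.y = y

        # first-Born extension above the grid ceiling: channel-to-channel
        # ratios are frozen except for the K-shell/valence ratio, which keeps
        # its Born ln(E/B_K)/ln(E/B_val) growth; per-event secondary-cascade
        # expectations are evaluated at the ceiling.
        etop = g[-1]
        sig_t = self.sigma[-1].copy()
        ml_t = self.mean_loss[-1].copy()
        sec_t = np.zeros((nC, nC))  # per event of channel c: cascade counts
        for j, name in enumerate(CHANNEL_NAMES):
            if sig_t[j] > 0 and name in IONIZING_CHANNELS:
                sec_t[j] = _secondary_y(j, name, etop, nG - 1)
        self._top = {
            "etop": etop,
            "sig": sig_t,
            "ml": ml_t,
            "sec": sec_t,
            "ip": ip,
            "kbind": kbind,
            "kref": math.log(etop / kbind) / math.log(etop / ip),
        }
        self.born_density = self._density_above(etop)

    def _density_above(self, energy: float) -> np.ndarray:
        """Per-channel events per eV degraded, for E at/above the ceiling."""
        top = self._top
        e = max(float(energy), top["etop"])
        sig = top["sig"].copy()
        kscale = (math.log(e / top["kbind"]) / math.log(e / top["ip"])) / top["kref"]
        sig[_CH_INDEX["kshell_ionization"]] *= kscale
        s = float((sig * top["ml"]).sum())
        dens = sig / s
        return dens + dens @ top["sec"]

    def counts(self, E0: float) -> dict:
        """Expected per-channel event counts for a full slowdown from E0 (eV)."""
        g = self.grid
        if E0 <= g[0]:
            return {c: 0.0 for c in CHANNEL_NAMES}
        if E0 <= g[-1]:
            idx = np.searchsorted(g, E0) - 1
            idx = max(min(idx, g.size - 2), 0)
            t = (math.log(E0) - math.log(g[idx])) / (
                math.log(g[idx + 1]) - math.log(g[idx])
            )
            row = (1 - t) * self.y[idx] + t * self.y[idx + 1]
        else:
            # integrate the extension density over the energy degraded
            pts = np.geomspace(g[-1], E0, 48)
            dens = np.stack([self._density_above(e) for e in pts])
            row = self.y[-1] + np.trapezoid(dens, pts, axis=0)
        return {c: float(row[j]) for j, c in enumerate(CHANNEL_NAMES)}

    def events_per_ev(self, energy: float) -> dict:
        """Per-channel expected events (cascade included) per eV of energy
        degraded by an electron at the given energy."""
        g = self.grid
        if energy >= g[-1]:
            row = self._density_above(energy)
        else:
            k = int(np.clip(np.searchsorted(g, energy) - 1, 0, g.size - 2))
            row = (self.y[k + 1] - self.y[k]) / (g[k + 1] - g[k])
        return {c: float(row[j]) for j, c in enumerate(CHANNEL_NAMES)}


def expected_collision_counts(E0_ev: float, xs: CrossSectionSet, density: CollisionDensity | None = None) -> dict:
    """Deterministic estimate of per-channel collision counts for a full
    slowdown from E0 (primary and all descendant secondaries)."""
    if density is None:
        density = CollisionDensity(xs)
    return density.counts(E0_ev)


def electronic_level_summary(counts: dict) -> dict:
    """Collapse a per-channel count map into the slowdown collision budget:
    total electronic-level inelastic events and their ionizing fraction."""
    from .xs import ELECTRONIC_LEVEL_CHANNELS

    total = sum(counts[c] for c in ELECTRONIC_LEVEL_CHANNELS)
    ionizing = sum(counts[c] for c in IONIZING_CHANNELS)
    return {
        "electronic_level_total": total,
        "ionizing": ionizing,
        "ionizing_fraction": ionizing / total if total > 0 else 0.0,
    }
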