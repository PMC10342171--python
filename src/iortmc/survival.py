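"""Clonogenic survival-fraction depth-response analysis.

Survival fractions (SF) measured at several depths in water, in repeated
irradiation sessions at a fixed absorbed dose, are normalized to a common
depth per session, pooled, and fitted with an ordinary least-squares line
SF = a + b*depth.  The fit is anchored so that the pooled line passes
through a reference SF at a reference depth (the reproducibility-study
value at R50).  Linear-quadratic (LQ) utilities convert between dose and
survival, and biological damage is derived from SF under a configurable
convention (default -ln SF, the Poisson lethal-event count).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DAMAGE_CONVENTIONS = ("neg_log_sf", "one_minus_sf", "inverse_sf")


@dataclass
class SurvivalSeries:
    """(depth, SF, session) records, optionally normalized/anchored."""

    depth_mm: np.ndarray
    sf: np.ndarray
    session: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, float)
        self.sf = np.asarray(self.sf, float)
        self.session = np.asarray(self.session)
        if np.any((self.sf <= 0) | (self.sf > 1.0 + 1e-12)):
            raise ValueError("survival fractions must lie in (0, 1]")
        if not (self.depth_mm.shape == self.sf.shape == self.session.shape):
            raise ValueError("depth, sf and session must have equal length")

    def sessions(self) -> list:
        return sorted(set(self.session.tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth_mm": self.depth_mm, "sf": self.sf, "session": self.session}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvivalSeries":
        df = pd.read_csv(path)
        return cls(
            df["depth_mm"].to_numpy(float),
            df["sf"].to_numpy(float),
            df["session"].to_numpy(),
        )


@dataclass
class DepthFit:
    """OLS fit SF = intercept + slope*depth with the Pearson test."""

    slope: float
    intercept: float
    pearson_r: float
    t_statistic: float
    p_value: float
    n: int
    anchor: tuple | None = None

    def predict(self, depth_mm) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(depth_mm, float)


@dataclass
class LQParams:
    """Linear-quadratic parameters, SF(D) = exp(-alpha D - beta D^2)."""

    alpha: float  # 1/Gy
    beta: float  # 1/Gy^2

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


# ---------------------------------------------------------------------------
# Fitting and normalization
# ---------------------------------------------------------------------------
def fit_depth_response(series) -> DepthFit:
    """Pooled OLS line through (depth, SF) with Pearson r, t and p.

    t = r sqrt(n-2)/sqrt(1-r^2); the p-value is two-sided from the t
    distribution with n-2 degrees of freedom.
    """
    if isinstance(series, SurvivalSeries):
        x, y = series.depth_mm, series.sf
    else:
        x, y = (np.asarray(a, float) for a in series)
    if np.unique(x).size < 2:
        raise ValueError("all depths identical: no depth response to fit")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct depths")
    slope, intercept = np.polyfit(x, y, 1)
    r = float(stats.pearsonr(x, y).statistic)
    n = x.size
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return DepthFit(float(slope), float(intercept), r, float(t), float(p), n)


def normalize_series(
    raw: SurvivalSeries,
    common_depth_mm: float,
    anchor: tuple,
    tolerance_mm: float = 0.3,
) -> SurvivalSeries:
    """Per-session normalization at a common depth, then anchor scaling.

    Every session is divided by its own SF at the common depth (within
    +-tolerance); the pooled series is then scaled so the OLS line evaluated
    at the anchor depth equals the anchor SF.  The scaling is a positive
    multiple of SF only, so Pearson r is unchanged.
    """
    anchor_depth, anchor_sf = anchor
    sf = raw.sf.copy().astype(float)
    for ses in raw.sessions():
        m = raw.session == ses
        near = m & (np.abs(raw.depth_mm - common_depth_mm) <= tolerance_mm)
        if not near.any():
            raise ValueError(
                f"session {ses!r} has no record within +-{tolerance_mm} mm of "
                f"the common depth {common_depth_mm} mm"
            )
        ref = float(sf[near].mean())
        sf[m] = sf[m] / ref
    fit = fit_depth_response((raw.depth_mm, sf))
    line_at_anchor = fit.intercept + fit.slope * anchor_depth
    if line_at_anchor <= 0:
        raise ValueError("fitted line non-positive at the anchor depth")
    scale = anchor_sf / line_at_anchor
    out_sf = np.clip(sf * scale, 1e-12, 1.0)
    return SurvivalSeries(raw.depth_mm.copy(), out_sf, raw.session.copy(), normalized=True)


def anchored_line(depth_mm, slope: float = -0.007, anchor: tuple = (24.2, 0.16)):
    """Evaluate the anchored depth-response line SF(d) = SF_a + slope (d - d_a)."""
    d_a, sf_a = anchor
    return sf_a + slope * (np.asarray(depth_mm, float) - d_a)


# ---------------------------------------------------------------------------
# Linear-quadratic model
# ---------------------------------------------------------------------------
def lq_survival(dose_gy, params: LQParams):
    """SF = exp(-alpha D - beta D^2)."""
    d = np.asarray(dose_gy, float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = np.exp(-params.alpha * d - params.beta * d**2)
    return out if np.ndim(dose_gy) else float(out)


def lq_equivalent_dose(sf_target: float, params: LQParams) -> float:
    """Dose (Gy) at which the LQ model reaches the target survival."""
    if not (0.0 < sf_target <= 1.0):
        raise ValueError("target SF must lie in (0, 1]")
    ln_sf = math.log(sf_target)
    a, b = params.alpha, params.beta
    if b == 0.0:
        if a == 0.0:
            if sf_target == 1.0:
                return 0.0
            raise ValueError("alpha = beta = 0 cannot reach SF < 1")
        return -ln_sf / a
    disc = a * a - 4.0 * b * ln_sf
    return (-a + math.sqrt(disc)) / (2.0 * b)


# ---------------------------------------------------------------------------
# Damage from survival
# ---------------------------------------------------------------------------
def biological_damage_from_sf(
    depth_mm,
    sf,
    convention: str = "neg_log_sf",
    reference_depth_mm: float = 15.3,
) -> pd.DataFrame:
    """Relative biological damage vs depth, normalized at the reference depth.

    Conventions: ``neg_log_sf`` (-ln SF: Poisson lethal events, default),
    ``one_minus_sf`` (killed fraction), ``inverse_sf``.
    """
    if convention not in DAMAGE_CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    depth = np.asarray(depth_mm, float)
    sf = np.asarray(sf, float)
    if np.any(sf <= 0):
        raise ValueError("SF = 0 is not representable under log conventions")
    if convention == "neg_log_sf":
        dmg = -np.log(sf)
    elif convention == "one_minus_sf":
        dmg = 1.0 - sf
    else:
        dmg = 1.0 / sf
    ref = float(np.interp(reference_depth_mm, depth, dmg))
    if ref <= 0:
        raise ValueError("zero damage at the reference depth")
    return pd.DataFrame(
        {"depth_mm": depth, "sf": sf, "damage": dmg, "relative_damage": dmg / ref}
    )


def rbe_per_mm(rbe_a: float, depth_a_mm: float, rbe_b: float, depth_b_mm: float) -> float:
    """Linear rate of RBE change with depth between two depths."""
    if depth_a_mm == depth_b_mm:
        raise ValueError("depths must be distinct")
    return (rbe_b - rbe_a) / (depth_b_mm - depth_a_mm)


# ---------------------------------------------------------------------------
# Synthetic SF generator (the study-condition emulator)
# ---------------------------------------------------------------------------
def generate_synthetic_sf(
    depths_mm=None,
    n: int = 18,
    depth_range_mm: tuple = (15.0, 33.0),
    slope: float = -0.007,
    anchor: tuple = (24.2, 0.16),
    noise_sd: float = 0.03,
    seed: int = 0,
    n_sessions: int = 3,
    session_sd: float = 0.0,
    sessions=None,
) -> SurvivalSeries:
    """Synthetic clonogenic series: linear depth trend plus Gaussian noise.

    SF(d) = SF_a + slope (d - d_a) + N(0, noise_sd), clipped to (0.001, 1];
    defaults reproduce the study design (18 points over 15–33 mm, slope
    -0.007 per mm, anchor 0.16 at 24.2 mm, session SD 0.03).  Optional
    multiplicative per-session factors are off by default.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if depths_mm is None:
        depths_mm = np.linspace(depth_range_mm[0], depth_range_mm[1], n)
    depths_mm = np.asarray(depths_mm, float)
    n = depths_mm.size
    truth = anchored_line(depths_mm, slope=slope, anchor=anchor)
    noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    sf = truth + noise
    if sessions is not None:
        session = np.asarray(sessions)
        if session.shape != depths_mm.shape:
            raise ValueError("sessions must match the depth design")
        n_sessions = len(set(session.tolist()))
    else:
        session = np.arange(n) % n_sessions + 1
    if session_sd > 0:
        factors = rng.normal(1.0, session_sd, n_sessions)
        sf = sf * factors[session - 1]
    sf = np.clip(sf, 0.001, 1.0)
    return SurvivalSeries(depths_mm, sf, session)
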