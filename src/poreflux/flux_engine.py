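"""Diffusion coefficients, gradients, Fick's-law fluxes, reaction rates, flux ratios.

The flux of a solute across a horizon in the sediment follows Fick's first law
with a porosity/tortuosity correction,

    J = phi * Ds * d[C]/dz,

with J in mmol m⁻² yr⁻¹, phi the sediment porosity, Ds the sedimentary
diffusion coefficient (m² yr⁻¹) and d[C]/dz the local concentration gradient
(mmol m⁻⁴) estimated by least squares over three neighbouring data points.
With z positive downward, a positive gradient (concentration increasing with
depth) drives upward diffusion; signed values are kept internally and all
headline quantities (nitrate influx, nitrite effluxes, their ratio) are
reported as magnitudes with a direction label.

The per-site statistic is r = (J_NO2_up + J_NO2_down) / J_NO3_in — the summed
nitrite effluxes out of the nitrate-depletion zone over the nitrate influx into
it — summarised across sites by the arithmetic mean and a Student-t 95%
confidence interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    ConfigurationError,
    FluxError,
    GradientError,
    SummaryError,
)
from .profile_io import DepthProfile, SiteMetadata, SoluteSpec

logger = logging.getLogger("poreflux")

SECONDS_PER_YEAR = 365.25 * 86400.0

#: Calibration range (degC) of the linear D0 fits.
D0_TEMPERATURE_RANGE = (-2.0, 30.0)


def seawater_viscosity(salinity: float, temperature: float, pressure: float) -> float:
    """Dynamic viscosity of (sea)water in centipoise.

    Empirical correlation in salinity (g/kg), temperature (degC) and pressure
    (bar), valid for 0-30 degC, S 0-36, P up to ~1000 bar; the same correlation
    used by standard porewater-diffusivity tooling.
    """
    s, t, p = float(salinity), float(temperature), float(pressure)
    return (
        1.7910
        - 6.144e-2 * t
        + 1.4510e-3 * t**2
        - 1.6826e-5 * t**3
        - 1.5290e-4 * p
        + 8.3885e-8 * p**2
        + 2.4727e-3 * s
        + t * (6.0574e-6 * p - 2.6760e-9 * p**2)
        + s * (4.8429e-5 * t - 4.7172e-6 * t**2 + 7.5986e-8 * t**3)
    )


def d0_infinite_dilution(
    solute: SoluteSpec,
    temperature: float,
    salinity: float = 0.0,
    pressure: float = 1.013,
) -> float:
    """Free-solution diffusion coefficient D0 in m² yr⁻¹.

    ``D0 = (m0 + m1*T) * 1e-6 cm² s⁻¹`` (the published linear fit, for pure
    water at atmospheric pressure), rescaled to in-situ salinity and pressure
    by the pure-water/seawater dynamic-viscosity ratio (Stokes-Einstein
    scaling), then converted to m² yr⁻¹.  Monotonically increasing in T.
    """
    lo, hi = D0_TEMPERATURE_RANGE
    if not lo <= temperature <= hi:
        warnings.warn(
            f"temperature {temperature} degC outside the D0 calibration range "
            f"[{lo}, {hi}]; extrapolating",
            stacklevel=2,
        )
    d0_cm2_s = (solute.d0_intercept + solute.d0_slope * temperature) * 1e-6
    mu_ref = seawater_viscosity(0.0, temperature, 1.013)
    mu = seawater_viscosity(salinity, temperature, pressure)
    d0_cm2_s *= mu_ref / mu
    return d0_cm2_s * 1e-4 * SECONDS_PER_YEAR


def sediment_diffusivity(
    d0: float, porosity: float, model: str = "log", m_exponent: float = 3.0
) -> float:
    """Tortuosity-corrected sedimentary diffusion coefficient Ds (m² yr⁻¹).

    Default model: ``Ds = D0 / (1 - ln(phi²))``.  Alternative ``"power"``
    (Archie-type): ``Ds = D0 * phi**(m-1)``.  Both satisfy Ds <= D0 with
    Ds -> D0 as phi -> 1.
    """
    phi = np.asarray(porosity, dtype=float)
    if np.any(phi <= 0) or np.any(phi > 1):
        raise ConfigurationError(f"porosity must lie in (0, 1], got {porosity}")
    if model == "log":
        ds = d0 / (1.0 - np.log(phi**2))
    elif model == "power":
        ds = d0 * phi ** (m_exponent - 1.0)
    else:
        raise ConfigurationError(f"unknown tortuosity model {model!r}")
    return float(ds) if np.ndim(porosity) == 0 else ds


@dataclass(frozen=True)
class TransportProperties:
    """Per-depth porosity and per-solute sedimentary diffusivities for a core."""

    phi: np.ndarray
    ds: Mapping[str, np.ndarray]  # m2/yr per solute, per depth
    d0: Mapping[str, float]  # m2/yr per solute (free solution, in situ T/S/P)


def build_transport(
    profile: DepthProfile,
    solutes: Mapping[str, SoluteSpec],
    site: SiteMetadata | None = None,
    tortuosity: str = "log",
) -> TransportProperties:
    """Evaluate D0 at the site's bottom-water conditions and Ds on the phi grid."""
    site = site or profile.site
    d0 = {
        name: d0_infinite_dilution(
            spec, site.bottom_temperature, site.salinity, site.pressure_bar
        )
        for name, spec in solutes.items()
        if name in profile.solutes
    }
    ds = {
        name: sediment_diffusivity(d0_val, profile.porosity, model=tortuosity)
        for name, d0_val in d0.items()
    }
    return TransportProperties(phi=profile.porosity, ds=ds, d0=d0)


@dataclass(frozen=True)
class GradientResult:
    """OLS slope of concentration vs depth over a 3-point window."""

    slope: float  # mmol m-4
    stderr: float
    points: tuple  # ((depth_cm, conc_uM), ...)
    n_censored: int


def local_gradient(
    profile: DepthProfile, solute: str, window: Sequence[int]
) -> GradientResult:
    """Concentration gradient (mmol m⁻⁴) from three consecutive data points.

    Ordinary least-squares slope of concentration (mmol m⁻³ = µM) against
    depth (m) over exactly 3 points; censored points enter as 0.
    """
    idx = np.asarray(window, dtype=int)
    if idx.size != 3:
        raise GradientError(f"gradient window must have exactly 3 points, got {idx.size}")
    if np.any(np.diff(idx) != 1):
        raise GradientError(f"gradient window indices must be consecutive, got {idx.tolist()}")
    if idx.min() < 0 or idx.max() >= profile.n_depths:
        raise GradientError(
            f"window {idx.tolist()} outside profile with {profile.n_depths} depths"
        )
    z = profile.depth_m[idx]
    c = profile.fit_values(solute)[idx]
    series = profile.series(solute)
    n_censored = int(series.censored[idx].sum())
    zbar, cbar = z.mean(), c.mean()
    sxx = float(np.sum((z - zbar) ** 2))
    slope = float(np.sum((z - zbar) * (c - cbar)) / sxx)
    resid = c - (cbar + slope * (z - zbar))
    # 3 points, 2 fitted parameters -> 1 residual degree of freedom
    stderr = float(np.sqrt(np.sum(resid**2) / 1.0 / sxx))
    points = tuple((float(profile.depth_cm[i]), float(c[k])) for k, i in enumerate(idx))
    return GradientResult(slope=slope, stderr=stderr, points=points, n_censored=n_censored)


@dataclass(frozen=True)
class FluxValue:
    """A signed Fickian flux with magnitude and direction label."""

    signed: float  # mmol m-2 yr-1; positive = upward transport (z down)
    magnitude: float
    direction: str  # "upward" | "downward" | "none"


def boundary_flux(gradient: float, phi: float, ds: float) -> FluxValue:
    """Fick's first law: J = phi * Ds * d[C]/dz.

    With z positive downward, a positive gradient means the solute diffuses
    upward; the sign is retained and a direction label attached.
    """
    if not 0 < phi <= 1:
        raise ConfigurationError(f"porosity must lie in (0, 1], got {phi}")
    if not ds > 0:
        raise ConfigurationError(f"Ds must be > 0, got {ds}")
    j = float(phi * ds * gradient)
    if j > 0:
        direction = "upward"
    elif j < 0:
        direction = "downward"
    else:
        direction = "none"
    return FluxValue(signed=j, magnitude=abs(j), direction=direction)


def net_reaction_rate(
    profile: DepthProfile, solute: str, transport: TransportProperties
) -> np.ndarray:
    """Discrete steady-state net reaction rate R (mmol m⁻³ yr⁻¹) per depth.

    ``R(z_i) = -phi * Ds * C''(z_i)`` with the second derivative by the central
    three-point difference on the (possibly non-uniform) grid — exact for
    locally quadratic profiles.  Endpoints are NaN (undefined).  R > 0 means
    net production, R < 0 net consumption.
    """
    if profile.n_depths < 3:
        raise GradientError("net reaction rate needs at least 3 depths")
    z = profile.depth_m
    c = profile.fit_values(solute)
    ds = np.asarray(transport.ds[solute], dtype=float)
    if ds.ndim == 0:
        ds = np.full(z.shape, float(ds))
    rate = np.full(z.shape, np.nan)
    h1 = z[1:-1] - z[:-2]
    h2 = z[2:] - z[1:-1]
    second = 2.0 * (
        c[:-2] / (h1 * (h1 + h2)) - c[1:-1] / (h1 * h2) + c[2:] / (h2 * (h1 + h2))
    )
    rate[1:-1] = -transport.phi[1:-1] * ds[1:-1] * second
    return rate


@dataclass(frozen=True)
class FluxResult:
    """Per-site boundary fluxes around the nitrate-depletion zone."""

    site_id: str
    j_no3_in: float  # mmol m-2 yr-1, magnitude of downward nitrate flux
    j_no2_up: float  # magnitude of upward nitrite efflux
    j_no2_down: float  # magnitude of downward nitrite efflux
    ratio: float  # (j_no2_up + j_no2_down) / j_no3_in
    gradient_windows: Mapping[str, GradientResult | None]
    ds_used: Mapping[str, float]
    options: Mapping[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "J_NO3_in": self.j_no3_in,
            "J_NO2_up": self.j_no2_up,
            "J_NO2_down": self.j_no2_down,
            "ratio": self.ratio,
            "Ds_used_m2_yr": {k: float(v) for k, v in self.ds_used.items()},
            "windows": {
                k: None
                if w is None
                else {"points": list(w.points), "slope_mmol_m4": w.slope}
                for k, w in self.gradient_windows.items()
            },
            "options": dict(self.options),
        }


def _window_at(indices: np.ndarray, anchor: str, side: str) -> np.ndarray:
    """Pick 3 consecutive indices at the edge of a run, optionally one step inward."""
    if indices.size < 3:
        raise FluxError("needs at least 3 points")
    shift = 1 if anchor == "offset1" and indices.size >= 4 else 0
    if side == "head":
        return indices[shift : shift + 3]
    return indices[indices.size - 3 - shift : indices.size - shift]


def site_fluxes(
    profile: DepthProfile,
    zones,
    solutes: Mapping[str, SoluteSpec],
    site: SiteMetadata | None = None,
    tortuosity: str = "log",
    window_anchor: str = "edge",
) -> FluxResult:
    """Nitrate influx, nitrite effluxes and their ratio for one core.

    * ``J_NO3_in``: from the 3 data points immediately above the nitrate
      depletion crossing.
    * ``J_NO2_up``: from the 3 shallowest points of the nitrite interval.
    * ``J_NO2_down``: from the 3 deepest points of the nitrite interval.
    * ``ratio`` r = (J_NO2_up + J_NO2_down) / J_NO3_in.

    ``window_anchor="offset1"`` shifts each window one sample away from the
    interval edge (a sensitivity option; the window choice is not fully pinned
    down by the three-point rule alone).  If nitrite is censored at every
    depth, both effluxes and the ratio are 0.
    """
    if window_anchor not in {"edge", "offset1"}:
        raise ConfigurationError(f"unknown window anchor {window_anchor!r}")
    site = site or profile.site
    if profile.n_depths < 3:
        raise FluxError("flux computation requires at least 3 depths")

    transport = build_transport(profile, solutes, site, tortuosity=tortuosity)
    options = {"tortuosity": tortuosity, "window_anchor": window_anchor}

    # --- nitrate influx ---------------------------------------------------
    if zones.nitrate_depletion is None:
        raise FluxError("nitrate window unavailable: no nitrate depletion depth")
    no3 = profile.series("nitrate")
    above = np.flatnonzero(
        (profile.depth_cm < zones.nitrate_depletion.first_censored_cm) & ~no3.censored
    )
    try:
        no3_window = _window_at(above, window_anchor, "tail")
    except FluxError:
        raise FluxError(
            "nitrate window unavailable: fewer than 3 points above the depletion crossing"
        ) from None
    g_no3 = local_gradient(profile, "nitrate", no3_window)
    phi_no3 = float(profile.porosity[no3_window].mean())
    ds_no3 = sediment_diffusivity(transport.d0["nitrate"], phi_no3, model=tortuosity)
    j_no3 = boundary_flux(g_no3.slope, phi_no3, ds_no3)

    windows: dict[str, GradientResult | None] = {"no3_in": g_no3}
    ds_used = {"nitrate": ds_no3}

    # --- nitrite effluxes -------------------------------------------------
    no2 = profile.series("nitrite")
    if not no2.detectable.any():
        windows["no2_up"] = windows["no2_down"] = None
        result = FluxResult(
            site_id=site.site_id,
            j_no3_in=j_no3.magnitude,
            j_no2_up=0.0,
            j_no2_down=0.0,
            ratio=0.0,
            gradient_windows=windows,
            ds_used=ds_used,
            options=options,
        )
        return result
    if zones.nitrite_interval is None or not zones.coherent_nitrite:
        raise FluxError("nitrite windows unavailable: no coherent nitrite interval")
    lo, hi = zones.nitrite_interval
    run = np.flatnonzero(
        (profile.depth_cm >= lo) & (profile.depth_cm <= hi) & no2.detectable
    )
    try:
        up_window = _window_at(run, window_anchor, "head")
        down_window = _window_at(run, window_anchor, "tail")
    except FluxError:
        raise FluxError("nitrite window unavailable: interval has fewer than 3 points") from None
    g_up = local_gradient(profile, "nitrite", up_window)
    g_down = local_gradient(profile, "nitrite", down_window)
    phi_up = float(profile.porosity[up_window].mean())
    phi_down = float(profile.porosity[down_window].mean())
    ds_up = sediment_diffusivity(transport.d0["nitrite"], phi_up, model=tortuosity)
    ds_down = sediment_diffusivity(transport.d0["nitrite"], phi_down, model=tortuosity)
    j_up = boundary_flux(g_up.slope, phi_up, ds_up)
    j_down = boundary_flux(g_down.slope, phi_down, ds_down)
    windows["no2_up"] = g_up
    windows["no2_down"] = g_down
    ds_used["nitrite"] = ds_up

    if j_no3.magnitude == 0:
        raise FluxError("nitrate influx is zero; ratio undefined")
    ratio = (j_up.magnitude + j_down.magnitude) / j_no3.magnitude
    return FluxResult(
        site_id=site.site_id,
        j_no3_in=j_no3.magnitude,
        j_no2_up=j_up.magnitude,
        j_no2_down=j_down.magnitude,
        ratio=ratio,
        gradient_windows=windows,
        ds_used=ds_used,
        options=options,
    )


@dataclass(frozen=True)
class RatioSummary:
    """Cross-site summary of the nitrite/nitrate flux ratio."""

    n_sites: int
    ratios: tuple
    mean: float
    ci95_halfwidth: float | None
    outlier_sites: tuple  # site ids with r >= 1

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "ratios": list(self.ratios),
            "mean": self.mean,
            "ci95_halfwidth": self.ci95_halfwidth,
            "outlier_sites": list(self.outlier_sites),
        }


def ratio_summary(
    results: Sequence[FluxResult],
    method: str = "t",
    n_boot: int = 2000,
    seed: int = 0,
) -> RatioSummary:
    """Mean and 95% CI of the per-site flux ratios.

    ``method="t"`` (default): halfwidth = t(0.975, n-1) * sd / sqrt(n).
    ``method="bootstrap"``: half the central-95% percentile interval width of
    the resampled mean.  n = 1 returns the mean with the CI undefined.
    """
    if not results:
        raise SummaryError("ratio summary requested for an empty result list")
    ratios = np.array([r.ratio for r in results], dtype=float)
    mean = float(ratios.mean())
    n = ratios.size
    if n < 2:
        half: float | None = None
    elif method == "t":
        sd = float(ratios.std(ddof=1))
        half = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        means = rng.choice(ratios, size=(n_boot, n), replace=True).mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
        half = float((hi - lo) / 2.0)
    else:
        raise ConfigurationError(f"unknown CI method {method!r}")
    outliers = tuple(r.site_id for r in results if r.ratio >= 1.0)
    return RatioSummary(
        n_sites=n,
        ratios=tuple(float(r) for r in ratios),
        mean=mean,
        ci95_halfwidth=half,
        outlier_sites=outliers,
    )
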