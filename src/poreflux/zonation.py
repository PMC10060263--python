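"""Geochemical zonation of a sediment core from its porewater profiles.

A core is partitioned into the features the porewater data support:

* **oxic zone** — from the shallowest sample to the oxygen depletion depth;
* **depletion depths** — where a solute first falls below detection, refined
  by linear interpolation of the detection-limit crossing;
* **nitrite interval** — the longest contiguous run of depths with detectable
  nitrite; the profile is *coherent* when the run spans more than two
  consecutive depths (i.e. at least 3);
* **NATZ** — the nitrate-ammonium transition zone, tagged ``"separated"``
  (gap between nitrate depletion and first ammonium) or ``"overlap"``;
* **net nitrite consumption zones** — the intervals flanking the nitrite
  maximum where the discrete steady-state rate estimator indicates net
  consumption.

All zonation decisions depend only on censoring flags and relative
comparisons, so the derived zones are invariant under a uniform positive
rescaling of concentrations and detection limits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, NamedTuple

import numpy as np

from . import flux_engine
from .errors import ZoneError
from .profile_io import DepthProfile, SoluteSpec

logger = logging.getLogger("poreflux")


class DepletionDepth(NamedTuple):
    """A solute's depletion horizon: interpolated DL crossing and the first
    censored sample depth (both cm; the crossing is never deeper)."""

    crossing_cm: float
    first_censored_cm: float


class NitriteMaximum(NamedTuple):
    depth_cm: float
    concentration_uM: float


@dataclass(frozen=True)
class ZoneSet:
    """The derived geochemical zonation of one core (all depths in cm)."""

    oxic_zone: tuple[float, float] | None = None
    nitrate_depletion: DepletionDepth | None = None
    nitrite_interval: tuple[float, float] | None = None
    nitrite_maximum: NitriteMaximum | None = None
    coherent_nitrite: bool = False
    natz: tuple[float, float] | None = None
    natz_relation: str | None = None  # "separated" | "overlap"
    natz_reason: str | None = None
    upper_consumption_zone: tuple[float, float] | None = None
    lower_consumption_zone: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        def pair(v):
            return None if v is None else [float(v[0]), float(v[1])]

        return {
            "oxic_zone_cm": pair(self.oxic_zone),
            "nitrate_depletion_cm": None
            if self.nitrate_depletion is None
            else {
                "crossing": float(self.nitrate_depletion.crossing_cm),
                "first_censored_sample": float(self.nitrate_depletion.first_censored_cm),
            },
            "nitrite_interval_cm": pair(self.nitrite_interval),
            "nitrite_maximum": None
            if self.nitrite_maximum is None
            else {
                "depth_cm": float(self.nitrite_maximum.depth_cm),
                "concentration_uM": float(self.nitrite_maximum.concentration_uM),
            },
            "coherent_nitrite": bool(self.coherent_nitrite),
            "natz_cm": pair(self.natz),
            "natz_relation": self.natz_relation,
            "natz_reason": self.natz_reason,
            "upper_consumption_zone_cm": pair(self.upper_consumption_zone),
            "lower_consumption_zone_cm": pair(self.lower_consumption_zone),
        }

    def to_bed(self, site_id: str) -> list[tuple[str, float, float, str]]:
        """BED-like rows (site_id, start_cm, end_cm, label) for interval export."""
        rows = []
        labelled = [
            ("oxic_zone", self.oxic_zone),
            ("nitrite_interval", self.nitrite_interval),
            ("natz", self.natz),
            ("upper_consumption_zone", self.upper_consumption_zone),
            ("lower_consumption_zone", self.lower_consumption_zone),
        ]
        for label, interval in labelled:
            if interval is not None:
                rows.append((site_id, float(interval[0]), float(interval[1]), label))
        return rows


def find_depletion_depth(profile: DepthProfile, solute: str) -> DepletionDepth | None:
    """Shallowest depth where the solute becomes censored below a detectable point.

    The crossing of the detection limit is interpolated linearly between the
    bracketing samples (the censored point enters at its fitted value, 0 by
    default).  Returns ``None`` if the solute never becomes censored below a
    detectable point.
    """
    series = profile.series(solute)
    dl = profile.detection_limit(solute)
    censored = series.censored
    values = profile.fit_values(solute)
    for i in range(1, profile.n_depths):
        if censored[i] and not censored[i - 1]:
            z0, z1 = profile.depth_cm[i - 1], profile.depth_cm[i]
            c0, c1 = values[i - 1], values[i]
            if c0 > dl and c0 > c1:
                frac = (c0 - dl) / (c0 - c1)
                crossing = float(z0 + frac * (z1 - z0))
            else:
                crossing = float(z0)
            return DepletionDepth(crossing_cm=crossing, first_censored_cm=float(z1))
    return None


def find_oxic_zone(profile: DepthProfile) -> tuple[float, float]:
    """Oxic zone [shallowest sample, O2 depletion crossing].

    Extends to the core bottom if oxygen never depletes; degenerates to an
    empty interval at the top if no oxygen is ever detected.
    """
    series = profile.series("oxygen")
    top = float(profile.depth_cm[0])
    if not series.detectable.any():
        return (top, top)
    depletion = find_depletion_depth(profile, "oxygen")
    if depletion is None:
        return (top, float(profile.depth_cm[-1]))
    return (top, depletion.crossing_cm)


class NitriteInterval(NamedTuple):
    interval: tuple[float, float] | None
    coherent: bool
    maximum: NitriteMaximum | None


def find_nitrite_interval(profile: DepthProfile) -> NitriteInterval:
    """Longest contiguous run of detectable nitrite (ties -> shallowest run).

    The profile is *coherent* when the run covers more than two consecutive
    depths (>=3).  The maximum is the largest concentration in the run, ties
    broken to the shallowest depth.
    """
    series = profile.series("nitrite")
    detectable = series.detectable
    best_start, best_len = None, 0
    i = 0
    n = profile.n_depths
    while i < n:
        if detectable[i]:
            j = i
            while j + 1 < n and detectable[j + 1]:
                j += 1
            run_len = j - i + 1
            if run_len > best_len:
                best_start, best_len = i, run_len
            i = j + 1
        else:
            i += 1
    if best_start is None:
        return NitriteInterval(None, False, None)
    idx = np.arange(best_start, best_start + best_len)
    interval = (float(profile.depth_cm[idx[0]]), float(profile.depth_cm[idx[-1]]))
    vals = series.values[idx]
    k = idx[int(np.argmax(vals))]  # argmax returns the first (shallowest) max
    maximum = NitriteMaximum(float(profile.depth_cm[k]), float(series.values[k]))
    return NitriteInterval(interval, best_len >= 3, maximum)


class NatzResult(NamedTuple):
    interval: tuple[float, float] | None
    relation: str | None  # "separated" | "overlap"
    reason: str | None


def find_natz(profile: DepthProfile) -> NatzResult:
    """Nitrate-ammonium transition zone.

    ``"separated"``: ammonium first appears below the nitrate depletion depth
    (the interval is the gap); ``"overlap"``: ammonium appears above it (the
    interval is the co-occurrence zone).
    """
    depletion = find_depletion_depth(profile, "nitrate")
    nh4 = profile.series("ammonium")
    if depletion is None:
        return NatzResult(None, None, "nitrate never depletes")
    if not nh4.detectable.any():
        return NatzResult(None, None, "ammonium never detected")
    z_nh4 = float(profile.depth_cm[np.flatnonzero(nh4.detectable)[0]])
    z_no3 = depletion.crossing_cm
    if z_nh4 >= z_no3:
        return NatzResult((z_no3, z_nh4), "separated", None)
    return NatzResult((z_nh4, z_no3), "overlap", None)


def classify_consumption_zones(
    profile: DepthProfile,
    zones: ZoneSet,
    transport: flux_engine.TransportProperties,
    rel_threshold: float = 0.1,
) -> tuple[tuple[float, float] | None, tuple[float, float] | None]:
    """Upper and lower net nitrite consumption zones flanking the nitrite maximum.

    Uses the discrete steady-state rate estimator R(z) for nitrite; the zones
    are the contiguous runs of interior points with R below ``-rel_threshold``
    times the maximum |R| in the interval, nearest to (and strictly above /
    below) the nitrite maximum.  A limb whose curvature is present but never
    clears the threshold (a noisy second derivative) falls back to
    [interval top, maximum] (upper) or [maximum, interval bottom] (lower);
    a numerically linear limb (zero curvature) classifies no consumption and
    returns ``None`` for that side.
    """
    if not zones.coherent_nitrite or zones.nitrite_interval is None:
        raise ZoneError("consumption zones require a coherent nitrite interval")
    assert zones.nitrite_maximum is not None
    z_max = zones.nitrite_maximum.depth_cm
    lo, hi = zones.nitrite_interval
    rate = flux_engine.net_reaction_rate(profile, "nitrite", transport)
    depth = profile.depth_cm
    detectable = profile.series("nitrite").detectable
    run = np.flatnonzero((depth >= lo) & (depth <= hi) & detectable)
    # drop the run's edge points: the censored-to-zero neighbours outside the
    # run fabricate curvature there that is an artifact of censoring
    interior = run[1:-1] if run.size > 2 else run
    interior = interior[~np.isnan(rate[interior])]
    if interior.size == 0:
        return ((lo, z_max), (z_max, hi))
    max_abs = float(np.max(np.abs(rate[interior])))
    threshold = rel_threshold * max_abs
    # below this the limb carries no curvature signal at all (numerically
    # linear) and no consumption is classified there
    floor = max(1e-9 * max_abs, 1e-12)
    fallback = object()

    def nearest_run(side: str):
        if side == "upper":
            candidates = interior[depth[interior] < z_max]
        else:
            candidates = interior[depth[interior] > z_max]
        if candidates.size == 0 or np.max(np.abs(rate[candidates])) <= floor:
            return None
        consuming = candidates[rate[candidates] < -threshold]
        if consuming.size == 0:
            # curvature present but too noisy/weak to clear the threshold
            return fallback
        # split into contiguous runs of profile indices
        breaks = np.flatnonzero(np.diff(consuming) != 1)
        runs = np.split(consuming, breaks + 1)
        run = runs[-1] if side == "upper" else runs[0]  # nearest to the maximum
        return (float(depth[run[0]]), float(depth[run[-1]]))

    upper = nearest_run("upper")
    lower = nearest_run("lower")
    upper = (lo, z_max) if upper is fallback else upper
    lower = (z_max, hi) if lower is fallback else lower
    return upper, lower


def derive_zones(
    profile: DepthProfile,
    solutes: Mapping[str, SoluteSpec] | None = None,
    transport: flux_engine.TransportProperties | None = None,
    rel_threshold: float = 0.1,
    tortuosity: str = "log",
) -> ZoneSet:
    """Assemble the full :class:`ZoneSet` for a core.

    Features whose prerequisite solutes are absent (or whose prerequisites
    fail, e.g. no coherent nitrite interval for consumption zones) are left
    ``None`` rather than raising.
    """
    oxic = None
    if "oxygen" in profile.solutes:
        oxic = find_oxic_zone(profile)
    depletion = (
        find_depletion_depth(profile, "nitrate") if "nitrate" in profile.solutes else None
    )
    nitrite = (
        find_nitrite_interval(profile)
        if "nitrite" in profile.solutes
        else NitriteInterval(None, False, None)
    )
    natz = (
        find_natz(profile)
        if {"nitrate", "ammonium"} <= set(profile.solutes)
        else NatzResult(None, None, "nitrate or ammonium series absent")
    )
    zones = ZoneSet(
        oxic_zone=oxic,
        nitrate_depletion=depletion,
        nitrite_interval=nitrite.interval,
        nitrite_maximum=nitrite.maximum,
        coherent_nitrite=nitrite.coherent,
        natz=natz.interval,
        natz_relation=natz.relation,
        natz_reason=natz.reason,
    )
    if zones.coherent_nitrite:
        if transport is None:
            from .profile_io import default_solutes

            transport = flux_engine.build_transport(
                profile, solutes or default_solutes(), tortuosity=tortuosity
            )
        upper, lower = classify_consumption_zones(
            profile, zones, transport, rel_threshold=rel_threshold
        )
        zones = replace(
            zones, upper_consumption_zone=upper, lower_consumption_zone=lower
        )
    return zones
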