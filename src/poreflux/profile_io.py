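"""Reading, validation and censoring of depth-resolved porewater and abundance tables.

The core in-memory containers live here:

* :class:`SiteMetadata` — where a core was taken and the bottom-water conditions
  (temperature, salinity, pressure) that set solute diffusivities.
* :class:`SoluteSpec` — a solute's infinite-dilution diffusivity model and
  detection limit.
* :class:`DepthProfile` — a site's depth-ordered solute concentrations with
  per-point censoring flags and porosity.
* :class:`CommunityTable` — per-depth 16S gene copies, functional-gene qPCR
  copies and per-taxon relative abundances.

Depths are centimetres below the seafloor, positive downward, measured at the
stated depth (no bin midpoints); they are converted to metres only inside the
flux computations.  Concentrations are µM (numerically identical to
mmol per cubic metre).  Censored points (below detection) carry the value 0 by
default with the flag preserved, so they enter gradient fits as zeros.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, ValidationError

logger = logging.getLogger("poreflux")

#: Canonical column names for delimited profile tables.
CANONICAL_COLUMNS = {
    "depth": "depth_cm",
    "nitrate": "no3_uM",
    "nitrite": "no2_uM",
    "ammonium": "nh4_uM",
    "oxygen": "o2_uM",
    "porosity": "porosity",
}

#: Cell contents treated as "below detection" sentinels (case-insensitive).
CENSORED_SENTINELS = {"bd", "b.d.", "bdl", "nd", "<dl", ""}

#: Porosity used when the table has no porosity column.
DEFAULT_POROSITY = 0.7


@dataclass(frozen=True)
class SiteMetadata:
    """Coring-site metadata and bottom-water conditions.

    ``bottom_temperature`` (°C), ``salinity`` (PSU) and ``pressure`` (bar) feed
    the diffusivity model; when ``pressure`` is omitted it defaults to the
    hydrostatic pressure at ``water_depth`` (1 atm + 1 bar per 10 m).
    ``sedimentation_rate`` is cm per kyr and is only needed to convert peak
    separations into durations.
    """

    site_id: str
    water_depth: float
    latitude: float | None = None
    longitude: float | None = None
    bottom_temperature: float = 2.0
    salinity: float = 35.0
    pressure: float | None = None
    sedimentation_rate: float | None = None
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.water_depth > 0:
            raise ValidationError(f"water_depth must be > 0, got {self.water_depth}")
        if self.salinity < 0:
            raise ValidationError(f"salinity must be >= 0, got {self.salinity}")
        if self.sedimentation_rate is not None and not self.sedimentation_rate > 0:
            raise ValidationError(
                f"sedimentation_rate must be > 0 when present, got {self.sedimentation_rate}"
            )

    @property
    def pressure_bar(self) -> float:
        """Pressure in bar; hydrostatic from water depth if not given."""
        if self.pressure is not None:
            return self.pressure
        return 1.013 + self.water_depth / 10.0


@dataclass(frozen=True)
class SoluteSpec:
    """A solute's linear infinite-dilution diffusivity model and detection limit.

    The free-solution diffusion coefficient follows the linear fit
    ``D0 = (m0 + m1 * T) * 1e-6 cm² s⁻¹`` with T in °C, the form used by the
    standard early-diagenesis diffusivity tables.
    """

    name: str
    d0_intercept: float  # m0, 1e-6 cm2/s
    d0_slope: float  # m1, 1e-6 cm2/s/degC
    detection_limit: float  # µM

    def __post_init__(self) -> None:
        if not self.d0_intercept > 0:
            raise ValidationError(f"d0_intercept must be > 0, got {self.d0_intercept}")
        if self.d0_slope < 0:
            raise ValidationError(f"d0_slope must be >= 0, got {self.d0_slope}")
        if self.detection_limit < 0:
            raise ValidationError(
                f"detection_limit must be >= 0, got {self.detection_limit}"
            )


# Infinite-dilution linear fits (1e-6 cm2/s, 1e-6 cm2/s/degC), 0-30 degC range.
# NO3- and NH4+ are the standard porewater-modelling linear fits; NO2- is the
# NO3- fit scaled by the ratio of limiting equivalent conductivities
# (71.8 / 71.42), consistent with the Nernst-Einstein value at 25 degC; O2 is a
# linear approximation to gas-diffusivity compilations over 0-25 degC.
# Detection limits are typical for colorimetric nutrient and optode O2 methods.
DEFAULT_SOLUTES: dict[str, SoluteSpec] = {
    "nitrate": SoluteSpec("nitrate", 9.50, 0.388, 0.1),
    "nitrite": SoluteSpec("nitrite", 9.55, 0.390, 0.1),
    "ammonium": SoluteSpec("ammonium", 9.50, 0.413, 0.1),
    "oxygen": SoluteSpec("oxygen", 11.40, 0.446, 2.0),
}


def default_solutes(
    detection_limits: Mapping[str, float] | None = None,
) -> dict[str, SoluteSpec]:
    """Return a copy of the default solute table, with optional DL overrides."""
    specs = dict(DEFAULT_SOLUTES)
    for name, dl in (detection_limits or {}).items():
        if name not in specs:
            raise ConfigurationError(f"unknown solute {name!r}")
        specs[name] = replace(specs[name], detection_limit=float(dl))
    return specs


@dataclass(frozen=True)
class SoluteSeries:
    """One solute's concentrations (µM) and per-point censoring flags."""

    values: np.ndarray
    censored: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        censored = np.asarray(self.censored, dtype=bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "censored", censored)
        if values.shape != censored.shape:
            raise ValidationError("values and censored flags differ in length")
        ok = ~censored & ~np.isnan(values)
        if np.any(values[ok] < 0):
            raise ValidationError("non-censored concentrations must be >= 0")

    @property
    def detectable(self) -> np.ndarray:
        return ~self.censored & ~np.isnan(self.values)


@dataclass(frozen=True)
class DepthProfile:
    """A site's depth-ordered porewater solute profiles."""

    site: SiteMetadata
    depth_cm: np.ndarray
    solutes: Mapping[str, SoluteSeries]
    porosity: np.ndarray
    detection_limits: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth_cm, dtype=float)
        object.__setattr__(self, "depth_cm", depth)
        if depth.ndim != 1 or depth.size < 2:
            raise ValidationError("profile needs at least 2 depths")
        if not np.all(np.diff(depth) > 0):
            raise ValidationError("depths must be strictly increasing")
        phi = np.asarray(self.porosity, dtype=float)
        if phi.ndim == 0:
            phi = np.full(depth.shape, float(phi))
        object.__setattr__(self, "porosity", phi)
        if phi.shape != depth.shape:
            raise ValidationError("porosity must match the depth grid")
        if np.any((phi <= 0) | (phi > 1)):
            raise ValidationError("porosity must lie in (0, 1]")
        for name, series in self.solutes.items():
            if series.values.shape != depth.shape:
                raise ValidationError(f"solute {name!r} length mismatch")

    @property
    def n_depths(self) -> int:
        return int(self.depth_cm.size)

    @property
    def depth_m(self) -> np.ndarray:
        return self.depth_cm / 100.0

    def series(self, solute: str) -> SoluteSeries:
        try:
            return self.solutes[solute]
        except KeyError:
            raise ConfigurationError(
                f"solute {solute!r} absent from profile "
                f"(has {sorted(self.solutes)})"
            ) from None

    def fit_values(self, solute: str) -> np.ndarray:
        """Concentrations for fitting: censored points enter as 0."""
        s = self.series(solute)
        out = np.where(s.censored | np.isnan(s.values), 0.0, s.values)
        return out

    def detection_limit(self, solute: str) -> float:
        return float(self.detection_limits.get(solute, 0.0))


def _resolve_schema(schema: Mapping[str, str] | None) -> dict[str, str]:
    resolved = dict(CANONICAL_COLUMNS)
    for key, col in (schema or {}).items():
        if key not in resolved:
            raise SchemaError(f"unknown schema key {key!r} (expected one of {sorted(resolved)})")
        resolved[key] = col
    return resolved


def _parse_cell(cell: object) -> tuple[float, bool]:
    """Parse one concentration cell -> (value, censored)."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return 0.0, True
    text = str(cell).strip()
    if text.lower() in CENSORED_SENTINELS:
        return 0.0, True
    try:
        value = float(text)
    except ValueError:
        raise ValidationError(f"cannot parse concentration cell {cell!r}") from None
    if value < 0:
        raise ValidationError(f"negative concentration {value}")
    return value, False


def read_profile_table(
    path,
    site: SiteMetadata,
    schema: Mapping[str, str] | None = None,
    solutes: Mapping[str, SoluteSpec] | None = None,
    default_porosity: float = DEFAULT_POROSITY,
) -> DepthProfile:
    """Read a delimited porewater table into a validated :class:`DepthProfile`.

    The table must have a depth column and at least one solute column
    (comma- or tab-delimited; the dialect is sniffed).  Sentinel cells
    (``bd``, blank, ...) become censored points with value 0.  Rows are sorted
    by depth; duplicate depths are rejected.
    """
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    cols = _resolve_schema(schema)
    if cols["depth"] not in frame.columns:
        raise SchemaError(
            f"missing depth column {cols['depth']!r} in {path} (has {list(frame.columns)})"
        )
    depth = pd.to_numeric(frame[cols["depth"]], errors="raise").to_numpy(dtype=float)
    order = np.argsort(depth, kind="stable")
    depth = depth[order]
    if np.any(np.diff(depth) == 0):
        raise ValidationError(f"duplicate depths in {path}")

    present = {
        name: cols[name]
        for name in ("nitrate", "nitrite", "ammonium", "oxygen")
        if cols[name] in frame.columns
    }
    if not present:
        raise SchemaError(f"no solute columns found in {path}")

    series: dict[str, SoluteSeries] = {}
    for name, col in present.items():
        parsed = [_parse_cell(c) for c in frame[col].to_numpy()[order]]
        values = np.array([p[0] for p in parsed])
        censored = np.array([p[1] for p in parsed])
        series[name] = SoluteSeries(values, censored)

    if cols["porosity"] in frame.columns:
        phi = pd.to_numeric(frame[cols["porosity"]], errors="raise").to_numpy(dtype=float)[order]
    else:
        logger.warning(
            "site %s: no porosity column; using constant default %.2f",
            site.site_id,
            default_porosity,
        )
        phi = np.full(depth.shape, float(default_porosity))

    profile = DepthProfile(site=site, depth_cm=depth, solutes=series, porosity=phi)
    if solutes is not None:
        profile = censor_to_detection(profile, solutes)
    return profile


def censor_to_detection(
    profile: DepthProfile,
    solutes: Mapping[str, SoluteSpec],
    censored_value: str = "zero",
) -> DepthProfile:
    """Flag every point below its solute's detection limit as censored.

    Censored points carry value 0 (policy ``"zero"``, the default) or half the
    detection limit (policy ``"half_dl"``); the flag is preserved either way.
    Censoring is monotone in the detection limit: raising a DL can only grow
    the censored set.
    """
    if censored_value not in {"zero", "half_dl"}:
        raise ConfigurationError(f"unknown censored-value policy {censored_value!r}")
    new_series: dict[str, SoluteSeries] = {}
    limits = dict(profile.detection_limits)
    for name, series in profile.solutes.items():
        if name not in solutes:
            raise ConfigurationError(f"no SoluteSpec supplied for {name!r}")
        dl = solutes[name].detection_limit
        limits[name] = dl
        censored = series.censored | (series.values < dl)
        fill = 0.0 if censored_value == "zero" else dl / 2.0
        values = np.where(censored, fill, series.values)
        new_series[name] = SoluteSeries(values, censored)
    return replace(profile, solutes=new_series, detection_limits=limits)


def write_profile_table(profile: DepthProfile, path, delimiter: str = ",") -> None:
    """Write a profile in the canonical delimited dialect (censored cells as ``bd``)."""
    columns: dict[str, list] = {"depth_cm": [f"{z:g}" for z in profile.depth_cm]}
    for name in ("nitrate", "nitrite", "ammonium", "oxygen"):
        if name not in profile.solutes:
            continue
        s = profile.solutes[name]
        columns[CANONICAL_COLUMNS[name]] = [
            "bd" if c else repr(float(v)) for v, c in zip(s.values, s.censored)
        ]
    columns["porosity"] = [repr(float(p)) for p in profile.porosity]
    pd.DataFrame(columns).to_csv(path, sep=delimiter, index=False)


def validation_report(profile: DepthProfile) -> dict:
    """JSON-serialisable summary of a profile's validation state."""
    report = {
        "site_id": profile.site.site_id,
        "n_depths": profile.n_depths,
        "depth_range_cm": [float(profile.depth_cm[0]), float(profile.depth_cm[-1])],
        "solutes": {},
        "detection_limits_uM": {k: float(v) for k, v in profile.detection_limits.items()},
        "porosity_range": [float(profile.porosity.min()), float(profile.porosity.max())],
    }
    for name, s in profile.solutes.items():
        report["solutes"][name] = {
            "n_detectable": int(s.detectable.sum()),
            "n_censored": int(s.censored.sum()),
            "max_uM": float(np.nanmax(np.where(s.censored, np.nan, s.values)))
            if s.detectable.any()
            else None,
        }
    return report


# ---------------------------------------------------------------------------
# Community tables
# ---------------------------------------------------------------------------

#: qPCR-assayed marker genes carried by CommunityTable.
FUNCTIONAL_GENES = ("hzo", "narG", "nirS", "nirK", "amoA")

#: Relative-abundance column labels for the two anammox families.
ANAMMOX_FAMILIES = ("Ca_Scalinduaceae", "Ca_Bathyanammoxibiaceae")


@dataclass(frozen=True)
class GeneSeries:
    """Per-depth qPCR copies g⁻¹ with the standard deviation of triplicates."""

    copies: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        copies = np.asarray(self.copies, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        object.__setattr__(self, "copies", copies)
        object.__setattr__(self, "sd", sd)
        if copies.shape != sd.shape:
            raise ValidationError("copies and sd differ in length")
        if np.any(copies < 0) or np.any(sd < 0):
            raise ValidationError("gene copies and sd must be >= 0")


@dataclass(frozen=True)
class CommunityTable:
    """Per-depth microbial abundance data for one core."""

    depths: np.ndarray  # cm bsf
    archaeal_16S: np.ndarray  # copies/g
    bacterial_16S: np.ndarray  # copies/g
    functional_genes: Mapping[str, GeneSeries]
    relative_abundance: pd.DataFrame  # rows = depths, columns = taxa, fractions

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        object.__setattr__(self, "depths", depths)
        for attr in ("archaeal_16S", "bacterial_16S"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            object.__setattr__(self, attr, arr)
            if arr.shape != depths.shape:
                raise ValidationError(f"{attr} length mismatch")
            if np.any(arr < 0):
                raise ValidationError(f"{attr} must be >= 0")
        rel = self.relative_abundance
        if len(rel) != depths.size:
            raise ValidationError("relative_abundance rows must match depths")
        vals = rel.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValidationError("relative abundances must lie in [0, 1]")
        if np.any(vals.sum(axis=1) > 1 + 1e-9):
            raise ValidationError("per-depth relative abundances must sum to <= 1")
        for gene, series in self.functional_genes.items():
            if series.copies.shape != depths.shape:
                raise ValidationError(f"gene {gene!r} length mismatch")


def write_community_table(table: CommunityTable, path, delimiter: str = ",") -> None:
    """One row per depth: 16S copies, per-gene copies/sd, per-taxon fractions."""
    data: dict[str, object] = {
        "depth_cm": table.depths,
        "arc_16S_copies_g": table.archaeal_16S,
        "bac_16S_copies_g": table.bacterial_16S,
    }
    for gene, series in table.functional_genes.items():
        data[f"{gene}_copies_g"] = series.copies
        data[f"{gene}_sd"] = series.sd
    for taxon in table.relative_abundance.columns:
        data[f"rel_{taxon}"] = table.relative_abundance[taxon].to_numpy()
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False, float_format="%.10g")


def read_community_table(path) -> CommunityTable:
    """Inverse of :func:`write_community_table`."""
    frame = pd.read_csv(path, sep=None, engine="python")
    if "depth_cm" not in frame.columns:
        raise SchemaError(f"missing depth_cm column in {path}")
    depths = frame["depth_cm"].to_numpy(dtype=float)
    genes: dict[str, GeneSeries] = {}
    for gene in FUNCTIONAL_GENES:
        col = f"{gene}_copies_g"
        if col in frame.columns:
            sd_col = f"{gene}_sd"
            sd = frame[sd_col].to_numpy(dtype=float) if sd_col in frame.columns else np.zeros_like(depths)
            genes[gene] = GeneSeries(frame[col].to_numpy(dtype=float), sd)
    taxa = [c[len("rel_"):] for c in frame.columns if c.startswith("rel_")]
    rel = pd.DataFrame(
        {t: frame[f"rel_{t}"].to_numpy(dtype=float) for t in taxa}
    )
    return CommunityTable(
        depths=depths,
        archaeal_16S=frame.get("arc_16S_copies_g", pd.Series(np.zeros_like(depths))).to_numpy(dtype=float),
        bacterial_16S=frame.get("bac_16S_copies_g", pd.Series(np.zeros_like(depths))).to_numpy(dtype=float),
        functional_genes=genes,
        relative_abundance=rel,
    )


def dump_json(obj, path) -> None:
    """Byte-stable JSON dump (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")
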