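"""Absolute microbial abundances and anammox niche-partitioning metrics.

Total prokaryotic cell counts come from summed archaeal and bacterial 16S rRNA
gene copies under the single-copy-per-genome assumption; a taxon's absolute
abundance (cells g⁻¹ wet sediment) is the product of that total and its
relative amplicon abundance.  The anammox guild is the sum of the two marine
anammox families, *Ca.* Scalinduaceae and *Ca.* Bathyanammoxibiaceae.

Niche partitioning between the two families is quantified by the vertical
separation Δz of their absolute-abundance maxima; at a steady sedimentation
rate ω (cm kyr⁻¹), that separation corresponds to a duration Δz/ω·1000 years —
an upper bound on how long the partitioning has persisted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConcordanceError, PeakError, ValidationError
from .profile_io import ANAMMOX_FAMILIES, CommunityTable

logger = logging.getLogger("poreflux")


def total_cell_count(archaeal_16S, bacterial_16S):
    """Total cells g⁻¹ as the sum of archaeal and bacterial 16S gene copies.

    Assumes a single 16S rRNA gene copy per archaeal or bacterial genome, so
    copies equal cells.  Accepts scalars or arrays.
    """
    a = np.asarray(archaeal_16S, dtype=float)
    b = np.asarray(bacterial_16S, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValidationError("16S gene copies must be >= 0")
    total = a + b
    return float(total) if total.ndim == 0 else total


def absolute_abundance(total_cells, relative_abundance):
    """Cells g⁻¹ of a taxon: total cell count times its relative abundance."""
    total = np.asarray(total_cells, dtype=float)
    rel = np.asarray(relative_abundance, dtype=float)
    if np.any((rel < 0) | (rel > 1)):
        raise ValidationError("relative abundance must lie in [0, 1]")
    out = total * rel
    return float(out) if out.ndim == 0 else out


def anammox_relative_abundance(table: CommunityTable) -> np.ndarray:
    """Per-depth summed fraction of the two anammox families.

    A family column missing from the table is treated as 0 with a warning.
    """
    rel = table.relative_abundance
    total = np.zeros(table.depths.size)
    for family in ANAMMOX_FAMILIES:
        if family in rel.columns:
            total += rel[family].to_numpy(dtype=float)
        else:
            logger.warning("family %s absent from community table; treated as 0", family)
    return total


@dataclass(frozen=True)
class AbsoluteAbundanceProfile:
    """Per-depth absolute abundance of one taxon (cells g⁻¹)."""

    depths: np.ndarray  # cm bsf
    taxon: str
    cells: np.ndarray
    method: str  # "amplicon-derived" | "qPCR-derived"

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        cells = np.asarray(self.cells, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "cells", cells)
        if depths.shape != cells.shape:
            raise ValidationError("depths and cells differ in length")
        if np.any(cells < 0):
            raise ValidationError("cells must be >= 0")


def abundance_profile(
    table: CommunityTable, taxon: str, method: str = "amplicon-derived"
) -> AbsoluteAbundanceProfile:
    """Amplicon-derived absolute abundance profile of one taxon."""
    if taxon not in table.relative_abundance.columns:
        raise ValidationError(f"taxon {taxon!r} absent from table")
    total = total_cell_count(table.archaeal_16S, table.bacterial_16S)
    cells = absolute_abundance(total, table.relative_abundance[taxon].to_numpy(dtype=float))
    return AbsoluteAbundanceProfile(table.depths, taxon, cells, method)


@dataclass(frozen=True)
class NichePartitionResult:
    """Family abundance peaks and the separation/duration metrics."""

    family_peaks: Mapping[str, tuple[float, float]]  # family -> (depth cm, cells/g)
    separation_cm: float
    sedimentation_rate: float | None = None  # cm/kyr
    duration_yr: float | None = None
    zones_hit: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "family_peaks": {
                f: {"depth_cm": float(d), "cells_per_g": float(c)}
                for f, (d, c) in self.family_peaks.items()
            },
            "separation_cm": float(self.separation_cm),
            "sedimentation_rate_cm_kyr": self.sedimentation_rate,
            "duration_yr": self.duration_yr,
            "zones_hit": {f: list(z) for f, z in self.zones_hit.items()},
        }


def family_peaks(
    profiles: Mapping[str, AbsoluteAbundanceProfile],
    zones=None,
) -> NichePartitionResult:
    """Per-family abundance maxima and their vertical separation Δz.

    Peaks are the argmax of *absolute* abundance (relative peaks can be
    artifacts of other taxa's decay); ties break to the shallowest depth.
    With exactly two families Δz is |depth₁ − depth₂|; with more, the span
    between the shallowest and deepest peak.
    """
    if not profiles:
        raise PeakError("no abundance profiles supplied")
    peaks: dict[str, tuple[float, float]] = {}
    for family, prof in profiles.items():
        if prof.depths.size == 0:
            raise PeakError(f"empty abundance profile for {family!r}")
        k = int(np.argmax(prof.cells))  # first occurrence = shallowest tie
        peaks[family] = (float(prof.depths[k]), float(prof.cells[k]))
    depths = [d for d, _ in peaks.values()]
    separation = float(max(depths) - min(depths)) if len(depths) > 1 else 0.0
    zones_hit: dict[str, tuple[str, ...]] = {}
    if zones is not None:
        for family, (depth, _) in peaks.items():
            hit = [
                label
                for label, lo, hi in (
                    ("oxic_zone", *(zones.oxic_zone or (np.nan, np.nan))),
                    ("nitrite_interval", *(zones.nitrite_interval or (np.nan, np.nan))),
                    ("natz", *(zones.natz or (np.nan, np.nan))),
                    (
                        "upper_consumption_zone",
                        *(zones.upper_consumption_zone or (np.nan, np.nan)),
                    ),
                    (
                        "lower_consumption_zone",
                        *(zones.lower_consumption_zone or (np.nan, np.nan)),
                    ),
                )
                if not np.isnan(lo) and lo <= depth <= hi
            ]
            zones_hit[family] = tuple(hit)
    return NichePartitionResult(
        family_peaks=peaks, separation_cm=separation, zones_hit=zones_hit
    )


def partition_duration(separation_cm: float, sedimentation_rate: float) -> float:
    """Years of sedimentation spanned by a depth separation.

    ``duration = (Δz / ω) * 1000`` with Δz in cm and ω in cm kyr⁻¹.
    """
    if not sedimentation_rate > 0:
        raise ValidationError(
            f"sedimentation rate must be > 0, got {sedimentation_rate}"
        )
    if separation_cm < 0:
        raise ValidationError(f"separation must be >= 0, got {separation_cm}")
    return separation_cm / sedimentation_rate * 1000.0


def with_duration(
    result: NichePartitionResult, sedimentation_rate: float
) -> NichePartitionResult:
    """Attach the Δz/ω duration to a peak-separation result."""
    return replace(
        result,
        sedimentation_rate=float(sedimentation_rate),
        duration_yr=partition_duration(result.separation_cm, sedimentation_rate),
    )


@dataclass(frozen=True)
class ConcordanceResult:
    """Per-depth log10(qPCR / amplicon-derived) abundance comparison."""

    depths: np.ndarray
    log10_ratios: np.ndarray
    median: float
    fraction_within_1: float  # |log10 ratio| <= 1 (one order of magnitude)
    pseudocount: float

    def to_dict(self) -> dict:
        return {
            "depths_cm": [float(z) for z in self.depths],
            "log10_ratios": [float(r) for r in self.log10_ratios],
            "median": float(self.median),
            "fraction_within_1_order": float(self.fraction_within_1),
            "pseudocount": float(self.pseudocount),
        }


def qpcr_concordance(
    amplicon_derived: AbsoluteAbundanceProfile,
    qpcr_depths,
    qpcr_copies,
    pseudocount: float | None = None,
) -> ConcordanceResult:
    """Agreement between qPCR and amplicon-derived absolute abundances.

    Per overlapping depth, log10(qPCR / amplicon-derived).  When zeros are
    present on either side both series are lifted by a pseudo-count (default:
    half the smallest nonzero value across both series); without zeros no
    pseudo-count is applied.  The summary is the median log-ratio and the
    fraction of depths within one order of magnitude.
    """
    qd = np.asarray(qpcr_depths, dtype=float)
    qc = np.asarray(qpcr_copies, dtype=float)
    mask_a = np.isin(amplicon_derived.depths, qd)
    if not mask_a.any():
        raise ConcordanceError("no overlapping depths between qPCR and amplicon series")
    depths = amplicon_derived.depths[mask_a]
    a = amplicon_derived.cells[mask_a]
    q = np.array([qc[np.flatnonzero(qd == z)[0]] for z in depths])
    if pseudocount is None:
        if np.any(a == 0) or np.any(q == 0):
            nonzero = np.concatenate([a[a > 0], q[q > 0]])
            pseudocount = float(nonzero.min() / 2.0) if nonzero.size else 1.0
        else:
            pseudocount = 0.0
    ratios = np.log10((q + pseudocount) / (a + pseudocount))
    return ConcordanceResult(
        depths=depths,
        log10_ratios=ratios,
        median=float(np.median(ratios)),
        fraction_within_1=float(np.mean(np.abs(ratios) <= 1.0)),
        pseudocount=pseudocount,
    )
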