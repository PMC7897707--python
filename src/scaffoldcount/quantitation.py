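"""Cell density per mm^3, summary statistics, and dual-channel viability.

The density of encapsulated cells is K = N / (B*C*D*1e-9), where N is the
mean nucleus count over fields of view, B and C the lateral field size in
um, D the analyzed depth in um, and 1e-9 converts um^3 to mm^3. Dispersion
over fields is reported as the sample standard deviation (n-1 denominator)
and the standard error of the mean. Viability compares densities from the
pan-nuclear channel with the dead-only channel of the same fields.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detection import NucleusObject
from .io_formats import Channel, FieldGeometry

logger = logging.getLogger(__name__)

#: Recommended minimum numbers of fields: at least 5 imaged, 10 averaged.
MIN_FIELDS_IMAGED = 5
MIN_FIELDS_AVERAGED = 10


@dataclass(frozen=True)
class FieldCount:
    """Nucleus count for one field of view."""

    field_id: str
    n: int
    geometry: FieldGeometry
    channel: Channel = Channel.total_nuclei

    def __post_init__(self) -> None:
        if self.n < 0 or self.n != int(self.n):
            raise ValueError("count must be a non-negative integer")

    def density_per_mm3(self) -> float:
        return self.n / self.geometry.volume_mm3


@dataclass(frozen=True)
class DensityResult:
    """Cells per mm^3 with dispersion over fields of view."""

    K: float
    N: float
    sigma: float
    sem: float
    n_fields: int
    per_field_K: tuple[float, ...]
    geometry: FieldGeometry | None = None
    channel: Channel = Channel.total_nuclei


@dataclass(frozen=True)
class ViabilityResult:
    """Dead-cell fraction from paired total/dead channel densities."""

    total_K: float
    dead_K: float
    percent_dead: float
    n_unmatched_dead: int | None = None


def summarize_densities(per_field_K: Sequence[float]) -> tuple[float, float, float]:
    """Mean, sample standard deviation (n-1) and SEM of per-field densities.

    With a single value the dispersion terms are NaN (undefined, not zero).
    """
    values = np.asarray(per_field_K, dtype=float)
    if values.size == 0:
        raise ValueError("summarize_densities requires at least one value")
    mean = float(values.mean())
    if values.size < 2:
        return mean, math.nan, math.nan
    sigma = float(values.std(ddof=1))
    sem = sigma / math.sqrt(values.size)
    return mean, sigma, sem


def density(counts: Sequence[FieldCount]) -> DensityResult:
    """Convert per-field counts sharing one geometry into cells per mm^3.

    All fields must share identical B, C, D (mixed geometries are rejected
    rather than silently volume-weighted). Fewer than the recommended
    numbers of fields is allowed but logged as a warning.
    """
    if not counts:
        raise ValueError("density requires at least one FieldCount")
    geom = counts[0].geometry
    for fc in counts[1:]:
        g = fc.geometry
        if (g.B, g.C, g.D) != (geom.B, geom.C, geom.D):
            raise ValueError(
                f"mixed field geometries: {g} (field {fc.field_id!r}) vs {geom}"
            )
    if geom.volume_mm3 <= 0:
        raise ValueError("field volume must be positive")
    if len(counts) < MIN_FIELDS_IMAGED:
        logger.warning("only %d fields of view; at least 5 recommended", len(counts))
    elif len(counts) < MIN_FIELDS_AVERAGED:
        logger.warning("averaging over %d fields; 10 or more recommended", len(counts))

    per_field_K = tuple(fc.density_per_mm3() for fc in counts)
    N = float(np.mean([fc.n for fc in counts]))
    K = N / geom.volume_mm3
    _, sigma, sem = summarize_densities(per_field_K)
    if len(counts) < 2:
        sigma = sem = math.nan
    return DensityResult(
        K=K,
        N=N,
        sigma=sigma,
        sem=sem,
        n_fields=len(counts),
        per_field_K=per_field_K,
        geometry=geom,
        channel=counts[0].channel,
    )


def density_from_values(
    per_field_K: Sequence[float], geometry: FieldGeometry | None = None
) -> DensityResult:
    """Build a DensityResult directly from per-field densities (cells/mm^3).

    Entry point for data already expressed as densities, e.g. previously
    published per-field tables.
    """
    mean, sigma, sem = summarize_densities(per_field_K)
    return DensityResult(
        K=mean,
        N=mean * geometry.volume_mm3 if geometry is not None else math.nan,
        sigma=sigma,
        sem=sem,
        n_fields=len(per_field_K),
        per_field_K=tuple(float(v) for v in per_field_K),
        geometry=geometry,
    )


def match_dead_to_total(
    total_objects: Sequence[NucleusObject],
    dead_objects: Sequence[NucleusObject],
    radius_um: float = 10.0,
) -> tuple[list[NucleusObject], list[NucleusObject]]:
    """Pair dead-channel nuclei with total-channel nuclei by centroid.

    Each dead object must lie within ``radius_um`` (default 10 um, about one
    nucleus diameter) of an unclaimed total-channel object; greedy
    nearest-neighbour matching. Returns (matched, unmatched) dead objects.
    """
    from scipy.spatial import cKDTree

    if not dead_objects:
        return [], []
    if not total_objects:
        return [], list(dead_objects)
    tree = cKDTree([o.centroid_xy_um for o in total_objects])
    claimed: set[int] = set()
    matched, unmatched = [], []
    for obj in dead_objects:
        dists, idxs = tree.query(obj.centroid_xy_um, k=min(4, len(total_objects)))
        dists, idxs = np.atleast_1d(dists), np.atleast_1d(idxs)
        for d, i in zip(dists, idxs):
            if d <= radius_um and i not in claimed:
                claimed.add(int(i))
                matched.append(obj)
                break
        else:
            unmatched.append(obj)
    return matched, unmatched


def viability(
    total: DensityResult,
    dead: DensityResult,
    *,
    n_unmatched_dead: int | None = None,
) -> ViabilityResult:
    """Percentage of dead cells per mm^3 from paired channel densities.

    percent_dead = 100 * dead_K / total_K. When centroid matching was
    applied upstream, pass the number of unmatched dead objects; matched
    dead counts are then a subset of the total and the percentage is
    guaranteed <= 100. Without matching the channels are counted
    independently and a percentage above 100 is reported as-is with a
    warning.
    """
    if total.K == 0:
        if dead.K > 0:
            raise ValueError(
                "dead-channel density positive while total-channel density is "
                "zero: channels are inconsistent"
            )
        return ViabilityResult(total_K=0.0, dead_K=0.0, percent_dead=0.0,
                               n_unmatched_dead=n_unmatched_dead)
    percent = 100.0 * dead.K / total.K
    if percent > 100.0:
        logger.warning(
            "percent_dead %.1f exceeds 100; enable centroid matching to "
            "enforce the subset relation", percent,
        )
    return ViabilityResult(
        total_K=total.K, dead_K=dead.K, percent_dead=percent,
        n_unmatched_dead=n_unmatched_dead,
    )
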