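"""Reading image stacks and calibration, writing tabular results.

A field of view is recorded as an ordered series of grayscale planes along
the optical axis (a z-stack), one multi-page TIFF per field per channel.
Physical calibration (pixel size, z-step) is never inferred from image
metadata: it comes from an explicit YAML config keyed by objective, so that
a run is reproducible from the config alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

#: Deepest analyzed z-extent (um) before a warning is raised; beyond this
#: depth out-of-focus rejection becomes unreliable in wide-field imaging.
MAX_RECOMMENDED_DEPTH_UM = 530.0

SUMMARY_ROW_LABELS = ("Average (M)", "mean square deviation", "standard error of the mean")


class Channel(str, Enum):
    """Fluorescence channel role.

    ``total_nuclei`` is the DNA stain visible in every cell (Hoechst 33342,
    DAPI channel); ``dead_nuclei`` is the membrane-impermeant counterstain
    visible only in dead cells (TO-PRO-3, Texas Red channel).
    """

    total_nuclei = "total_nuclei"
    dead_nuclei = "dead_nuclei"


class Objective(str, Enum):
    x4 = "4x"
    x10 = "10x"


@dataclass(frozen=True)
class FieldGeometry:
    """Physical extent of one analyzed field of view.

    Attributes
    ----------
    B, C : float
        Lateral size of the field along X and Y, in micrometers.
    D : float
        Analyzed depth along the optical axis, in micrometers.
    objective : Objective
        Objective the field was imaged with (bookkeeping only).
    """

    B: float
    C: float
    D: float
    objective: Objective = Objective.x4

    def __post_init__(self) -> None:
        for name in ("B", "C", "D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"FieldGeometry.{name} must be strictly positive")

    @property
    def volume_mm3(self) -> float:
        """Sampled volume B*C*D converted from um^3 to mm^3."""
        return self.B * self.C * self.D * 1e-9


@dataclass
class ImageStack:
    """One field of view as ordered z-planes with physical calibration.

    Planes are ordered from the first acquired depth; ``z_step_um`` is the
    spacing between consecutive planes and ``z_extent_um`` the total depth
    covered, i.e. ``z_step_um * (n_planes - 1)``.
    """

    planes: np.ndarray  # (z, y, x), unsigned integer
    pixel_size_um: float
    z_step_um: float
    channel: Channel = Channel.total_nuclei
    field_id: str = "field"
    objective: Objective = Objective.x4

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3:
            raise ValueError("planes must be a (z, y, x) array")
        if self.planes.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
            raise ValueError(
                f"unsupported bit depth {self.planes.dtype}; expected uint8 or uint16"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.z_step_um < 0:
            raise ValueError("z_step_um must be non-negative")
        if self.z_extent_um > MAX_RECOMMENDED_DEPTH_UM + 1e-9:
            warnings.warn(
                f"z extent {self.z_extent_um:.0f} um exceeds the recommended "
                f"maximum of {MAX_RECOMMENDED_DEPTH_UM:.0f} um; deep planes may "
                "be unusable",
                stacklevel=2,
            )

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def z_extent_um(self) -> float:
        return self.z_step_um * (self.n_planes - 1)

    @property
    def bit_depth(self) -> int:
        return 8 * self.planes.dtype.itemsize

    def geometry(self) -> FieldGeometry:
        """Field geometry implied by plane shape, pixel size and z extent.

        A single-plane stack has zero z extent; callers quantifying volume
        must supply an explicit depth instead.
        """
        ny, nx = self.planes.shape[1:]
        depth = self.z_extent_um if self.z_extent_um > 0 else self.z_step_um
        if depth <= 0:
            raise ValueError(
                "stack has no z extent; pass an explicit FieldGeometry for volume work"
            )
        return FieldGeometry(
            B=nx * self.pixel_size_um,
            C=ny * self.pixel_size_um,
            D=depth,
            objective=self.objective,
        )


@dataclass(frozen=True)
class Calibration:
    """Per-objective physical calibration, loaded from YAML."""

    pixel_size_um: float
    z_step_um: float

    @staticmethod
    def from_yaml(path: str | Path, objective: Objective | str) -> "Calibration":
        obj = Objective(objective)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        try:
            entry = cfg["objectives"][obj.value]
            return Calibration(
                pixel_size_um=float(entry["pixel_size_um"]),
                z_step_um=float(entry["z_step_um"]),
            )
        except (KeyError, TypeError) as exc:
            raise KeyError(
                f"calibration file {path} missing key for objective "
                f"'{obj.value}': expected objectives.{obj.value}."
                "{pixel_size_um,z_step_um}"
            ) from exc


#: Default calibration for the two supported objectives. Pixel sizes assume a
#: camera with ~6.5 um pixels behind the objective, typical of wide-field
#: imagers of this class; override via YAML for a real instrument.
DEFAULT_CALIBRATIONS = {
    Objective.x4: Calibration(pixel_size_um=1.625, z_step_um=106.0),
    Objective.x10: Calibration(pixel_size_um=0.65, z_step_um=106.0),
}


def load_stack(
    path: str | Path,
    calibration: Calibration,
    *,
    channel: Channel = Channel.total_nuclei,
    field_id: str | None = None,
    objective: Objective = Objective.x4,
) -> ImageStack:
    """Load a z-stack from a multi-page TIFF or a directory of plane TIFFs.

    Plane order is the page order of a multi-page file, or the lexicographic
    filename order within a directory — never file-system enumeration order.

    Raises
    ------
    FileNotFoundError, ValueError
        On unreadable input, non-TIFF planes, inconsistent plane shapes or
        bit depths; the message names the offending plane.
    """
    path = Path(path)
    if path.is_dir():
        plane_files = sorted(p for p in path.iterdir() if p.is_file())
        if not plane_files:
            raise FileNotFoundError(f"no plane files in directory {path}")
        planes = []
        for pf in plane_files:
            if pf.suffix.lower() not in (".tif", ".tiff"):
                raise ValueError(f"plane {pf.name}: only TIFF planes are supported")
            planes.append(tifffile.imread(pf))
    else:
        if not path.exists():
            raise FileNotFoundError(f"stack file not found: {path}")
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ValueError(f"{path.name}: only multi-page grayscale TIFF is supported")
        data = tifffile.imread(path)
        planes = [data] if data.ndim == 2 else list(data)

    first = np.asarray(planes[0])
    for i, pl in enumerate(planes):
        pl = np.asarray(pl)
        if pl.ndim != 2:
            raise ValueError(f"plane {i}: expected 2D grayscale, got shape {pl.shape}")
        if pl.shape != first.shape:
            raise ValueError(
                f"plane {i}: shape {pl.shape} differs from plane 0 shape {first.shape}"
            )
        if pl.dtype != first.dtype:
            raise ValueError(
                f"plane {i}: dtype {pl.dtype} differs from plane 0 dtype {first.dtype}"
            )

    return ImageStack(
        planes=np.stack([np.asarray(p) for p in planes]),
        pixel_size_um=calibration.pixel_size_um,
        z_step_um=calibration.z_step_um,
        channel=channel,
        field_id=field_id if field_id is not None else path.stem,
        objective=objective,
    )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page grayscale TIFF."""
    tifffile.imwrite(Path(path), stack.planes)


# ---------------------------------------------------------------------------
# Tabular results


def write_counts_table(results: Sequence, path: str | Path) -> pd.DataFrame:
    """Write per-field densities plus summary rows as CSV.

    One row per field (field number, nucleus count, cells/mm^3) followed by
    three summary rows over the per-field densities: mean, sample standard
    deviation (n-1) and standard error of the mean. Numbers are printed with
    two decimal places. With a single field the dispersion rows carry "n/a".

    Parameters
    ----------
    results : sequence of FieldCount
        Per-field counts; all must share a common geometry.

    Returns
    -------
    pandas.DataFrame
        The table as written (strings, 2 d.p.).
    """
    from .quantitation import summarize_densities  # local import: avoid cycle

    if not results:
        raise ValueError("write_counts_table requires at least one FieldCount")
    rows = []
    per_field_k = []
    for i, fc in enumerate(results, start=1):
        k = fc.density_per_mm3()
        per_field_k.append(k)
        rows.append(
            {
                "field": str(i),
                "field_id": fc.field_id,
                "n_nuclei": str(fc.n),
                "cells_per_mm3": f"{k:.2f}",
            }
        )
    if len(per_field_k) >= 2:
        mean, sigma, sem = summarize_densities(per_field_k)
        summaries = [f"{mean:.2f}", f"{sigma:.2f}", f"{sem:.2f}"]
    else:
        summaries = [f"{per_field_k[0]:.2f}", "n/a", "n/a"]
    for label, value in zip(SUMMARY_ROW_LABELS, summaries):
        rows.append({"field": label, "field_id": "", "n_nuclei": "", "cells_per_mm3": value})
    table = pd.DataFrame(rows)
    table.to_csv(path, index=False)
    return table


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Read back a counts table written by :func:`write_counts_table`."""
    return pd.read_csv(path, dtype=str, keep_default_na=False)
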