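"""Nucleus detection on fused images: intensity threshold plus area filter.

Nuclei are brightest at their centers, so keeping only pixels strictly above
an intensity threshold isolates the nuclear cores and splits closely spaced
nuclei whose dimmer haloes touch. Connected components of the supra-threshold
set are then filtered by physical core area: components at or above the
maximum are rejected (dye debris, unsplit clusters), components below the
minimum floor are rejected as hot-pixel specks. The accepted/rejected "mask"
overlay exists so a user can visually confirm that every visible nucleus was
counted before trusting the numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from skimage import measure, segmentation

from .io_formats import FieldGeometry
from .zfusion import FusedImage

logger = logging.getLogger(__name__)


class RejectionReason(str, Enum):
    below_intensity = "below_intensity"
    too_large = "too_large"
    too_small = "too_small"


class AreaUnit(str, Enum):
    #: Area limits are in um^2 of supra-threshold core area (default).
    um2 = "um2"
    #: Area limits are equivalent-circle diameters in um, converted to um^2.
    equivalent_diameter_um = "equivalent_diameter_um"


@dataclass(frozen=True)
class DetectionParams:
    """Filters applied to supra-threshold connected components.

    intensity_threshold is in arbitrary units on a 16-bit scale (default
    7000); pixels must be strictly greater to count. max_area_um2 excludes
    objects whose core area is >= the limit (default 30 um^2); min_area_um2
    rejects specks below the floor (default 2 um^2, set 0 to disable).
    ``area_unit`` lets the two limits be read as equivalent-circle diameters
    instead of areas, for instruments that report object size that way.
    """

    intensity_threshold: float = 7000.0
    max_area_um2: float = 30.0
    min_area_um2: float = 2.0
    connectivity: int = 8
    area_unit: AreaUnit = AreaUnit.um2

    def __post_init__(self) -> None:
        if self.intensity_threshold <= 0:
            raise ValueError("intensity_threshold must be positive")
        if not (0 <= self.min_area_um2 < self.max_area_um2):
            raise ValueError("need 0 <= min_area_um2 < max_area_um2")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def area_limits_um2(self) -> tuple[float, float]:
        """(min, max) area limits in um^2 regardless of the configured unit."""
        if self.area_unit is AreaUnit.um2:
            return self.min_area_um2, self.max_area_um2
        to_area = lambda d: np.pi * (d / 2.0) ** 2  # noqa: E731
        return to_area(self.min_area_um2), to_area(self.max_area_um2)


@dataclass(frozen=True)
class NucleusObject:
    """One accepted nuclear core.

    Centroid is intensity-weighted within the supra-threshold core, in um
    from the top-left pixel center (x rightward, y downward).
    """

    label: int
    centroid_xy_um: tuple[float, float]
    area_um2: float
    peak_intensity: float
    mean_intensity: float


@dataclass
class MaskOverlay:
    """QC mask: which components were counted and why others were not."""

    base: FusedImage
    accepted_labels: np.ndarray
    rejected_labels: np.ndarray
    rejection_reasons: dict[int, RejectionReason] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any((self.accepted_labels > 0) & (self.rejected_labels > 0)):
            raise ValueError("accepted and rejected label rasters overlap")


def segment_nuclei(
    image: FusedImage, params: DetectionParams | None = None
) -> tuple[list[NucleusObject], MaskOverlay]:
    """Detect nuclear cores on a fused image.

    Returns the accepted objects (sorted by label) and the mask overlay
    holding both accepted and rejected label rasters.

    8-bit images are rescaled to the 16-bit range before thresholding (the
    threshold convention assumes a 16-bit scale); this is logged.
    """
    if params is None:
        params = DetectionParams()
    pixels = image.pixels
    max_repr = float(np.iinfo(pixels.dtype).max) if pixels.dtype.kind == "u" else float(
        pixels.max(initial=1)
    )
    if image.bit_depth == 8:
        logger.warning(
            "8-bit input rescaled to 16-bit (x257) before applying the "
            "intensity threshold %g", params.intensity_threshold,
        )
        pixels = pixels.astype(np.uint16) * 257
        max_repr = 65535.0
    if params.intensity_threshold >= max_repr:
        raise ValueError(
            f"intensity threshold {params.intensity_threshold} >= maximum "
            f"representable intensity {max_repr}: nothing can pass"
        )

    core = pixels > params.intensity_threshold  # strict: 'more than'
    skimage_conn = 1 if params.connectivity == 4 else 2
    labels = measure.label(core, connectivity=skimage_conn)

    px_area_um2 = image.pixel_size_um**2
    min_area, max_area = params.area_limits_um2()

    accepted = np.zeros_like(labels)
    rejected = np.zeros_like(labels)
    reasons: dict[int, RejectionReason] = {}
    objects: list[NucleusObject] = []

    for region in measure.regionprops(labels, intensity_image=pixels):
        area_um2 = region.area * px_area_um2
        mask = labels == region.label
        if area_um2 >= max_area:  # strict 'less than' on acceptance
            rejected[mask] = region.label
            reasons[region.label] = RejectionReason.too_large
            continue
        if area_um2 < min_area:
            rejected[mask] = region.label
            reasons[region.label] = RejectionReason.too_small
            continue
        accepted[mask] = region.label
        cy, cx = region.centroid_weighted
        objects.append(
            NucleusObject(
                label=int(region.label),
                centroid_xy_um=(cx * image.pixel_size_um, cy * image.pixel_size_um),
                area_um2=float(area_um2),
                peak_intensity=float(region.intensity_max),
                mean_intensity=float(region.intensity_mean),
            )
        )

    objects.sort(key=lambda o: o.label)
    logger.info(
        "segment_nuclei: %d supra-threshold components, %d accepted, %d rejected",
        labels.max(), len(objects), len(reasons),
    )
    overlay = MaskOverlay(
        base=image,
        accepted_labels=accepted,
        rejected_labels=rejected,
        rejection_reasons=reasons,
    )
    return objects, overlay


def count_field(objects: list[NucleusObject], geometry: FieldGeometry, *, field_id: str = "field"):
    """Bundle the accepted objects of one field into a FieldCount."""
    from .quantitation import FieldCount

    return FieldCount(field_id=field_id, n=len(objects), geometry=geometry)


def render_mask(overlay: MaskOverlay, path: str | Path) -> Path:
    """Write the QC mask as an RGB image plus machine-readable sidecars.

    The base image is rendered in gray, accepted object outlines in green,
    rejected outlines in red. Alongside ``<path>`` two label rasters
    (``<stem>_accepted_labels.tif``, ``<stem>_rejected_labels.tif``) and a
    ``<stem>_legend.txt`` listing rejection reason codes are written.
    """
    import tifffile

    path = Path(path)
    base = overlay.base.pixels.astype(np.float64)
    hi = base.max()
    gray = (base / hi * 255).astype(np.uint8) if hi > 0 else base.astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    acc_edge = segmentation.find_boundaries(overlay.accepted_labels, mode="inner")
    rej_edge = segmentation.find_boundaries(overlay.rejected_labels, mode="inner")
    rgb[acc_edge] = (0, 255, 0)
    rgb[rej_edge] = (255, 0, 0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, rgb)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, rgb)
    stem = path.with_suffix("")
    tifffile.imwrite(f"{stem}_accepted_labels.tif", overlay.accepted_labels.astype(np.int32))
    tifffile.imwrite(f"{stem}_rejected_labels.tif", overlay.rejected_labels.astype(np.int32))
    with open(f"{stem}_legend.txt", "w") as fh:
        fh.write("accepted: green outline\nrejected: red outline\n")
        for label, reason in sorted(overlay.rejection_reasons.items()):
            fh.write(f"label {label}: {reason.value}\n")
    return path
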