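"""Ground-truthed synthetic z-stacks of stained nuclei in a scaffold slab.

Emulates wide-field imaging of a ~530 um-thick hydrogel volume with nuclei
suspended at random depths: each nucleus is an isotropic Gaussian blob that
is tight and bright in the plane nearest its own depth and spreads (with
falling peak, conserving integrated signal) in planes further away, on a
noisy background. An optional second channel renders only the dead-flagged
nuclei, mimicking a membrane-impermeant counterstain.

The generator's scope is deliberately modest: no physically derived PSF,
no scattering or depth-dependent attenuation in the gel, no photobleaching.
It reproduces the features the pipeline actually exploits — in-focus peaks
above threshold, defocused copies below it — with exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import Channel, FieldGeometry, ImageStack, Objective


@dataclass(frozen=True)
class Nucleus:
    x_um: float
    y_um: float
    z_um: float
    core_radius_um: float  # Gaussian sigma of the in-focus blob
    peak_intensity: float  # in-focus amplitude, a.u. on a 16-bit scale
    dead: bool = False


@dataclass(frozen=True)
class NoiseModel:
    """Additive background: constant offset + Gaussian read noise; optional
    Poisson shot noise on the signal."""

    background_mean: float = 500.0
    gaussian_sd: float = 100.0
    poisson: bool = False


@dataclass(frozen=True)
class SyntheticScene:
    """Ground truth for one synthetic field of view."""

    nuclei: tuple[Nucleus, ...]
    geometry: FieldGeometry
    noise: NoiseModel
    psf_blur_per_um: float  # added defocus sigma (um) per um of |z - plane_z|
    seed: int

    @property
    def n_dead(self) -> int:
        return sum(n.dead for n in self.nuclei)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "x_um": n.x_um, "y_um": n.y_um, "z_um": n.z_um,
                    "core_radius_um": n.core_radius_um,
                    "peak_intensity": n.peak_intensity, "dead": n.dead,
                }
                for n in self.nuclei
            ]
        )

    def write_ground_truth(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


DEFAULT_GEOMETRY = FieldGeometry(B=1000.0, C=1000.0, D=530.0, objective=Objective.x4)


def generate_scene(
    n_nuclei: int,
    seed: int,
    *,
    geometry: FieldGeometry = DEFAULT_GEOMETRY,
    min_separation_um: float = 30.0,
    dead_fraction: float = 0.0,
    core_radius_um: float = 1.4,
    peak_intensity: float = 20000.0,
    noise: NoiseModel = NoiseModel(),
    psf_blur_per_um: float = 0.03,
    margin_um: float = 5.0,
    max_attempts_per_nucleus: int = 200,
) -> SyntheticScene:
    """Place nuclei uniformly at random with a minimum pairwise separation.

    Dart throwing with a bounded retry budget; if the requested count cannot
    be packed, the error names the count that was achievable. The number of
    dead nuclei is ``round(dead_fraction * n_nuclei)`` exactly, assigned to
    a random subset.
    """
    if not 0.0 <= dead_fraction <= 1.0:
        raise ValueError("dead_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lo = margin_um
    positions: list[tuple[float, float, float]] = []
    budget = max_attempts_per_nucleus * max(n_nuclei, 1)
    attempts = 0
    while len(positions) < n_nuclei:
        if attempts >= budget:
            raise RuntimeError(
                f"could only place {len(positions)} of {n_nuclei} nuclei at "
                f"min separation {min_separation_um} um in a "
                f"{geometry.B:g}x{geometry.C:g} um field after {budget} attempts"
            )
        attempts += 1
        x = rng.uniform(lo, geometry.B - lo)
        y = rng.uniform(lo, geometry.C - lo)
        z = rng.uniform(0.0, geometry.D)
        if all(
            (x - px) ** 2 + (y - py) ** 2 >= min_separation_um**2
            for px, py, _ in positions
        ):
            positions.append((x, y, z))

    n_dead = int(round(dead_fraction * n_nuclei))
    dead_idx = set(rng.choice(n_nuclei, size=n_dead, replace=False).tolist()) if n_dead else set()
    nuclei = tuple(
        Nucleus(
            x_um=x, y_um=y, z_um=z,
            core_radius_um=core_radius_um,
            peak_intensity=peak_intensity,
            dead=(i in dead_idx),
        )
        for i, (x, y, z) in enumerate(positions)
    )
    return SyntheticScene(
        nuclei=nuclei, geometry=geometry, noise=noise,
        psf_blur_per_um=psf_blur_per_um, seed=seed,
    )


def blob_profile(
    nucleus: Nucleus, plane_z_um: float, psf_blur_per_um: float
) -> tuple[float, float]:
    """(amplitude, sigma_um) of a nucleus as seen in one plane.

    The defocus blur sigma grows linearly with axial distance and adds in
    quadrature to the core sigma; the amplitude falls as the inverse of the
    variance ratio so that the integrated 2D signal is conserved.
    """
    sigma0 = nucleus.core_radius_um
    defocus = psf_blur_per_um * abs(nucleus.z_um - plane_z_um)
    sigma_sq = sigma0**2 + defocus**2
    amplitude = nucleus.peak_intensity * sigma0**2 / sigma_sq
    return amplitude, float(np.sqrt(sigma_sq))


def _render_plane(
    scene: SyntheticScene,
    nuclei: Sequence[Nucleus],
    plane_z_um: float,
    pixel_size_um: float,
    shape: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    ny, nx = shape
    img = np.zeros(shape, dtype=np.float64)
    for nuc in nuclei:
        amp, sigma = blob_profile(nuc, plane_z_um, scene.psf_blur_per_um)
        if amp < 1.0:
            continue
        half = 4.0 * sigma
        x0 = max(int((nuc.x_um - half) / pixel_size_um), 0)
        x1 = min(int((nuc.x_um + half) / pixel_size_um) + 2, nx)
        y0 = max(int((nuc.y_um - half) / pixel_size_um), 0)
        y1 = min(int((nuc.y_um + half) / pixel_size_um) + 2, ny)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = (np.arange(x0, x1) + 0.5) * pixel_size_um - nuc.x_um
        ys = (np.arange(y0, y1) + 0.5) * pixel_size_um - nuc.y_um
        r2 = ys[:, None] ** 2 + xs[None, :] ** 2
        img[y0:y1, x0:x1] += amp * np.exp(-r2 / (2.0 * sigma**2))
    if scene.noise.poisson:
        img = rng.poisson(np.maximum(img, 0.0)).astype(np.float64)
    img += scene.noise.background_mean
    if scene.noise.gaussian_sd > 0:
        img += rng.normal(0.0, scene.noise.gaussian_sd, size=shape)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def render_stack(
    scene: SyntheticScene,
    n_planes: int = 6,
    z_step_um: float = 106.0,
    *,
    pixel_size_um: float = 1.625,
    field_id: str = "synthetic",
) -> tuple[ImageStack, ImageStack]:
    """Render the scene into a total-nuclei stack and a dead-only stack.

    Planes sit at 0, z_step, ..., (n_planes-1)*z_step um. The dead channel
    images the same field with only dead-flagged nuclei emitting (background
    and noise are still present, as on a real counterstain channel).
    Rendering is fully deterministic in (scene, arguments): noise streams
    are derived from the scene seed per channel and plane.
    """
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    shape = (
        int(round(scene.geometry.C / pixel_size_um)),
        int(round(scene.geometry.B / pixel_size_um)),
    )
    stacks = []
    for ch_idx, (channel, nuclei) in enumerate(
        [
            (Channel.total_nuclei, scene.nuclei),
            (Channel.dead_nuclei, tuple(n for n in scene.nuclei if n.dead)),
        ]
    ):
        planes = []
        for p in range(n_planes):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=scene.seed, spawn_key=(ch_idx, p))
            )
            planes.append(
                _render_plane(scene, nuclei, p * z_step_um, pixel_size_um, shape, rng)
            )
        stacks.append(
            ImageStack(
                planes=np.stack(planes),
                pixel_size_um=pixel_size_um,
                z_step_um=z_step_um,
                channel=channel,
                field_id=field_id,
                objective=scene.geometry.objective,
            )
        )
    return stacks[0], stacks[1]


def write_scene_yaml(scene: SyntheticScene, path: str | Path) -> None:
    """Serialize the scene parameters (not the rendered pixels) as YAML."""
    doc = {
        "seed": scene.seed,
        "geometry": {
            "B": scene.geometry.B, "C": scene.geometry.C, "D": scene.geometry.D,
            "objective": scene.geometry.objective.value,
        },
        "noise": {
            "background_mean": scene.noise.background_mean,
            "gaussian_sd": scene.noise.gaussian_sd,
            "poisson": scene.noise.poisson,
        },
        "psf_blur_per_um": scene.psf_blur_per_um,
        "nuclei": [
            {
                "x_um": n.x_um, "y_um": n.y_um, "z_um": n.z_um,
                "core_radius_um": n.core_radius_um,
                "peak_intensity": n.peak_intensity, "dead": bool(n.dead),
            }
            for n in scene.nuclei
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
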