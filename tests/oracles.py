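"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written the slow, obvious way on purpose: BFS flood
fill for connected components, explicit per-pixel window loops for the
focus measure, and the closed-form blob profile re-derived from first
principles. None of it shares code with the package paths it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np

NEIGHBORS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
NEIGHBORS_8 = NEIGHBORS_4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def flood_fill_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label connected True regions of a boolean raster by BFS."""
    neigh = NEIGHBORS_8 if connectivity == 8 else NEIGHBORS_4
    ny, nx = mask.shape
    labels = np.zeros(mask.shape, dtype=int)
    next_label = 0
    for sy in range(ny):
        for sx in range(nx):
            if mask[sy, sx] and labels[sy, sx] == 0:
                next_label += 1
                queue = deque([(sy, sx)])
                labels[sy, sx] = next_label
                while queue:
                    y, x = queue.popleft()
                    for dy, dx in neigh:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < ny and 0 <= xx < nx and mask[yy, xx] and labels[yy, xx] == 0:
                            labels[yy, xx] = next_label
                            queue.append((yy, xx))
    return labels


def components_as_sets(labels: np.ndarray) -> set[frozenset]:
    """Connected components as sets of pixel coordinates, label-agnostic."""
    comps: dict[int, set] = {}
    ny, nx = labels.shape
    for y in range(ny):
        for x in range(nx):
            if labels[y, x] > 0:
                comps.setdefault(labels[y, x], set()).add((y, x))
    return {frozenset(s) for s in comps.values()}


def _reflect_pad(img: np.ndarray, pad: int) -> np.ndarray:
    # edge-inclusive reflection (a b c | c b a), matching the package's
    # boundary convention
    return np.pad(img, pad, mode="symmetric")


def laplacian_direct(img: np.ndarray) -> np.ndarray:
    """5-point discrete Laplacian with reflective boundaries, by loops."""
    padded = _reflect_pad(img.astype(float), 1)
    ny, nx = img.shape
    out = np.empty((ny, nx))
    for y in range(ny):
        for x in range(nx):
            c = padded[y + 1, x + 1]
            out[y, x] = (
                padded[y, x + 1] + padded[y + 2, x + 1]
                + padded[y + 1, x] + padded[y + 1, x + 2] - 4 * c
            )
    return out


def windowed_variance_direct(img: np.ndarray, window: int) -> np.ndarray:
    """Population variance over a window x window neighbourhood, by loops."""
    pad = window // 2
    padded = _reflect_pad(img.astype(float), pad)
    ny, nx = img.shape
    out = np.empty((ny, nx))
    for y in range(ny):
        for x in range(nx):
            patch = padded[y : y + window, x : x + window]
            out[y, x] = patch.var()
    return out


def focus_score_direct(plane: np.ndarray, window: int, laplacian: bool = True) -> np.ndarray:
    img = laplacian_direct(plane) if laplacian else plane.astype(float)
    return windowed_variance_direct(img, window)


def defocused_peak(peak: float, core_sigma: float, blur_per_um: float, dz: float) -> float:
    """Peak amplitude of a Gaussian blob observed |dz| um out of focus.

    The in-focus 2D Gaussian (amplitude A, sd s) convolved with an isotropic
    Gaussian blur of sd b has sd sqrt(s^2+b^2) and amplitude
    A*s^2/(s^2+b^2), conserving the integral A*2*pi*s^2.
    """
    blur = blur_per_um * abs(dz)
    return peak * core_sigma**2 / (core_sigma**2 + blur**2)
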