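"""Rendering of 3D intensity volumes and local-maximum spot detection.

Volumes are stored z-major (``data[z, y, x]``) with explicit voxel size and
world origin: the centre of voxel (0, 0, 0) sits at ``origin`` (µm), and
world x = origin_x + ix * voxel_size_x, etc.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import Point3, ValidationError

__all__ = ["Volume", "render_volume", "detect_spots"]


@dataclass
class Volume:
    data: np.ndarray  # (nz, ny, nx) float intensities
    voxel_size: Tuple[float, float, float]  # (vx, vy, vz) in µm
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError("volume data must be 3D (z, y, x)")
        if self.voxel_size is None or len(self.voxel_size) != 3 or any(
            v <= 0 for v in self.voxel_size
        ):
            raise ValidationError("voxel_size metadata (vx, vy, vz) is required")

    def world_to_index(self, p: Point3) -> np.ndarray:
        vx, vy, vz = self.voxel_size
        ox, oy, oz = self.origin
        return np.array([(p.z - oz) / vz, (p.y - oy) / vy, (p.x - ox) / vx])

    def index_to_world(self, idx: Sequence[float]) -> Point3:
        iz, iy, ix = (float(i) for i in idx)
        vx, vy, vz = self.voxel_size
        ox, oy, oz = self.origin
        return Point3(ox + ix * vx, oy + iy * vy, oz + iz * vz)


def render_volume(
    positions: Sequence[Point3],
    shape: Tuple[int, int, int],
    voxel_size: Tuple[float, float, float] = (0.1, 0.1, 0.3),
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    psf_sigma: Tuple[float, float, float] = (0.15, 0.15, 0.3),
    amplitudes: Optional[Sequence[float]] = None,
    poisson_noise: bool = False,
    photons_per_unit: float = 500.0,
    rng=None,
) -> Volume:
    """Sum of anisotropic Gaussian blobs on a voxel grid.

    ``shape`` is (nz, ny, nx).  Spots outside the grid raise an error
    listing the offenders; optional Poisson noise scales intensities to
    photon counts and back.
    """
    vol = Volume(np.zeros(shape, dtype=float), tuple(voxel_size), tuple(origin))
    nz, ny, nx = shape
    if amplitudes is None:
        amplitudes = [1.0] * len(positions)

    offenders = []
    for k, p in enumerate(positions):
        iz, iy, ix = vol.world_to_index(p)
        if not (0 <= iz <= nz - 1 and 0 <= iy <= ny - 1 and 0 <= ix <= nx - 1):
            offenders.append((k, p))
    if offenders:
        raise ValidationError(
            "spots outside volume grid: "
            + ", ".join(f"#{k} at ({p.x:.2f},{p.y:.2f},{p.z:.2f})" for k, p in offenders)
        )

    vx, vy, vz = vol.voxel_size
    sx, sy, sz = psf_sigma
    rx = max(1, int(np.ceil(4 * sx / vx)))
    ry = max(1, int(np.ceil(4 * sy / vy)))
    rz = max(1, int(np.ceil(4 * sz / vz)))
    for amp, p in zip(amplitudes, positions):
        ciz, ciy, cix = vol.world_to_index(p)
        z0, z1 = max(0, int(ciz) - rz), min(nz, int(ciz) + rz + 2)
        y0, y1 = max(0, int(ciy) - ry), min(ny, int(ciy) + ry + 2)
        x0, x1 = max(0, int(cix) - rx), min(nx, int(cix) + rx + 2)
        zz = (np.arange(z0, z1) * vz + vol.origin[2] - p.z) / sz
        yy = (np.arange(y0, y1) * vy + vol.origin[1] - p.y) / sy
        xx = (np.arange(x0, x1) * vx + vol.origin[0] - p.x) / sx
        blob = np.exp(
            -0.5
            * (
                zz[:, None, None] ** 2
                + yy[None, :, None] ** 2
                + xx[None, None, :] ** 2
            )
        )
        vol.data[z0:z1, y0:y1, x0:x1] += amp * blob

    if poisson_noise:
        rng = np.random.default_rng(rng)
        vol.data = rng.poisson(vol.data * photons_per_unit).astype(float) / photons_per_unit
    return vol


def detect_spots(
    volume: Volume,
    smoothing_sigma: Tuple[float, float, float] = (0.05, 0.05, 0.1),
    min_intensity: float = 0.1,
    centroid_radius: int = 2,
) -> List[Point3]:
    """Local-maximum spot detection with sub-voxel localization.

    Gaussian smoothing (sigma in µm per world axis), 26-connected local
    maxima above ``min_intensity``, then an intensity-weighted centroid in
    a fixed window around each maximum.  Centres are returned in world µm.
    """
    if not isinstance(volume, Volume):
        raise ValidationError("detect_spots requires a Volume with voxel metadata")
    vx, vy, vz = volume.voxel_size
    sig_vox = (smoothing_sigma[2] / vz, smoothing_sigma[1] / vy, smoothing_sigma[0] / vx)
    smooth = ndimage.gaussian_filter(volume.data, sigma=sig_vox)

    footprint = np.ones((3, 3, 3), dtype=bool)
    maxima = (smooth == ndimage.maximum_filter(smooth, footprint=footprint)) & (
        smooth > min_intensity
    )
    # collapse plateaus to one representative voxel
    labels, n = ndimage.label(maxima)
    centers = ndimage.center_of_mass(maxima, labels, range(1, n + 1))

    out: List[Point3] = []
    nz, ny, nx = volume.data.shape
    r = int(centroid_radius)
    for cz, cy, cx in centers:
        iz, iy, ix = int(round(cz)), int(round(cy)), int(round(cx))
        z0, z1 = max(0, iz - r), min(nz, iz + r + 1)
        y0, y1 = max(0, iy - r), min(ny, iy + r + 1)
        x0, x1 = max(0, ix - r), min(nx, ix + r + 1)
        w = smooth[z0:z1, y0:y1, x0:x1]
        tot = w.sum()
        if tot <= 0:
            continue
        gz, gy, gx = np.meshgrid(
            np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
        )
        sub = (
            float((w * gz).sum() / tot),
            float((w * gy).sum() / tot),
            float((w * gx).sum() / tot),
        )
        out.append(volume.index_to_world(sub))
    out.sort(key=lambda p: (p.z, p.y, p.x))
    return out
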