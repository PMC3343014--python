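"""Photon emission along a trajectory and pixel accumulation.

Models the image a single moving molecule forms on the camera during one
integration window.  Photons are emitted at evenly distributed times during
the exposure: at each of the ``N_steps + 1`` trajectory positions a photon is
generated with probability ``p = n_photons / n_positions`` (capped at 1), so
the expected photon yield is independent of how finely the walk is
discretised.  Each photon lands at the emitting position plus point-spread
scatter with the same half-normal radial convention used for localization
scatter: radial magnitude ``|Normal(0, s)|`` with uniform angle, ``s`` being
the PSF width (250 nm by default).

Accumulating the photons on a grid of square pixels (100 nm by default)
yields the motion-blurred single-molecule image: motion during the exposure
spreads photons over more pixels, lowering the brightest pixel and distorting
the apparent PSF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .walks import Trajectory

__all__ = [
    "ImagingParams",
    "PhotonSet",
    "PixelImage",
    "emit_photons",
    "accumulate_image",
    "brightest_pixel",
    "default_grid",
    "write_tiff_stack",
    "write_photon_csv",
]


@dataclass(frozen=True)
class ImagingParams:
    """Photon budget, PSF and detector geometry for one integration window.

    Parameters
    ----------
    n_photons : int
        Expected number of photons emitted during the exposure (default 1000).
    psf_sigma : float
        PSF scatter width ``s`` in nm (default 250).
    pixel_size : float
        Detector pixel size ``a`` in nm (default 100).
    background : float
        Per-pixel Gaussian background noise sd ``b`` in photons (default 0;
        background is generally omitted to prevent localization failures).
    """

    n_photons: int = 1000
    psf_sigma: float = 250.0
    pixel_size: float = 100.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError(f"n_photons must be >= 1, got {self.n_photons}")
        if self.psf_sigma <= 0 or self.pixel_size <= 0:
            raise ValueError("psf_sigma and pixel_size must be > 0")
        if self.background < 0:
            raise ValueError("background sd must be >= 0")


@dataclass
class PhotonSet:
    """Emitted photon landing positions and the trajectory steps that emitted them."""

    photon_positions: np.ndarray  # (k, 2) nm
    source_step_indices: np.ndarray  # (k,) int
    source_positions: np.ndarray  # (k, 2) nm, true emitter position per photon

    def __len__(self) -> int:
        return self.photon_positions.shape[0]

    @property
    def emission_centroid(self) -> tuple[float, float]:
        """Mean true emitter position over the emitted photons.

        This is the position an unbiased fitter of the blurred image
        estimates, and serves as the "true position" of a moving molecule
        when quantifying empirical localization error.
        """
        if len(self) == 0:
            raise ValueError("no photons emitted")
        c = self.source_positions.mean(axis=0)
        return (float(c[0]), float(c[1]))


@dataclass
class PixelImage:
    """Photon counts accumulated on a square-pixel grid.

    ``origin`` is the nm position of the outer corner of pixel (0, 0);
    ``counts[iy, ix]`` covers ``origin + [ix*a, (ix+1)*a) x [iy*a, (iy+1)*a)``.
    ``overflow`` counts photons that fell outside the grid.
    """

    counts: np.ndarray  # (ny, nx)
    pixel_size: float
    origin: tuple[float, float]
    overflow: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def pixel_center(self, ix, iy) -> tuple[np.ndarray, np.ndarray]:
        """nm coordinates of the center of pixel (ix, iy)."""
        a = self.pixel_size
        return (
            self.origin[0] + (np.asarray(ix) + 0.5) * a,
            self.origin[1] + (np.asarray(iy) + 0.5) * a,
        )


def emit_photons(
    traj: Trajectory, params: ImagingParams, rng: np.random.Generator
) -> PhotonSet:
    """Emit PSF-scattered photons at evenly distributed times along a trajectory.

    The number of photons is ``Binomial(n_positions, p)`` with
    ``p = n_photons / n_positions`` capped at 1, and the emitting steps are a
    uniform random subset of the trajectory.  A fixed molecule (single-position
    trajectory) emits exactly ``n_photons`` from its one position.
    """
    n_pos = len(traj)
    if n_pos == 0:
        raise ValueError("empty trajectory")
    if n_pos == 1:
        idx = np.zeros(params.n_photons, dtype=np.intp)
    else:
        p = min(1.0, params.n_photons / n_pos)
        k = rng.binomial(n_pos, p)
        idx = np.sort(rng.choice(n_pos, size=k, replace=False))
    src = traj.positions[idx]
    d = np.abs(rng.normal(0.0, params.psf_sigma, len(idx)))
    phi = rng.uniform(0.0, 2.0 * np.pi, len(idx))
    landing = src + np.column_stack((d * np.cos(phi), d * np.sin(phi)))
    return PhotonSet(photon_positions=landing, source_step_indices=idx, source_positions=src)


def default_grid(
    traj: Trajectory, params: ImagingParams, n_pixels: int = 15
) -> tuple[tuple[int, int], tuple[float, float]]:
    """Grid shape and origin of an ``n_pixels`` square grid centred on the walk start."""
    a = params.pixel_size
    ox = traj.start[0] - n_pixels * a / 2.0
    oy = traj.start[1] - n_pixels * a / 2.0
    return (n_pixels, n_pixels), (ox, oy)


def accumulate_image(
    photons: PhotonSet,
    params: ImagingParams,
    grid_shape: tuple[int, int],
    origin: tuple[float, float],
    rng: np.random.Generator | None = None,
) -> PixelImage:
    """Bin photon landing positions into a pixel grid.

    Photons outside the grid are dropped and tallied in ``overflow`` so that
    ``counts.sum() + overflow`` equals the emitted photon count.  When the
    background sd ``b`` is positive, additive Gaussian noise (clipped at 0)
    is applied per pixel; ``rng`` is then required.
    """
    ny, nx = grid_shape
    if ny <= 0 or nx <= 0:
        raise ValueError(f"grid shape must be positive, got {grid_shape}")
    a = params.pixel_size
    pos = photons.photon_positions
    ix = np.floor((pos[:, 0] - origin[0]) / a).astype(np.intp)
    iy = np.floor((pos[:, 1] - origin[1]) / a).astype(np.intp)
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    counts = np.zeros((ny, nx))
    np.add.at(counts, (iy[inside], ix[inside]), 1.0)
    overflow = int((~inside).sum())
    if params.background > 0:
        if rng is None:
            raise ValueError("rng required when background noise is enabled")
        counts = np.clip(counts + rng.normal(0.0, params.background, counts.shape), 0.0, None)
    return PixelImage(counts=counts, pixel_size=a, origin=(float(origin[0]), float(origin[1])), overflow=overflow)


def brightest_pixel(image: PixelImage) -> float:
    """Maximum pixel count of the image (first in row-major order on ties)."""
    if image.counts.size == 0:
        raise ValueError("empty image")
    return float(image.counts.max())


def write_tiff_stack(path, images: list[PixelImage]) -> None:
    """Write images as a 16-bit grayscale TIFF stack (one frame per window)."""
    import tifffile

    stack = np.stack([np.clip(im.counts, 0, 65535).astype(np.uint16) for im in images])
    tifffile.imwrite(path, stack)


def write_photon_csv(path, photons: PhotonSet) -> None:
    """Write a photon table with columns x_nm, y_nm, step."""
    import pandas as pd

    pd.DataFrame(
        {
            "x_nm": photons.photon_positions[:, 0],
            "y_nm": photons.photon_positions[:, 1],
            "step": photons.source_step_indices,
        }
    ).to_csv(path, index=False)
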