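"""Concatenated-walk tracks across camera frames and D_eff estimation.

A track is a series of localizations of one molecule over successive frames.
Within each frame the molecule diffuses for the integration (excitation) time
``t_e`` while emitting ~``n_photons`` photons, is localized from the blurred
image, and then continues to diffuse "in the dark" for the remainder of the
frame interval; trajectories are continuous across frames.  Setting
``t_e = frame_interval`` reproduces continuous exposure; ``t_e <
frame_interval`` models pulsed excitation synchronized to the camera frame.

The effective diffusion coefficient follows the standard two-point estimator
``D_eff = <R^2> / (4 * dt)`` over consecutive detected localizations, where
``R`` is the measured jump and ``dt`` the frame interval (the time between
localized positions, not the exposure).  In bounded regions each localization
is the centroid of the path covered during the exposure; for fast molecules
and long exposures these centroids collapse toward the region center, so the
measured D_eff can *decrease* with increasing true D — the confinement
artifact this module quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import FitParams, FitResult, localize_molecule
from .imaging import ImagingParams
from .loc_error import _scatter
from .walks import Region, Trajectory, WalkParams, make_walk, sample_region_point

__all__ = ["Track", "make_track", "estimate_deff", "scatter_track", "track_table"]

#: nm^2/ms -> um^2/s
_D_OUT = 1.0 / 1000.0


@dataclass
class Track:
    """Per-frame localizations of one molecule plus ground-truth summaries.

    ``true_positions`` holds the true trajectory end position of each frame
    and ``true_centroids`` the per-frame emission centroids; full per-step
    trajectories are retained in ``true_trajectories`` only on request (they
    can run to millions of points for long exposures).
    """

    localizations: list[FitResult]
    frame_interval: float  # ms
    region: Region | None = None
    true_positions: np.ndarray | None = None  # (n_frames, 2) frame-end positions
    true_trajectories: list[Trajectory] | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.localizations)

    @property
    def detected_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of (x, y) and a boolean detected mask, aligned to frames."""
        xy = np.array([[f.x0, f.y0] for f in self.localizations])
        mask = np.array([bool(f.detected and f.converged) for f in self.localizations])
        return xy, mask


def make_track(
    D: float,
    region: Region | None,
    frame_interval: float,
    t_e: float,
    n_frames: int,
    imaging_params: ImagingParams | None = None,
    fit_params: FitParams | None = None,
    rng: np.random.Generator | None = None,
    start: tuple[float, float] | None = None,
    step_mode: str = "as-stated",
    keep_trajectories: bool = False,
    grid_pixels: int = 15,
) -> Track:
    """Simulate ``n_frames`` sequential exposures of one diffusing molecule.

    Parameters
    ----------
    D : float
        True diffusion coefficient, um^2/s.
    region : Region or None
        Confining geometry; None for free diffusion.  The start point is
        drawn uniformly over the region unless ``start`` is given.
    frame_interval : float
        Time between frames (between localized positions), ms.
    t_e : float
        Integration/excitation time within each frame, ms; must satisfy
        ``t_e <= frame_interval``.
    n_frames : int
        Number of frames; must be >= 2 for a D_eff estimate downstream.
    """
    if t_e > frame_interval:
        raise ValueError("t_e must not exceed the frame interval")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = rng if rng is not None else np.random.default_rng()
    imaging_params = imaging_params or ImagingParams()
    if start is None:
        start = sample_region_point(region, rng) if region is not None else (0.0, 0.0)
    bright = WalkParams(D=D, t=t_e, step_mode=step_mode)
    dark = WalkParams(D=D, t=frame_interval - t_e, step_mode=step_mode)
    pos = start
    locs: list[FitResult] = []
    ends = np.empty((n_frames, 2))
    trajs: list[Trajectory] | None = [] if keep_trajectories else None
    for i in range(n_frames):
        traj = make_walk(bright, pos, region, rng)
        locs.append(
            localize_molecule(traj, imaging_params, fit_params, rng, grid_pixels=grid_pixels)
        )
        pos = traj.end
        if dark.n_steps > 0:
            pos = make_walk(dark, pos, region, rng).end
        ends[i] = pos
        if trajs is not None:
            trajs.append(traj)
    return Track(
        localizations=locs,
        frame_interval=frame_interval,
        region=region,
        true_positions=ends,
        true_trajectories=trajs,
        meta={"D": D, "t_e": t_e, "n_frames": n_frames, "start": start},
    )


def scatter_track(
    center: tuple[float, float],
    sigma_loc: float,
    n_frames: int,
    frame_interval: float,
    rng: np.random.Generator,
) -> Track:
    """Track of a fixed molecule whose localizations follow the scatter model.

    This is the zero-motion limit with an exactly known localization law
    (half-normal radial, scale ``sigma_loc``), bypassing image formation and
    fitting.  It is the analytic reference for D_eff of an immobile molecule:
    E[R^2] = 2*sigma_loc^2, hence D_eff -> sigma_loc^2 / (2*dt).
    """
    pts = _scatter(center, sigma_loc, n_frames, rng)
    locs = [
        FitResult(
            x0=float(x), y0=float(y), sx=np.nan, sy=np.nan, amplitude=np.nan,
            offset=0.0, n_fit=1.0, precision=sigma_loc, converged=True,
        )
        for x, y in pts
    ]
    return Track(
        localizations=locs,
        frame_interval=frame_interval,
        true_positions=np.tile(center, (n_frames, 1)),
        meta={"D": 0.0, "sigma_loc": sigma_loc},
    )


def estimate_deff(track: Track, estimator: str = "msd") -> float:
    """Effective diffusion coefficient (um^2/s) from consecutive localizations.

    ``estimator="msd"`` (default) evaluates ``<R^2> / (4*dt)``, the standard
    mean-squared-jump form of D = R^2/4t.  ``estimator="mean-distance"``
    evaluates ``<R>^2 / (4*dt)`` instead, reading "mean distance" literally.
    Only jumps between *consecutive* detected frames contribute; frames with
    failed detection leave gaps.
    """
    if track.frame_interval <= 0:
        raise ValueError("frame interval must be > 0")
    xy, mask = track.detected_xy
    if mask.sum() < 2:
        raise ValueError("need at least two detected localizations")
    both = mask[:-1] & mask[1:]
    if not both.any():
        raise ValueError("no consecutive pair of detected localizations")
    jumps = xy[1:][both] - xy[:-1][both]
    r2 = (jumps**2).sum(axis=1)
    if estimator == "msd":
        msd = float(r2.mean())
    elif estimator == "mean-distance":
        msd = float(np.sqrt(r2).mean()) ** 2
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return msd / (4.0 * track.frame_interval) * _D_OUT


def track_table(track: Track):
    """Tabulate a track as a DataFrame with per-frame jump distances."""
    import pandas as pd

    xy, mask = track.detected_xy
    jump = np.full(len(track), np.nan)
    both = mask[:-1] & mask[1:]
    d = np.hypot(*(xy[1:] - xy[:-1]).T)
    jump[1:][both] = d[both]
    return pd.DataFrame(
        {
            "frame": np.arange(len(track)),
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "detected": mask,
            "jump_nm": jump,
        }
    )
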