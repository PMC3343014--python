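"""Per-step random walks, free or confined to bounded 2D regions.

Diffusion with coefficient ``D`` over an integration time ``t`` is discretised
into ``N_steps = round(4*D*t / r**2)`` steps of mean size ``r`` (1 nm by
default), so that even a few-millisecond camera exposure resolves the path of
the molecule at nanometre granularity.  Units: ``D`` in um^2/s, ``t`` in ms,
lengths in nm (1 um^2/s = 1000 nm^2/ms).

Two step conventions are provided:

``as-stated`` (default)
    Each step displaces x and y independently by ``Uniform(-sqrt(2)*r,
    +sqrt(2)*r)``.  The per-axis step variance is then ``2*r**2/3`` and the
    mean squared displacement after ``N_steps`` steps is ``(4/3)*4*D*t`` —
    a 33% overshoot of the nominal diffusion law.  This convention is kept as
    the default because it is the generator whose artifacts this package
    reproduces and studies.

``calibrated``
    The uniform bound is scaled by ``sqrt(3)/2`` so ``E[dx^2 + dy^2] = r**2``
    exactly and the free-walk MSD recovers ``4*D*t``.

Confinement follows a rejection rule: a step that would leave the region is
redrawn in full until the new position is inside (no reflection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import confined_walk

__all__ = [
    "WalkParams",
    "Trajectory",
    "Region",
    "Rectangle",
    "SpineRegion",
    "n_steps",
    "make_walk",
    "sample_region_point",
]

#: nm^2/ms per um^2/s
_D_UNIT = 1000.0
#: proposals per step before a confined walk gives up
_MAX_RETRY = 10_000


def _step_bound(r: float, step_mode: str) -> float:
    """Half-width of the per-axis uniform step distribution."""
    if step_mode == "as-stated":
        return np.sqrt(2.0) * r
    if step_mode == "calibrated":
        return np.sqrt(2.0) * r * (np.sqrt(3.0) / 2.0)  # = sqrt(3/2) * r
    raise ValueError(f"unknown step_mode {step_mode!r}")


@dataclass(frozen=True)
class WalkParams:
    """Diffusion and discretisation parameters of one random walk.

    Parameters
    ----------
    D : float
        Diffusion coefficient in um^2/s (converted internally to nm^2/ms).
    t : float
        Integration time in ms; ``t = 0`` means a fixed molecule.
    r : float
        Mean step size in nm (default 1).
    step_mode : {"as-stated", "calibrated"}
        Step-size convention, see module docstring.
    """

    D: float
    t: float
    r: float = 1.0
    step_mode: str = "as-stated"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.D) and np.isfinite(self.t) and np.isfinite(self.r)):
            raise ValueError("walk parameters must be finite")
        if self.D < 0 or self.t < 0:
            raise ValueError("D and t must be >= 0")
        if self.r <= 0:
            raise ValueError(f"step size r must be > 0, got {self.r}")
        _step_bound(self.r, self.step_mode)  # validates step_mode

    @property
    def n_steps(self) -> int:
        return n_steps(self.D, self.t, self.r)


class Region:
    """Bounded 2D geometry expressed as a union of axis-aligned rectangles.

    Subclasses set ``_rects``, an ``(n, 4)`` float array of
    ``(xmin, xmax, ymin, ymax)`` in nm.  Containment is inclusive of bounds
    and consistent with uniform sampling: every sampled point passes
    ``contains``.
    """

    kind: str = "region"
    _rects: np.ndarray

    @property
    def rects(self) -> np.ndarray:
        return self._rects

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """Bounding box (xmin, xmax, ymin, ymax) in nm."""
        r = self._rects
        return (
            float(r[:, 0].min()),
            float(r[:, 1].max()),
            float(r[:, 2].min()),
            float(r[:, 3].max()),
        )

    @property
    def area(self) -> float:
        r = self._rects
        return float(((r[:, 1] - r[:, 0]) * (r[:, 3] - r[:, 2])).sum())

    def contains(self, x, y) -> np.ndarray | bool:
        x = np.asarray(x)
        y = np.asarray(y)
        r = self._rects
        inside = np.zeros(np.broadcast(x, y).shape, dtype=bool)
        for k in range(r.shape[0]):
            inside |= (r[k, 0] <= x) & (x <= r[k, 1]) & (r[k, 2] <= y) & (y <= r[k, 3])
        return inside if inside.shape else bool(inside)

    @property
    def center(self) -> tuple[float, float]:
        xmin, xmax, ymin, ymax = self.bounds
        return ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)


class Rectangle(Region):
    """Axis-aligned rectangle of ``width`` (x) by ``length`` (y) nm.

    The origin sits at the lower-left corner, so the transverse coordinate of
    a filopodium-like strip of width ``w`` runs over ``[0, w]``.
    """

    kind = "rectangle"

    def __init__(self, width: float, length: float):
        if width <= 0 or length <= 0:
            raise ValueError(f"degenerate rectangle {width} x {length}")
        self.width = float(width)
        self.length = float(length)
        self._rects = np.array([[0.0, width, 0.0, length]])

    def __repr__(self) -> str:
        return f"Rectangle(width={self.width}, length={self.length})"


class SpineRegion(Region):
    """Dendritic-spine-shaped composite: head, neck and dendrite rectangles.

    Default geometry: a 500 x 500 nm spine head connected by a neck 100 nm
    wide and 1000 nm long to a dendrite 500 nm wide and 1500 nm long.  The
    dendrite lies horizontally at the bottom; the neck rises from the
    dendrite midline to the head midline, so the union is connected.
    """

    kind = "spine"

    def __init__(
        self,
        head: float = 500.0,
        neck_width: float = 100.0,
        neck_length: float = 1000.0,
        dendrite_width: float = 500.0,
        dendrite_length: float = 1500.0,
    ):
        if min(head, neck_width, neck_length, dendrite_width, dendrite_length) <= 0:
            raise ValueError("spine dimensions must be positive")
        self.head = float(head)
        self.neck_width = float(neck_width)
        self.neck_length = float(neck_length)
        self.dendrite_width = float(dendrite_width)
        self.dendrite_length = float(dendrite_length)
        cx = dendrite_length / 2.0
        y0 = dendrite_width  # top of the dendrite
        self._rects = np.array(
            [
                [0.0, dendrite_length, 0.0, dendrite_width],
                [cx - neck_width / 2.0, cx + neck_width / 2.0, y0, y0 + neck_length],
                [cx - head / 2.0, cx + head / 2.0, y0 + neck_length, y0 + neck_length + head],
            ]
        )

    @property
    def head_rect(self) -> np.ndarray:
        return self._rects[2]

    @property
    def neck_rect(self) -> np.ndarray:
        return self._rects[1]

    def __repr__(self) -> str:
        return (
            f"SpineRegion(head={self.head}, neck={self.neck_width}x{self.neck_length}, "
            f"dendrite={self.dendrite_width}x{self.dendrite_length})"
        )


@dataclass
class Trajectory:
    """Ordered true positions of one molecule during one integration window."""

    positions: np.ndarray  # (n_steps + 1, 2) nm
    start: tuple[float, float]
    region: Region | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def end(self) -> tuple[float, float]:
        return (float(self.positions[-1, 0]), float(self.positions[-1, 1]))


def n_steps(D: float, t: float, r: float = 1.0) -> int:
    """Number of random-walk steps for diffusion D over integration time t.

    Evaluates ``round(4*D*t / r**2)`` with D in um^2/s, t in ms, r in nm
    (round-half-to-even).  D = 1 um^2/s for 10 ms at r = 1 nm gives 40,000.
    """
    if r <= 0:
        raise ValueError(f"step size r must be > 0, got {r}")
    if D < 0 or t < 0:
        raise ValueError("D and t must be >= 0")
    return int(np.rint(4.0 * (D * _D_UNIT) * t / r**2))


def make_walk(
    params: WalkParams,
    start: tuple[float, float],
    region: Region | None,
    rng: np.random.Generator,
) -> Trajectory:
    """Generate one random-walk trajectory, optionally confined to ``region``.

    Free walks are vectorised; confined walks run a jitted per-step loop that
    redraws any step landing outside the region.  The trajectory includes the
    start, so it holds ``N_steps + 1`` positions.
    """
    x0, y0 = float(start[0]), float(start[1])
    if region is not None and not region.contains(x0, y0):
        raise ValueError(f"start {start} is outside the region")
    n = params.n_steps
    bound = _step_bound(params.r, params.step_mode)
    if n == 0 or bound == 0.0:
        pos = np.tile([x0, y0], (n + 1, 1))
        return Trajectory(positions=pos, start=(x0, y0), region=region)
    if region is None:
        steps = rng.uniform(-bound, bound, size=(n, 2))
        pos = np.empty((n + 1, 2))
        pos[0] = (x0, y0)
        np.cumsum(steps, axis=0, out=pos[1:])
        pos[1:] += (x0, y0)
    else:
        seed = int(rng.integers(0, 2**31 - 1))
        pos = confined_walk(x0, y0, n, bound, region.rects, seed, _MAX_RETRY)
    return Trajectory(positions=pos, start=(x0, y0), region=region)


def sample_region_point(region: Region, rng: np.random.Generator) -> tuple[float, float]:
    """Draw a point uniformly over the region area.

    Uses rejection sampling from the bounding box, which remains uniform for
    any rectangle union (overlaps included).
    """
    if region.area <= 0:
        raise ValueError("cannot sample from a zero-area region")
    xmin, xmax, ymin, ymax = region.bounds
    for _ in range(_MAX_RETRY):
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        if region.contains(x, y):
            return (float(x), float(y))
    raise RuntimeError("region sampling: retry limit exhausted")
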