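"""Numba kernels for per-step confined random walks.

Confined walks resample each boundary-crossing step until it lands inside the
region, which makes the loop inherently sequential; these kernels keep it fast
for the hundreds of thousands of 1-nm steps a single camera exposure implies.

Regions are passed as an ``(n_rect, 4)`` array of axis-aligned rectangles
``(xmin, xmax, ymin, ymax)``; a point is inside the region if it is inside any
rectangle (bounds inclusive).  Reproducibility uses numba's legacy-seeded
``np.random`` inside the jitted function; callers derive the integer seed from
an injected Generator.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def confined_walk(
    start_x: float,
    start_y: float,
    n_steps: int,
    bound: float,
    rects: np.ndarray,
    seed: int,
    max_retry: int,
) -> np.ndarray:
    """Random walk of ``n_steps`` uniform steps confined to a rectangle union.

    Each proposed step adds (dx, dy) with dx, dy ~ Uniform(-bound, +bound);
    a step that would exit the region is recalculated until the new position
    is inside.  Raises if ``max_retry`` proposals are exhausted for one step.
    """
    np.random.seed(seed)
    out = np.empty((n_steps + 1, 2))
    out[0, 0] = start_x
    out[0, 1] = start_y
    x = start_x
    y = start_y
    n_rect = rects.shape[0]
    for i in range(n_steps):
        retries = 0
        while True:
            nx = x + np.random.uniform(-bound, bound)
            ny = y + np.random.uniform(-bound, bound)
            inside = False
            # unchained comparisons: numba compiles these to straight branches
            for k in range(n_rect):
                if (
                    nx >= rects[k, 0]
                    and nx <= rects[k, 1]
                    and ny >= rects[k, 2]
                    and ny <= rects[k, 3]
                ):
                    inside = True
                    break
            if inside:
                break
            retries += 1
            if retries >= max_retry:
                raise RuntimeError("confined walk: step retry limit exhausted")
        x = nx
        y = ny
        out[i + 1, 0] = x
        out[i + 1, 1] = y
    return out
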