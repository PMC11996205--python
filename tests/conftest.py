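"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from hypothesis import settings

from fractaldim.boxcount import BoxGrid, _snap

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def oracle_box_count(points, grid: BoxGrid) -> int:
    """Brute-force exact box count via segment-rectangle intersection.

    Independent of the crossing-point construction: every candidate box in
    each segment's bounding neighborhood is clipped against the segment
    (Liang-Barsky); a box is counted when the clipped portion contains a
    point whose half-open floor index is that box.
    """
    pts = np.asarray(points, dtype=float)
    u = _snap(grid.to_grid_frame(pts))
    boxes = set()
    for a, b in zip(u[:-1], u[1:]):
        lo = np.floor(np.minimum(a, b)).astype(int) - 1
        hi = np.floor(np.maximum(a, b)).astype(int) + 1
        for m in range(lo[0], hi[0] + 1):
            for k in range(lo[1], hi[1] + 1):
                t0, t1 = 0.0, 1.0
                ok = True
                for dim, mm in enumerate((m, k)):
                    d = b[dim] - a[dim]
                    if d == 0:
                        if not mm <= a[dim] <= mm + 1:
                            ok = False
                            break
                    else:
                        ta, tb = (mm - a[dim]) / d, (mm + 1 - a[dim]) / d
                        if ta > tb:
                            ta, tb = tb, ta
                        t0, t1 = max(t0, ta), min(t1, tb)
                        if t0 > t1:
                            ok = False
                            break
                if not ok:
                    continue
                p = _snap(a + 0.5 * (t0 + t1) * (b - a))
                if np.floor(p[0]) == m and np.floor(p[1]) == k:
                    boxes.add((m, k))
    return len(boxes)


def oracle_avg_step(points, delta: int, offset: int = 1):
    """Index-list oracle for the mean lag distance (1-based indexing)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    m = (n - offset) // delta
    dists = [
        np.linalg.norm(pts[i * delta + offset - 1] - pts[(i - 1) * delta + offset - 1])
        for i in range(1, m + 1)
    ]
    return float(np.mean(dists)), m


@pytest.fixture(scope="session")
def koch3():
    from fractaldim import generate_koch

    return generate_koch(3)


@pytest.fixture(scope="session")
def koch6():
    from fractaldim import generate_koch

    return generate_koch(6)
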