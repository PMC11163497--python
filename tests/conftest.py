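"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library calls the implementation
uses: point-in-polygon is a hand-rolled ray-casting (crossing-number)
test, and boundary distances are computed with an explicit all-pairs
point-to-segment formula.
"""

import numpy as np
import pytest

from segqa.geometry import ContourSlice, ContourStack


# ------------------------------------------------------------------- builders

def square(cx: float, cy: float, half: float) -> np.ndarray:
    """Axis-aligned square polygon centred at (cx, cy), edge 2*half."""
    return np.array(
        [
            [cx - half, cy - half],
            [cx + half, cy - half],
            [cx + half, cy + half],
            [cx - half, cy + half],
        ]
    )


def stack_of(polygons_by_z, organ="fixture") -> ContourStack:
    """Build a ContourStack from {z: [poly, ...]}."""
    slices = tuple(
        ContourSlice(z=z, polygons=tuple(polys))
        for z, polys in sorted(polygons_by_z.items())
    )
    return ContourStack(organ_name=organ, slices=slices)


def random_star_polygon(rng, n_vertices=16, r_mean=8.0, r_jitter=3.0, center=(0.0, 0.0)):
    """Random star-shaped (hence simple) polygon around ``center``."""
    theta = 2 * np.pi * np.arange(n_vertices) / n_vertices
    theta = theta + rng.uniform(0, 2 * np.pi / n_vertices)
    r = r_mean + rng.uniform(-r_jitter, r_jitter, size=n_vertices)
    return np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
    )


# -------------------------------------------------------------------- oracles

def raycast_inside(polygon: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Crossing-number point-in-polygon oracle (strict interior rule).

    ``points`` is (m, 2); returns a boolean array.  Points exactly on an
    edge are resolved by the half-open crossing convention — callers use
    points away from edges.
    """
    x = points[:, 0][:, None]
    y = points[:, 1][:, None]
    x1, y1 = polygon[:, 0], polygon[:, 1]
    x2, y2 = np.roll(polygon[:, 0], -1), np.roll(polygon[:, 1], -1)
    crosses = (y1 > y) != (y2 > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_at_y = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
    hits = crosses & (x < x_at_y)
    return (hits.sum(axis=1) % 2).astype(bool)


def evenodd_inside(polygons, points: np.ndarray) -> np.ndarray:
    """Even-odd membership across several polygons (XOR of ray casts)."""
    inside = np.zeros(len(points), dtype=bool)
    for poly in polygons:
        inside ^= raycast_inside(poly, points)
    return inside


def point_segment_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to each segment [a_i, b_i]; (m, s) array."""
    ab = b - a
    ap = points[:, None, :] - a[None, :, :]
    denom = (ab**2).sum(axis=1)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / denom, 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    return np.hypot(*(points[:, None, :] - closest).transpose(2, 0, 1))


def _segments(polygons):
    a = np.vstack([p for p in polygons])
    starts, ends = [], []
    for p in polygons:
        starts.append(p)
        ends.append(np.roll(p, -1, axis=0))
    return np.vstack(starts), np.vstack(ends)


def brute_force_pooled_distances(gold_stack, auto_stack, step):
    """All-pairs directed boundary distances pooled over shared slices.

    Uses the package's resampling (the sampling convention under test is
    the distance computation, not the sampling) but explicit
    point-to-segment arithmetic for the distances.  Slices are matched on
    exact z equality, which the fixtures guarantee.
    """
    from segqa.metrics import resample_boundary

    gz = {s.z: s for s in gold_stack.slices}
    az = {s.z: s for s in auto_stack.slices}
    pooled = []
    for z in sorted(set(gz) & set(az)):
        gpolys, apolys = gz[z].polygons, az[z].polygons
        gpts = resample_boundary(gpolys, step)
        apts = resample_boundary(apolys, step)
        sa, sb = _segments(apolys)
        pooled.append(point_segment_distances(gpts, sa, sb).min(axis=1))
        sa, sb = _segments(gpolys)
        pooled.append(point_segment_distances(apts, sa, sb).min(axis=1))
    return np.concatenate(pooled) if pooled else np.array([])


def shoelace_area(polygon: np.ndarray) -> float:
    x, y = polygon[:, 0], polygon[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# ------------------------------------------------------------------- fixtures

@pytest.fixture
def rng():
    return np.random.default_rng(20240123)


@pytest.fixture
def cylinder20():
    """Uniform-cross-section cylinder, radius 10 mm, 20 slices of 2 mm."""
    from segqa.synthetic import PhantomSpec, make_phantom

    spec = PhantomSpec("cylinder", radii=(10.0,), n_slices=20)
    return make_phantom(spec, seed=11, organ_name="cylinder")
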