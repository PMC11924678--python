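"""Muscle-fiber morphometry: minimum Feret diameter, area filtering, size
binning, and MHC fiber-type composition.

Fiber cross-sections arrive as simple polygons (e.g. boundaries exported from
a segmentation tool). The minimum Feret diameter — the smallest caliper width
over all orientations — is computed exactly on the convex hull: the minimum
width of a convex polygon is always attained with one caliper jaw flush to a
hull edge, so enumerating edge normals suffices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon

__all__ = [
    "MHC_TYPES",
    "FiberShape",
    "SizeDistribution",
    "FiberTypeComposition",
    "min_feret",
    "filter_by_area",
    "bin_by_feret",
    "type_composition",
    "generate_fibers",
    "fibers_to_frame",
    "read_fibers",
    "write_fibers",
]

MHC_TYPES = ("I", "IIa", "IIx", "IIb")


@dataclass
class FiberShape:
    """A fiber cross-section polygon with an optional MHC type label."""

    vertices: np.ndarray  # (n, 2)
    label: str | None = None
    fiber_id: str = ""
    sample_id: str = ""
    target_feret: float | None = None  # generator truth, synthetic fibers only

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("vertices must be an (n>=3, 2) array")
        poly = Polygon(self.vertices)
        if not poly.is_simple:
            raise ValueError("polygon must be simple (non-self-intersecting)")
        if poly.area <= 0:
            raise ValueError("polygon area must be positive")
        if self.label is not None and self.label not in MHC_TYPES:
            raise ValueError(f"unknown MHC type {self.label!r}")

    @property
    def area(self) -> float:
        return float(Polygon(self.vertices).area)

    @property
    def min_feret(self) -> float:
        return min_feret(self.vertices)


@dataclass(frozen=True)
class SizeDistribution:
    """Min-Feret histogram with half-open bins [e_i, e_{i+1})."""

    edges: tuple[float, ...]
    counts: tuple[int, ...]
    overflow: int  # fibers outside [edges[0], edges[-1])

    @property
    def total(self) -> int:
        return sum(self.counts) + self.overflow

    def percentages(self) -> tuple[float, ...]:
        retained = sum(self.counts)
        if retained == 0:
            return tuple(0.0 for _ in self.counts)
        return tuple(100.0 * c / retained for c in self.counts)


@dataclass(frozen=True)
class FiberTypeComposition:
    """Percent of typed fibers per MHC class; sums to exactly 100."""

    percent: dict[str, float]
    n_typed: int
    n_unlabeled: int

    def __post_init__(self) -> None:
        total = sum(self.percent.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"composition sums to {total}, not 100")


def min_feret(vertices) -> float:
    """Exact minimum caliper width of a polygon via hull edge normals.

    For each convex-hull edge, the width is the maximum distance of any hull
    vertex from the edge's supporting line; the minimum Feret diameter is the
    smallest such width. Degenerate (collinear) input is rejected.
    """
    pts = np.asarray(vertices, dtype=float)
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull raises on degenerate input
        raise ValueError("degenerate polygon (zero area)") from exc
    hp = pts[hull.vertices]  # counter-clockwise hull points
    edges = np.roll(hp, -1, axis=0) - hp
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    normals = np.column_stack([-edges[:, 1], edges[:, 0]]) / lengths[:, None]
    # distance of every hull point from every edge line; width per edge is max
    offsets = hp @ normals.T  # (n_points, n_edges) projections onto normals
    widths = offsets.max(axis=0) - offsets.min(axis=0)
    return float(widths.min())


def filter_by_area(fibers: list[FiberShape], min_area: float = 300.0) -> list[FiberShape]:
    """Discard fibers with area below ``min_area`` (boundary kept).

    The default of 300 (measurement units²) removes segmentation artifacts;
    idempotent. Warns when nothing survives.
    """
    kept = [f for f in fibers if f.area >= min_area]
    if fibers and not kept:
        warnings.warn("all fibers removed by the area filter", stacklevel=2)
    return kept


def bin_by_feret(fibers: list[FiberShape], edges) -> SizeDistribution:
    """Bin fibers by minimum Feret diameter into half-open bins.

    Fibers outside ``[edges[0], edges[-1])`` land in the reported overflow
    count, so fiber number is conserved: sum(counts) + overflow == n fibers.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 entries")
    ferets = np.array([f.min_feret for f in fibers])
    if ferets.size == 0:
        return SizeDistribution(tuple(edges), tuple(0 for _ in edges[:-1]), 0)
    inside = (ferets >= edges[0]) & (ferets < edges[-1])
    counts, _ = np.histogram(ferets[inside], bins=edges)
    return SizeDistribution(tuple(edges), tuple(int(c) for c in counts), int((~inside).sum()))


def type_composition(labels) -> FiberTypeComposition:
    """Fiber-type percentages over labeled fibers.

    Unlabeled fibers (``None`` or empty) are excluded from the denominator and
    reported separately. The last type's percentage is computed as the
    remainder so the total is exactly 100.
    """
    labels = list(labels)
    typed = [l for l in labels if l]
    n_unlabeled = len(labels) - len(typed)
    if not typed:
        raise ValueError("no typed fibers after excluding unlabeled")
    unknown = set(typed) - set(MHC_TYPES)
    if unknown:
        raise ValueError(f"unknown MHC types: {sorted(unknown)}")
    percent: dict[str, float] = {}
    for t in MHC_TYPES[:-1]:
        percent[t] = 100.0 * typed.count(t) / len(typed)
    percent[MHC_TYPES[-1]] = 100.0 - sum(percent.values())
    return FiberTypeComposition(percent=percent, n_typed=len(typed), n_unlabeled=n_unlabeled)


def generate_fibers(
    n: int,
    feret_mean: float = 40.0,
    feret_sd: float = 8.0,
    type_probs=(0.0, 0.12, 0.24, 0.64),
    seed: int | None = None,
    sample_id: str = "sim",
    jitter: float = 0.005,
) -> list[FiberShape]:
    """Simulate fiber cross-sections with known minimum Feret diameters.

    Each fiber is a regular polygon with an even number of sides (6–12),
    radius set so its across-flats width equals a Normal(feret_mean,
    feret_sd) draw (truncated at 20% of the mean), randomly rotated and
    translated, with ±``jitter`` relative radial perturbation — small enough
    that the realized min Feret stays within ~2% of the target. MHC labels
    are multinomial over (I, IIa, IIx, IIb) with ``type_probs``. Default type
    probabilities follow the wild-type TA composition (~64% IIb, ~23% IIx,
    ~12% IIa, ~0–1% I).
    """
    type_probs = np.asarray(type_probs, dtype=float)
    if type_probs.size != 4 or np.any(type_probs < 0) or abs(type_probs.sum() - 1.0) > 1e-9:
        raise ValueError("type_probs must be 4 non-negative values summing to 1")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    fibers = []
    for i in range(n):
        target = max(rng.normal(feret_mean, feret_sd), 0.2 * feret_mean)
        n_sides = int(rng.choice([6, 8, 10, 12]))
        radius = target / (2.0 * np.cos(np.pi / n_sides))
        theta = (
            2 * np.pi * np.arange(n_sides) / n_sides + rng.uniform(0, 2 * np.pi)
        )
        radii = radius * (1.0 + rng.uniform(-jitter, jitter, size=n_sides))
        center = rng.uniform(0, 50 * feret_mean, size=2)
        verts = center + np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
        label = MHC_TYPES[int(rng.choice(4, p=type_probs))]
        fibers.append(
            FiberShape(
                vertices=verts,
                label=label,
                fiber_id=f"{sample_id}_f{i:04d}",
                sample_id=sample_id,
                target_feret=float(target),
            )
        )
    return fibers


def fibers_to_frame(fibers: list[FiberShape]) -> pd.DataFrame:
    """Long-format vertex table: fiber_id, sample_id, vertex_index, x, y, label."""
    rows = []
    for f in fibers:
        for i, (x, y) in enumerate(f.vertices):
            rows.append((f.fiber_id, f.sample_id, i, x, y, f.label or ""))
    return pd.DataFrame(
        rows, columns=["fiber_id", "sample_id", "vertex_index", "x", "y", "label"]
    )


def write_fibers(fibers: list[FiberShape], path: str | Path) -> None:
    fibers_to_frame(fibers).to_csv(path, index=False)


def read_fibers(path: str | Path) -> list[FiberShape]:
    df = pd.read_csv(path, keep_default_na=False)
    fibers = []
    for (fiber_id, sample_id), group in df.groupby(["fiber_id", "sample_id"], sort=False):
        group = group.sort_values("vertex_index")
        label = str(group["label"].iloc[0]) or None
        fibers.append(
            FiberShape(
                vertices=group[["x", "y"]].to_numpy(),
                label=label,
                fiber_id=str(fiber_id),
                sample_id=str(sample_id),
            )
        )
    return fibers
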