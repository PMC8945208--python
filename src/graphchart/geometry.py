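"""Graph chart diagrams as planar shapes; the trajectory-area abnormality score.

A diagram is the ordered 2D trajectory of encoded kernel slices.  To score
it, the polyline through its points is buffered by a small radius ``r``,
giving a capsule-union region whose area measures how much of the normal
latent itinerary the sweep covered.  Abnormal sweeps miss parts of the
itinerary (their substructure patterns are absent), so their area shrinks.

The abnormality score normalises the area against the largest-area diagram
``G_max`` of the evaluated collection::

    score(G) = 1 - area(G) / area(G_max)

which is 0 for the maximum-area diagram and 1 for a zero-area one.  The
shape construction is traversal-order invariant and idempotent under
revisits, which is what makes the score robust to probe back-and-forth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point

from .model import PROXY_TARGETS, GraphChartEncoder, LatentPoint
from .timeline import BarcodeTimeline, slice_kernels

__all__ = [
    "GraphChartDiagram",
    "AbnormalityScore",
    "diagram_from_timeline",
    "trajectory_shape",
    "shape_area",
    "abnormality_score",
    "reference_area",
    "assign_plane_markers",
]

#: Buffer radius (latent units) used to thicken trajectories into regions.
DEFAULT_BUFFER_RADIUS = 0.05


@dataclass
class GraphChartDiagram:
    """Ordered 2D latent trajectory of one timeline at one level."""

    points: np.ndarray  # (n, 2)
    kernel_starts: np.ndarray  # (n,)
    level: str = "main"  # main | sub_vessels | sub_heart
    video_id: str = ""
    plane_markers: list[str] | None = None  # per point: FOUR_CV/THREE_VTV/none

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ValueError("diagram needs an (n, 2) point array with n >= 1")
        ks = np.asarray(self.kernel_starts)
        if np.any(np.diff(ks) < 0):
            raise ValueError("points must be ordered by kernel start")
        if not np.isfinite(pts).all():
            raise ValueError("non-finite latent coordinates")
        self.points = pts
        self.kernel_starts = ks

    @property
    def latent_points(self) -> list[LatentPoint]:
        return [
            LatentPoint(main=(float(x), float(y)), kernel_start=int(k))
            for (x, y), k in zip(self.points, self.kernel_starts)
        ]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "kernel_start": self.kernel_starts,
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "level": self.level,
                "plane_marker": self.plane_markers or ["none"] * len(self.points),
            }
        )


@dataclass(frozen=True)
class AbnormalityScore:
    """Area-deficit score of one diagram against the collection maximum."""

    score: float
    area: float
    area_max: float


def diagram_from_timeline(
    encoder: GraphChartEncoder,
    tl: BarcodeTimeline,
    width: int | None = None,
    stride: int | None = None,
) -> dict[str, GraphChartDiagram]:
    """Encode every kernel slice of a timeline into diagram(s).

    Returns ``{"main": ...}`` plus ``sub_vessels`` / ``sub_heart`` entries
    for cascade encoders; one point per slice, in slice order.
    """
    width = width or encoder.kernel_width
    stride = stride or encoder.kernel_stride
    slices = slice_kernels(tl, width, stride)  # raises if width > T
    X = np.stack([s.flatten() for s in slices])
    starts = np.array([s.start_frame for s in slices])
    z = encoder.encode(X)
    return {
        level: GraphChartDiagram(
            points=z[level], kernel_starts=starts, level=level, video_id=tl.video_id
        )
        for level in z
    }


def _as_points(diagram) -> np.ndarray:
    if isinstance(diagram, GraphChartDiagram):
        return diagram.points
    return np.atleast_2d(np.asarray(diagram, dtype=np.float64))


def trajectory_shape(diagram, buffer_radius: float = DEFAULT_BUFFER_RADIUS):
    """Planar region swept by the trajectory: polyline buffered by ``r``.

    Consecutive points are joined by segments; buffering with round caps
    yields the union of capsules plus disks at the points, so coincident or
    revisited points add nothing (union idempotence).
    """
    if buffer_radius <= 0:
        raise ValueError("buffer radius must be > 0")
    pts = _as_points(diagram)
    if len(pts) == 1 or np.allclose(pts, pts[0]):
        return Point(pts[0]).buffer(buffer_radius, quad_segs=32)
    return LineString(pts).buffer(buffer_radius, quad_segs=32)


def shape_area(diagram, buffer_radius: float = DEFAULT_BUFFER_RADIUS) -> float:
    """Area of the buffered-trajectory region (latent units squared)."""
    return float(trajectory_shape(diagram, buffer_radius).area)


def abnormality_score(area: float, area_max: float) -> AbnormalityScore:
    """Normalised area deficit: ``1 - area / area_max`` clipped to [0, 1].

    The clip only engages for diagrams outside the collection that defined
    ``area_max`` (frozen-reference scoring); within it, areas never exceed
    the maximum.
    """
    if area_max <= 0:
        raise ValueError("area_max must be > 0")
    if area < 0:
        raise ValueError("area must be >= 0")
    score = 1.0 - area / area_max
    return AbnormalityScore(
        score=float(min(max(score, 0.0), 1.0)), area=float(area), area_max=float(area_max)
    )


def reference_area(
    diagrams, buffer_radius: float = DEFAULT_BUFFER_RADIUS
) -> float:
    """Largest shape area over a diagram collection (the ``G_max`` area)."""
    areas = [shape_area(d, buffer_radius) for d in diagrams]
    if not areas:
        raise ValueError("empty diagram collection")
    return float(max(areas))


def assign_plane_markers(
    diagram: GraphChartDiagram, threshold: float = 0.15
) -> GraphChartDiagram:
    """Tag points lying within ``threshold`` of a proxy anchor as 4CV/3VTV.

    Visualization-only heuristic (real frames carry no plane annotations):
    latent proximity to the anchors stands in for plane identity.  Ties go
    to the nearer anchor.
    """
    markers = []
    anchors = {p: np.array(t) for p, t in PROXY_TARGETS.items()}
    for pt in diagram.points:
        dists = {p: float(np.linalg.norm(pt - a)) for p, a in anchors.items()}
        best = min(dists, key=dists.get)
        markers.append(best if dists[best] <= threshold else "none")
    diagram.plane_markers = markers
    return diagram
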