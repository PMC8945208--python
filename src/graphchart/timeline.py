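"""Barcode-like timelines: data model, CSV I/O, kernel slicing, ideal planes.

A barcode-like timeline is the binary table (frames x 18 substructure
channels) recording, for each frame of a sweep video, which substructures a
detector found.  Timelines are stored as UTF-8 CSV with a ``frame`` column
plus one column per channel, alongside a JSON sidecar carrying video/case
identifiers and the normal/abnormal label.

A *kernel* of width ``w`` slides along the time axis with stride ``s``; each
window is flattened row-major (frame-major) into a ``w * 18`` vector that the
cascade encoder consumes.  ``synthesize_ideal_slice`` builds the stationary
ideal 4CV / 3VTV blocks used as view proxies during training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import SubstructureRegistry, default_registry

__all__ = [
    "BarcodeTimeline",
    "KernelSlice",
    "IdealPlaneSlice",
    "TimelineFormatError",
    "load_timeline",
    "save_timeline",
    "slice_kernels",
    "slice_matrix",
    "synthesize_ideal_slice",
]


class TimelineFormatError(ValueError):
    """Raised when a timeline file does not match the expected schema."""


@dataclass
class BarcodeTimeline:
    """One video's frames x channels binary detection matrix plus metadata."""

    frames: np.ndarray
    video_id: str = ""
    case_id: str = ""
    label: str = "normal"
    disease_tag: str | None = None
    registry: SubstructureRegistry = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames)
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValueError("frames must be a T x C matrix with T >= 1")
        if arr.shape[1] != self.registry.n_channels:
            raise ValueError(
                f"expected {self.registry.n_channels} channels, got {arr.shape[1]}"
            )
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("timeline entries must be binary")
        if self.label not in ("normal", "abnormal"):
            raise ValueError(f"label must be normal/abnormal, got {self.label!r}")
        self.frames = arr.astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def copy(self, **changes) -> "BarcodeTimeline":
        tl = replace(self, **changes)
        tl.frames = tl.frames.copy()
        return tl


@dataclass(frozen=True)
class KernelSlice:
    """One kernel window: ``width`` consecutive frames of the source timeline."""

    start_frame: int
    values: np.ndarray  # (width, n_channels) binary

    @property
    def width(self) -> int:
        return self.values.shape[0]

    def flatten(self) -> np.ndarray:
        """Frame-major flattening used as encoder input."""
        return self.values.reshape(-1).astype(np.float64)


@dataclass(frozen=True)
class IdealPlaneSlice:
    """A stationary ideal diagnostic-plane block (constant across frames)."""

    plane: str
    values: np.ndarray

    @property
    def width(self) -> int:
        return self.values.shape[0]

    def flatten(self) -> np.ndarray:
        return self.values.reshape(-1).astype(np.float64)


def load_timeline(
    path: str | Path, registry: SubstructureRegistry | None = None
) -> BarcodeTimeline:
    """Read a timeline CSV (+ JSON sidecar if present), canonicalising columns.

    The file may list channel columns in any order; they are reordered to the
    registry order.  A missing or unknown channel column raises
    :class:`TimelineFormatError`; a non-binary cell raises ``ValueError``.
    """
    registry = registry or default_registry()
    path = Path(path)
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c != "frame"]
    missing = set(registry.names) - set(cols)
    extra = set(cols) - set(registry.names)
    if missing or extra:
        raise TimelineFormatError(
            f"{path.name}: missing channels {sorted(missing)}, "
            f"unknown channels {sorted(extra)}"
        )
    mat = df[list(registry.names)].to_numpy()
    if not np.isin(mat, (0, 1)).all():
        raise ValueError(f"{path.name}: non-binary cell values")

    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
    return BarcodeTimeline(
        frames=mat,
        video_id=meta.get("video_id", path.stem),
        case_id=meta.get("case_id", path.stem),
        label=meta.get("label", "normal"),
        disease_tag=meta.get("disease_tag"),
        registry=registry,
    )


def save_timeline(tl: BarcodeTimeline, path: str | Path) -> None:
    """Write the CSV + JSON sidecar representation of a timeline."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(tl.frames, columns=list(tl.registry.names))
    df.insert(0, "frame", np.arange(tl.n_frames))
    df.to_csv(path, index=False)
    meta = {
        "video_id": tl.video_id,
        "case_id": tl.case_id,
        "label": tl.label,
        "disease_tag": tl.disease_tag,
    }
    path.with_suffix(".json").write_text(
        json.dumps(meta, indent=1), encoding="utf-8"
    )


def slice_kernels(tl: BarcodeTimeline, width: int, stride: int = 1) -> list[KernelSlice]:
    """Slide a ``width``-frame kernel along the timeline with ``stride``.

    Windows are half-open ``[start, start + width)`` at starts ``0, s, 2s,
    ...``; the number of slices is ``floor((T - w) / s) + 1``.
    """
    if width < 1 or stride < 1:
        raise ValueError("width and stride must be >= 1")
    T = tl.n_frames
    if width > T:
        raise ValueError(f"kernel width {width} exceeds timeline length {T}")
    return [
        KernelSlice(start_frame=s0, values=tl.frames[s0 : s0 + width])
        for s0 in range(0, T - width + 1, stride)
    ]


def slice_matrix(tl: BarcodeTimeline, width: int, stride: int = 1) -> np.ndarray:
    """All kernel slices of a timeline as one (n_slices, width*C) float matrix."""
    slices = slice_kernels(tl, width, stride)
    return np.stack([s.flatten() for s in slices])


def synthesize_ideal_slice(
    plane: str, registry: SubstructureRegistry | None = None, width: int = 16
) -> IdealPlaneSlice:
    """Build the ideal stationary barcode block for a diagnostic plane.

    The block is constant across its ``width`` frames: every channel in the
    registry's plane-visibility set for ``plane`` is 1, all others 0.  These
    blocks stand in for unannotated real diagnostic-plane frames as the
    anchors of the view-proxy loss.
    """
    registry = registry or default_registry()
    if width < 1:
        raise ValueError("width must be >= 1")
    idx = registry.visibility_indices(plane)  # raises ValueError on bad plane
    row = np.zeros(registry.n_channels, dtype=np.uint8)
    row[list(idx)] = 1
    return IdealPlaneSlice(plane=plane, values=np.tile(row, (width, 1)))
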