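"""Per-slide scan-time models, effective scan-area geometry, and the
normalized-throughput metric.

Whole-slide scanners differ both in raw speed and in how much of the glass
they actually scan: a *line* scanner sweeps one or more bounding boxes drawn
around the tissue, while a *tile* scanner acquires fixed-size tiles whose
(padded) footprint touches the tissue boxes.  Because tissue area varies by an
order of magnitude across slides, raw scan times are not comparable between
scanners; the field's convention is to rescale a scan to a 15 x 15 mm
(225 mm^2) reference area, the "normalized scan time".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "REFERENCE_AREA_MM2",
    "Box",
    "SlideSpec",
    "ScannerProfile",
    "ScanEvent",
    "normalized_scan_time",
    "effective_scan_area",
    "draw_scan_time",
]

#: Reference tissue area (mm^2) of the 15 x 15 mm square used to normalize
#: scan times across scanners.
REFERENCE_AREA_MM2 = 225.0

SlideClass = Literal["resection", "biopsy", "ihc"]
SLIDE_CLASSES: tuple[str, ...] = ("resection", "biopsy", "ihc")


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle on the slide, in mm."""

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"box width/height must be positive, got {self.width} x {self.height}"
            )

    @property
    def area(self) -> float:
        return self.width * self.height

    def padded(self, pad: float) -> "Box":
        """Expand by ``pad`` mm on every side."""
        if pad == 0:
            return self
        return Box(self.x - pad, self.y - pad, self.width + 2 * pad, self.height + 2 * pad)


@dataclass
class SlideSpec:
    """A physical slide: class, tissue geometry/area, latent true quality.

    ``true_quality`` is the latent quality in [0, 1] used by the QC
    simulation; when absent it is drawn uniformly at simulation time.
    ``tissue_boxes`` bound the tissue — the tissue need not fill them.
    """

    slide_id: str
    slide_class: str
    tissue_area_mm2: float
    tissue_boxes: list[Box] | None = None
    true_quality: float | None = None

    def __post_init__(self) -> None:
        if self.slide_class not in SLIDE_CLASSES:
            raise ValueError(
                f"unknown slide_class {self.slide_class!r}; expected one of {SLIDE_CLASSES}"
            )
        if not self.tissue_area_mm2 > 0:
            raise ValueError(f"tissue_area_mm2 must be > 0, got {self.tissue_area_mm2}")
        if self.tissue_boxes is not None:
            self.tissue_boxes = [
                b if isinstance(b, Box) else Box(*b) for b in self.tissue_boxes
            ]
        if self.true_quality is not None and not 0 <= self.true_quality <= 1:
            raise ValueError(f"true_quality must lie in [0, 1], got {self.true_quality}")


@dataclass
class ScannerProfile:
    """A scanner: scan-time model, loading time, capacity, geometry strategy.

    Two time models are supported:

    ``poisson``
        Scan durations are integer-second draws from a Poisson distribution
        with mean ``mean_scan_s`` (scan time is dominated by many small
        acquisition steps; the batch-level model used for workflow studies).
    ``area_rate``
        Deterministic ``rate_s_per_mm2 * effective_area + overhead_s``,
        linking duration to the geometry-dependent effective scan area.

    ``load_s`` is the constant robotic slide-loading time added to each scan.
    ``capacity`` is the number of slides one loaded batch can hold.
    """

    name: str = "scanner"
    time_model: Literal["poisson", "area_rate"] = "poisson"
    mean_scan_s: float = 60.0
    rate_s_per_mm2: float = 0.0
    overhead_s: float = 0.0
    load_s: float = 10.0
    capacity: int = 360
    geometry: Literal["line", "tile"] = "line"
    tile_mm: float = 1.0
    padding_mm: float = 0.0
    internal_qc: bool = True

    def __post_init__(self) -> None:
        if self.time_model not in ("poisson", "area_rate"):
            raise ValueError(f"unknown time_model {self.time_model!r}")
        if self.time_model == "poisson" and not self.mean_scan_s > 0:
            raise ValueError("poisson time model requires mean_scan_s > 0")
        if self.time_model == "area_rate" and self.rate_s_per_mm2 < 0:
            raise ValueError("rate_s_per_mm2 must be >= 0")
        if self.overhead_s < 0 or self.load_s < 0 or self.padding_mm < 0:
            raise ValueError("overhead_s, load_s and padding_mm must be >= 0")
        if self.capacity < 1:
            raise ValueError(f"capacity must be >= 1, got {self.capacity}")
        if self.geometry not in ("line", "tile"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.tile_mm <= 0:
            raise ValueError("tile_mm must be > 0")


@dataclass
class ScanEvent:
    """One pass of a slide through the scanner.

    ``stringent`` marks a rescan performed under the slower, more stringent
    profile; ``load_s`` is the loading time actually charged for this pass
    (0 when the slide never left the scanner).
    """

    attempt: int
    duration_s: float
    load_s: float
    stringent: bool = False

    def __post_init__(self) -> None:
        if self.attempt < 1:
            raise ValueError("attempt must be >= 1")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        if self.load_s < 0:
            raise ValueError("load_s must be >= 0")

    @property
    def total_s(self) -> float:
        return self.duration_s + self.load_s


def normalized_scan_time(scan_time_s: float, tissue_area_mm2: float) -> float:
    """Rescale a scan time to the 15 x 15 mm (225 mm^2) reference area.

    Returns ``scan_time_s / tissue_area_mm2 * 225``, the estimated time the
    scanner would have needed for a 225 mm^2 tissue region — the throughput
    metric that makes scanners comparable across slides of different size.
    Scale-invariant: doubling both inputs leaves the result unchanged.

    Raises
    ------
    ValueError
        If either input is not strictly positive.
    """
    if not scan_time_s > 0:
        raise ValueError(f"scan_time_s must be > 0, got {scan_time_s}")
    if not tissue_area_mm2 > 0:
        raise ValueError(f"tissue_area_mm2 must be > 0, got {tissue_area_mm2}")
    return scan_time_s / tissue_area_mm2 * REFERENCE_AREA_MM2


def effective_scan_area(slide: SlideSpec, profile: ScannerProfile) -> float:
    """Area (mm^2) the scanner actually acquires for ``slide``.

    Line geometry: the sum of the tissue bounding-box areas, each box
    expanded by ``padding_mm`` on every side.  Tile geometry: the number of
    tiles of side ``tile_mm`` (grid anchored at the slide origin, tiles
    half-open ``[i*s, (i+1)*s)``) whose footprint overlaps any padded box
    with positive area, times ``tile_mm**2``.

    Raises
    ------
    ValueError
        If the slide carries no tissue boxes (the geometry is undefined).
    """
    if not slide.tissue_boxes:
        raise ValueError(
            f"slide {slide.slide_id!r} has no tissue_boxes; "
            "effective scan area requires tissue bounding boxes"
        )
    pad = profile.padding_mm
    boxes = [b.padded(pad) for b in slide.tissue_boxes]
    if profile.geometry == "line":
        return float(sum(b.area for b in boxes))

    s = profile.tile_mm
    tiles: set[tuple[int, int]] = set()
    for b in boxes:
        # strict overlap: a tile touching a box only at its edge is not scanned
        i0 = math.floor(b.x / s)
        i1 = math.ceil((b.x + b.width) / s)
        j0 = math.floor(b.y / s)
        j1 = math.ceil((b.y + b.height) / s)
        for i in range(i0, i1):
            if not (i * s < b.x + b.width and b.x < (i + 1) * s):
                continue
            for j in range(j0, j1):
                if j * s < b.y + b.height and b.y < (j + 1) * s:
                    tiles.add((i, j))
    return float(len(tiles)) * s * s


def draw_scan_time(
    profile: ScannerProfile,
    slide: SlideSpec,
    rng: np.random.Generator,
    *,
    attempt: int = 1,
    stringent: bool = False,
) -> ScanEvent:
    """Draw one scan event for ``slide`` under ``profile``.

    Poisson mode draws an integer-second duration with mean
    ``mean_scan_s`` (zero draws are resampled so durations stay positive);
    area_rate mode is deterministic, ``rate * effective_area + overhead``,
    using the geometry-dependent effective area when tissue boxes are present
    and the tissue area itself otherwise.  The same seeded ``rng`` state
    yields the identical event.
    """
    if profile.time_model == "poisson":
        duration = float(rng.poisson(profile.mean_scan_s))
        while duration == 0.0:
            duration = float(rng.poisson(profile.mean_scan_s))
    else:
        area = (
            effective_scan_area(slide, profile)
            if slide.tissue_boxes
            else slide.tissue_area_mm2
        )
        duration = profile.rate_s_per_mm2 * area + profile.overhead_s
        if not duration > 0:
            raise ValueError(
                "area_rate profile produced a nonpositive duration; "
                "set rate_s_per_mm2 or overhead_s > 0"
            )
    return ScanEvent(
        attempt=attempt,
        duration_s=duration,
        load_s=profile.load_s,
        stringent=stringent,
    )
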