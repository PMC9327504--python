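"""Synthetic slide-manifest generator.

Emulates the composition of the embedded 9-slide benchmark: a mix of
resections, biopsies and IHC slides whose scanned areas span the printed
per-class ranges.  Areas are drawn log-uniformly within per-class bounds
(scale-spanning and bounded), latent quality uniformly on [0, 1], and each
slide is given 1-3 tissue bounding boxes consistent with its area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scan_model import SLIDE_CLASSES, Box, SlideSpec

__all__ = ["GeneratorSpec", "generate_manifest"]

# per-class scanned-area bounds (mm^2) spanning the benchmark's printed ranges
DEFAULT_AREA_BOUNDS: dict[str, tuple[float, float]] = {
    "resection": (439.0, 778.0),
    "biopsy": (67.0, 426.0),
    "ihc": (34.0, 898.0),
}

# usable region of a standard 25 x 75 mm slide, minus the label end
SLIDE_W_MM = 25.0
SLIDE_H_MM = 50.0
BOX_FILL = 0.7  # tissue fills ~70% of its bounding boxes


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic manifest generator."""

    n_slides: int = 9
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"resection": 1 / 3, "biopsy": 1 / 3, "ihc": 1 / 3}
    )
    area_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AREA_BOUNDS)
    )
    draw_quality: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slides < 0:
            raise ValueError("n_slides must be >= 0")
        if set(self.class_mix) - set(SLIDE_CLASSES):
            raise ValueError(f"unknown classes in class_mix: {set(self.class_mix) - set(SLIDE_CLASSES)}")
        total = sum(self.class_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class_mix proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.class_mix.values()):
            raise ValueError("class_mix proportions must be nonnegative")
        for cls, (lo, hi) in self.area_bounds.items():
            if not (0 < lo <= hi):
                raise ValueError(f"area bounds for {cls!r} must be positive and ordered")


def _boxes_for_area(area: float, rng: np.random.Generator) -> list[Box]:
    """1-3 bounding boxes whose total area exceeds the tissue area."""
    k = int(rng.integers(1, 4))
    weights = rng.dirichlet(np.ones(k))
    boxes = []
    for w_frac in weights:
        box_area = area * w_frac / BOX_FILL
        aspect = rng.uniform(0.5, 2.0)
        w = min(np.sqrt(box_area * aspect), SLIDE_W_MM)
        h = min(box_area / w, SLIDE_H_MM)
        x = rng.uniform(0.0, SLIDE_W_MM - min(w, SLIDE_W_MM - 1e-9))
        y = rng.uniform(0.0, SLIDE_H_MM - min(h, SLIDE_H_MM - 1e-9))
        boxes.append(Box(x, y, w, h))
    return boxes


def generate_manifest(spec: GeneratorSpec) -> list[SlideSpec]:
    """Draw a deterministic synthetic manifest for the given spec."""
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.class_mix)
    probs = np.array([spec.class_mix[c] for c in classes])
    slides: list[SlideSpec] = []
    for i in range(spec.n_slides):
        cls = classes[rng.choice(len(classes), p=probs)]
        lo, hi = spec.area_bounds[cls]
        area = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        quality = float(rng.uniform()) if spec.draw_quality else None
        slides.append(
            SlideSpec(
                slide_id=f"synthetic-{i:04d}",
                slide_class=cls,
                tissue_area_mm2=area,
                tissue_boxes=_boxes_for_area(area, rng),
                true_quality=quality,
            )
        )
    return slides
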