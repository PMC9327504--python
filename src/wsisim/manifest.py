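"""Slide-manifest and results I/O.

Manifests are headered comma-separated text with columns ``slide_id``,
``slide_class``, ``tissue_area_mm2`` and the optional columns ``boxes``
(semicolon-separated ``x:y:w:h`` quadruples, mm) and ``true_quality``.
Writers emit exactly what the readers parse, so write-then-read is a
field-for-field identity.
"""

from __future__ import annotations

import csv
import os
from typing import Iterable, Sequence

import pandas as pd

from .scan_model import SLIDE_CLASSES, Box, SlideSpec
from .workflow import BatchResult, SlideRecord

__all__ = [
    "ManifestError",
    "read_manifest",
    "write_manifest",
    "write_records",
    "write_batch_summary",
]

MANIFEST_COLUMNS = ["slide_id", "slide_class", "tissue_area_mm2", "boxes", "true_quality"]


class ManifestError(ValueError):
    """Malformed manifest content; the message names the offending line."""


def _parse_boxes(text: str, line_no: int) -> list[Box]:
    boxes = []
    for quad in text.split(";"):
        parts = quad.split(":")
        if len(parts) != 4:
            raise ManifestError(
                f"line {line_no}: box {quad!r} is not an x:y:w:h quadruple"
            )
        try:
            x, y, w, h = (float(p) for p in parts)
        except ValueError as exc:
            raise ManifestError(f"line {line_no}: non-numeric box value in {quad!r}") from exc
        try:
            boxes.append(Box(x, y, w, h))
        except ValueError as exc:
            raise ManifestError(f"line {line_no}: {exc}") from exc
    return boxes


def _num(v: float) -> str:
    """Shortest decimal that round-trips the float exactly."""
    return repr(float(v))


def _format_boxes(boxes: Sequence[Box]) -> str:
    return ";".join(
        f"{_num(b.x)}:{_num(b.y)}:{_num(b.width)}:{_num(b.height)}" for b in boxes
    )


def read_manifest(path: str | os.PathLike) -> list[SlideSpec]:
    """Parse a slide manifest; errors name the 1-based file line."""
    slides: list[SlideSpec] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ManifestError("line 1: manifest is empty (no header row)")
        missing = {"slide_id", "slide_class", "tissue_area_mm2"} - set(reader.fieldnames)
        if missing:
            raise ManifestError(f"line 1: missing required column(s) {sorted(missing)}")
        for row in reader:
            line_no = reader.line_num
            cls = (row["slide_class"] or "").strip()
            if cls not in SLIDE_CLASSES:
                raise ManifestError(
                    f"line {line_no}: unknown slide_class {cls!r} "
                    f"(expected one of {SLIDE_CLASSES})"
                )
            try:
                area = float(row["tissue_area_mm2"])
            except (TypeError, ValueError) as exc:
                raise ManifestError(
                    f"line {line_no}: tissue_area_mm2 {row['tissue_area_mm2']!r} "
                    "is not numeric"
                ) from exc
            if not area > 0:
                raise ManifestError(f"line {line_no}: tissue_area_mm2 must be > 0, got {area}")
            boxes = None
            if row.get("boxes"):
                boxes = _parse_boxes(row["boxes"].strip(), line_no)
            quality = None
            if row.get("true_quality") not in (None, ""):
                try:
                    quality = float(row["true_quality"])
                except ValueError as exc:
                    raise ManifestError(
                        f"line {line_no}: true_quality {row['true_quality']!r} is not numeric"
                    ) from exc
                if not 0 <= quality <= 1:
                    raise ManifestError(
                        f"line {line_no}: true_quality must lie in [0, 1], got {quality}"
                    )
            slides.append(
                SlideSpec(
                    slide_id=row["slide_id"],
                    slide_class=cls,
                    tissue_area_mm2=area,
                    tissue_boxes=boxes,
                    true_quality=quality,
                )
            )
    return slides


def write_manifest(path: str | os.PathLike, slides: Iterable[SlideSpec]) -> None:
    """Write a manifest the package's own reader round-trips losslessly."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for s in slides:
            writer.writerow(
                [
                    s.slide_id,
                    s.slide_class,
                    _num(s.tissue_area_mm2),
                    _format_boxes(s.tissue_boxes) if s.tissue_boxes else "",
                    "" if s.true_quality is None else _num(s.true_quality),
                ]
            )


def write_records(path: str | os.PathLike, records: Iterable[SlideRecord]) -> None:
    """Write the per-slide event log, one row per scan event."""
    rows = []
    for r in records:
        for e in r.events:
            rows.append(
                {
                    "slide_id": r.slide_id,
                    "attempt": e.attempt,
                    "duration_s": e.duration_s,
                    "load_s": e.load_s,
                    "stringent": e.stringent,
                    "flagged_external": r.flagged_external,
                    "visually_reviewed": r.visually_reviewed,
                    "control_sampled": r.control_sampled,
                    "disposition": r.disposition,
                    "missed_bad": r.missed_bad,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_batch_summary(path: str | os.PathLike, results: Iterable[BatchResult]) -> None:
    """Write one summary row per simulated batch."""
    rows = [
        {
            "n_slides": b.n_slides,
            "total_time_s": b.total_time_s,
            "relative_time": b.relative_time,
            "n_rescans": b.n_rescans,
            "n_visual_reviews": b.n_visual_reviews,
            "n_control_reviews": b.n_control_reviews,
            "n_accepted": b.n_accepted,
            "n_rejected": b.n_rejected,
            "missed_fraction_observed": b.missed_fraction_observed,
        }
        for b in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
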