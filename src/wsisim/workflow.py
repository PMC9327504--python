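"""Monte-Carlo engine for the multi-stage AI-enabled QC workflow.

Each slide passes through up to four stages:

1. **Scan** — one scan event (duration model per the scanner profile, plus
   the constant loading time).
2. **Scanner-internal QC** — with probability ``auto_rescan_rate`` the image
   fails the vendor's built-in check and is automatically rescanned under a
   more stringent (slower) profile while still in the scanner; the rescan
   takes ``rescan_multiplier`` times the original duration.
3. **External QC** — an independent algorithm observes the slide's latent
   quality through Gaussian noise and flags it when the score falls below
   the threshold; flagged slides go to visual review, which accepts with
   probability ``visual_accept_prob`` or sends the slide for a stringent
   rescan if the rescan budget is not exhausted — otherwise the slide is
   rejected outright.
4. **Control sampling** — a small random fraction of slides that passed all
   automated checks is reviewed visually anyway, to monitor the algorithm.

A slide is rescanned at most ``max_rescans`` times in total (default 1):
once rescanned, a second failure leads to rejection, not another rescan.

Two engines implement the model.  :func:`run_slide` is the event-level
reference: it produces a full :class:`SlideRecord` per slide and supports
every configuration.  :func:`simulate_relative_times` is a vectorized batch
engine for large parameter sweeps (homogeneous Poisson batches,
``max_rescans <= 1``); the test suite checks that both agree with each other
and with the closed-form expectations.  RNG draws happen in documented
order within each engine, so runs are bit-reproducible per engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .quality_model import QualityModel, decide_rescan, observe_quality
from .scan_model import ScanEvent, ScannerProfile, SlideSpec, draw_scan_time

__all__ = [
    "QCPolicy",
    "SlideRecord",
    "BatchResult",
    "FleetReport",
    "run_slide",
    "simulate_batch",
    "simulate_relative_times",
    "expected_relative_time",
    "simulate_fleet",
]


@dataclass
class QCPolicy:
    """QC decision parameters for the workflow simulation.

    Parameters
    ----------
    auto_rescan_rate : float
        First-stage (scanner-internal) QC rejection probability, modelled as
        a Bernoulli coin independent of true quality.
    rescan_multiplier : float
        Factor (>= 1) by which the stringent rescan's duration exceeds the
        original scan's.
    rescan_includes_load : bool
        Whether a rescan is charged the slide-loading time.  Default True
        (loading time added to each scan); False models rescans that happen
        while the slide never leaves the stage.
    rescan_time_mode : str
        ``scaled_original`` (default) scales this slide's original duration;
        ``fresh_draw_scaled`` scales a fresh draw from the time model.
    quality : QualityModel
        External-QC noise/threshold model.
    visual_accept_prob : float
        Probability that visual review accepts a flagged slide.
    control_rate : float
        Probability that a slide passing automated QC is visually reviewed
        as a control; a control review always catches a truly bad slide.
    max_rescans : int
        Total rescan budget per slide (scanner-internal + QC-triggered).
    """

    auto_rescan_rate: float = 0.05
    rescan_multiplier: float = 2.0
    rescan_includes_load: bool = True
    rescan_time_mode: Literal["scaled_original", "fresh_draw_scaled"] = "scaled_original"
    quality: QualityModel = field(default_factory=QualityModel)
    visual_accept_prob: float = 0.5
    control_rate: float = 0.05
    max_rescans: int = 1

    def __post_init__(self) -> None:
        for name in ("auto_rescan_rate", "visual_accept_prob", "control_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.rescan_multiplier < 1:
            raise ValueError(f"rescan_multiplier must be >= 1, got {self.rescan_multiplier}")
        if self.rescan_time_mode not in ("scaled_original", "fresh_draw_scaled"):
            raise ValueError(f"unknown rescan_time_mode {self.rescan_time_mode!r}")
        if self.max_rescans < 0:
            raise ValueError(f"max_rescans must be >= 0, got {self.max_rescans}")


@dataclass
class SlideRecord:
    """Per-slide event log and terminal disposition."""

    slide_id: str
    events: list[ScanEvent]
    flagged_external: bool = False
    visually_reviewed: bool = False
    control_sampled: bool = False
    disposition: Literal["accepted", "rejected"] = "accepted"
    missed_bad: bool = False
    true_quality: float | None = None

    @property
    def n_rescans(self) -> int:
        return len(self.events) - 1

    @property
    def total_time_s(self) -> float:
        return sum(e.total_s for e in self.events)


@dataclass
class BatchResult:
    """Batch-level aggregates of a simulated scan run."""

    n_slides: int
    total_time_s: float
    relative_time: float
    n_rescans: int
    n_visual_reviews: int
    n_control_reviews: int
    n_accepted: int
    n_rejected: int
    missed_fraction_observed: float
    records: list[SlideRecord] | None = None


def _rescan_event(
    original: ScanEvent,
    profile: ScannerProfile,
    policy: QCPolicy,
    slide: SlideSpec,
    rng: np.random.Generator,
    attempt: int,
) -> ScanEvent:
    if policy.rescan_time_mode == "scaled_original":
        base = original.duration_s
    else:
        base = draw_scan_time(profile, slide, rng, attempt=attempt).duration_s
    return ScanEvent(
        attempt=attempt,
        duration_s=policy.rescan_multiplier * base,
        load_s=profile.load_s if policy.rescan_includes_load else 0.0,
        stringent=True,
    )


def run_slide(
    slide: SlideSpec,
    profile: ScannerProfile,
    policy: QCPolicy,
    rng: np.random.Generator,
) -> SlideRecord:
    """Push one slide through the full QC workflow.

    RNG draw order: scan duration; internal-QC coin; (fresh rescan draw if
    applicable); true quality (if the slide has none); then, per external-QC
    round: observation noise, visual-review coin, (fresh rescan draw);
    finally the control-sampling coin.  Always terminates with a disposition;
    the event count never exceeds ``1 + max_rescans``.
    """
    first = draw_scan_time(profile, slide, rng, attempt=1)
    events = [first]
    rescans_used = 0

    # stage 2: scanner-internal QC -> automatic stringent rescan
    if (
        profile.internal_qc
        and policy.auto_rescan_rate > 0
        and rescans_used < policy.max_rescans
        and rng.uniform() < policy.auto_rescan_rate
    ):
        rescans_used += 1
        events.append(
            _rescan_event(first, profile, policy, slide, rng, attempt=len(events) + 1)
        )

    q_true = (
        slide.true_quality if slide.true_quality is not None else float(rng.uniform())
    )
    bad = q_true < policy.quality.bad_cutoff

    rec = SlideRecord(slide_id=slide.slide_id, events=events, true_quality=q_true)

    # stage 3: external QC -> visual review -> possible stringent rescan
    while True:
        score = observe_quality(q_true, policy.quality, rng)
        if not decide_rescan(score, policy.quality):
            rec.disposition = "accepted"
            # stage 4: control sampling of slides that passed automated QC
            if policy.control_rate > 0 and rng.uniform() < policy.control_rate:
                rec.control_sampled = True
                if bad:
                    rec.disposition = "rejected"
            break
        rec.flagged_external = True
        rec.visually_reviewed = True
        if rng.uniform() < policy.visual_accept_prob:
            rec.disposition = "accepted"
            break
        if rescans_used < policy.max_rescans:
            rescans_used += 1
            events.append(
                _rescan_event(first, profile, policy, slide, rng, attempt=len(events) + 1)
            )
            continue
        rec.disposition = "rejected"
        break

    rec.missed_bad = (
        bad
        and rec.disposition == "accepted"
        and not rec.visually_reviewed
        and not rec.control_sampled
    )
    return rec


def _baseline_time(
    slides: Sequence[SlideSpec], profile: ScannerProfile
) -> float:
    """Expected zero-rescan batch time: the relative-time denominator."""
    n = len(slides)
    if profile.time_model == "poisson":
        return n * (profile.mean_scan_s + profile.load_s)
    total = 0.0
    for s in slides:
        from .scan_model import effective_scan_area

        area = effective_scan_area(s, profile) if s.tissue_boxes else s.tissue_area_mm2
        total += profile.rate_s_per_mm2 * area + profile.overhead_s + profile.load_s
    return total


def simulate_batch(
    slides: Sequence[SlideSpec],
    profile: ScannerProfile,
    policy: QCPolicy,
    rng: np.random.Generator,
    *,
    keep_records: bool = True,
) -> BatchResult:
    """Simulate one batch slide-by-slide and aggregate the records.

    ``relative_time`` is the batch's total time divided by the analytic
    zero-rescan baseline ``n * (mean_scan_s + load_s)`` (or its area-rate
    analogue), so its expectation follows the closed-form linear law of
    :func:`expected_relative_time`.
    """
    if len(slides) == 0:
        raise ValueError("cannot simulate an empty batch")
    records = [run_slide(s, profile, policy, rng) for s in slides]
    total = sum(r.total_time_s for r in records)
    n_acc = sum(r.disposition == "accepted" for r in records)
    return BatchResult(
        n_slides=len(records),
        total_time_s=total,
        relative_time=total / _baseline_time(slides, profile),
        n_rescans=sum(r.n_rescans for r in records),
        n_visual_reviews=sum(r.visually_reviewed for r in records),
        n_control_reviews=sum(r.control_sampled for r in records),
        n_accepted=n_acc,
        n_rejected=len(records) - n_acc,
        missed_fraction_observed=sum(r.missed_bad for r in records) / len(records),
        records=records if keep_records else None,
    )


def expected_relative_time(
    auto_rescan_rate: float,
    multiplier: float,
    mean_scan_s: float = 60.0,
    load_s: float = 10.0,
    rescan_includes_load: bool = True,
) -> float:
    """Closed-form expected relative batch time under internal-QC rescans only.

    ``1 + r * (m * mu + L*[includes_load]) / (mu + L)`` — linear in the
    rescan rate r with a slope that grows with the multiplier m.
    """
    if not 0 <= auto_rescan_rate <= 1:
        raise ValueError("auto_rescan_rate must lie in [0, 1]")
    if multiplier < 1 or mean_scan_s <= 0 or load_s < 0:
        raise ValueError("require multiplier >= 1, mean_scan_s > 0, load_s >= 0")
    extra = multiplier * mean_scan_s + (load_s if rescan_includes_load else 0.0)
    return 1.0 + auto_rescan_rate * extra / (mean_scan_s + load_s)


def simulate_relative_times(
    n_batches: int,
    batch_size: int,
    profile: ScannerProfile,
    policy: QCPolicy,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized batch simulation for parameter sweeps.

    Simulates ``n_batches`` homogeneous batches of ``batch_size`` slides
    (Poisson time model, latent quality drawn U(0,1), ``max_rescans <= 1``)
    and returns ``(relative_times, missed_fractions)``, one entry per batch.
    Semantics match :func:`run_slide`; draws are vectorized so the per-seed
    stream differs from the per-slide engine.
    """
    if profile.time_model != "poisson":
        raise ValueError("vectorized engine requires the poisson time model")
    if policy.max_rescans > 1:
        raise ValueError("vectorized engine supports max_rescans <= 1")
    if n_batches < 1 or batch_size < 1:
        raise ValueError("n_batches and batch_size must be >= 1")

    n = n_batches * batch_size
    mu, L = profile.mean_scan_s, profile.load_s
    q_model = policy.quality
    m = policy.rescan_multiplier
    rescan_load = L if policy.rescan_includes_load else 0.0
    budget = policy.max_rescans

    d1 = rng.poisson(mu, size=n).astype(float)
    while np.any(d1 == 0.0):
        zero = d1 == 0.0
        d1[zero] = rng.poisson(mu, size=int(zero.sum()))

    can_auto = profile.internal_qc and policy.auto_rescan_rate > 0 and budget >= 1
    auto = (
        rng.uniform(size=n) < policy.auto_rescan_rate
        if can_auto
        else np.zeros(n, dtype=bool)
    )

    def rescan_duration(mask: np.ndarray) -> np.ndarray:
        if policy.rescan_time_mode == "scaled_original":
            return m * d1[mask]
        fresh = rng.poisson(mu, size=int(mask.sum())).astype(float)
        fresh[fresh == 0.0] = 1.0
        return m * fresh

    total = d1 + L
    total[auto] += rescan_duration(auto) + rescan_load
    used = auto.astype(int)

    q = rng.uniform(size=n)
    bad = q < q_model.bad_cutoff

    def observe(mask: np.ndarray) -> np.ndarray:
        s = np.full(n, np.nan)
        if q_model.sigma > 0:
            s[mask] = q[mask] + rng.normal(0.0, q_model.sigma, size=int(mask.sum()))
        else:
            s[mask] = q[mask]
        return s

    alive = np.ones(n, dtype=bool)  # still awaiting a disposition
    accepted = np.zeros(n, dtype=bool)
    reviewed = np.zeros(n, dtype=bool)
    control = np.zeros(n, dtype=bool)
    eligible_control = np.zeros(n, dtype=bool)

    # at most two external-QC rounds are reachable with a budget of one
    for _ in range(budget + 1):
        if not alive.any():
            break
        score = observe(alive)
        flagged = alive & (score < q_model.threshold)
        passed = alive & ~flagged
        accepted[passed] = True
        eligible_control[passed] = True
        alive[passed] = False

        reviewed[flagged] = True
        vis = flagged & (rng.uniform(size=n) < policy.visual_accept_prob)
        accepted[vis] = True
        alive[vis] = False

        declined = flagged & ~vis
        rescan = declined & (used < budget)
        rejected_now = declined & ~rescan
        alive[rejected_now] = False
        if rescan.any():
            total[rescan] += rescan_duration(rescan) + rescan_load
            used[rescan] += 1
        alive = rescan  # only rescanned slides re-enter the loop
    # budget exhausted: any slide still alive was flagged with no rescans left
    accepted[alive] = False

    if policy.control_rate > 0:
        control = eligible_control & (rng.uniform(size=n) < policy.control_rate)
        accepted[control & bad] = False

    missed = bad & accepted & ~reviewed & ~control

    shape = (n_batches, batch_size)
    rel = total.reshape(shape).sum(axis=1) / (batch_size * (mu + L))
    missed_frac = missed.reshape(shape).mean(axis=1)
    return rel, missed_frac


@dataclass
class FleetReport:
    """Parallel-fleet scheduling summary."""

    n_slides: int
    n_days: int
    makespan_s: float
    n_reloads: int
    per_scanner: list[dict]

    @property
    def total_reloads(self) -> int:
        return self.n_reloads


def simulate_fleet(
    slides: Sequence[SlideSpec],
    profiles: Sequence[ScannerProfile],
    rng: np.random.Generator,
    *,
    daily_load: int | None = None,
) -> FleetReport:
    """Schedule slides across a parallel scanner fleet.

    Slides are split into consecutive days of at most ``daily_load`` slides
    (all in one day when None), assigned greedily round-robin to scanners,
    and each scanner works through its queue in loaded batches of at most
    ``capacity`` slides.  A reload event occurs whenever a scanner finishes
    its loaded batch and more of its queue remains.  Reports the makespan
    (longest single-day per-scanner finish time, scanners running in
    parallel), the total reload count, and each scanner's unused capacity
    (capacity minus the largest batch ever loaded into it).
    """
    if len(profiles) == 0:
        raise ValueError("simulate_fleet requires at least one scanner profile")
    slides = list(slides)
    if daily_load is not None and daily_load < 1:
        raise ValueError("daily_load must be >= 1")

    chunk = daily_load or max(len(slides), 1)
    days = [slides[i : i + chunk] for i in range(0, len(slides), chunk)] or [[]]

    stats = [
        {"scanner": p.name, "capacity": p.capacity, "n_slides": 0, "busy_s": 0.0,
         "reloads": 0, "max_loaded": 0}
        for p in profiles
    ]
    makespan = 0.0
    n_reloads = 0
    for day in days:
        day_busy = [0.0] * len(profiles)
        queues: list[list[SlideSpec]] = [[] for _ in profiles]
        for i, s in enumerate(day):
            queues[i % len(profiles)].append(s)
        for k, (p, queue) in enumerate(zip(profiles, queues)):
            if not queue:
                continue
            n_batches = math.ceil(len(queue) / p.capacity)
            reloads = n_batches - 1
            busy = sum(
                draw_scan_time(p, s, rng).total_s for s in queue
            )
            day_busy[k] += busy
            st = stats[k]
            st["n_slides"] += len(queue)
            st["busy_s"] += busy
            st["reloads"] += reloads
            st["max_loaded"] = max(st["max_loaded"], min(len(queue), p.capacity))
            n_reloads += reloads
        makespan = max(makespan, max(day_busy))

    for st in stats:
        st["unused_capacity"] = st["capacity"] - st["max_loaded"]
    return FleetReport(
        n_slides=len(slides),
        n_days=len(days),
        makespan_s=makespan,
        n_reloads=n_reloads,
        per_scanner=stats,
    )
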