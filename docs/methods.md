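# Methods

## Scope and model overview

`wsisim` is a metadata-level simulator: it models scan *times*, *areas* and
*QC decisions* for whole-slide imaging operations, never pixels. Its three
model layers — per-slide scan time, the multi-stage QC workflow, and the
noisy-threshold quality classifier — are deliberately simple enough that
every stochastic result has a closed-form or quadrature oracle the test
suite checks against.

## Scan-time models

Two per-slide duration models are supported, chosen per scanner profile:

- **poisson** — duration is an integer-second Poisson draw with mean
  `mean_scan_s` (default 60 s). Poisson is discrete, so durations are
  integer seconds; the 1-second granularity is immaterial at batch scale.
  A zero draw (probability e^−60 ≈ 10⁻²⁶ at the default mean) is resampled
  so durations stay positive. A constant `load_s` (default 10 s) is added
  to every scan.
- **area_rate** — deterministic `rate_s_per_mm2 × effective_area +
  overhead_s`, linking duration to scan geometry. It is noise-free by
  design so the two models stay orthogonal; when a slide carries no tissue
  boxes the tissue area stands in for the effective area.

### Effective scan area

A **line** scanner scans the tissue bounding boxes themselves: effective
area is the sum of box areas after expanding each box by `padding_mm` on
every side (overlap between boxes is not deduplicated — each configured box
is swept). A **tile** scanner acquires fixed tiles of side `tile_mm` on a
grid anchored at the slide origin, tiles half-open `[i·s, (i+1)·s)`; a tile
is scanned iff it overlaps a padded box with positive area, so an
edge-touching tile does not count. This makes the tile area deterministic,
monotone in padding, and exactly reproducible by a brute-force
rasterization oracle (used in the tests at 0.1 mm resolution with box
coordinates on a 0.5 mm lattice, where the discretization is exact).
Note the tile area can exceed the area of the boxes' union bounding box
when boxes are smaller than a tile — tiles overhang.

### Normalized scan time

`normalized_scan_time(t, A) = t/A × 225` rescales a scan to a 15 × 15 mm
reference area. The embedded 9-slide × 4-scanner benchmark stores the
published scan times, areas and rounded normalized times; recomputation
agrees with every printed value within ±0.5 (the printed areas were
themselves rounded). The benchmark's "Size" column is treated as scanned
area and consumed by the metric as printed. Per-scanner slowdown ratios
are reported under three conventions — ratio of mean raw times, mean of
per-slide raw-time ratios, ratio of mean normalized times — because no
single convention is canonical; the report labels each and the package
never asserts a preferred one. On the embedded benchmark the three give
7.55, 7.59 and 5.97 for scanner C vs A.

## QC workflow

Per slide, in order:

1. **Scan** (duration model above).
2. **Scanner-internal QC**: Bernoulli(`auto_rescan_rate`) failure,
   independent of true quality — the rescan *rate* is treated as a free
   policy axis. On failure, a stringent rescan costing
   `rescan_multiplier × ` the original duration (`scaled_original`,
   default) or `× ` a fresh draw (`fresh_draw_scaled`). `rescan_includes_load`
   (default true) controls whether the rescan is charged `load_s`; the flag
   exists because a rescan may occur while the slide is still on the stage.
3. **External QC**: the latent quality (given in the manifest or drawn
   U(0,1)) is observed through Gaussian noise and thresholded (below).
   Flagged slides go to visual review, modelled as Bernoulli acceptance
   with `visual_accept_prob` (default 0.5) independent of truth — no
   reviewer-error model is imposed. A declined slide is rescanned if the
   per-slide budget `max_rescans` (default 1, shared with stage 2) is not
   exhausted, then re-observed; otherwise it is rejected outright.
4. **Control sampling**: slides that passed automated QC are visually
   reviewed with probability `control_rate` (default 0.05, "a small
   number"); a control review of a truly bad slide always catches it.

A slide is **truly bad** when its latent quality is below `bad_cutoff`
(default 0.05; ground-truth badness is this package's parameter, chosen to
match the default operating rescan rate — it is fully configurable). A
slide counts as **missed** when it is bad, accepted, and never seen by a
human (neither flagged to visual review nor control-sampled). Under
`visual_accept_prob = 1, control_rate = 0` the observed missed fraction
converges to the closed form below, which the tests verify.

`relative_time` of a batch divides total time by the analytic zero-rescan
baseline `n(μ + L)` rather than a paired simulated baseline: this removes
baseline sampling noise and makes the expectation exactly
`1 + r(mμ + L·[includes_load])/(μ + L)` when only stage 2 is active.

### Engines

`run_slide`/`simulate_batch` is the event-level reference implementation
(full per-slide records, any configuration). `simulate_relative_times` is
a numpy-vectorized engine for parameter sweeps, restricted to homogeneous
Poisson batches and `max_rescans ≤ 1`; it implements identical semantics
but draws in a different order, so same-seed equality holds within an
engine, not across engines. The suite checks both engines agree
statistically with each other and with the closed forms.

### RNG discipline

Every simulation takes a `numpy.random.Generator`; draws occur in the
documented stage order, so a run is bit-reproducible from its seed (the
CLI writes seed and resolved parameters to a JSON-lines run log). Sweep
cells use `SeedSequence.spawn` so each grid cell is an independent,
order-insensitive stream.

## Quality classifier closed forms

With q ~ U(0,1), noise ε ~ N(0, σ²), threshold t and bad cutoff c:

- missed = P(q < c, q + ε ≥ t) = ∫₀ᶜ Φ((q−t)/σ) dq = σ[G((c−t)/σ) − G(−t/σ)]
- flagged = P(q + ε < t) = ∫₀¹ Φ((t−q)/σ) dq = σ[G(t/σ) − G((t−1)/σ)]

where G(z) = zΦ(z) + φ(z) is the antiderivative of the normal CDF. For
|z| > 40 the asymptotes G(z) ≈ z (z → ∞) and G(z) ≈ 0 (z → −∞) are used to
avoid overflow; σ = 0 falls back to the indicator limits, and t = ±∞ is
handled explicitly. Scores are *not* clipped to [0,1] (the threshold
applies to the noisy value itself), and the tie at score = threshold is
resolved as "keep" so σ = 0 is deterministic. The missed fraction is
reported as a fraction of *all* slides (joint probability) by default,
with `conditional=True` giving the per-bad-slide miss rate; the joint
convention is primary because batch-level proportions are what the
workflow aggregates. Closed forms are verified against an independent
adaptive-quadrature oracle to 10⁻⁹ and against 10⁶-slide Monte Carlo.

## Fleet scheduling

Slides are partitioned into consecutive days of at most `daily_load`
slides (one day if unset), assigned round-robin to the fleet, and each
scanner works through its queue in loaded batches of at most `capacity`.
Reloads per scanner and day are `ceil(queue/capacity) − 1`; unused
capacity is `capacity −` the largest batch ever loaded; makespan is the
longest single-day per-scanner busy time with scanners in parallel. This
is deliberately a capacity-arithmetic model: no staffing, queueing-at-load
or scanner-failure dynamics.

## Synthetic manifest generator

The generator emulates the embedded benchmark's composition: equal thirds
of resections, biopsies and IHC slides by default, with scanned areas
drawn log-uniformly within per-class bounds spanning the benchmark's
printed ranges (resection 439–778 mm², biopsy 67–426 mm², IHC 34–898 mm²;
log-uniform because areas span an order of magnitude and the benchmark
gives no distribution). Latent quality is U(0,1). Each slide gets 1–3
bounding boxes sized so tissue fills ~70% of them, placed uniformly on a
25 × 50 mm usable slide region; boxes may overlap (they bound tissue, they
need not tile it). What the generator does *not* emulate: correlation
between area and quality, per-class quality differences, heavy-tailed scan
times from focus failures, or inter-slide batching effects — so passing
tests show the workflow engine and its oracles are internally consistent
at realistic scales, not that any particular laboratory's throughput is
predicted.

## Problem sizes and numerical choices

The sweep analyses use 1,000 replicate batches of 100 slides per grid cell
(the scale at which the linear law's slope is resolved to well under 1%)
and 10⁶ slides per Monte-Carlo check of the classifier closed forms. The
statistical tests bound each cell at 3 standard errors; because a ~170-cell
grid is expected to produce an occasional chance exceedance at that level,
a cell exceeding the bound is re-simulated once with fresh draws and must
exceed again to count as a disagreement. Quadrature agreement is asserted
at 10⁻⁹ absolute; closed-form probabilities are clamped to their valid
ranges to absorb last-ulp excursions.

## Known limitations

- The Bernoulli internal-QC stage is independent of true quality; a
  quality-coupled internal QC is out of scope.
- Visual review has no error model beyond a constant acceptance
  probability; control review is a perfect detector of bad slides.
- The area_rate model is deterministic; stochastic area-rate scanning is
  out of scope.
- Focus-map generation time, tile overlap and z-stacks are not
  parameterized.
- Image-derived quality scoring (e.g. integrating HistoQC- or
  PathProfiler-style tools) is a non-goal; the classifier consumes a
  latent scalar quality.
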