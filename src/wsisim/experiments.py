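"""Parameter sweeps and the scanner benchmark report.

Two sweeps mirror the standard workflow analyses: relative batch time as a
function of the internal-QC rescan rate for a family of rescan multipliers,
and the missed-slide / batch-time trade-off as a function of the external-QC
threshold for a family of noise levels.  Sweeps store every replicate value
(not only cell means) so standard errors and re-aggregations remain
verifiable downstream.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .quality_model import QualityModel, flagged_fraction, missed_fraction
from .scan_model import ScannerProfile, normalized_scan_time
from .workflow import QCPolicy, expected_relative_time, simulate_relative_times

__all__ = [
    "SweepResult",
    "ScannerReport",
    "sweep_rescan_rate",
    "sweep_threshold",
    "fit_slopes",
    "scanner_comparison",
]


@dataclass
class SweepResult:
    """Long-format sweep output with per-replicate values.

    ``replicates`` has one row per (cell, replicate); ``summary()``
    aggregates to per-cell mean, standard error and replication count.
    """

    axes: tuple[str, ...]
    response: str
    replicates: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        g = self.replicates.groupby(list(self.axes))[self.response]
        out = g.agg(["mean", "sem", "count"]).reset_index()
        out = out.rename(columns={"mean": self.response, "sem": "se", "count": "n"})
        extras = [
            c
            for c in self.replicates.columns
            if c not in (*self.axes, self.response, "replicate")
        ]
        if extras:
            first = self.replicates.groupby(list(self.axes))[extras].first().reset_index()
            out = out.merge(first, on=list(self.axes))
        return out


def _cell_rngs(seed: int, n_cells: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_cells)]


def sweep_rescan_rate(
    rates: Sequence[float] = tuple(np.round(np.arange(0.0, 0.21, 0.02), 2)),
    multipliers: Sequence[float] = (1.5, 2.0, 3.0, 4.0),
    n_batches: int = 1000,
    batch_size: int = 100,
    profile: ScannerProfile | None = None,
    seed: int = 0,
) -> SweepResult:
    """Relative batch time across a (rescan rate x multiplier) grid.

    Each cell simulates ``n_batches`` batches of ``batch_size`` slides with
    the internal-QC stage only (no external flagging), and records the
    relative time of every replicate batch alongside the closed-form
    expectation ``expected_relative_time``.
    """
    profile = profile or ScannerProfile()
    cells = [(r, m) for m in multipliers for r in rates]
    rngs = _cell_rngs(seed, len(cells))
    frames = []
    for (r, m), rng in zip(cells, rngs):
        policy = QCPolicy(
            auto_rescan_rate=r,
            rescan_multiplier=m,
            quality=QualityModel(sigma=0.0, threshold=-np.inf),
            control_rate=0.0,
        )
        rel, _ = simulate_relative_times(n_batches, batch_size, profile, policy, rng)
        frames.append(
            pd.DataFrame(
                {
                    "rescan_rate": r,
                    "multiplier": m,
                    "replicate": np.arange(n_batches),
                    "relative_time": rel,
                    "expected": expected_relative_time(
                        r, m, profile.mean_scan_s, profile.load_s,
                        rescan_includes_load=True,
                    ),
                }
            )
        )
    return SweepResult(
        axes=("rescan_rate", "multiplier"),
        response="relative_time",
        replicates=pd.concat(frames, ignore_index=True),
    )


def fit_slopes(sweep: SweepResult) -> pd.DataFrame:
    """Per-multiplier OLS slope of mean relative time versus rescan rate."""
    summ = sweep.summary()
    rows = []
    for m, grp in summ.groupby("multiplier"):
        slope, intercept = np.polyfit(grp["rescan_rate"], grp[sweep.response], 1)
        rows.append({"multiplier": m, "slope": slope, "intercept": intercept})
    return pd.DataFrame(rows)


def sweep_threshold(
    sigmas: Sequence[float] = (0.1, 0.15, 0.2, 0.25),
    thresholds: Sequence[float] = tuple(np.round(np.arange(0.0, 1.01, 0.05), 2)),
    policy: QCPolicy | None = None,
    n_batches: int = 1000,
    batch_size: int = 100,
    profile: ScannerProfile | None = None,
    seed: int = 0,
) -> SweepResult:
    """Batch time and missed-slide fraction across a (sigma x threshold) grid.

    Defaults follow the standard operating point: rescan multiplier 2.0,
    internal-QC rescan rate 0.05, control sampling off so the simulated
    missed fraction is directly comparable with the closed-form oracle,
    which is stored per cell together with the closed-form flagged fraction.
    """
    profile = profile or ScannerProfile()
    base = policy or QCPolicy(
        auto_rescan_rate=0.05,
        rescan_multiplier=2.0,
        visual_accept_prob=1.0,
        control_rate=0.0,
    )
    cells = [(s, t) for s in sigmas for t in thresholds]
    rngs = _cell_rngs(seed, len(cells))
    frames = []
    for (s, t), rng in zip(cells, rngs):
        q = dataclasses.replace(base.quality, sigma=s, threshold=t)
        pol = dataclasses.replace(base, quality=q)
        rel, missed = simulate_relative_times(n_batches, batch_size, profile, pol, rng)
        frames.append(
            pd.DataFrame(
                {
                    "sigma": s,
                    "threshold": t,
                    "replicate": np.arange(n_batches),
                    "missed_fraction": missed,
                    "relative_time": rel,
                    "missed_closed_form": missed_fraction(q),
                    "flagged_closed_form": flagged_fraction(q),
                }
            )
        )
    return SweepResult(
        axes=("sigma", "threshold"),
        response="missed_fraction",
        replicates=pd.concat(frames, ignore_index=True),
    )


@dataclass
class ScannerReport:
    """Benchmark comparison of scanners over a shared slide set.

    ``ratios`` lists each scanner's slowdown versus the fastest scanner
    under three labelled conventions: ``ratio_of_mean_raw`` (ratio of mean
    raw scan times), ``mean_per_slide_raw_ratio`` (mean of per-slide
    raw-time ratios over shared slides) and ``ratio_of_mean_normalized``
    (ratio of mean normalized times).  No single convention is canonical;
    consumers must read the label.
    """

    per_slide: pd.DataFrame
    per_scanner: pd.DataFrame
    fastest: str
    ratios: pd.DataFrame


def scanner_comparison(
    measurements: pd.DataFrame | Sequence[tuple],
) -> ScannerReport:
    """Build a scanner benchmark report from raw (scanner, slide, time, area) rows.

    Rows with a missing area are skipped with a warning (the normalized
    metric is undefined for them).  The fastest scanner is the one with the
    smallest mean normalized time.
    """
    df = (
        measurements.copy()
        if isinstance(measurements, pd.DataFrame)
        else pd.DataFrame(
            measurements, columns=["scanner", "slide", "scan_time_s", "area_mm2"]
        )
    )
    missing = df["area_mm2"].isna()
    if missing.any():
        warnings.warn(
            f"skipping {int(missing.sum())} measurement(s) with missing area",
            stacklevel=2,
        )
        df = df[~missing]
    if df.empty:
        raise ValueError("no usable measurements")
    df = df.copy()
    df["norm_time"] = [
        normalized_scan_time(t, a) for t, a in zip(df["scan_time_s"], df["area_mm2"])
    ]
    per_scanner = (
        df.groupby("scanner")
        .agg(mean_raw_s=("scan_time_s", "mean"), mean_norm_time=("norm_time", "mean"))
        .reset_index()
    )
    fastest = per_scanner.loc[per_scanner["mean_norm_time"].idxmin(), "scanner"]
    fast_df = df[df["scanner"] == fastest].set_index("slide")
    fast_row = per_scanner.set_index("scanner").loc[fastest]

    rows = []
    for _, r in per_scanner.iterrows():
        sc = r["scanner"]
        sub = df[df["scanner"] == sc].set_index("slide")
        shared = sub.index.intersection(fast_df.index)
        per_slide_ratio = (
            sub.loc[shared, "scan_time_s"] / fast_df.loc[shared, "scan_time_s"]
        ).mean()
        for convention, ratio in (
            ("ratio_of_mean_raw", r["mean_raw_s"] / fast_row["mean_raw_s"]),
            ("mean_per_slide_raw_ratio", per_slide_ratio),
            ("ratio_of_mean_normalized", r["mean_norm_time"] / fast_row["mean_norm_time"]),
        ):
            rows.append({"scanner": sc, "convention": convention, "ratio": float(ratio)})
    return ScannerReport(
        per_slide=df.reset_index(drop=True),
        per_scanner=per_scanner,
        fastest=str(fastest),
        ratios=pd.DataFrame(rows),
    )
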