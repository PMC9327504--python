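"""Latent-quality threshold classifier with closed-form miss/flag oracles.

The external QC stage is modelled as a signal-detection problem: each slide
carries a latent true quality q ~ U(0, 1); the QC algorithm observes
q + eps with eps ~ Normal(0, sigma^2) (sigma encodes the algorithm's
accuracy) and flags the slide for rescan when the observed score falls
strictly below a threshold t.  A slide is *truly bad* when q < bad_cutoff;
a bad slide whose noisy score clears the threshold is a "missed slide".

Both operating characteristics have closed forms under this model:

    missed(t, sigma)  = P(q < c, q + eps >= t) = int_0^c Phi((q - t)/sigma) dq
    flagged(t, sigma) = P(q + eps < t)         = int_0^1 Phi((t - q)/sigma) dq

using the Gaussian CDF Phi; the antiderivative of Phi is
G(z) = z*Phi(z) + phi(z), so each integral is a two-point evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "QualityModel",
    "observe_quality",
    "decide_rescan",
    "missed_fraction",
    "flagged_fraction",
    "missed_fraction_quadrature",
    "simulate_rates",
]


@dataclass
class QualityModel:
    """QC-algorithm operating point.

    Parameters
    ----------
    sigma : float
        Standard deviation of the Gaussian observation noise (the QC
        algorithm's inaccuracy). 0 means a perfect observer.
    threshold : float
        Rescan decision boundary; a slide is flagged iff its observed score
        is strictly below this value. Not restricted to [0, 1] — the noisy
        score is unbounded.
    bad_cutoff : float
        True quality below which a slide "should have been rejected".
        Default 0.05.
    """

    sigma: float = 0.15
    threshold: float = 0.1
    bad_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not 0 <= self.bad_cutoff <= 1:
            raise ValueError(f"bad_cutoff must lie in [0, 1], got {self.bad_cutoff}")


def observe_quality(
    q_true: float, model: QualityModel, rng: np.random.Generator
) -> float:
    """Noisy observation ``q_true + Normal(0, sigma^2)``; not clipped to [0, 1]."""
    if not 0 <= q_true <= 1:
        raise ValueError(f"q_true must lie in [0, 1], got {q_true}")
    if model.sigma == 0:
        return float(q_true)
    return float(q_true + rng.normal(0.0, model.sigma))


def decide_rescan(score: float, model: QualityModel) -> bool:
    """True iff ``score`` is strictly below the model threshold."""
    return score < model.threshold


def _gauss_int(z: np.ndarray | float) -> np.ndarray | float:
    """Antiderivative of the standard normal CDF: G(z) = z*Phi(z) + phi(z)."""
    z = np.asarray(z, dtype=float)
    # asymptotes: G(z) -> z as z -> +inf (Phi -> 1, phi -> 0), G(z) -> 0 as z -> -inf
    zc = np.clip(z, -40.0, 40.0)
    out = zc * norm.cdf(zc) + norm.pdf(zc)
    out = np.where(z > 40.0, z, out)
    out = np.where(z < -40.0, 0.0, out)
    return out


def missed_fraction(model: QualityModel, *, conditional: bool = False) -> float:
    """Probability that a slide is truly bad yet clears the threshold.

    Closed form of ``P(q < bad_cutoff and q + eps >= threshold)`` for
    q ~ U(0, 1).  With ``conditional=True`` the probability is divided by
    ``bad_cutoff``, giving the miss rate among bad slides instead of the
    batch-level proportion (the primary convention).
    """
    c, t, s = model.bad_cutoff, model.threshold, model.sigma
    if c == 0:
        return 0.0
    if math.isinf(t):
        joint = 0.0 if t > 0 else c
    elif s == 0:
        # indicator limit: bad slides with q >= t survive
        joint = max(0.0, c - min(max(t, 0.0), c))
    else:
        # int_0^c Phi((q-t)/s) dq = s * (G((c-t)/s) - G((0-t)/s))
        joint = float(s * (_gauss_int((c - t) / s) - _gauss_int((0.0 - t) / s)))
        joint = min(max(joint, 0.0), c)
    return joint / c if conditional else joint


def flagged_fraction(model: QualityModel) -> float:
    """Probability that a slide's noisy score falls below the threshold.

    Closed form of ``P(q + eps < threshold)`` for q ~ U(0, 1); for sigma = 0
    this is ``clamp(threshold, 0, 1)``.
    """
    t, s = model.threshold, model.sigma
    if math.isinf(t):
        return 1.0 if t > 0 else 0.0
    if s == 0:
        return min(max(t, 0.0), 1.0)
    # int_0^1 Phi((t-q)/s) dq = s * (G(t/s) - G((t-1)/s))
    val = float(s * (_gauss_int(t / s) - _gauss_int((t - 1.0) / s)))
    return min(max(val, 0.0), 1.0)


def missed_fraction_quadrature(model: QualityModel) -> float:
    """Missed fraction by adaptive quadrature of the defining integral.

    Independent numerical evaluation of ``int_0^c Phi((q - t)/sigma) dq``;
    used to cross-check the closed form.
    """
    from scipy.integrate import quad

    c, t, s = model.bad_cutoff, model.threshold, model.sigma
    if s == 0 or c == 0 or math.isinf(t):
        return missed_fraction(model)
    val, _ = quad(lambda q: norm.cdf((q - t) / s), 0.0, c, epsabs=1e-12, epsrel=1e-12)
    return float(val)


def simulate_rates(
    model: QualityModel, n: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo (missed, flagged) fractions over ``n`` simulated slides.

    Draws q ~ U(0,1) and eps ~ Normal(0, sigma^2) vectorized; returns the
    empirical counterparts of :func:`missed_fraction` (joint convention) and
    :func:`flagged_fraction`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    q = rng.uniform(0.0, 1.0, size=n)
    score = q + rng.normal(0.0, model.sigma, size=n) if model.sigma > 0 else q
    flagged = score < model.threshold
    missed = (q < model.bad_cutoff) & ~flagged
    return float(missed.mean()), float(flagged.mean())
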