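"""Signal-detection observer for the same/different pitch task.

The observer follows a differencing rule: on each trial the internal
estimate of the fo difference between the two intervals is ``D ~
Normal(shift, sigma)`` (in cents), and the response is "different" when
``|D|`` exceeds a fixed criterion ``c``.  Attention lapses occur with
probability ``lapse_rate`` and produce an unbiased coin-flip response.

The probability of responding "different" at shift Δ is therefore

    p(Δ) = (1 - λ) · [1 - (Φ((c - Δ)/σ) - Φ((-c - Δ)/σ))] + λ/2.

False alarms on catch trials (Δ = 0) emerge from the same model, so catch
accuracy and staircase behavior are controlled jointly.  ``calibrate``
solves for (σ, c) so that p(JND) equals the 2-down/1-up convergence
probability 2^(-1/2) ≈ 0.7071 and p("same" | Δ=0) equals a target catch
accuracy — giving each synthetic listener a nominal JND that is exactly
the staircase's tracked point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm


def _phi(x: float) -> float:
    """Standard normal CDF (scalar fast path)."""
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))

#: 2-down/1-up staircases converge to the stimulus level where the
#: probability of a correct response is sqrt(1/2).
CONVERGENCE_P = 2.0 ** (-0.5)

DEFAULT_LAPSE_RATE = 0.02
DEFAULT_CATCH_ACCURACY_TARGET = 0.94


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of a differencing-model same/different observer.

    sigma_cents : SD of the internal pitch-difference noise (cents).
    criterion_cents : decision criterion on |internal difference| (cents).
    lapse_rate : probability of a random (coin-flip) response.
    nominal_jnd_cents : shift at which p("different") equals the 2-down/1-up
        convergence probability; set by :func:`calibrate`.
    """

    sigma_cents: float
    criterion_cents: float
    lapse_rate: float = DEFAULT_LAPSE_RATE
    nominal_jnd_cents: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_cents <= 0:
            raise ValueError("sigma_cents must be positive")
        if self.criterion_cents <= 0:
            raise ValueError("criterion_cents must be positive")
        if not 0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5)")


def p_respond_different(observer: ObserverParams, shift_cents: float) -> float:
    """Probability that the observer responds "different" at a given shift."""
    if shift_cents < 0:
        raise ValueError("shift_cents must be non-negative")
    s, c = observer.sigma_cents, observer.criterion_cents
    base = 1.0 - (_phi((c - shift_cents) / s) - _phi((-c - shift_cents) / s))
    lam = observer.lapse_rate
    return (1.0 - lam) * base + lam * 0.5


def respond(
    observer: ObserverParams, shift_cents: float, rng: np.random.Generator
) -> str:
    """Draw a "same"/"different" response at the given fo shift.

    Catch trials use shift 0; false alarms then occur at the rate implied
    by criterion/sigma (plus lapses).
    """
    p = p_respond_different(observer, shift_cents)
    return "different" if rng.random() < p else "same"


def calibrate(
    nominal_jnd_cents: float,
    catch_accuracy_target: float = DEFAULT_CATCH_ACCURACY_TARGET,
    lapse_rate: float = DEFAULT_LAPSE_RATE,
) -> ObserverParams:
    """Solve for (sigma, criterion) hitting a JND and a catch accuracy.

    Constraints: ``p_respond_different(nominal_jnd) = 2**-0.5`` and
    ``p_respond_different(0) = 1 - catch_accuracy_target``.  The second
    constraint fixes the ratio r = criterion/sigma in closed form; the
    first is then solved for sigma by bracketed root finding.  Residuals
    are below 1e-10.

    Raises
    ------
    ValueError
        If the targets are infeasible (e.g. catch accuracy of 1, or a
        false-alarm rate at or above the convergence probability).
    """
    if nominal_jnd_cents <= 0:
        raise ValueError("nominal_jnd_cents must be positive")
    if not 0.5 < catch_accuracy_target < 1.0:
        raise ValueError("catch_accuracy_target must be in (0.5, 1)")
    if not 0 <= lapse_rate < 0.5:
        raise ValueError("lapse_rate must be in [0, 0.5)")

    lam = lapse_rate
    # lapse-corrected base rates the differencing model must produce
    base_fa = ((1.0 - catch_accuracy_target) - lam / 2.0) / (1.0 - lam)
    base_hit = (CONVERGENCE_P - lam / 2.0) / (1.0 - lam)
    if not 0.0 < base_fa < base_hit < 1.0:
        raise ValueError(
            "incompatible calibration targets: need false-alarm rate below "
            "the convergence probability after lapse correction"
        )
    # at shift 0 the base rate is 2·(1 − Φ(c/σ)), fixing r = c/σ
    r = norm.ppf(1.0 - base_fa / 2.0)

    def hit_residual(sigma: float) -> float:
        z = nominal_jnd_cents / sigma
        base = 1.0 - (_phi(r - z) - _phi(-r - z))
        return base - base_hit

    # base(sigma) decreases from 1 (sigma→0) to base_fa (sigma→∞)
    lo, hi = 1e-6 * nominal_jnd_cents, nominal_jnd_cents
    while hit_residual(hi) > 0:
        hi *= 2.0
        if hi > 1e9 * nominal_jnd_cents:  # pragma: no cover
            raise ValueError("calibration failed to bracket a solution")
    sigma = brentq(hit_residual, lo, hi, xtol=1e-14, rtol=1e-15)
    return ObserverParams(
        sigma_cents=float(sigma),
        criterion_cents=float(r * sigma),
        lapse_rate=lapse_rate,
        nominal_jnd_cents=float(nominal_jnd_cents),
    )
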