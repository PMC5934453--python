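"""Degree-based circular statistics primitives.

All public angles are in degrees. Canonical range is [0, 360); signed
differences live in (-180, 180]. Radians appear only inside trig calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "canonical",
    "wrap_diff",
    "circ_mean",
    "VonMisesTuning",
    "fit_von_mises_rate",
]

#: resultant lengths below this are treated as "no mean direction"
RESULTANT_TOL = 1e-9


def canonical(angle):
    """Wrap angle(s) into the canonical range [0, 360)."""
    return np.asarray(angle, dtype=float) % 360.0


def wrap_diff(a, b=0.0):
    """Signed angular difference ``a - b`` wrapped into (-180, 180].

    The boundary case of exactly opposite angles returns +180, never -180.
    Accepts scalars or arrays (broadcast).
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    if d.ndim == 0:
        return float(d)
    return d


def circ_mean(angles, weights=None):
    """Weighted circular mean of angles in degrees.

    Returns ``(mean_deg, resultant_length)`` where the mean is in [0, 360)
    and the resultant length is the norm of the first trigonometric moment
    (1 for identical angles, 0 for balanced antipodal configurations).
    When the resultant length is below tolerance the mean direction is
    undefined and ``nan`` is returned for it.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circ_mean requires at least one angle")
    rad = np.radians(angles)
    if weights is None:
        w = np.ones_like(rad)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.any(w > 0):
            raise ValueError("circ_mean requires at least one positive weight")
    wsum = w.sum()
    c = float(np.sum(w * np.cos(rad)) / wsum)
    s = float(np.sum(w * np.sin(rad)) / wsum)
    r = float(np.hypot(c, s))
    if r < RESULTANT_TOL:
        return float("nan"), r
    mean = float(np.degrees(np.arctan2(s, c)) % 360.0)
    if mean >= 360.0:  # guard the -0.0 % 360 float artifact
        mean = 0.0
    return mean, r


@dataclass
class VonMisesTuning:
    """Rate tuning curve ``rate(phi) = alpha * exp(beta * cos(phi - phi_star))``.

    ``phi_star`` (degrees, [0, 360)) is the preferred angle; ``beta >= 0``
    is the concentration; ``alpha`` the amplitude scale (may be negative for
    suppressive residual fits). ``reliable`` is False for degenerate fits
    (flat tuning, too few samples spanning the circle).
    """

    alpha: float
    beta: float
    phi_star: float
    reliable: bool = True
    residual_rms: float = float("nan")

    def predict(self, phi):
        rad = np.radians(np.asarray(phi, dtype=float) - self.phi_star)
        return self.alpha * np.exp(self.beta * np.cos(rad))


#: cap on the fitted concentration; spike solutions beyond this are
#: narrower than any physiological tuning and only ever fit noise
BETA_MAX = 10.0


def _vm_fit_once(phi_rad, rates, alpha0, beta0, mu0):
    def resid(p):
        a, b, mu = p
        return a * np.exp(b * np.cos(phi_rad - mu)) - rates

    sol = least_squares(resid, x0=[alpha0, beta0, mu0], method="trf",
                        bounds=([-np.inf, -BETA_MAX, -np.inf],
                                [np.inf, BETA_MAX, np.inf]),
                        max_nfev=2000)
    return sol


def fit_von_mises_rate(angles, rates, beta_flat_tol=1e-3):
    """Least-squares von Mises fit of rates against angles (degrees).

    The objective is ordinary least squares (targets may be negative after
    covariate subtraction, so a Poisson objective is not applicable).
    ``beta`` is constrained to be nonnegative by flipping ``phi_star`` by
    180 degrees when the optimizer prefers an inverted curve. Multi-start
    initialization at the rate-weighted circular mean plus 0/120/240 degree
    offsets guards against local minima.
    """
    angles = np.asarray(angles, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if angles.shape != rates.shape or angles.ndim != 1:
        raise ValueError("angles and rates must be 1-D arrays of equal length")
    if angles.size < 10:
        raise ValueError("need at least 10 samples for a von Mises fit")
    srt = np.sort(canonical(angles))
    gaps = np.diff(np.concatenate([srt, [srt[0] + 360.0]]))
    if 360.0 - gaps.max() < 180.0 - 1e-9:
        raise ValueError("angles must span at least half the circle")

    if np.ptp(rates) < 1e-12:
        # constant rates: beta -> 0, preferred angle undefined
        return VonMisesTuning(
            alpha=float(np.mean(rates)), beta=0.0, phi_star=float("nan"),
            reliable=False, residual_rms=0.0,
        )

    phi_rad = np.radians(angles)
    shifted = rates - rates.min()
    mu0_deg, _ = circ_mean(angles, weights=shifted + 1e-12)
    if np.isnan(mu0_deg):
        mu0_deg = 0.0
    alpha0 = max(float(np.mean(rates)), 1e-3)
    best = None
    for off in (0.0, 120.0, 240.0):
        mu0 = np.radians(mu0_deg + off)
        for beta0 in (0.5, 2.0):
            try:
                sol = _vm_fit_once(phi_rad, rates, alpha0, beta0, mu0)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("von Mises fit failed to converge from all starts")

    a, b, mu = best.x
    if b < 0:  # flip to the beta >= 0 parameterization
        b = -b
        mu = mu + np.pi
    phi_star = float(np.degrees(mu) % 360.0)
    rms = float(np.sqrt(2.0 * best.cost / angles.size))
    reliable = b > beta_flat_tol
    if not reliable:
        phi_star = float("nan")
    return VonMisesTuning(alpha=float(a), beta=float(b), phi_star=phi_star,
                          reliable=reliable, residual_rms=rms)
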