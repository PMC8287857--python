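"""Lapse-logistic psychometric function and the stochastic virtual observer.

The probability of a clockwise (CW) judgement of a center grating tilted
``theta`` degrees from vertical is modelled as

    p(theta) = l + (1 - 2 l) / (1 + exp(-k (theta - mu) / sigma)),

with ``k = ln(21/4) = ln(5.25)``.  Under this slope constant ``sigma`` is
exactly the 84%-correct half-width of the function: with no lapses,
``p(mu + sigma) = logistic(ln 5.25) = 5.25 / 6.25 = 0.84``.  ``mu`` is the
point of subjective equality (the orientation perceived as vertical, the
"bias" induced by the surround), and ``l`` is the lapse rate — the
probability of a stimulus-independent error, which compresses both
asymptotes to ``l`` and ``1 - l``.

Angles are degrees from vertical, clockwise positive, everywhere in this
package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import ValidationError

#: Slope constant ln(21/4); makes sigma the 84%-correct half-width.
SLOPE_CONSTANT: float = math.log(5.25)

#: Canonical response tokens (clockwise / counterclockwise).
CW = "CW"
CCW = "CCW"
RESPONSES = (CW, CCW)


@dataclass(frozen=True)
class PsychometricParams:
    """Parameter triplet (bias mu, threshold sigma, lapse rate) for one
    surround condition.

    Parameters
    ----------
    mu : float
        Perceived-vertical orientation (PSE) in degrees, CW positive.
    sigma : float
        84%-correct discrimination threshold in degrees; strictly positive.
    lapse : float
        Stimulus-independent error probability, in ``[0, 0.5)``.
    """

    mu: float
    sigma: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu)):
            raise ValidationError(f"mu must be finite, got {self.mu!r}")
        if not (math.isfinite(self.sigma) and self.sigma > 0):
            raise ValidationError(
                f"sigma must be a finite positive threshold, got {self.sigma!r}"
            )
        if not (0.0 <= self.lapse < 0.5):
            raise ValidationError(
                f"lapse must lie in [0, 0.5), got {self.lapse!r}"
            )


def prob_clockwise(params: PsychometricParams, theta):
    """Probability of a CW response to a center tilted ``theta`` degrees.

    Accepts a scalar or array ``theta`` (degrees from vertical, CW
    positive) and returns the corresponding probability in
    ``[lapse, 1 - lapse]``.  ``p(mu) = 0.5`` for any lapse rate.
    """
    if not isinstance(params, PsychometricParams):
        raise ValidationError("params must be a PsychometricParams instance")
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValidationError("theta must be finite")
    core = expit(SLOPE_CONSTANT * (theta - params.mu) / params.sigma)
    out = params.lapse + (1.0 - 2.0 * params.lapse) * core
    return float(out) if out.ndim == 0 else out


def sample_response(
    params: PsychometricParams, theta: float, rng: np.random.Generator
) -> str:
    """Draw one CW/CCW response of the virtual observer at ``theta``.

    The response is a Bernoulli draw with success probability
    ``prob_clockwise(params, theta)``; identical generator state yields
    identical sequences.
    """
    p = prob_clockwise(params, theta)
    return CW if rng.random() < p else CCW


def normalize_response(token: str) -> str:
    """Map a response token to its canonical form (case-insensitive)."""
    t = str(token).strip().upper()
    if t not in RESPONSES:
        raise ValidationError(f"unknown response token {token!r}; expected CW or CCW")
    return t
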