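"""Bayesian estimation of psychometric parameters on a dense grid.

The posterior over (mu, sigma, lapse) combines a Bernoulli likelihood of
the CW/CCW responses under the lapse-logistic model with the priors used
in the analysis: lapse ~ Beta(1.2, 15), sigma ~ Gamma(shape 2.5, scale
2.5) and mu uniform on a configurable window (default [-25, +25] deg, just
beyond the +/-21 deg staircase starts).

Estimates are posterior means obtained by deterministic marginalization on
a dense rectangular grid (default 121 x 81 x 61 points over mu in
[-25, 25], sigma in (0, 20], lapse in (0, 0.35]).  The grid makes the fit
exactly reproducible, cheap, and testable for refinement stability; the
posterior mean is preferred over the MAP because staircase sampling
concentrates trials near the PSE and can leave plateaued posteriors.

Note the Gamma(2.5, 2.5) prior is read in the shape-scale convention
(mean 6.25 deg): plausible vertical-orientation thresholds under strong
surrounds (a few degrees) sit inside its bulk, whereas the shape-rate
reading (mean 1 deg) concentrates mass implausibly low.  The convention is
configurable through :class:`PriorSpec`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .errors import ValidationError
from .psychometric import CW, SLOPE_CONSTANT, PsychometricParams, normalize_response
from .staircase import SURROUNDS, TrialRecord

#: Lapse rate above which a single fit is QC-flagged as high-lapse.
QC_LAPSE_THRESHOLD = 0.20


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the Bayesian fit.

    ``lapse_beta``: (a, b) of the Beta prior on the lapse rate.
    ``sigma_gamma``: (shape, scale) of the Gamma prior on the threshold.
    ``mu_bounds``: support of the uniform prior on the bias, degrees.
    """

    lapse_beta: tuple[float, float] = (1.2, 15.0)
    sigma_gamma: tuple[float, float] = (2.5, 2.5)
    mu_bounds: tuple[float, float] = (-25.0, 25.0)

    def __post_init__(self) -> None:
        a, b = self.lapse_beta
        k, s = self.sigma_gamma
        lo, hi = self.mu_bounds
        if not (a > 0 and b > 0 and k > 0 and s > 0):
            raise ValidationError("prior shape/scale parameters must be positive")
        if not lo < hi:
            raise ValidationError("mu_bounds must be an increasing interval")


@dataclass(frozen=True)
class GridSpec:
    """Resolution and extent of the posterior grid.

    sigma and lapse grids are open at zero (first point one spacing above
    0) so the likelihood and priors stay finite.
    """

    n_mu: int = 121
    n_sigma: int = 81
    n_lapse: int = 61
    sigma_max: float = 20.0
    lapse_max: float = 0.35

    def __post_init__(self) -> None:
        if min(self.n_mu, self.n_sigma, self.n_lapse) < 3:
            raise ValidationError("grid needs at least 3 points per axis")
        if not (self.sigma_max > 0 and 0 < self.lapse_max < 0.5):
            raise ValidationError("invalid grid extents")

    def axes(self, priors: PriorSpec):
        # mu: closed interval; sigma/lapse: cell midpoints of (0, max],
        # which keeps the integrand off the singular boundary and makes
        # the marginal means second-order accurate in the spacing
        mu = np.linspace(priors.mu_bounds[0], priors.mu_bounds[1], self.n_mu)
        sigma = (np.arange(self.n_sigma) + 0.5) * (self.sigma_max / self.n_sigma)
        lapse = (np.arange(self.n_lapse) + 0.5) * (self.lapse_max / self.n_lapse)
        return mu, sigma, lapse


@dataclass(frozen=True)
class FitResult:
    """Posterior summaries for one subject x condition x measurement x
    surround cell."""

    mu_hat: float
    sigma_hat: float
    lapse_hat: float
    mu_sd: float
    sigma_sd: float
    lapse_sd: float
    n_trials: int
    surround_deg: int | None = None
    qc_flag: bool = False

    @property
    def log10_lapse(self) -> float:
        return float(np.log10(self.lapse_hat))


def _extract_trials(trials) -> tuple[np.ndarray, np.ndarray]:
    """Return (theta, is_cw) arrays from a trial table, records, or pairs."""
    if isinstance(trials, pd.DataFrame):
        theta = trials["center_deg"].to_numpy(dtype=float)
        resp = [normalize_response(r) for r in trials["response"]]
    else:
        theta_list, resp = [], []
        for t in trials:
            if isinstance(t, TrialRecord):
                theta_list.append(t.center_deg)
                resp.append(normalize_response(t.response))
            else:
                th, r = t
                theta_list.append(float(th))
                resp.append(normalize_response(r))
        theta = np.asarray(theta_list, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValidationError("trial center orientations must be finite")
    is_cw = np.array([r == CW for r in resp], dtype=bool)
    return theta, is_cw


def _log_prior_axes(priors: PriorSpec, mu, sigma, lapse):
    a, b = priors.lapse_beta
    shape, scale = priors.sigma_gamma
    lp_mu = np.full_like(mu, -np.log(priors.mu_bounds[1] - priors.mu_bounds[0]))
    lp_sigma = sps.gamma.logpdf(sigma, a=shape, scale=scale)
    lp_lapse = sps.beta.logpdf(lapse, a, b)
    return lp_mu, lp_sigma, lp_lapse


def log_posterior(
    params: PsychometricParams,
    trials,
    priors: PriorSpec | None = None,
    *,
    allow_empty: bool = False,
) -> float:
    """Unnormalized log posterior density at a single parameter point.

    Returns ``-inf`` (by contract, not an exception) when the point lies
    outside the prior support.  With ``allow_empty`` the likelihood term
    vanishes and the value is the log prior alone.
    """
    priors = priors or PriorSpec()
    theta, is_cw = _extract_trials(trials)
    if theta.size == 0 and not allow_empty:
        raise ValidationError("empty trial list (pass allow_empty=True for a prior-only value)")
    lo, hi = priors.mu_bounds
    if not (lo <= params.mu <= hi):
        return -np.inf
    a, b = priors.lapse_beta
    shape, scale = priors.sigma_gamma
    lp = (
        -np.log(hi - lo)
        + sps.gamma.logpdf(params.sigma, a=shape, scale=scale)
        + sps.beta.logpdf(params.lapse, a, b)
    )
    if not np.isfinite(lp):
        return -np.inf
    if theta.size:
        p = params.lapse + (1.0 - 2.0 * params.lapse) * expit(
            SLOPE_CONSTANT * (theta - params.mu) / params.sigma
        )
        lp += float(np.sum(np.log(np.where(is_cw, p, 1.0 - p))))
    return float(lp)


def _posterior_cube(theta, is_cw, priors: PriorSpec, grid: GridSpec):
    """Log posterior on the full (lapse, mu, sigma) grid."""
    mu, sigma, lapse = grid.axes(priors)
    lp_mu, lp_sigma, lp_lapse = _log_prior_axes(priors, mu, sigma, lapse)
    ll = (
        lp_lapse[:, None, None]
        + lp_mu[None, :, None]
        + lp_sigma[None, None, :]
    ).astype(float)
    if theta.size:
        # Aggregate duplicate levels: staircase levels live on a coarse
        # lattice, so the per-level Bernoulli counts make the likelihood
        # cost proportional to the number of distinct levels, not trials.
        levels, inv = np.unique(theta, return_inverse=True)
        n_tot = np.bincount(inv, minlength=levels.size).astype(float)
        n_cw = np.bincount(inv, weights=is_cw.astype(float), minlength=levels.size)
        l3 = lapse[:, None, None]
        one_minus_2l = 1.0 - 2.0 * l3
        inv_sigma = 1.0 / sigma[None, :]
        work = np.empty((lapse.size, mu.size, sigma.size))
        for lev, ncw, ntot in zip(levels, n_cw, n_tot):
            core = expit(SLOPE_CONSTANT * (lev - mu)[:, None] * inv_sigma)
            np.multiply(one_minus_2l, core[None, :, :], out=work)
            work += l3
            if ncw:
                ll += ncw * np.log(work)
            if ntot - ncw:
                np.subtract(1.0, work, out=work)
                ll += (ntot - ncw) * np.log(work)
    return ll, (mu, sigma, lapse)


def fit_psychometric(
    trials,
    priors: PriorSpec | None = None,
    grid: GridSpec | None = None,
    *,
    allow_empty: bool = False,
    surround_deg: int | None = None,
) -> FitResult:
    """Fit the psychometric function to one cell of trials.

    Returns posterior means and marginal posterior SDs of (mu, sigma,
    lapse).  The fit is deterministic for fixed input and grid.  The
    ``qc_flag`` marks high-lapse fits (lapse_hat > 0.20).
    """
    priors = priors or PriorSpec()
    grid = grid or GridSpec()
    theta, is_cw = _extract_trials(trials)
    if theta.size == 0 and not allow_empty:
        raise ValidationError("cannot fit an empty trial list")
    if theta.size and (is_cw.all() or (~is_cw).all()):
        logging.getLogger(__name__).warning(
            "all %d responses identical (%s); the priors regularize this fit "
            "but the estimates deserve QC scrutiny",
            theta.size,
            "CW" if is_cw.all() else "CCW",
        )
    ll, (mu, sigma, lapse) = _posterior_cube(theta, is_cw, priors, grid)
    ll -= ll.max()
    w = np.exp(ll)
    total = w.sum()
    w_mu = w.sum(axis=(0, 2)) / total
    w_sigma = w.sum(axis=(0, 1)) / total
    w_lapse = w.sum(axis=(1, 2)) / total

    def _moments(axis, weights):
        m = float(np.dot(weights, axis))
        v = float(np.dot(weights, (axis - m) ** 2))
        return m, np.sqrt(max(v, 0.0))

    mu_hat, mu_sd = _moments(mu, w_mu)
    sigma_hat, sigma_sd = _moments(sigma, w_sigma)
    lapse_hat, lapse_sd = _moments(lapse, w_lapse)
    return FitResult(
        mu_hat=mu_hat,
        sigma_hat=sigma_hat,
        lapse_hat=lapse_hat,
        mu_sd=mu_sd,
        sigma_sd=sigma_sd,
        lapse_sd=lapse_sd,
        n_trials=int(theta.size),
        surround_deg=surround_deg,
        qc_flag=bool(lapse_hat > QC_LAPSE_THRESHOLD),
    )


def normalize_block_biases(fits: Sequence[FitResult]) -> list[FitResult]:
    """Zero-center the seven bias estimates of one measurement block.

    The block mean of ``mu_hat`` is subtracted from each fit, removing any
    overall miscalibration of the observer's internal vertical; all other
    fields are unchanged.  Requires exactly one fit per surround.
    """
    fits = list(fits)
    if len(fits) != len(SURROUNDS):
        raise ValidationError(f"expected {len(SURROUNDS)} fits, got {len(fits)}")
    seen = [f.surround_deg for f in fits]
    if sorted(seen) != sorted(SURROUNDS):
        raise ValidationError(f"fits must cover each surround exactly once, got {seen}")
    mean_mu = float(np.mean([f.mu_hat for f in fits]))
    return [replace(f, mu_hat=f.mu_hat - mean_mu) for f in fits]


def fit_trial_table(
    trials: pd.DataFrame,
    priors: PriorSpec | None = None,
    grid: GridSpec | None = None,
    *,
    normalize: bool = True,
) -> pd.DataFrame:
    """Fit every (subject, condition, measurement, surround) cell of a
    trial table and return a tidy fits table.

    With ``normalize`` the seven biases of each measurement block are
    zero-centered, as in the analysis pipeline.
    """
    required = {"subject_id", "condition", "measurement_index", "surround_deg"}
    missing = required - set(trials.columns)
    if missing:
        raise ValidationError(f"trial table missing columns: {sorted(missing)}")
    rows = []
    keys = ["subject_id", "condition", "measurement_index"]
    for (subj, cond, meas), block in trials.groupby(keys, sort=True):
        fits = []
        for surround, cell in block.groupby("surround_deg", sort=True):
            fits.append(
                fit_psychometric(cell, priors, grid, surround_deg=int(surround))
            )
        if normalize and len(fits) == len(SURROUNDS):
            fits = normalize_block_biases(fits)
        for f in fits:
            rows.append(
                {
                    "subject_id": subj,
                    "condition": cond,
                    "measurement_index": meas,
                    "surround_deg": f.surround_deg,
                    "mu_hat": f.mu_hat,
                    "sigma_hat": f.sigma_hat,
                    "lapse_hat": f.lapse_hat,
                    "log10_lapse": f.log10_lapse,
                    "mu_sd": f.mu_sd,
                    "sigma_sd": f.sigma_sd,
                    "lapse_sd": f.lapse_sd,
                    "n_trials": f.n_trials,
                    "qc_flag": f.qc_flag,
                }
            )
    return pd.DataFrame(rows)
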