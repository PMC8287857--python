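"""Summary variables and the statistical battery of the tilt-illusion
analysis.

Per measurement block the seven per-surround fits are reduced to four
absolute-orientation levels (0, 15, 30, 75 deg):

* bias: half-difference ``(mu(+s) - mu(-s)) / 2`` so that repulsion
  (perceived shift away from the surround tilt) is positive; the 0-deg
  level uses the single 0-deg fit's (block-adjusted) bias directly.
* threshold: mean of the two symmetric surrounds' sigma estimates.
* lapse: mean of the two symmetric surrounds' log10 lapse rates.

The battery comprises a two-way within-subject ANOVA (Condition x
Orientation) with Greenhouse-Geisser (box epsilon-hat) sphericity
correction, Bonferroni-corrected paired t contrasts per orientation,
one-sample t tests of the 75-deg attraction effect against zero, Pearson
bias-threshold correlations (family of 12), and the lapse-based QC rule
flagging a measurement when at least 4 of its 7 fits have lapse above
0.20.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

from .errors import ValidationError
from .fitting import QC_LAPSE_THRESHOLD, FitResult
from .staircase import SURROUNDS

#: Absolute surround orientations entering the four-level analyses.
ABS_SURROUNDS = (0, 15, 30, 75)

#: Minimum count of high-lapse fits (of 7) that flags a measurement.
QC_MIN_HIGH = 4


# ---------------------------------------------------------------------------
# Summary variables


def summarize_block(block: pd.DataFrame) -> pd.DataFrame:
    """Reduce one measurement block (7 rows: surround_deg, mu, sigma,
    lapse) to the four absolute-orientation summary rows.

    Expects block-adjusted biases (mean-zero across the seven surrounds).
    """
    cols = {"surround_deg", "mu", "sigma", "lapse"}
    missing = cols - set(block.columns)
    if missing:
        raise ValidationError(f"block table missing columns: {sorted(missing)}")
    got = sorted(int(s) for s in block["surround_deg"])
    if got != sorted(SURROUNDS):
        raise ValidationError(
            f"block must contain each surround exactly once, got {got}"
        )
    by = block.set_index(block["surround_deg"].astype(int))
    rows = []
    for s in ABS_SURROUNDS:
        if s == 0:
            bias = float(by.loc[0, "mu"])
            thr = float(by.loc[0, "sigma"])
            lap = float(np.log10(by.loc[0, "lapse"]))
        else:
            bias = float(by.loc[s, "mu"] - by.loc[-s, "mu"]) / 2.0
            thr = float(by.loc[s, "sigma"] + by.loc[-s, "sigma"]) / 2.0
            lap = float(np.log10(by.loc[s, "lapse"]) + np.log10(by.loc[-s, "lapse"])) / 2.0
        rows.append(
            {"abs_surround": s, "bias": bias, "threshold": thr, "log10_lapse": lap}
        )
    return pd.DataFrame(rows)


def summarize_condition(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Summary rows for one measurement given its seven (adjusted) fits."""
    fits = list(fits)
    if len(fits) != len(SURROUNDS):
        raise ValidationError(f"expected {len(SURROUNDS)} fits, got {len(fits)}")
    block = pd.DataFrame(
        {
            "surround_deg": [f.surround_deg for f in fits],
            "mu": [f.mu_hat for f in fits],
            "sigma": [f.sigma_hat for f in fits],
            "lapse": [f.lapse_hat for f in fits],
        }
    )
    return summarize_block(block)


def summarize_fits_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Tidy summary table from a fits table (one row per subject x
    condition x measurement x surround, as written by the fitter)."""
    rows = []
    keys = ["subject_id", "condition", "measurement_index"]
    for (subj, cond, meas), block in fits.groupby(keys, sort=True):
        summ = summarize_block(
            block.rename(
                columns={"mu_hat": "mu", "sigma_hat": "sigma", "lapse_hat": "lapse"}
            )
        )
        summ.insert(0, "subject_id", subj)
        summ.insert(1, "condition", cond)
        summ.insert(2, "measurement_index", meas)
        rows.append(summ)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with Greenhouse-Geisser correction


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    df_num: int
    df_den: int
    F: float
    p_uncorrected: float
    ehat: float
    p_gg: float

    def format(self) -> str:
        return (
            f"{self.effect}: F({self.df_num}, {self.df_den}) = {self.F:.2f}, "
            f"p = {self.p_uncorrected:.4f}, ehat = {self.ehat:.2f}, "
            f"p-GG = {self.p_gg:.4f}"
        )


def _gg_epsilon(data: np.ndarray, contrast: np.ndarray) -> float:
    """Box epsilon-hat from per-subject vectors and an orthonormal
    contrast matrix (rows span the effect subspace)."""
    cov = np.cov(data, rowvar=False, ddof=1)
    e = contrast @ cov @ contrast.T
    d = contrast.shape[0]
    return float(np.trace(e) ** 2 / (d * np.sum(e * e)))


def rm_anova_gg(
    table: pd.DataFrame,
    dv: str = "value",
    within: tuple[str, str] = ("condition", "orientation"),
    subject: str = "subject_id",
) -> list[AnovaResult]:
    """Two-way fully within-subject ANOVA with GG-adjusted p values.

    ``table`` must be a complete balanced long table (every subject
    observed once in every factor-level combination; complete cases only).
    Returns the two main effects and their interaction, each with nominal
    dfs, F, uncorrected p, Greenhouse-Geisser epsilon-hat, and the
    epsilon-adjusted p value.
    """
    fa, fb = within
    for col in (subject, fa, fb, dv):
        if col not in table.columns:
            raise ValidationError(f"ANOVA table missing column {col!r}")
    wide = table.pivot_table(
        index=subject, columns=[fa, fb], values=dv, aggfunc="count"
    )
    if wide.isna().any().any() or (wide != 1).any().any():
        raise ValidationError(
            "ANOVA table must be complete and balanced (one observation per "
            "subject per cell); analyze complete cases only"
        )
    y = (
        table.pivot_table(index=subject, columns=[fa, fb], values=dv)
        .sort_index(axis=1)
    )
    n = y.shape[0]
    a = y.columns.get_level_values(0).nunique()
    b = y.columns.get_level_values(1).nunique()
    if n < 3:
        raise ValidationError(f"need at least 3 subjects, got {n}")
    cube = y.to_numpy().reshape(n, a, b)

    grand = cube.mean()
    subj_m = cube.mean(axis=(1, 2))
    a_m = cube.mean(axis=(0, 2))
    b_m = cube.mean(axis=(0, 1))
    as_m = cube.mean(axis=2)
    bs_m = cube.mean(axis=1)
    ab_m = cube.mean(axis=0)

    ss_a = n * b * np.sum((a_m - grand) ** 2)
    ss_b = n * a * np.sum((b_m - grand) ** 2)
    ss_as = b * np.sum((as_m - subj_m[:, None] - a_m[None, :] + grand) ** 2)
    ss_bs = a * np.sum((bs_m - subj_m[:, None] - b_m[None, :] + grand) ** 2)
    ss_ab = n * np.sum((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2)
    resid = (
        cube
        - as_m[:, :, None]
        - bs_m[:, None, :]
        - ab_m[None, :, :]
        + subj_m[:, None, None]
        + a_m[None, :, None]
        + b_m[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    ca = helmert(a)
    cb = helmert(b)
    eps_a = _gg_epsilon(cube.mean(axis=2), ca)
    eps_b = _gg_epsilon(cube.mean(axis=1), cb)
    eps_ab = _gg_epsilon(cube.reshape(n, a * b), np.kron(ca, cb))

    results = []
    for name, ss_eff, ss_err, d_eff, eps in (
        (fa.capitalize(), ss_a, ss_as, a - 1, eps_a),
        (fb.capitalize(), ss_b, ss_bs, b - 1, eps_b),
        (
            f"{fa.capitalize()} x {fb.capitalize()}",
            ss_ab,
            ss_abs,
            (a - 1) * (b - 1),
            eps_ab,
        ),
    ):
        d_err = d_eff * (n - 1)
        f_val = (ss_eff / d_eff) / (ss_err / d_err)
        p_unc = float(sps.f.sf(f_val, d_eff, d_err))
        p_gg = float(sps.f.sf(f_val, d_eff * eps, d_err * eps))
        results.append(
            AnovaResult(
                effect=name,
                df_num=d_eff,
                df_den=d_err,
                F=float(f_val),
                p_uncorrected=p_unc,
                ehat=eps,
                p_gg=p_gg,
            )
        )
    return results


def format_anova_report(results: Sequence[AnovaResult], title: str = "") -> str:
    """Text report in the conventional F(df1, df2) = ..., p = ... style."""
    lines = [title] if title else []
    lines += [r.format() for r in results]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# t tests, correlations, corrections


def paired_t(x, y) -> tuple[float, int, float]:
    """Two-sided paired t test; returns (t, df, p) with df = n - 1.

    Identical samples give t = 0 with p = 1 by convention; a nonzero mean
    difference with zero variance is rejected (t undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired_t needs two equal-length 1-D samples")
    n = x.size
    if n < 2:
        raise ValidationError("paired_t needs at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, n - 1, 1.0
        raise ValidationError("zero variance of nonzero differences: t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return float(t), n - 1, p


def one_sample_t(x, ref: float = 0.0) -> tuple[float, int, float]:
    """Two-sided one-sample t test of the mean against ``ref``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("one_sample_t needs a 1-D sample of size >= 2")
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0:
        if np.all(x == ref):
            return 0.0, n - 1, 1.0
        raise ValidationError("zero-variance sample off the reference: t undefined")
    t = (x.mean() - ref) / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return float(t), n - 1, p


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t approximation.

    Constant input yields (nan, nan): the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("pearson_r needs two equal-length samples of size >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt(np.sum(xd**2) * np.sum(yd**2))
    if denom == 0:
        return float("nan"), float("nan")
    r = float(np.sum(xd * yd) / denom)
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return r, p


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance level alpha / m."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha!r}")
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValidationError(f"number of comparisons must be >= 1, got {m!r}")
    return alpha / m


# ---------------------------------------------------------------------------
# Battery pieces operating on summary tables


def anova_table(summaries: pd.DataFrame, dv: str) -> pd.DataFrame:
    """Long ANOVA table (subject, condition, orientation, value) for one
    dependent variable of a summary table."""
    if dv not in ("bias", "threshold", "log10_lapse"):
        raise ValidationError(f"unknown dependent variable {dv!r}")
    out = summaries[["subject_id", "condition", "abs_surround", dv]].rename(
        columns={"abs_surround": "orientation", dv: "value"}
    )
    return out


def condition_contrasts(
    summaries: pd.DataFrame,
    dv: str = "bias",
    pair: tuple[str, str] = ("alcohol", "placebo"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t contrasts of two conditions at each absolute orientation,
    Bonferroni-corrected across the four orientations."""
    adj = bonferroni_alpha(alpha, len(ABS_SURROUNDS))
    rows = []
    for s in ABS_SURROUNDS:
        sub = summaries[summaries["abs_surround"] == s]
        wide = sub.pivot_table(index="subject_id", columns="condition", values=dv)
        if any(c not in wide.columns for c in pair):
            raise ValidationError(f"conditions {pair} not both present at {s} deg")
        wide = wide.dropna(subset=list(pair))
        t, df, p = paired_t(wide[pair[0]].to_numpy(), wide[pair[1]].to_numpy())
        rows.append(
            {
                "abs_surround": s,
                "contrast": f"{pair[0]} - {pair[1]}",
                "t": t,
                "df": df,
                "p": p,
                "alpha_bonferroni": adj,
                "significant": p < adj,
            }
        )
    return pd.DataFrame(rows)


def attraction_tests(summaries: pd.DataFrame, surround: int = 75) -> pd.DataFrame:
    """One-sample t tests of the (weak, attractive) bias at the given
    absolute surround against a zero reference, per condition."""
    rows = []
    sub = summaries[summaries["abs_surround"] == surround]
    for cond, grp in sub.groupby("condition", sort=True):
        t, df, p = one_sample_t(grp["bias"].to_numpy(), 0.0)
        rows.append({"condition": cond, "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)


def bias_threshold_correlations(
    summaries: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson correlations between bias and threshold across subjects,
    one per (condition, orientation) cell — a family of 12 comparisons
    under Bonferroni correction."""
    conditions = sorted(summaries["condition"].unique())
    m = len(conditions) * len(ABS_SURROUNDS)
    adj = bonferroni_alpha(alpha, m)
    rows = []
    for cond in conditions:
        for s in ABS_SURROUNDS:
            cell = summaries[
                (summaries["condition"] == cond) & (summaries["abs_surround"] == s)
            ]
            if cell["subject_id"].nunique() < 3:
                raise ValidationError("correlations need at least 3 subjects")
            r, p = pearson_r(cell["bias"].to_numpy(), cell["threshold"].to_numpy())
            rows.append(
                {
                    "condition": cond,
                    "abs_surround": s,
                    "r": r,
                    "p": p,
                    "alpha_bonferroni": adj,
                    "significant": bool(p < adj) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)


def qc_measurement(fits: Sequence[FitResult]) -> tuple[bool, int]:
    """Lapse-based QC of one measurement block: flag it when at least 4 of
    the 7 surround fits have lapse above 0.20 (the observer responded
    near-randomly for much of the block).  Returns (flagged, count)."""
    fits = list(fits)
    if len(fits) != len(SURROUNDS):
        raise ValidationError(f"expected {len(SURROUNDS)} fits, got {len(fits)}")
    n_high = sum(1 for f in fits if f.lapse_hat > QC_LAPSE_THRESHOLD)
    return n_high >= QC_MIN_HIGH, n_high
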