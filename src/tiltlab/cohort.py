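"""Synthetic cohorts with the statistical structure of the alcohol
tilt-illusion study.

A cohort assigns every subject, condition (sober / placebo / alcohol) and
measurement a true psychometric parameter triplet per signed surround.
The default effect profile encodes the study's qualitative finding
pattern: symmetric repulsive bias at 15 and 30 deg surrounds, a small
attraction at 75 deg, roughly zero bias with a collinear (0 deg)
surround; alcohol selectively increases the repulsion at 15 and 30 deg,
raises discrimination thresholds at all surrounds, and multiplies lapse
rates globally, while leaving the 75-deg attraction and the 0-deg bias
untouched.  Placebo changes nothing in truth.  Magnitudes are explicit
modelling assumptions (the study reports its group effects only
graphically), chosen to sit in the typical range of tilt-illusion
psychophysics: peak repulsion of 2-3 deg, attraction a fraction of a
degree, vertical-discrimination thresholds of ~2-3 deg.

Randomness is layered: subject-level deviations (internal-vertical
offset, idiosyncratic repulsion strength, threshold and lapse offsets)
persist across conditions, while session-level noise varies per
measurement cell and represents everything that makes a repeated
measurement differ (state fluctuations plus, at the summary level,
trial-sampling and estimation error).  Seeds follow a spawn hierarchy
from the master seed, so truth tables and full trial tables are
byte-identical across runs with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fitting import GridSpec, PriorSpec, fit_trial_table
from .psychometric import PsychometricParams
from .staircase import CONDITIONS, SURROUNDS, pair_staircases
from . import stats as tl_stats

#: Column order of the canonical trial table.
TRIAL_COLUMNS = [
    "subject_id",
    "condition",
    "measurement_index",
    "surround_deg",
    "staircase_id",
    "trial_index",
    "center_deg",
    "response",
]


@dataclass(frozen=True)
class EffectProfile:
    """True parameter structure of a synthetic cohort (degrees throughout).

    ``bias_base``/``sigma_base`` map absolute surround to baseline
    repulsive bias (negative = attraction) and threshold; alcohol deltas
    act on top of them as described in the module docstring.
    """

    bias_base: dict = field(
        default_factory=lambda: {0: 0.0, 15: 2.5, 30: 2.0, 75: -0.5}
    )
    sigma_base: dict = field(
        default_factory=lambda: {0: 2.0, 15: 2.6, 30: 2.4, 75: 2.2}
    )
    lapse_base: float = 0.04
    bias_delta_15: float = 1.2
    bias_delta_30: float = 1.0
    threshold_delta: float = 0.8
    lapse_multiplier: float = 2.5
    placebo_bias_delta: float = 0.0
    placebo_threshold_delta: float = 0.0
    placebo_lapse_multiplier: float = 1.0
    subject_vertical_sd: float = 1.0
    subject_bias_sd: float = 0.8
    subject_sigma_sd: float = 0.5
    subject_loglapse_sd: float = 0.35
    session_bias_sd: float = 0.5
    session_sigma_sd: float = 0.3
    session_loglapse_sd: float = 0.15
    sigma_floor: float = 0.8
    lapse_bounds: tuple[float, float] = (0.005, 0.30)

    def __post_init__(self) -> None:
        if sorted(self.bias_base) != [0, 15, 30, 75]:
            raise ValidationError("bias_base must cover absolute surrounds 0/15/30/75")
        if sorted(self.sigma_base) != [0, 15, 30, 75]:
            raise ValidationError("sigma_base must cover absolute surrounds 0/15/30/75")
        if any(v <= 0 for v in self.sigma_base.values()):
            raise ValidationError("baseline thresholds must be positive")
        lo, hi = self.lapse_bounds
        if not (0 < lo < hi < 0.35):
            raise ValidationError("lapse_bounds must satisfy 0 < lo < hi < 0.35")
        if not lo <= self.lapse_base <= hi:
            raise ValidationError("lapse_base must lie inside lapse_bounds")
        if self.lapse_multiplier <= 0 or self.placebo_lapse_multiplier <= 0:
            raise ValidationError("lapse multipliers must be positive")
        if self.sigma_floor <= 0:
            raise ValidationError("sigma_floor must be positive")

    def condition_deltas(self, condition: str, abs_surround: int):
        """(bias delta, threshold delta, lapse multiplier) for a cell."""
        if condition == "alcohol":
            bias = {15: self.bias_delta_15, 30: self.bias_delta_30}.get(abs_surround, 0.0)
            return bias, self.threshold_delta, self.lapse_multiplier
        if condition == "placebo":
            bias = (
                self.placebo_bias_delta if abs_surround in (15, 30) else 0.0
            )
            return bias, self.placebo_threshold_delta, self.placebo_lapse_multiplier
        return 0.0, 0.0, 1.0


def null_profile(**overrides) -> EffectProfile:
    """Profile with no condition effects anywhere (for calibration runs)."""
    return EffectProfile(
        bias_delta_15=0.0,
        bias_delta_30=0.0,
        threshold_delta=0.0,
        lapse_multiplier=1.0,
        **overrides,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Size and session structure of a synthetic study."""

    master_seed: int
    n_subjects: int = 26
    conditions: tuple = CONDITIONS
    alcohol_measurements: int = 1

    def __post_init__(self) -> None:
        if not (isinstance(self.master_seed, (int, np.integer)) and self.master_seed >= 0):
            raise ValidationError("master_seed must be a non-negative integer")
        if self.n_subjects < 3:
            raise ValidationError("need at least 3 subjects")
        if not 1 <= self.alcohol_measurements <= 3:
            raise ValidationError("alcohol_measurements must be 1, 2, or 3")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValidationError(f"unknown conditions: {sorted(unknown)}")


def _measurements(spec: CohortSpec, condition: str) -> range:
    return range(1, (spec.alcohol_measurements if condition == "alcohol" else 1) + 1)


def make_cohort(spec: CohortSpec, profile: EffectProfile | None = None) -> pd.DataFrame:
    """Draw the true psychometric parameters of every measurement cell.

    Returns a truth table with one row per subject x condition x
    measurement x signed surround, reproducible under ``master_seed``.
    """
    profile = profile or EffectProfile()
    root = np.random.SeedSequence([int(spec.master_seed), 0])
    subject_seqs = root.spawn(spec.n_subjects)
    rows = []
    for i, seq in enumerate(subject_seqs):
        rng = np.random.default_rng(seq)
        subj = f"S{i + 1:02d}"
        vertical = rng.normal(0.0, profile.subject_vertical_sd)
        repulsion_dev = {
            s: rng.normal(0.0, profile.subject_bias_sd) for s in (15, 30, 75)
        }
        sigma_dev = rng.normal(0.0, profile.subject_sigma_sd)
        loglapse_dev = rng.normal(0.0, profile.subject_loglapse_sd)
        for condition in spec.conditions:
            for meas in _measurements(spec, condition):
                for surround in SURROUNDS:
                    s_abs = abs(surround)
                    d_bias, d_thr, mult = profile.condition_deltas(condition, s_abs)
                    eps_b = rng.normal(0.0, profile.session_bias_sd)
                    eps_s = rng.normal(0.0, profile.session_sigma_sd)
                    eps_l = rng.normal(0.0, profile.session_loglapse_sd)
                    if s_abs == 0:
                        mu = vertical + eps_b
                    else:
                        b_true = profile.bias_base[s_abs] + d_bias + repulsion_dev[s_abs]
                        mu = vertical + np.sign(surround) * b_true + eps_b
                    sigma = max(
                        profile.sigma_floor,
                        profile.sigma_base[s_abs] + sigma_dev + d_thr + eps_s,
                    )
                    lo, hi = profile.lapse_bounds
                    lapse = float(
                        np.clip(
                            profile.lapse_base * mult * np.exp(loglapse_dev + eps_l),
                            lo,
                            hi,
                        )
                    )
                    rows.append(
                        {
                            "subject_id": subj,
                            "condition": condition,
                            "measurement_index": meas,
                            "surround_deg": surround,
                            "mu_true": float(mu),
                            "sigma_true": float(sigma),
                            "lapse_true": lapse,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_study(truth: pd.DataFrame, master_seed: int) -> pd.DataFrame:
    """Run the paired-staircase session of every measurement cell.

    Each (subject, condition, measurement) block yields 560 trials: 80 per
    surround (two interleaved 40-trial tracks).  Byte-identical under the
    same seed and truth table.
    """
    required = {
        "subject_id", "condition", "measurement_index", "surround_deg",
        "mu_true", "sigma_true", "lapse_true",
    }
    missing = required - set(truth.columns)
    if missing:
        raise ValidationError(f"truth table missing columns: {sorted(missing)}")
    root = np.random.SeedSequence([int(master_seed), 1])
    seqs = iter(root.spawn(len(truth)))
    frames = []
    for row in truth.itertuples(index=False):
        observer = PsychometricParams(
            mu=row.mu_true, sigma=row.sigma_true, lapse=row.lapse_true
        )
        rng = np.random.default_rng(next(seqs))
        records = pair_staircases(
            observer,
            int(row.surround_deg),
            rng,
            subject_id=row.subject_id,
            condition=row.condition,
            measurement_index=int(row.measurement_index),
        )
        frames.append(pd.DataFrame([r.__dict__ for r in records]))
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_COLUMNS]


def truth_summaries(truth: pd.DataFrame) -> pd.DataFrame:
    """Summary variables computed directly from true parameters.

    Applies the same block mean-zero bias adjustment and half-difference /
    symmetric-mean reduction as the fitted pipeline, but on the generating
    truth.  The generator's session-level noise plays the role of the
    combined session-state, trial-sampling and estimation variability, so
    these summaries calibrate the statistical battery without the cost of
    trial simulation and fitting.
    """
    rows = []
    keys = ["subject_id", "condition", "measurement_index"]
    for (subj, cond, meas), block in truth.groupby(keys, sort=True):
        b = block.rename(
            columns={"mu_true": "mu", "sigma_true": "sigma", "lapse_true": "lapse"}
        ).copy()
        b["mu"] = b["mu"] - b["mu"].mean()
        summ = tl_stats.summarize_block(b)
        summ.insert(0, "subject_id", subj)
        summ.insert(1, "condition", cond)
        summ.insert(2, "measurement_index", meas)
        rows.append(summ)
    return pd.concat(rows, ignore_index=True)


def true_group_bias(truth: pd.DataFrame) -> pd.DataFrame:
    """Group-mean true bias per condition and absolute surround."""
    summ = truth_summaries(truth)
    return (
        summ.groupby(["condition", "abs_surround"], sort=True)["bias"]
        .mean()
        .reset_index()
        .rename(columns={"bias": "bias_true"})
    )


def end_to_end_recovery(
    spec: CohortSpec,
    profile: EffectProfile | None = None,
    priors: PriorSpec | None = None,
    grid: GridSpec | None = None,
) -> dict:
    """Full pipeline on one synthetic cohort: simulate -> fit ->
    summarize -> test, scored against the generating truth.

    Intended for desk-scale cohorts (n <= 30).  The report carries the
    truth and trial tables, the fits and summaries, group-level bias
    recovery errors per condition x orientation, and the statistical
    battery's outcomes (bias ANOVA, alcohol-placebo contrasts, attraction
    tests).
    """
    if spec.n_subjects > 30:
        raise ValidationError("end_to_end_recovery is intended for n_subjects <= 30")
    profile = profile or EffectProfile()
    truth = make_cohort(spec, profile)
    trials = simulate_study(truth, spec.master_seed)
    fits = fit_trial_table(trials, priors, grid)
    summaries = tl_stats.summarize_fits_table(fits)
    recovered = (
        summaries.groupby(["condition", "abs_surround"], sort=True)["bias"]
        .mean()
        .reset_index()
        .rename(columns={"bias": "bias_recovered"})
    )
    recovery = recovered.merge(true_group_bias(truth), on=["condition", "abs_surround"])
    recovery["bias_error"] = recovery["bias_recovered"] - recovery["bias_true"]
    anova = tl_stats.rm_anova_gg(tl_stats.anova_table(summaries, "bias"))
    contrasts = tl_stats.condition_contrasts(summaries, "bias")
    attraction = tl_stats.attraction_tests(summaries)
    return {
        "truth": truth,
        "trials": trials,
        "fits": fits,
        "summaries": summaries,
        "recovery": recovery,
        "anova_bias": anova,
        "contrasts_bias": contrasts,
        "attraction": attraction,
    }


def interaction_significance_rate(
    profile: EffectProfile,
    n_cohorts: int,
    base_seed: int,
    n_subjects: int = 26,
    dv: str = "bias",
    alpha: float = 0.05,
) -> float:
    """Fraction of truth-level cohorts whose GG-adjusted Condition x
    Orientation interaction is significant at ``alpha``.

    Used for type-I calibration (null profile) and power checks (effect
    profile) of the statistical battery.
    """
    hits = 0
    for j in range(n_cohorts):
        spec = CohortSpec(master_seed=int(base_seed) + j, n_subjects=n_subjects)
        summ = truth_summaries(make_cohort(spec, profile))
        res = tl_stats.rm_anova_gg(tl_stats.anova_table(summ, dv))
        inter = [r for r in res if "x" in r.effect][0]
        hits += inter.p_gg < alpha
    return hits / n_cohorts
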