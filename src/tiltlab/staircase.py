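"""Weighted up-down adaptive staircases for the 2AFC verticality task.

Each staircase moves the center orientation down by ``down_weight`` base
steps after a CW response and up by ``up_weight`` base steps after a CCW
response.  The level therefore equilibrates where the expected movement is
zero, i.e. at the orientation whose CW-response probability is

    p* = up_weight / (up_weight + down_weight),

the Kaernbach convergence point.  The experimental design pairs two
reciprocal tracks per surround: track A starts at +21 deg with weights
up=2 / down=5 (converging at p* = 2/7, on the CCW side of the PSE) and
track B starts at -21 deg with weights up=5 / down=2 (p* = 5/7), so each
track starts on the side opposite its convergence point and sweeps rapidly
through the transition region of the psychometric function.  Each track
runs 40 trials; a surround condition thus contributes 80 trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .psychometric import CW, PsychometricParams, normalize_response, sample_response

#: Surround orientations used in the study design (degrees, CW positive).
SURROUNDS = (0, 15, -15, 30, -30, 75, -75)

#: Experimental conditions.
CONDITIONS = ("sober", "placebo", "alcohol")


@dataclass(frozen=True)
class StaircaseConfig:
    """Configuration of one weighted up-down track.

    ``base_step`` is in degrees (default 1); ``up_weight``/``down_weight``
    are the integer step multipliers ((2,5) and (5,2) in the study design);
    ``start_level`` the first presented orientation; ``clamp`` an absolute
    bound on the level, keeping stimuli meaningful under high-lapse
    observers (the design itself states no bound).
    """

    up_weight: int
    down_weight: int
    start_level: float
    base_step: float = 1.0
    n_trials: int = 40
    clamp: float = 45.0

    def __post_init__(self) -> None:
        for name in ("up_weight", "down_weight"):
            w = getattr(self, name)
            if not (isinstance(w, (int, np.integer)) and w > 0):
                raise ValidationError(f"{name} must be a positive integer, got {w!r}")
        if not self.base_step > 0:
            raise ValidationError(f"base_step must be positive, got {self.base_step!r}")
        if not (isinstance(self.n_trials, (int, np.integer)) and self.n_trials > 0):
            raise ValidationError(f"n_trials must be a positive count, got {self.n_trials!r}")
        if not self.clamp > 0:
            raise ValidationError(f"clamp must be positive, got {self.clamp!r}")
        if abs(self.start_level) > self.clamp:
            raise ValidationError(
                f"start_level {self.start_level!r} exceeds clamp {self.clamp!r}"
            )


@dataclass(frozen=True)
class StaircaseState:
    """Current level and response history of one running track."""

    level: float
    trial_index: int = 0
    history: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.trial_index != len(self.history):
            raise ValidationError("trial_index must equal the history length")


@dataclass(frozen=True)
class TrialRecord:
    """One 2AFC trial with its provenance.

    ``trial_index`` is 1-based within the staircase; ``measurement_index``
    is 1..3 for alcohol sessions and 1 otherwise.
    """

    subject_id: str
    condition: str
    measurement_index: int
    surround_deg: int
    staircase_id: str
    trial_index: int
    center_deg: float
    response: str


def update_level(
    state: StaircaseState, cfg: StaircaseConfig, response: str
) -> StaircaseState:
    """Apply the weighted up-down rule to one response.

    A CW response moves the level by ``-down_weight * base_step``; a CCW
    response by ``+up_weight * base_step``.  The new level is clamped to
    ``[-clamp, +clamp]`` and the (presented level, response) pair appended
    to the history.
    """
    token = normalize_response(response)
    if token == CW:
        new = state.level - cfg.down_weight * cfg.base_step
    else:
        new = state.level + cfg.up_weight * cfg.base_step
    new = float(np.clip(new, -cfg.clamp, cfg.clamp))
    return StaircaseState(
        level=new,
        trial_index=state.trial_index + 1,
        history=state.history + ((state.level, token),),
    )


def convergence_point(up_weight: float, down_weight: float) -> float:
    """Equilibrium CW-response probability of a weighted up-down rule.

    Solves ``up_weight * (1 - p) = down_weight * p``, giving
    ``p = up_weight / (up_weight + down_weight)``.
    """
    if not (up_weight > 0 and down_weight > 0):
        raise ValidationError("staircase weights must be positive")
    return up_weight / (up_weight + down_weight)


def run_staircase(
    observer: PsychometricParams,
    cfg: StaircaseConfig,
    rng: np.random.Generator,
    *,
    subject_id: str = "sim",
    condition: str = "sober",
    measurement_index: int = 1,
    surround_deg: int = 0,
    staircase_id: str = "A",
) -> list[TrialRecord]:
    """Run one track against a virtual observer; returns ``cfg.n_trials``
    trial records, fully reproducible under a fixed generator state."""
    state = StaircaseState(level=float(cfg.start_level))
    records: list[TrialRecord] = []
    for i in range(cfg.n_trials):
        theta = state.level
        resp = sample_response(observer, theta, rng)
        records.append(
            TrialRecord(
                subject_id=subject_id,
                condition=condition,
                measurement_index=measurement_index,
                surround_deg=surround_deg,
                staircase_id=staircase_id,
                trial_index=i + 1,
                center_deg=theta,
                response=resp,
            )
        )
        state = update_level(state, cfg, resp)
    return records


#: Per-track configuration of the paired design: (start, up, down).
PAIR_DESIGN = {"A": (21.0, 2, 5), "B": (-21.0, 5, 2)}


def pair_staircases(
    observer: PsychometricParams,
    surround_deg: int,
    rng: np.random.Generator,
    *,
    n_trials: int = 40,
    base_step: float = 1.0,
    clamp: float = 45.0,
    subject_id: str = "sim",
    condition: str = "sober",
    measurement_index: int = 1,
    interleave: bool = True,
) -> list[TrialRecord]:
    """Run the two reciprocal tracks for one surround (80 trials total).

    Track A: start +21, weights up=2/down=5 (converges at p=2/7); track B:
    start -21, weights up=5/down=2 (p=5/7).  With a memoryless observer the
    presentation order is statistically irrelevant; when ``interleave`` is
    true the two tracks are shuffled trial-by-trial under the session
    stream, mimicking the interleaved experimental schedule.
    """
    rng_a, rng_b, rng_order = rng.spawn(3)
    records = []
    for track, child in (("A", rng_a), ("B", rng_b)):
        start, up, down = PAIR_DESIGN[track]
        cfg = StaircaseConfig(
            up_weight=up,
            down_weight=down,
            start_level=start,
            base_step=base_step,
            n_trials=n_trials,
            clamp=clamp,
        )
        records.append(
            run_staircase(
                observer,
                cfg,
                child,
                subject_id=subject_id,
                condition=condition,
                measurement_index=measurement_index,
                surround_deg=surround_deg,
                staircase_id=track,
            )
        )
    track_a, track_b = records
    if not interleave:
        return track_a + track_b
    merged: list[TrialRecord] = []
    ia = ib = 0
    order = rng_order.permutation(["A"] * len(track_a) + ["B"] * len(track_b))
    for tag in order:
        if tag == "A":
            merged.append(track_a[ia])
            ia += 1
        else:
            merged.append(track_b[ib])
            ib += 1
    return merged
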