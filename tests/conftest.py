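import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def session_trials():
    """One seeded 80-trial paired-staircase session of a known observer
    (mu=2.0, sigma=2.5, lapse=0.03) at the +15 deg surround."""
    from tiltlab import PsychometricParams, pair_staircases

    observer = PsychometricParams(mu=2.0, sigma=2.5, lapse=0.03)
    rng = np.random.default_rng(1)
    return observer, pair_staircases(observer, 15, rng)


@pytest.fixture(scope="session")
def anova_fixture():
    """Seeded balanced within-subject table (12 subjects x 3 conditions x
    4 orientations) with a condition-by-orientation structure, shared with
    the external statistics oracles."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(12):
        base = rng.normal(0, 1)
        for c in ["a", "b", "c"]:
            for o in [0, 15, 30, 75]:
                rows.append(
                    {
                        "subject_id": f"S{i}",
                        "condition": c,
                        "orientation": o,
                        "value": base
                        + rng.normal(0, 1)
                        + (0.5 if c == "b" else 0.0) * np.log1p(o),
                    }
                )
    return pd.DataFrame(rows)


def make_summary_table(rng, n_subjects=8, effect=1.0):
    """Synthetic summary table (bias/threshold/log10_lapse per subject x
    condition x orientation) for exercising the battery without fitting."""
    rows = []
    for i in range(n_subjects):
        subj = f"S{i + 1:02d}"
        for cond in ("sober", "placebo", "alcohol"):
            for s in (0, 15, 30, 75):
                bias = {0: 0.0, 15: 2.5, 30: 2.0, 75: -0.5}[s]
                if cond == "alcohol" and s in (15, 30):
                    bias += effect
                rows.append(
                    {
                        "subject_id": subj,
                        "condition": cond,
                        "measurement_index": 1,
                        "abs_surround": s,
                        "bias": bias + rng.normal(0, 0.5),
                        "threshold": 2.5
                        + (0.8 if cond == "alcohol" else 0.0)
                        + rng.normal(0, 0.3),
                        "log10_lapse": -1.4
                        + (0.4 if cond == "alcohol" else 0.0)
                        + rng.normal(0, 0.15),
                    }
                )
    return pd.DataFrame(rows)
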