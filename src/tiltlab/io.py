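"""Trial-table CSV schema, run configuration, and provenance headers.

Trial tables are UTF-8 comma-delimited CSV with a mandatory header row
and the fixed column order

    subject_id, condition, measurement_index, surround_deg,
    staircase_id, trial_index, center_deg, response

Center orientations are decimal degrees (CW positive) written with at
least three decimals; condition and response tokens are parsed
case-insensitively and written in canonical form (lowercase conditions,
uppercase CW/CCW).  Lines starting with ``#`` are provenance comments
(package version, seed, config hash) and are ignored on read, so any
artifact can be regenerated bit-identically from the trial CSV plus the
recorded seed and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import TRIAL_COLUMNS, EffectProfile
from .errors import ValidationError
from .fitting import GridSpec, PriorSpec
from .psychometric import normalize_response
from .staircase import CONDITIONS, SURROUNDS

__all__ = ["read_trials", "write_trials", "RunConfig", "TRIAL_COLUMNS"]

_VERSION = "0.1.0"


def _canonical_condition(token, row: int):
    t = str(token).strip().lower()
    if t not in CONDITIONS:
        raise ValidationError(
            f"row {row}, column 'condition': unknown token {token!r} "
            f"(expected one of {CONDITIONS})"
        )
    return t


def _fmt_center(value: float) -> str:
    """Write center_deg with >= 3 decimals without losing the value."""
    s = f"{value:.3f}"
    return s if float(s) == value else repr(float(value))


def write_trials(
    table: pd.DataFrame,
    path,
    *,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """Write a schema-conformant trial CSV with a provenance header."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"trial table missing columns: {missing}")
    out = table[TRIAL_COLUMNS].copy()
    out["center_deg"] = out["center_deg"].map(_fmt_center)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# tiltlab {_VERSION} trial table\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if config_hash is not None:
            fh.write(f"# config={config_hash}\n")
        out.to_csv(fh, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV; errors name the offending row and
    column.  Returns canonical tokens and numeric dtypes."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if extra:
        raise ValidationError(f"{path.name}: unknown column(s) {extra}")
    df = df[TRIAL_COLUMNS]
    records = df.to_dict("records")
    out = {c: [] for c in TRIAL_COLUMNS}
    for i, rec in enumerate(records, start=1):
        for col in TRIAL_COLUMNS:
            if rec[col] is None or (isinstance(rec[col], float) and np.isnan(rec[col])):
                raise ValidationError(f"row {i}, column {col!r}: missing value")
        out["subject_id"].append(str(rec["subject_id"]))
        out["condition"].append(_canonical_condition(rec["condition"], i))
        try:
            meas = int(rec["measurement_index"])
            surround = int(rec["surround_deg"])
            trial = int(rec["trial_index"])
            center = float(rec["center_deg"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {i}: malformed numeric field ({exc})") from None
        if surround not in SURROUNDS:
            raise ValidationError(
                f"row {i}, column 'surround_deg': {surround} not in {sorted(SURROUNDS)}"
            )
        if not np.isfinite(center):
            raise ValidationError(f"row {i}, column 'center_deg': non-finite value")
        if trial < 1:
            raise ValidationError(f"row {i}, column 'trial_index': must be 1-based")
        try:
            resp = normalize_response(rec["response"])
        except ValidationError as exc:
            raise ValidationError(f"row {i}, column 'response': {exc}") from None
        out["measurement_index"].append(meas)
        out["surround_deg"].append(surround)
        out["staircase_id"].append(str(rec["staircase_id"]))
        out["trial_index"].append(trial)
        out["center_deg"].append(center)
        out["response"].append(resp)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class RunConfig:
    """Serializable bundle of everything that determines a run."""

    seed: int = 0
    n_subjects: int = 26
    alcohol_measurements: int = 1
    priors: PriorSpec = field(default_factory=PriorSpec)
    grid: GridSpec = field(default_factory=GridSpec)
    profile: EffectProfile = field(default_factory=EffectProfile)
    output_dir: str = "."

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            return obj

        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "alcohol_measurements": self.alcohol_measurements,
            "priors": enc(self.priors),
            "grid": enc(self.grid),
            "profile": enc(self.profile),
            "output_dir": self.output_dir,
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        priors = d.get("priors", {})
        grid = d.get("grid", {})
        profile = dict(d.get("profile", {}))
        if "lapse_beta" in priors:
            priors = {
                **priors,
                "lapse_beta": tuple(priors["lapse_beta"]),
                "sigma_gamma": tuple(priors["sigma_gamma"]),
                "mu_bounds": tuple(priors["mu_bounds"]),
            }
        for key in ("bias_base", "sigma_base"):
            if key in profile:
                profile[key] = {int(k): float(v) for k, v in profile[key].items()}
        if "lapse_bounds" in profile:
            profile["lapse_bounds"] = tuple(profile["lapse_bounds"])
        return cls(
            seed=int(d.get("seed", 0)),
            n_subjects=int(d.get("n_subjects", 26)),
            alcohol_measurements=int(d.get("alcohol_measurements", 1)),
            priors=PriorSpec(**priors),
            grid=GridSpec(**grid),
            profile=EffectProfile(**profile),
            output_dir=str(d.get("output_dir", ".")),
        )

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        return cls.from_dict(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode("utf-8")).hexdigest()[:12]
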