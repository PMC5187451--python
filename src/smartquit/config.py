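"""Study configuration: every protocol constant in one validated object.

The defaults encode the 3-week protocol: a 1-week prequit period followed by
2 postquit weeks, 5 system-prompted EMAs per day (1 daily diary 30 minutes
after waking + 4 random prompts in the waking window), a 60-second answer
window, 15-minute event-contingent follow-ups, at most 2 sampled smoking
occasions per day, a strict >25% daily-diary escalation threshold, strict
CO verification cutoffs (<8 ppm at follow-ups, <10 ppm on the quit date),
and the $40/$80/$120 completion-based compensation tiers.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError

__all__ = ["RiskEstimatorSpec", "StudyConfig", "load_config", "save_config"]

#: Items a risk-estimator weight may refer to. ``motivation_deficit`` is
#: scale_max − motivation_to_quit so that "low motivation to quit" is a
#: high-is-bad axis like the other three triggers; ``smoked_since_last``
#: enters as a 0/1 indicator.
RISK_FEATURES = (
    "urge",
    "negative_affect_stress",
    "cigarette_availability",
    "motivation_deficit",
    "smoked_since_last",
)


class RiskEstimatorSpec(BaseModel):
    """Pluggable linear lapse-risk score: score = intercept + Σ w·x.

    This is deliberately a placeholder contract — the published momentary
    lapse-risk estimators are richer models — so a replacement only needs
    to honour ``estimate_lapse_risk``'s output shape, not this spec.
    """

    model_config = ConfigDict(extra="forbid")

    intercept: float = 0.0
    threshold: float = 4.0
    weights: dict[str, float] = Field(
        default_factory=lambda: {
            "urge": 0.3,
            "negative_affect_stress": 0.3,
            "cigarette_availability": 0.2,
            "motivation_deficit": 0.2,
            "smoked_since_last": 1.0,
        }
    )

    @model_validator(mode="after")
    def _check(self) -> "RiskEstimatorSpec":
        unknown = set(self.weights) - set(RISK_FEATURES)
        if unknown:
            raise ValueError(f"risk weights refer to unknown items: {sorted(unknown)}")
        if not all(abs(v) < float("inf") for v in self.weights.values()):
            raise ValueError("risk weights must be finite")
        if not abs(self.threshold) < float("inf"):
            raise ValueError("risk threshold must be finite")
        return self


class StudyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    quit_datetime: datetime = datetime(2023, 1, 9, 0, 0)
    prequit_days: int = Field(7, gt=0)
    postquit_days: int = Field(14, gt=0)

    diary_offset_min: int = Field(30, gt=0)
    n_random_per_day: int = Field(4, ge=0)
    min_gap_min: int = Field(30, gt=0)
    prompt_window_sec: int = Field(60, gt=0)
    postcig_delay_min: int = Field(15, gt=0)
    slip_followup_delay_min: int = Field(15, gt=0)
    max_sampled_cigs_per_day: int = Field(2, ge=0)
    p_sample_occasion: float = Field(1.0, ge=0.0, le=1.0)

    diary_risk_threshold_pct: float = Field(25.0, ge=0.0)  # strict > escalates
    co_cutoff_followup_ppm: float = Field(8.0, ge=0.0)  # strict "below"
    co_cutoff_quitdate_ppm: float = Field(10.0, ge=0.0)  # strict "below"

    # (completion-fraction lower bound, USD); below the first bound pays 0
    compensation_tiers: list[tuple[float, float]] = Field(
        default_factory=lambda: [(0.50, 40.0), (0.75, 80.0), (0.90, 120.0)]
    )

    item_scale_max: int = Field(10, gt=0)
    diary_scale_max: int = Field(100, gt=0)
    min_waking_hours: float = Field(8.0, gt=0.0)

    risk_estimator: RiskEstimatorSpec = Field(default_factory=RiskEstimatorSpec)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "StudyConfig":
        bounds = [b for b, _ in self.compensation_tiers]
        amounts = [a for _, a in self.compensation_tiers]
        if any(not (0.0 <= b <= 1.0) for b in bounds):
            raise ValueError("compensation_tiers: bounds must lie in [0, 1]")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("compensation_tiers: bounds must be strictly increasing")
        if any(a2 < a1 for a1, a2 in zip(amounts, amounts[1:])):
            raise ValueError("compensation_tiers: amounts must be nondecreasing")
        if any(a < 0 for a in amounts):
            raise ValueError("compensation_tiers: amounts must be nonnegative")
        return self

    @property
    def total_days(self) -> int:
        """Length of the EMA period in days (prequit + postquit)."""
        return self.prequit_days + self.postquit_days

    @property
    def enrollment_datetime(self) -> datetime:
        from datetime import timedelta

        return self.quit_datetime - timedelta(days=self.prequit_days)


def load_config(path: str | Path) -> StudyConfig:
    """Read a YAML/JSON study configuration, filling protocol defaults.

    An empty file yields the all-defaults configuration. Malformed YAML
    raises :class:`ConfigError`, as does any field-level validation failure
    (the message names the offending field).
    """
    path = Path(path)
    try:
        raw: Any = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse configuration: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping, got {type(raw).__name__}")
    try:
        return StudyConfig(**raw)
    except ValidationError as exc:
        fields = ", ".join(".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors())
        raise ConfigError(f"{path}: invalid configuration (fields: {fields}): {exc}") from exc


def save_config(config: StudyConfig, path: str | Path) -> None:
    """Write a configuration so that ``load_config`` round-trips it."""
    data = config.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
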