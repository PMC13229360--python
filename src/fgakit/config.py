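"""Flat analysis configuration: every tunable constant in one
documented key set, loadable from a YAML file of plain key: value
pairs. Unknown keys are rejected so typos fail loudly; emitted reports
embed the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .events import EventConfig
from .scoring import ScoringThresholds
from .steps import WALKWAY_HALFWIDTH

__all__ = ["AnalysisConfig", "load_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Resolved pipeline configuration with protocol defaults."""

    # event detection
    speed_threshold: float = 0.15
    foot_speed_cutoff: float = 3.0
    min_stance: float = 0.15
    min_swing_gap: float = 0.10
    template_cadence: float = 2.0
    template_speed: float = 1.2
    min_peak_corr: float = 0.5
    footstep_position: str = "stance_mean"
    speed_axis: str = "ap"
    # scoring thresholds
    cond2_score3: float = 1.25
    cond2_score2_low: float = 1.10
    cond2_score1_low: float = 1.05
    cond34_score3_low: float = 0.95
    cond34_score3_high: float = 1.05
    cond34_score2_low: float = 0.90
    cond34_score2_high: float = 1.10
    cond34_score1_low: float = 0.75
    lateral_limit: float = 0.1524
    cond5_score3_max: float = 3.0
    cond5_score2_max: float = 4.5
    cond6_speed_floor: float = 0.75
    clearance_high: float = 0.10
    turn_speed_threshold: float = 0.2
    # geometry & ingest
    walkway_halfwidth: float = WALKWAY_HALFWIDTH
    frame_forward_dist: float = 5.0
    frame_right_dist: float = 1.0
    keypoint_smoothing_cutoff: float = 12.0  # Hz, raw-position smoothing
    dialect: str = "markerless"
    max_gap: int = 5

    def event_config(self) -> EventConfig:
        return EventConfig(
            speed_threshold=self.speed_threshold,
            foot_speed_cutoff=self.foot_speed_cutoff,
            min_stance=self.min_stance,
            min_swing_gap=self.min_swing_gap,
            template_cadence=self.template_cadence,
            template_speed=self.template_speed,
            min_peak_corr=self.min_peak_corr,
            footstep_position=self.footstep_position,
            speed_axis=self.speed_axis,
        )

    def thresholds(self) -> ScoringThresholds:
        return ScoringThresholds(
            cond2_score3=self.cond2_score3,
            cond2_score2_low=self.cond2_score2_low,
            cond2_score1_low=self.cond2_score1_low,
            cond34_score3_band=(self.cond34_score3_low, self.cond34_score3_high),
            cond34_score2_band=(self.cond34_score2_low, self.cond34_score2_high),
            cond34_score1_low=self.cond34_score1_low,
            lateral_limit=self.lateral_limit,
            cond5_score3_max=self.cond5_score3_max,
            cond5_score2_max=self.cond5_score2_max,
            cond6_speed_floor=self.cond6_speed_floor,
            clearance_high=self.clearance_high,
            turn_speed_threshold=self.turn_speed_threshold,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path=None, overrides: dict | None = None) -> AnalysisConfig:
    """Build a configuration from an optional YAML file plus overrides.

    The file is a flat mapping; any key not in :class:`AnalysisConfig`
    raises ``ValueError`` naming it.
    """
    known = {f.name for f in fields(AnalysisConfig)}
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must be a flat key: value mapping")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = sorted(set(values) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return AnalysisConfig(**values)
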