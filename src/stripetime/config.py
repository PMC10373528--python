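"""Simulation configuration for synthetic embryo datasets.

Defaults are calibrated to the live-imaging measurements the generator
emulates: transcription occurs in a short/dim "low" burst mode (mean dot
intensity ~0.4 a.u., bursts under 5 min) and a long/bright "high" mode
(~1.1 a.u., bursts up to ~20 min); posterior-boundary (PB) nuclei reach about
4-fold the anterior-boundary (AB) protein level at gastrulation; AB
transcription shuts down after the zebra divergence around -30 min; the
autoregulatory unit activates around -15 min; a second (engrailed-like) unit
follows ~10 min later; heat-shock protein pulses last ~15 min at
half-maximum. Time is measured in minutes relative to gastrulation (t = 0).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

from .datatypes import ConfigError

CONSTRUCTS = ("endogenous", "zebra", "autoregulatory", "engrailed", "heatshock")


@dataclass
class ModeParams:
    """One transcription burst mode (on/off episode statistics)."""

    mean_intensity: float
    intensity_sd: float
    burst_duration_mean: float  # minutes, mean of the truncated exponential
    burst_duration_max: float  # minutes, truncation bound
    interburst_mean: float  # minutes, exponential mean beyond the floor
    interburst_min: float = 1.0  # floor keeps gap-filling from merging bursts


def low_mode_default() -> ModeParams:
    return ModeParams(0.4, 0.08, 2.0, 5.0, 3.0)


def high_mode_default() -> ModeParams:
    return ModeParams(1.1, 0.12, 8.0, 20.0, 2.0)


@dataclass
class NoiseParams:
    """Measurement noise and biological variability amplitudes."""

    protein_sd: float = 0.05  # a.u., per-frame Gaussian on protein
    spot_sd: float = 0.05  # a.u., per-frame Gaussian on in-burst intensity
    detection_dropout_prob: float = 0.05  # chance an on-frame is missed
    protein_amp_sd: float = 0.15  # per-nucleus amplitude scatter (fraction)
    time_shift_sd: float = 4.0  # minutes, per-nucleus shift of the rise
    position_sd: float = 0.2  # px, per-frame jitter of centroids

    @classmethod
    def zero(cls) -> "NoiseParams":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    @property
    def any_nonzero(self) -> bool:
        return any(v > 0 for v in asdict(self).values())


@dataclass
class HeatShockParams:
    """Ectopic protein pulse driven by a heat-shock promoter."""

    start: float = -40.0  # minutes relative to gastrulation
    pulse_duration: float = 15.0  # minutes, width at half maximum
    amplitude: float = 1.5  # a.u., peak added protein
    peak_delay: float = 15.0  # minutes from start to pulse peak


@dataclass
class SimConfig:
    """Full specification of one synthetic embryo."""

    construct: str = "endogenous"
    n_stripes: int = 3
    nuclei_per_row: int = 18  # lattice columns (anterior -> posterior)
    rows: int = 16  # lattice rows (dorsal-ventral)
    frame_interval: float = 20.0  # seconds
    t_start: float = -60.0  # minutes relative to gastrulation
    t_end: float = 10.0
    protein_ratio_pb_ab: float = 4.0  # PB/AB protein fold at gastrulation
    mrna_ratio_pb_ab: float = 50.0  # calibration target, emergent from AB fade
    low_mode: ModeParams = field(default_factory=low_mode_default)
    high_mode: ModeParams = field(default_factory=high_mode_default)
    divergence_time: float = -30.0  # zebra divergence, minutes
    activation_model: str = "timer"  # 'timer' | 'threshold'
    timer_mean: float = -15.0  # minutes
    timer_sd: float = 3.0
    threshold_level: float = 1.2  # a.u. on the clean protein signal
    second_gene: bool = False
    second_gene_offset: float = 10.0  # minutes after first-unit activation
    heat_shock: Optional[HeatShockParams] = None
    noise: NoiseParams = field(default_factory=NoiseParams)
    background: float = 0.2  # a.u., nuclear GFP background added to protein
    ab_level_at_gastrulation: float = 0.5  # a.u., AB protein anchor at t=0
    ab_fade_mean: float = 6.0  # minutes, AB shutdown spread past divergence
    gastrulation_jitter_sd: float = 0.4  # minutes, per-nucleus onset scatter
    ectopic_fraction: float = 0.8  # silent nuclei responding to late heat shock
    rng_seed: int = 0

    def validate(self) -> "SimConfig":
        if self.construct not in CONSTRUCTS:
            raise ConfigError(f"unknown construct {self.construct!r}")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.t_end <= self.t_start:
            raise ConfigError("t_end must exceed t_start")
        if not (self.t_start < self.divergence_time < self.timer_mean <= 0):
            raise ConfigError("need t_start < divergence_time < timer_mean <= 0")
        if self.activation_model not in ("timer", "threshold"):
            raise ConfigError(f"unknown activation model {self.activation_model!r}")
        if not (self.low_mode.mean_intensity < self.high_mode.mean_intensity):
            raise ConfigError("low mode must be dimmer than high mode")
        for m in (self.low_mode, self.high_mode):
            if min(m.mean_intensity, m.burst_duration_mean, m.burst_duration_max) <= 0:
                raise ConfigError("mode intensities and durations must be positive")
        if self.background < 0 or self.ab_level_at_gastrulation <= 0:
            raise ConfigError("intensities must be nonnegative")
        if self.nuclei_per_row < 6 * self.n_stripes:
            raise ConfigError(
                "nuclei_per_row must be at least 6 per stripe to fit the bands"
            )
        if self.heat_shock is not None and self.heat_shock.start > self.t_end:
            # handled downstream with a warning; still a sane config
            pass
        return self

    @property
    def dt_min(self) -> float:
        return self.frame_interval / 60.0

    @property
    def n_frames(self) -> int:
        return int(math.floor((self.t_end - self.t_start) / self.dt_min + 0.5)) + 1
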