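"""Run configuration: one flat key = value file drives the whole pipeline.

Defaults encode the standard study constants — 400 Hz sampling, 4 s trials,
125 g / 518 g cubes of 6 cm, a fourth-order 14 Hz zero-phase Butterworth
filter, 0.2 N handle and 0.4 N platform onset thresholds, +/-3 SD trimming,
alpha = .05 with a Bonferroni family of 2 — alongside the simulator's
behavioural parameters (see :class:`liftforce.simulate.SimulationConfig`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .exceptions import InvalidArgumentError, SchemaError
from .measures import ExtractionConfig
from .signal import FilterSpec
from .simulate import SimulationConfig, StimulusSpec


@dataclass
class RunConfig:
    """Union of simulation, extraction and analysis settings plus paths."""

    # global
    seed: int = 0
    log_level: str = "INFO"
    input_manifest: str = ""  # when set, ingest instead of simulating

    # design / simulation
    n_participants: int = 29
    n_per_transition: int = 20
    sampling_rate: float = 400.0
    trial_duration: float = 4.0
    mass_light: float = 125.0
    mass_heavy: float = 518.0
    side_length: float = 6.0
    memory_weight: float = 1.0
    overshoot: float = 1.1
    rise_time: float = 0.5
    correction_rate: float = 8.0
    grip_ratio: float = 1.5
    noise_sd: float = 0.02
    perceptual_gain: float = 0.03
    rating_noise_sd: float = 0.1
    reaction_time: float = 0.3
    participant_sd: float = 0.15
    trial_jitter_sd: float = 0.05
    scale_spread: float = 0.8

    # extraction
    filter_order: int = 4
    filter_cutoff: float = 14.0
    handle_onset_threshold: float = 0.2
    platform_onset_threshold: float = 0.4
    handle_force_scale: float = 2.0
    min_prominence: float = 0.05
    baseline_window: float = 0.2
    literal_percent_sign: bool = False
    trim_k: float = 3.0

    # analysis
    alpha: float = 0.05
    bonferroni_family: int = 2
    d_variant: str = "dz"
    icc_form: str = "consistency"
    icc_boundary: str = "lower"

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_participants=self.n_participants,
            n_per_transition=self.n_per_transition,
            sampling_rate=self.sampling_rate,
            trial_duration=self.trial_duration,
            masses=(
                StimulusSpec(self.mass_light, self.side_length),
                StimulusSpec(self.mass_heavy, self.side_length),
            ),
            memory_weight=self.memory_weight,
            overshoot=self.overshoot,
            rise_time=self.rise_time,
            correction_rate=self.correction_rate,
            grip_ratio=self.grip_ratio,
            noise_sd=self.noise_sd,
            perceptual_gain=self.perceptual_gain,
            rating_noise_sd=self.rating_noise_sd,
            reaction_time=self.reaction_time,
            participant_sd=self.participant_sd,
            trial_jitter_sd=self.trial_jitter_sd,
            scale_spread=self.scale_spread,
            seed=self.seed,
        )

    def extraction_config(self) -> ExtractionConfig:
        return ExtractionConfig(
            handle_onset_threshold=self.handle_onset_threshold,
            platform_onset_threshold=self.platform_onset_threshold,
            handle_force_scale=self.handle_force_scale,
            filter=FilterSpec(order=self.filter_order, cutoff=self.filter_cutoff),
            min_prominence=self.min_prominence,
            baseline_window=self.baseline_window,
            literal_percent_sign=self.literal_percent_sign,
        )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a flat ``key = value`` text file ('#' starts a comment)."""
        values: dict[str, str] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise SchemaError(f"{path}: line {lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                values[key] = value
        values.update({k: str(v) for k, v in overrides.items()})
        return cls.from_mapping(values, source=str(path))

    @classmethod
    def from_mapping(cls, values: dict, source: str = "<config>") -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in values.items():
            if key not in fields:
                raise InvalidArgumentError(f"{source}: unknown config key {key!r}")
            kwargs[key] = _coerce(value, fields[key].type, key, source)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")


def _coerce(value, ftype, key: str, source: str):
    if not isinstance(value, str):
        return value
    ftype = str(ftype)
    try:
        if "bool" in ftype:
            lowered = value.strip().lower()
            if lowered in ("true", "1", "yes", "on"):
                return True
            if lowered in ("false", "0", "no", "off"):
                return False
            raise ValueError(value)
        if "int" in ftype:
            return int(value)
        if "float" in ftype:
            return float(value)
        return value
    except ValueError as exc:
        raise InvalidArgumentError(
            f"{source}: could not parse {key} = {value!r} as {ftype}"
        ) from exc
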