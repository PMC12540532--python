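"""Synthetic dual-transducer lifting trials.

The simulator emulates a session in which a participant repeatedly lifts a
light (125 g) or heavy (518 g) cube off a force-transducer platform by a
transducer-equipped handle, with channels sampled at 400 Hz:

* ``load`` — the handle's vertical-force reading.  By convention the handle
  sees only the index finger, i.e. half of the total applied load force.
* ``grip`` — normal (pinch) force, proportional to total load force.
* ``platform`` — downward force on the platform: the object's weight minus
  the total load force, clamped at zero from lift-off onward.  This clamp is
  the platform's defining limitation — it cannot record anything past
  lift-off.
* ``photogate`` — boolean, True once the object leaves the surface.

The programmed lift is a minimum-jerk force ramp from zero to
``overshoot x expected weight-force`` over ``rise_time`` seconds, where the
expected mass follows an exponential one-trial-back memory of previously
lifted masses.  When the participant underestimates the weight the ramp
plateaus below the weight-force and a secondary linear ramp
(``correction_rate`` N/s) — the feedback correction — continues until
lift-off.  Because a minimum-jerk ramp's rate peaks at its temporal
midpoint, a strong overestimate (light object after a heavy one) drives
lift-off before the midpoint and the platform truncates the force-rate peak;
a well-anticipated lift crosses its weight-force after the midpoint and the
platform records the full peak.

Magnitude-estimation ratings use each participant's idiosyncratic
(log-normal) scale and are biased by the expectation violation: objects
heavier than expected feel heavier still, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import (
    HEAVY,
    LIGHT,
    ConditionLabel,
    generate_balanced_sequence,
    label_transitions,
)
from .exceptions import InvalidArgumentError

#: Standard gravity, m/s^2.  Masses are accepted in grams and converted to
#: weight-force in newtons once, at the boundary.
GRAVITY = 9.81


@dataclass(frozen=True)
class StimulusSpec:
    """A cubic stimulus: mass in grams, side length in centimetres."""

    mass: float
    side_length: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise InvalidArgumentError(f"mass must be > 0 g, got {self.mass}")
        if self.side_length <= 0:
            raise InvalidArgumentError(
                f"side_length must be > 0 cm, got {self.side_length}"
            )

    @property
    def volume(self) -> float:
        """Volume in cm^3."""
        return self.side_length**3

    @property
    def density(self) -> float:
        """Density in g/cm^3."""
        return self.mass / self.volume

    @property
    def weight_force(self) -> float:
        """Weight-force in newtons."""
        return self.mass / 1000.0 * GRAVITY


#: The two standard stimuli: equal-volume 6 cm cubes of 125 g and 518 g.
LIGHT_CUBE = StimulusSpec(mass=125.0, side_length=6.0)
HEAVY_CUBE = StimulusSpec(mass=518.0, side_length=6.0)


@dataclass
class SimulationConfig:
    """Parameters of a simulated lifting session.

    Defaults reproduce the standard study conditions: 29 participants, 81
    lifts each (20 per ordered weight transition), 4-s trials at 400 Hz with
    the 125 g / 518 g cube pair.

    Parameters
    ----------
    memory_weight
        Weight lambda of the previous trial's mass in the expectation update
        ``E_t = lambda * mass_{t-1} + (1 - lambda) * E_{t-1}``; 1 is a pure
        one-trial-back expectation.
    overshoot
        alpha >= 1; the programmed ramp targets ``alpha x expected
        weight-force`` so a correctly anticipated object is guaranteed to
        lift off during the ramp.
    rise_time
        Duration (s) of the programmed minimum-jerk force ramp.
    correction_rate
        Slope (N/s) of the secondary linear ramp engaged when the programmed
        ramp plateaus below the object's weight-force.
    grip_ratio
        Grip force per unit of total load force.
    noise_sd
        Additive white sensor noise per channel (N).
    perceptual_gain
        beta weighting the expectation-violation contrast in ratings.
    rating_noise_sd
        SD of the multiplicative log-normal rating noise.
    reaction_time
        Quiet interval (s) before force onset; also the platform baseline
        window of downstream extraction.
    participant_sd, trial_jitter_sd
        SDs of the log-normal multiplicative jitters applied per participant
        (rise time, grip ratio, overshoot) and per trial (rise time,
        overshoot); these create the between- and within-participant
        variance real cohorts show.
    scale_spread
        SD of the log of the participant's idiosyncratic rating scale.
    """

    n_participants: int = 29
    n_per_transition: int = 20
    sampling_rate: float = 400.0
    trial_duration: float = 4.0
    masses: tuple[StimulusSpec, StimulusSpec] = (LIGHT_CUBE, HEAVY_CUBE)
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
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be > 0")
        if self.trial_duration * self.sampling_rate < 3:
            raise InvalidArgumentError(
                "trial_duration x sampling_rate must be at least 3 samples"
            )
        if self.overshoot < 1:
            raise InvalidArgumentError(
                f"overshoot must be >= 1 to guarantee lift-off, got {self.overshoot}"
            )
        for name in ("memory_weight", "grip_ratio", "noise_sd", "perceptual_gain"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if not 0 <= self.memory_weight <= 1:
            raise InvalidArgumentError("memory_weight must lie in [0, 1]")
        if self.rise_time <= 0 or self.correction_rate <= 0:
            raise InvalidArgumentError("rise_time and correction_rate must be > 0")
        if self.n_participants < 1 or self.n_per_transition < 1:
            raise InvalidArgumentError(
                "n_participants and n_per_transition must be >= 1"
            )

    @property
    def light(self) -> StimulusSpec:
        return min(self.masses, key=lambda s: s.mass)

    @property
    def heavy(self) -> StimulusSpec:
        return max(self.masses, key=lambda s: s.mass)


@dataclass
class ForceTrace:
    """One trial's uniformly sampled multichannel recording.

    ``load`` is the handle transducer's reading (half of the total load
    force); ``platform`` is the downward force on the platform transducer;
    ``photogate`` is True from lift-off onward.  ``true_liftoff_time`` is
    simulation ground truth and is None for imported real data or trials
    that never lifted off.
    """

    sampling_rate: float
    grip: np.ndarray
    load: np.ndarray
    platform: np.ndarray
    photogate: np.ndarray
    true_liftoff_time: float | None = None

    def __post_init__(self) -> None:
        lengths = {len(self.grip), len(self.load), len(self.platform), len(self.photogate)}
        if len(lengths) != 1:
            raise InvalidArgumentError(f"channel lengths differ: {sorted(lengths)}")
        gate = np.asarray(self.photogate, dtype=bool)
        if gate.any():
            first = int(np.argmax(gate))
            if not gate[first:].all():
                raise InvalidArgumentError("photogate must be monotone within a trial")

    @property
    def n_samples(self) -> int:
        return len(self.load)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.sampling_rate

    @property
    def lifted_off(self) -> bool:
        return bool(np.asarray(self.photogate, dtype=bool).any())

    def plot(self, ax=None):
        """Plot all force channels and the lift-off marker on one axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.times
        ax.plot(t, 2.0 * np.asarray(self.load), label="total load force (2 x handle)")
        ax.plot(t, self.grip, label="grip force")
        ax.plot(t, self.platform, label="platform force")
        if self.lifted_off:
            gate = np.asarray(self.photogate, dtype=bool)
            ax.axvline(t[int(np.argmax(gate))], ls="--", c="k", label="lift-off")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("force (N)")
        ax.legend(frameon=False)
        return ax


@dataclass
class TrialRecord:
    """A simulated (or imported) trial: trace, stimulus, condition, rating."""

    trace: ForceTrace
    stimulus: StimulusSpec
    condition: ConditionLabel
    magnitude_estimate: float
    participant_id: str
    trial_index: int

    def __post_init__(self) -> None:
        if self.magnitude_estimate <= 0:
            raise InvalidArgumentError(
                f"magnitude_estimate must be > 0, got {self.magnitude_estimate}"
            )


def _minimum_jerk(s: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on s in [0, 1]: 10 s^3 - 15 s^4 + 6 s^5."""
    return s**3 * (10.0 - 15.0 * s + 6.0 * s**2)


def simulate_trial(
    stimulus: StimulusSpec,
    expected_mass: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    rise_time: float | None = None,
    grip_ratio: float | None = None,
    overshoot: float | None = None,
    correction_rate: float | None = None,
) -> ForceTrace:
    """Simulate one lift of ``stimulus`` under an expectation of ``expected_mass``.

    The keyword overrides carry per-participant / per-trial jitter from
    :func:`simulate_cohort`; when omitted the config values are used.  A
    trial whose load force never reaches the weight-force within the trial
    window is returned flagged (photogate never True), not raised.
    """
    if expected_mass <= 0:
        raise InvalidArgumentError(f"expected_mass must be > 0 g, got {expected_mass}")
    fs = config.sampling_rate
    n = int(round(config.trial_duration * fs))
    t = np.arange(n) / fs
    rise = config.rise_time if rise_time is None else rise_time
    ratio = config.grip_ratio if grip_ratio is None else grip_ratio
    alpha = config.overshoot if overshoot is None else overshoot
    correction = config.correction_rate if correction_rate is None else correction_rate
    t0 = config.reaction_time

    weight = stimulus.weight_force
    target = alpha * expected_mass / 1000.0 * GRAVITY

    s = np.clip((t - t0) / rise, 0.0, 1.0)
    load = target * _minimum_jerk(s)
    if target < weight:
        # Programmed ramp plateaus short of the weight: linear feedback
        # correction until the weight-force is exceeded.
        late = t > t0 + rise
        load[late] = target + correction * (t[late] - (t0 + rise))

    crossed = load >= weight
    photogate = np.zeros(n, dtype=bool)
    liftoff_time: float | None = None
    if crossed.any():
        li = int(np.argmax(crossed))
        liftoff_time = t[li]
        photogate[li:] = True
        if target < weight:
            # Post-lift-off steady state: hold the force reached at lift-off.
            load[li:] = load[li]
        # (If lift-off happened during the programmed ramp, the ramp simply
        # completes and holds its plateau — the post-lift-off steady state.)

    platform = np.maximum(weight - load, 0.0)
    if liftoff_time is not None:
        platform[int(round(liftoff_time * fs)) :] = 0.0
    grip = ratio * load
    handle_load = load / 2.0

    noise = rng.standard_normal((3, n)) * config.noise_sd
    return ForceTrace(
        sampling_rate=fs,
        grip=grip + noise[0],
        load=handle_load + noise[1],
        platform=platform + noise[2],
        photogate=photogate,
        true_liftoff_time=liftoff_time,
    )


def generate_rating(
    actual_mass: float,
    expected_mass: float,
    participant_scale: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> float:
    """Magnitude estimate of perceived heaviness on the participant's scale.

    ``rating = scale * actual * (1 + beta * (actual - expected) / actual) * exp(eps)``
    with ``eps ~ Normal(0, rating_noise_sd)``; floored at a small positive
    constant so the idiosyncratic scale stays positive.
    """
    if actual_mass <= 0 or expected_mass <= 0 or participant_scale <= 0:
        raise InvalidArgumentError("masses and participant_scale must be > 0")
    contrast = (actual_mass - expected_mass) / actual_mass
    value = participant_scale * actual_mass * (1.0 + config.perceptual_gain * contrast)
    eps = rng.normal(0.0, config.rating_noise_sd) if config.rating_noise_sd > 0 else 0.0
    return max(value * float(np.exp(eps)), 1e-6)


def simulate_cohort(config: SimulationConfig) -> list[TrialRecord]:
    """Simulate a full cohort of balanced lifting sessions.

    Seeds fan out from ``config.seed`` through ``numpy.random.SeedSequence``
    spawning, one independent stream per participant, so results are
    deterministic given the config and adding a participant never perturbs
    earlier participants' data.
    """
    root = np.random.SeedSequence(config.seed)
    masses = {LIGHT: config.light, HEAVY: config.heavy}
    mean_mass = (config.light.mass + config.heavy.mass) / 2.0
    records: list[TrialRecord] = []
    for p, child in enumerate(root.spawn(config.n_participants)):
        rng = np.random.default_rng(child)
        seq_seed = int(rng.integers(0, 2**31 - 1))
        seq = generate_balanced_sequence(config.n_per_transition, seq_seed)
        conditions = label_transitions(seq)
        scale = float(np.exp(rng.normal(0.0, config.scale_spread)))
        rise_p = config.rise_time * float(np.exp(rng.normal(0.0, config.participant_sd)))
        grip_p = config.grip_ratio * float(np.exp(rng.normal(0.0, config.participant_sd)))
        alpha_p = config.overshoot * float(np.exp(rng.normal(0.0, config.participant_sd)))
        corr_p = config.correction_rate * float(
            np.exp(rng.normal(0.0, config.participant_sd))
        )
        expectation = mean_mass
        for i, condition in enumerate(conditions):
            stimulus = masses[condition.cube]
            rise_t = rise_p * float(np.exp(rng.normal(0.0, config.trial_jitter_sd)))
            alpha_t = alpha_p * float(np.exp(rng.normal(0.0, config.trial_jitter_sd)))
            corr_t = corr_p * float(np.exp(rng.normal(0.0, config.trial_jitter_sd)))
            trace = simulate_trial(
                stimulus,
                expectation,
                config,
                rng,
                rise_time=rise_t,
                grip_ratio=grip_p,
                overshoot=alpha_t,
                correction_rate=corr_t,
            )
            rating = generate_rating(stimulus.mass, expectation, scale, config, rng)
            records.append(
                TrialRecord(
                    trace=trace,
                    stimulus=stimulus,
                    condition=condition,
                    magnitude_estimate=rating,
                    participant_id=f"P{p + 1:02d}",
                    trial_index=i + 1,
                )
            )
            expectation = (
                config.memory_weight * stimulus.mass
                + (1.0 - config.memory_weight) * expectation
            )
    return records
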