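"""Transition-balanced trial sequences for two-weight lifting experiments.

A session presents a light and a heavy object in a pseudo-random order that
is nevertheless exactly balanced over ordered weight transitions: every one
of the four ordered pairs (light->light, light->heavy, heavy->heavy,
heavy->light) occurs the same number of times.  A sequence with ``n`` trials
per transition therefore has ``4 n + 1`` lifts; the first lift has no
predecessor and is discarded from analysis, leaving ``4 n`` analyzable
trials, ``n`` in each (cube, switch) cell.

Exact balance is obtained constructively rather than by rejection sampling:
the four transition types are the edges of a two-node multigraph (one node
per weight, ``n`` parallel edges per ordered pair).  In- and out-degrees are
equal by construction, so an Eulerian circuit always exists; a randomized
Hierholzer traversal emits one uniformly-shuffled circuit, and the node
visitation order is the trial sequence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import InvalidArgumentError, SchemaError

LIGHT = "light"
HEAVY = "heavy"
WEIGHT_LABELS = (LIGHT, HEAVY)

SWITCH = "switch"
NO_SWITCH = "no_switch"
DISCARD = "discard"

#: The four ordered weight transitions, as (previous, current) pairs.
TRANSITIONS = tuple((a, b) for a in WEIGHT_LABELS for b in WEIGHT_LABELS)


@dataclass(frozen=True)
class TrialSequence:
    """An ordered list of weight labels balanced over ordered transitions.

    Parameters
    ----------
    labels
        Ordered weight labels, each ``"light"`` or ``"heavy"``.
    n_per_transition
        Number of occurrences of each ordered (previous, current) pair.

    Raises
    ------
    InvalidArgumentError
        If the labels are not drawn from the two weights, the length is not
        ``4 * n_per_transition + 1``, or any transition count is off.
    """

    labels: tuple[str, ...]
    n_per_transition: int

    def __post_init__(self) -> None:
        if self.n_per_transition < 1:
            raise InvalidArgumentError(
                f"n_per_transition must be >= 1, got {self.n_per_transition}"
            )
        bad = sorted({lab for lab in self.labels} - set(WEIGHT_LABELS))
        if bad:
            raise InvalidArgumentError(f"unknown weight labels: {bad}")
        expected_len = 4 * self.n_per_transition + 1
        if len(self.labels) != expected_len:
            raise InvalidArgumentError(
                f"sequence length must be 4 * n_per_transition + 1 = "
                f"{expected_len}, got {len(self.labels)}"
            )
        counts = self.transition_counts()
        off = {t: c for t, c in counts.items() if c != self.n_per_transition}
        if off:
            raise InvalidArgumentError(
                f"unbalanced transition counts (expected "
                f"{self.n_per_transition} each): {off}"
            )

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def transition_counts(self) -> dict[tuple[str, str], int]:
        """Count each ordered (previous, current) pair along the sequence."""
        counts = {t: 0 for t in TRANSITIONS}
        for prev, cur in zip(self.labels, self.labels[1:]):
            counts[(prev, cur)] += 1
        return counts

    @property
    def n_analyzable(self) -> int:
        """Number of trials remaining after the first lift is discarded."""
        return len(self.labels) - 1


@dataclass(frozen=True)
class ConditionLabel:
    """A trial's weight and its relation to the preceding trial.

    ``switch`` is ``"discard"`` for the first trial of a sequence (it has no
    predecessor), ``"switch"`` when the preceding weight differs, and
    ``"no_switch"`` when it repeats.
    """

    cube: str
    switch: str

    def __post_init__(self) -> None:
        if self.cube not in WEIGHT_LABELS:
            raise InvalidArgumentError(f"unknown cube label {self.cube!r}")
        if self.switch not in (SWITCH, NO_SWITCH, DISCARD):
            raise InvalidArgumentError(f"unknown switch label {self.switch!r}")

    @property
    def analyzable(self) -> bool:
        return self.switch != DISCARD


def _max_run_length(labels: list[str]) -> int:
    longest = run = 1
    for prev, cur in zip(labels, labels[1:]):
        run = run + 1 if cur == prev else 1
        longest = max(longest, run)
    return longest


def generate_balanced_sequence(
    n_per_transition: int,
    seed: int | None = None,
    max_run_length: int | None = None,
) -> TrialSequence:
    """Generate a random weight sequence exactly balanced over transitions.

    Parameters
    ----------
    n_per_transition
        Number of trials per ordered weight transition (20 in the standard
        81-lift session).
    seed
        Seed for the random number generator; the same seed reproduces the
        same sequence.
    max_run_length
        Optional post-hoc cap on the longest run of identical weights.
        Disabled by default; when set, candidate circuits are redrawn until
        the cap is met.

    Returns
    -------
    TrialSequence
        A sequence of ``4 * n_per_transition + 1`` labels.
    """
    if int(n_per_transition) != n_per_transition or n_per_transition < 1:
        raise InvalidArgumentError(
            f"n_per_transition must be a positive integer, got {n_per_transition!r}"
        )
    n = int(n_per_transition)
    if max_run_length is not None and max_run_length < 2:
        # Self-transitions are required n times, so runs of 2 are unavoidable.
        raise InvalidArgumentError("max_run_length must be >= 2 when set")
    rng = np.random.default_rng(seed)
    max_attempts = 10_000
    for _ in range(max_attempts):
        labels = _random_eulerian_circuit(n, rng)
        if max_run_length is None or _max_run_length(labels) <= max_run_length:
            return TrialSequence(tuple(labels), n)
    raise InvalidArgumentError(
        f"no sequence satisfying max_run_length={max_run_length} found in "
        f"{max_attempts} attempts"
    )


def _random_eulerian_circuit(n: int, rng: np.random.Generator) -> list[str]:
    """Randomized Hierholzer circuit on the 2-node transition multigraph."""
    out: dict[str, list[str]] = {
        node: [target for target in WEIGHT_LABELS for _ in range(n)]
        for node in WEIGHT_LABELS
    }
    for node in WEIGHT_LABELS:
        rng.shuffle(out[node])
    start = WEIGHT_LABELS[int(rng.integers(len(WEIGHT_LABELS)))]
    stack = [start]
    circuit: list[str] = []
    while stack:
        node = stack[-1]
        if out[node]:
            stack.append(out[node].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    return circuit


def label_transitions(seq: TrialSequence | list[str] | tuple[str, ...]) -> list[ConditionLabel]:
    """Label each trial with its (cube, switch) condition.

    The first trial is labelled ``discard`` (it has no predecessor); every
    later trial is ``switch`` when its weight differs from the preceding
    trial's and ``no_switch`` otherwise.
    """
    labels = tuple(seq.labels if isinstance(seq, TrialSequence) else seq)
    if len(labels) < 2:
        raise InvalidArgumentError(
            f"need at least 2 trials to label transitions, got {len(labels)}"
        )
    out = [ConditionLabel(labels[0], DISCARD)]
    for prev, cur in zip(labels, labels[1:]):
        out.append(ConditionLabel(cur, SWITCH if cur != prev else NO_SWITCH))
    return out


def save_sequence(path: str | Path, seq: TrialSequence) -> None:
    """Write a sequence as two-column delimited text (trial_index, label)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial_index", "label"])
        for i, label in enumerate(seq.labels, start=1):
            writer.writerow([i, label])


def load_sequence(path: str | Path) -> TrialSequence:
    """Read a sequence written by :func:`save_sequence` and validate it."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["trial_index", "label"]:
            raise SchemaError(
                f"{path}: expected header 'trial_index,label', got {header!r}"
            )
        rows = [row for row in reader if row]
    labels = []
    for lineno, row in enumerate(rows, start=2):
        if len(row) < 2:
            raise SchemaError(f"{path}: line {lineno}: expected 2 columns")
        labels.append(row[1].strip())
    n, remainder = divmod(len(labels) - 1, 4)
    if remainder or n < 1:
        raise InvalidArgumentError(
            f"{path}: {len(labels)} labels is not a balanced sequence length "
            "(must be 4 n + 1)"
        )
    return TrialSequence(tuple(labels), n)
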