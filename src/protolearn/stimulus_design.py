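"""Stimulus space, category structure, and trial schedules.

The task is a probabilistic A/B prototype category-learning paradigm: stimuli
vary on ``n_features`` binary features (default 10, giving 1,024 stimuli).
Prototype A carries the 0 value on every feature, Prototype B the 1 value, and
every other stimulus is characterised by its distance from Prototype A (the
number of B-characteristic values it carries).  Category membership follows
distance: 1-4 -> A, 6-9 -> B; the two prototypes and midline (distance-5)
stimuli are never shown in training, and midline stimuli are conventionally
coded A during testing.

Training schedules show 20 stimuli four times each (80 trials).  The 20
stimuli are chosen so that each feature-value bin occurs in exactly half the
stimuli, and so that every characteristic feature value co-occurs with its
category on 70-80% of the trials in which it appears (the reinforcement-rate
window that makes the task probabilistic).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Stimulus",
    "CategoryStructure",
    "TrialSchedule",
    "ScheduleConstraintError",
    "enumerate_space",
    "category_label",
    "distance_from_A",
    "build_training_schedule",
    "build_testing_schedule",
    "schedule_to_frame",
]

# Display/response timing (ms), carried as epoch bookkeeping only.
OBSERVATIONAL_TIMING = {"stimulus_ms": 7000, "fixation_ms": 1000}
FEEDBACK_TIMING = {
    "response_window_ms": 4000,
    "feedback_delay_ms": 500,
    "feedback_ms": 3000,
}

MIDLINE_FRACTION = 0.5  # midline = distance n/2, only defined for even n


class ScheduleConstraintError(RuntimeError):
    """Raised when constraint-based schedule sampling exhausts its retry cap."""


@dataclass(frozen=True)
class Stimulus:
    """One stimulus: an ordered tuple of binary feature values.

    0 codes the Prototype-A-characteristic value of a feature, 1 the
    Prototype-B-characteristic value.
    """

    features: tuple[int, ...]

    def __post_init__(self) -> None:
        if not all(v in (0, 1) for v in self.features):
            raise ValueError("features must be binary (0/1)")

    @property
    def id(self) -> int:
        """Integer encoding of the feature string (feature 0 = MSB)."""
        out = 0
        for v in self.features:
            out = (out << 1) | v
        return out

    @property
    def distance(self) -> int:
        """Distance from Prototype A = number of B-characteristic values."""
        return sum(self.features)

    @property
    def bits(self) -> str:
        return "".join(str(v) for v in self.features)

    @classmethod
    def from_bits(cls, bits: str) -> "Stimulus":
        return cls(tuple(int(c) for c in bits))


def distance_from_A(s: Stimulus) -> int:
    return s.distance


@dataclass(frozen=True)
class CategoryStructure:
    """Feature count, reinforcement window, and the two prototypes.

    ``reinforcement_window`` is the admissible range for the empirical
    probability that a characteristic feature value co-occurs with its
    category during training.  The two bins of a feature are complementary
    within a delivered schedule: if value 1 co-occurs with B at rate r, value
    0 co-occurs with A at a rate in the same window by construction.
    """

    n_features: int = 10
    reinforcement_window: tuple[float, float] = (0.70, 0.80)

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        lo, hi = self.reinforcement_window
        if not (0.5 < lo <= hi <= 1.0):
            raise ValueError("reinforcement window must lie in (0.5, 1.0]")

    @property
    def prototype_A(self) -> Stimulus:
        return Stimulus((0,) * self.n_features)

    @property
    def prototype_B(self) -> Stimulus:
        return Stimulus((1,) * self.n_features)

    @property
    def midline_distance(self) -> int:
        return self.n_features // 2


@dataclass
class TrialSchedule:
    """An ordered list of (stimulus, correct label) pairs for one phase."""

    phase: str  # observational_training | feedback_training | testing
    trials: list[tuple[Stimulus, str]]
    timing: dict = field(default_factory=dict)
    seen_in_training: list[bool] | None = None  # testing schedules only

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def unique_stimuli(self) -> set[Stimulus]:
        return {s for s, _ in self.trials}


def enumerate_space(n_features: int) -> list[Stimulus]:
    """All 2**n_features stimuli, in feature-string order."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return [Stimulus(bits) for bits in itertools.product((0, 1), repeat=n_features)]


def category_label(s: Stimulus, n_features: int | None = None) -> str:
    """Distance <= midline -> A, above -> B (midline coded A by convention)."""
    n = n_features if n_features is not None else len(s.features)
    return "A" if s.distance <= n // 2 else "B"


# ---------------------------------------------------------------------------
# training schedule construction
# ---------------------------------------------------------------------------

# Distances of the 10 Category-A training stimuli.  Two each at distances 1
# and 4, three each at 2 and 3: this multiset makes per-bin reinforcement
# rates of exactly 0.7 or 0.8 attainable (see _sample_training_set).
_A_DISTANCE_MULTISET = (1, 1, 2, 2, 2, 3, 3, 3, 4, 4)


def _sample_training_set(
    structure: CategoryStructure, rng: np.random.Generator, max_tries: int
) -> list[Stimulus]:
    """Choose the 20 unique training stimuli by rejection sampling.

    The B-side stimuli are the bitwise complements of the A-side stimuli,
    which guarantees (a) each feature-value bin occurs in exactly 10 of the
    20 stimuli and (b) complementary reinforcement of the two bins of each
    feature.  The rejection condition (column sums in {2, 3} over the A-side
    matrix) pins every bin's co-occurrence rate with its characteristic
    category to 0.7 or 0.8.
    """
    n = structure.n_features
    if n != 10:
        raise ValueError("training schedules are defined for the 10-feature task")
    lo, hi = structure.reinforcement_window
    for _ in range(max_tries):
        rows = np.zeros((10, n), dtype=int)
        for i, d in enumerate(_A_DISTANCE_MULTISET):
            rows[i, rng.choice(n, size=d, replace=False)] = 1
        # distinct A stimuli
        if len({tuple(r) for r in rows}) != 10:
            continue
        col = rows.sum(axis=0)
        # B-side co-occurrence rate per value-1 bin is (10 - col_f) / 10
        rates = (10 - col) / 10.0
        if np.all((rates >= lo - 1e-12) & (rates <= hi + 1e-12)):
            a_side = [Stimulus(tuple(r)) for r in rows]
            b_side = [Stimulus(tuple(1 - r)) for r in rows]
            return a_side + b_side
    raise ScheduleConstraintError(
        f"no training set satisfying the reinforcement window {structure.reinforcement_window} "
        f"found in {max_tries} attempts"
    )


def build_training_schedule(
    structure: CategoryStructure,
    condition: str = "feedback",
    seed: int = 0,
    max_tries: int = 10_000,
) -> TrialSchedule:
    """80-trial training schedule: 20 unique stimuli, four presentations each.

    Ten stimuli per category at distances 1-4; prototypes and midline stimuli
    never appear; each feature-value bin occurs in exactly 10 of the 20
    stimuli; per-bin empirical reinforcement rates fall in the structure's
    window.  Fully reproducible from (structure, condition, seed).
    """
    if condition not in ("observational", "feedback"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    stimuli = _sample_training_set(structure, rng, max_tries)
    trials = [
        (s, category_label(s, structure.n_features)) for s in stimuli for _ in range(4)
    ]
    order = rng.permutation(len(trials))
    trials = [trials[i] for i in order]
    phase = f"{condition}_training"
    timing = dict(OBSERVATIONAL_TIMING if condition == "observational" else FEEDBACK_TIMING)
    return TrialSchedule(phase=phase, trials=trials, timing=timing)


def build_testing_schedule(
    structure: CategoryStructure,
    training: TrialSchedule,
    seed: int = 0,
    prototype_repetitions: int = 3,
    max_tries: int = 10_000,
) -> TrialSchedule:
    """50-trial testing schedule.

    Composition: each prototype ``prototype_repetitions`` times (default 3),
    exactly 2 midline trials (coded A), 10 trials of stimuli seen in
    training (5 per category, once each), and novel distance-1-4 stimuli
    filling the remainder to 50 trials.
    """
    if prototype_repetitions not in (2, 3):
        raise ValueError("prototype_repetitions must be 2 or 3")
    n = structure.n_features
    rng = np.random.default_rng(seed)

    trained = sorted(training.unique_stimuli, key=lambda s: s.id)
    trained_a = [s for s in trained if category_label(s, n) == "A"]
    trained_b = [s for s in trained if category_label(s, n) == "B"]
    seen = [trained_a[i] for i in rng.choice(len(trained_a), 5, replace=False)]
    seen += [trained_b[i] for i in rng.choice(len(trained_b), 5, replace=False)]

    n_novel = 50 - 2 * prototype_repetitions - 2 - 10
    trained_set = set(trained)
    mid = structure.midline_distance
    novel: list[Stimulus] = []
    chosen: set[Stimulus] = set()
    # balance novels across categories and distances 1..4 each side
    per_side = n_novel // 2
    for side in ("A", "B"):
        quota = per_side + (n_novel % 2 if side == "A" else 0)
        dists = [1 + i % 4 for i in range(quota)]  # cycle distances 1..4
        for d in dists:
            target = d if side == "A" else n - d
            for _ in range(max_tries):
                feats = np.zeros(n, dtype=int)
                feats[rng.choice(n, size=target, replace=False)] = 1
                s = Stimulus(tuple(feats))
                if s not in trained_set and s not in chosen:
                    novel.append(s)
                    chosen.add(s)
                    break
            else:  # pragma: no cover - 2^10 space never exhausts at these sizes
                raise ScheduleConstraintError("could not draw a novel testing stimulus")

    midline: list[Stimulus] = []
    while len(midline) < 2:
        feats = np.zeros(n, dtype=int)
        feats[rng.choice(n, size=mid, replace=False)] = 1
        s = Stimulus(tuple(feats))
        if s not in chosen and s not in trained_set:
            midline.append(s)
            chosen.add(s)

    pool: list[tuple[Stimulus, str, bool]] = []
    pool += [(structure.prototype_A, "A", False)] * prototype_repetitions
    pool += [(structure.prototype_B, "B", False)] * prototype_repetitions
    pool += [(s, "A", False) for s in midline]  # midline coded A
    pool += [(s, category_label(s, n), True) for s in seen]
    pool += [(s, category_label(s, n), False) for s in novel]
    assert len(pool) == 50

    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]
    return TrialSchedule(
        phase="testing",
        trials=[(s, lab) for s, lab, _ in pool],
        timing={"response_window_ms": 4000},
        seen_in_training=[seen_flag for _, _, seen_flag in pool],
    )


def schedule_to_frame(schedule: TrialSchedule) -> pd.DataFrame:
    """Tidy CSV-ready view of a schedule (one row per trial)."""
    rows = []
    for i, (s, lab) in enumerate(schedule.trials):
        row = {
            "trial_index": i + 1,
            "phase": schedule.phase,
            "stimulus_id": s.id,
            "feature_bits": s.bits,
            "distance": s.distance,
            "correct_label": lab,
        }
        if schedule.seen_in_training is not None:
            row["seen_in_training"] = schedule.seen_in_training[i]
        rows.append(row)
    return pd.DataFrame(rows)
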