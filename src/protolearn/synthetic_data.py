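"""Simulated learners, feedback streams, and feedback-locked EEG epochs.

Since no trial-level human data are deposited, every analysis in this package
is exercised on synthetic cohorts.  Three generative response strategies are
implemented, mirroring the three strategy classes the fitting layer is meant
to recover:

* ``multi_cue`` - integrates evidence across features under limited
  attention: on each trial the agent samples ``attention_breadth`` features
  (without replacement) and responds B with probability
  logistic(evidence_slope x (B-votes - breadth/2)), blended with a uniform
  lapse.  With ``attention_breadth=10`` this reduces to a logistic in the
  stimulus's distance from the category midline.  The default (breadth 5,
  steep slope) yields per-bin B-response rates close to the 70-80%
  reinforcement rates, which is what defines multi-cue responding for the
  strategy fit; a shallow-attention configuration (breadth 3, lapse 0.2)
  produces probability-matching behaviour with testing accuracy in the
  70-80% band.
* ``single_feature`` - keys on one feature: responds ``keyed_direction``
  whenever the B-characteristic value of ``keyed_feature`` is shown (with
  probability ``consistency``), and the opposite label otherwise.
* ``random`` - flips a fair coin on every trial.

Feedback-locked epochs are synthesised as 1/f + white noise plus two Gaussian
components: an FRN-like negativity (default peak 248 ms, larger for negative
feedback) and a P3a-like positivity (default peak 360 ms).  Component
amplitudes may be modulated by training phase per strategy group, which is
how the cohort preset injects the single-feature group's early-to-late FRN
attenuation for end-to-end recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stimulus_design import (
    CategoryStructure,
    Stimulus,
    TrialSchedule,
    build_testing_schedule,
    build_training_schedule,
)

__all__ = [
    "AgentSpec",
    "TrialRecord",
    "EpochSet",
    "ErpParams",
    "Participant",
    "simulate_agent",
    "simulate_cohort",
    "change_in_negative_feedback",
    "simulate_epochs",
    "records_to_frame",
    "paper_cohort_mixture",
    "PAPER_COHORT_GROUP_ERP",
]


@dataclass(frozen=True)
class AgentSpec:
    """Parameters of one simulated learner."""

    strategy_kind: str  # multi_cue | single_feature | random
    keyed_feature: int | None = None  # single_feature only
    keyed_direction: str = "B"  # response when keyed feature's value is 1
    consistency: float = 0.98  # P(follow the rule), single_feature
    evidence_slope: float = 5.0  # logistic slope per net B-vote, multi_cue
    attention_breadth: int = 5  # features sampled per trial, multi_cue
    lapse_rate: float = 0.0  # P(uniform random response), multi_cue
    # probability of expressing the strategy (vs guessing) at the first and
    # last feedback-training trial; linear ramp in between models acquisition
    acquisition: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy_kind not in ("multi_cue", "single_feature", "random"):
            raise ValueError(f"unknown strategy_kind {self.strategy_kind!r}")
        if not 0.0 <= self.consistency <= 1.0:
            raise ValueError("consistency must be in [0, 1]")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")
        if self.strategy_kind == "single_feature":
            if self.keyed_feature is None:
                raise ValueError("single_feature agent requires keyed_feature")
            if self.keyed_direction not in ("A", "B"):
                raise ValueError("keyed_direction must be 'A' or 'B'")
        if self.evidence_slope <= 0:
            raise ValueError("evidence_slope must be positive")
        if not 1 <= self.attention_breadth:
            raise ValueError("attention_breadth must be >= 1")
        if not all(0.0 <= a <= 1.0 for a in self.acquisition):
            raise ValueError("acquisition probabilities must be in [0, 1]")


@dataclass(frozen=True)
class TrialRecord:
    """One trial's stimulus, response, and feedback."""

    trial_index: int  # 1-based within phase
    phase: str
    stimulus: Stimulus
    response: str | None
    correct_label: str
    seen_in_training: bool | None = None

    @property
    def accuracy(self) -> str | None:
        if self.response is None:
            return None
        return "correct" if self.response == self.correct_label else "incorrect"

    @property
    def feedback_valence(self) -> str:
        if self.phase != "feedback_training" or self.response is None:
            return "none"
        return "positive" if self.response == self.correct_label else "negative"


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_index": [r.trial_index for r in records],
            "phase": [r.phase for r in records],
            "stimulus_id": [r.stimulus.id for r in records],
            "feature_bits": [r.stimulus.bits for r in records],
            "distance": [r.stimulus.distance for r in records],
            "response": [r.response for r in records],
            "correct_label": [r.correct_label for r in records],
            "accuracy": [r.accuracy for r in records],
            "feedback_valence": [r.feedback_valence for r in records],
        }
    )


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_agent(
    spec: AgentSpec, schedule: TrialSchedule, rng: np.random.Generator | None = None
) -> list[TrialRecord]:
    """One response per trial, per the agent's strategy.

    Observational training produces button-press echoes of the displayed
    label (excluded from strategy analysis downstream).
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_feat = len(schedule.trials[0][0].features)
    breadth = min(spec.attention_breadth, n_feat)
    n_trials = len(schedule.trials)
    records = []
    for i, (stim, label) in enumerate(schedule.trials):
        if schedule.phase == "feedback_training" and n_trials > 1:
            a0, a1 = spec.acquisition
            p_express = a0 + (a1 - a0) * i / (n_trials - 1)
        else:
            p_express = 1.0  # strategy fully expressed outside acquisition
        if schedule.phase == "observational_training":
            resp = label  # echo of the displayed category label
        elif p_express < 1.0 and rng.random() >= p_express:
            resp = "B" if rng.random() < 0.5 else "A"  # pre-acquisition guess
        elif spec.strategy_kind == "random":
            resp = "B" if rng.random() < 0.5 else "A"
        elif spec.strategy_kind == "single_feature":
            keyed_on = stim.features[spec.keyed_feature] == 1
            rule = spec.keyed_direction if keyed_on else (
                "A" if spec.keyed_direction == "B" else "B"
            )
            follow = rng.random() < spec.consistency
            resp = rule if follow else ("A" if rule == "B" else "B")
        else:  # multi_cue: limited-attention evidence integration
            if rng.random() < spec.lapse_rate:
                resp = "B" if rng.random() < 0.5 else "A"
            else:
                attended = rng.choice(n_feat, size=breadth, replace=False)
                votes = sum(stim.features[j] for j in attended)
                p_b = _logistic(spec.evidence_slope * (votes - breadth / 2.0))
                resp = "B" if rng.random() < p_b else "A"
        records.append(
            TrialRecord(
                trial_index=i + 1,
                phase=schedule.phase,
                stimulus=stim,
                response=resp,
                correct_label=label,
                seen_in_training=(
                    schedule.seen_in_training[i]
                    if schedule.seen_in_training is not None
                    else None
                ),
            )
        )
    return records


def change_in_negative_feedback(records: list[TrialRecord]) -> int:
    """(# negative feedback in trials 1-40) - (# in trials 41-80).

    Positive values mean fewer errors late in training, i.e. improvement.
    """
    fb = sorted(
        (r for r in records if r.phase == "feedback_training"),
        key=lambda r: r.trial_index,
    )
    if len(fb) != 80:
        raise ValueError(f"expected 80 feedback-training records, got {len(fb)}")
    early = sum(r.feedback_valence == "negative" for r in fb[:40])
    late = sum(r.feedback_valence == "negative" for r in fb[40:])
    return early - late


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class Participant:
    """All four phases' records for one simulated participant."""

    participant_id: int
    spec: AgentSpec
    observational_training: list[TrialRecord]
    observational_testing: list[TrialRecord]
    feedback_training: list[TrialRecord]
    feedback_testing: list[TrialRecord]
    training_schedules: dict[str, TrialSchedule] = field(default_factory=dict)

    def testing_accuracy(self, condition: str) -> float:
        recs = (
            self.observational_testing
            if condition == "observational"
            else self.feedback_testing
        )
        return float(np.mean([r.accuracy == "correct" for r in recs])) * 100.0


def paper_cohort_mixture(
    n_multi: int = 26, n_single: int = 8, n_random: int = 4
) -> list[tuple[AgentSpec, int]]:
    """Default cohort preset: the study's feedback-testing strategy counts.

    Multi-cue learners acquire their strategy over feedback training (ramp
    0.3 -> 0.85), which reproduces the study's negative-feedback counts
    (roughly 13 early / 9 late on average) and a realistic handful of
    low-negative-trial exclusions; single-feature and random responders are
    stationary.
    """
    return [
        (AgentSpec("multi_cue", acquisition=(0.3, 0.85)), n_multi),
        (AgentSpec("single_feature", keyed_feature=0), n_single),
        (AgentSpec("random"), n_random),
    ]


def simulate_cohort(
    mixture: list[tuple[AgentSpec, int]],
    structure: CategoryStructure | None = None,
    master_seed: int = 0,
) -> list[Participant]:
    """Simulate a cohort; each participant runs all four task phases.

    Every participant gets an independent seed stream derived from
    ``master_seed`` and their own training/testing schedules (presentation
    order and trained-stimulus selection varied across participants, as in
    counterbalanced stimulus sets).  Single-feature agents are keyed to a
    participant-specific feature and direction.
    """
    if not mixture:
        raise ValueError("mixture must not be empty")
    if any(count < 1 for _, count in mixture):
        raise ValueError("mixture counts must be >= 1")
    structure = structure or CategoryStructure()
    n_total = sum(count for _, count in mixture)
    seeds = np.random.SeedSequence(master_seed).spawn(n_total)
    participants: list[Participant] = []
    pid = 0
    for spec, count in mixture:
        for _ in range(count):
            ss = seeds[pid]
            child = ss.generate_state(4)  # independent per-stage seeds
            rng = np.random.default_rng(ss)
            p_spec = spec
            if spec.strategy_kind == "single_feature":
                p_spec = replace(
                    spec,
                    keyed_feature=int(rng.integers(structure.n_features)),
                    keyed_direction="B" if rng.random() < 0.5 else "A",
                )
            obs_train = build_training_schedule(
                structure, "observational", seed=int(child[0])
            )
            obs_test = build_testing_schedule(structure, obs_train, seed=int(child[1]))
            fb_train = build_training_schedule(structure, "feedback", seed=int(child[2]))
            fb_test = build_testing_schedule(structure, fb_train, seed=int(child[3]))
            participants.append(
                Participant(
                    participant_id=pid + 1,
                    spec=p_spec,
                    observational_training=simulate_agent(p_spec, obs_train, rng),
                    observational_testing=simulate_agent(p_spec, obs_test, rng),
                    feedback_training=simulate_agent(p_spec, fb_train, rng),
                    feedback_testing=simulate_agent(p_spec, fb_test, rng),
                    training_schedules={
                        "observational": obs_train,
                        "feedback": fb_train,
                    },
                )
            )
            pid += 1
    return participants


# ---------------------------------------------------------------------------
# synthetic feedback-locked epochs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErpParams:
    """Generator parameters for feedback-locked epochs (amplitudes in uV).

    The FRN is stored as a negative-going deflection: ``frn_base`` is its
    amplitude after positive feedback, ``frn_valence_effect`` (negative) is
    added after negative feedback, and ``frn_late_shift`` is added in late
    training (positive values = attenuation, i.e. a less negative FRN).
    """

    sampling_rate: float = 1000.0
    window_ms: tuple[float, float] = (-200.0, 800.0)
    noise_white_sd: float = 3.0
    noise_pink_sd: float = 1.5
    frn_latency_ms: float = 248.0
    frn_width_ms: float = 40.0
    frn_base: float = -1.0
    frn_valence_effect: float = -1.5
    frn_late_shift: float = 0.0
    frn_individual_sd: float = 0.5  # between-participant amplitude SD
    p3a_latency_ms: float = 360.0
    p3a_width_ms: float = 50.0
    p3a_base: float = 2.5
    p3a_valence_effect: float = 0.0
    p3a_late_shift: float = 0.0
    p3a_individual_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.frn_width_ms <= 0 or self.p3a_width_ms <= 0:
            raise ValueError("component widths must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.noise_white_sd < 0 or self.noise_pink_sd < 0:
            raise ValueError("noise SDs must be non-negative")


# Per-strategy-group ERP parameters for the default cohort: the
# single-feature group's FRN attenuates from early to late training (the
# phase-by-strategy interaction under study); other groups keep a stable FRN.
PAPER_COHORT_GROUP_ERP: dict[str, ErpParams] = {
    "multi_cue": ErpParams(),
    "single_feature": ErpParams(frn_late_shift=2.0),
    "random": ErpParams(),
}


@dataclass
class EpochSet:
    """Feedback-locked single-channel epochs plus per-epoch labels."""

    data: np.ndarray  # (n_epochs, n_samples) uV
    times_ms: np.ndarray  # (n_samples,)
    labels: pd.DataFrame  # trial_index, feedback_valence, training_phase
    sampling_rate: float = 1000.0
    channel: str = "FCz"
    participant_id: int | None = None

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.labels):
            raise ValueError("label rows must match epoch count")
        if self.data.shape[1] != len(self.times_ms):
            raise ValueError("times_ms must match epoch length")


def _gaussian_bump(times_ms: np.ndarray, latency: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times_ms - latency) / width) ** 2)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float) -> np.ndarray:
    """1/f-amplitude noise, generated in the frequency domain per epoch."""
    if sd == 0:
        return np.zeros(shape)
    n = shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    white = rng.standard_normal((shape[0], freqs.size)) + 1j * rng.standard_normal(
        (shape[0], freqs.size)
    )
    x = np.fft.irfft(white * scale, n=n, axis=1)
    x_sd = x.std()
    return x * (sd / x_sd) if x_sd > 0 else x


def simulate_epochs(
    records: list[TrialRecord],
    erp_params: ErpParams | None = None,
    seed: int = 0,
    participant_id: int | None = None,
) -> EpochSet:
    """One synthetic feedback-locked epoch per feedback-training trial.

    Each epoch is noise (1/f + white) plus an FRN-like Gaussian negativity and
    a P3a-like Gaussian positivity whose amplitudes depend on feedback valence
    and training phase (trials 1-40 = early, 41-80 = late).
    """
    p = erp_params or ErpParams()
    fb = sorted(
        (r for r in records if r.phase == "feedback_training"),
        key=lambda r: r.trial_index,
    )
    if not fb:
        raise ValueError("no feedback-training records supplied")
    n_half = len(fb) // 2
    rng = np.random.default_rng(seed)
    dt = 1000.0 / p.sampling_rate
    times = np.arange(p.window_ms[0], p.window_ms[1], dt)
    frn_shape = _gaussian_bump(times, p.frn_latency_ms, p.frn_width_ms)
    p3a_shape = _gaussian_bump(times, p.p3a_latency_ms, p.p3a_width_ms)

    n_ep = len(fb)
    # participant-level amplitude offsets: individuals differ in overall
    # component size, which carries the between-observation variance the
    # temporal PCA decomposes
    frn_indiv = rng.normal(0.0, p.frn_individual_sd)
    p3a_indiv = rng.normal(0.0, p.p3a_individual_sd)
    data = _pink_noise(rng, (n_ep, times.size), p.noise_pink_sd)
    if p.noise_white_sd > 0:
        data += rng.normal(0.0, p.noise_white_sd, size=(n_ep, times.size))

    rows = []
    for i, r in enumerate(fb):
        neg = r.feedback_valence == "negative"
        late = r.trial_index > n_half
        frn_amp = p.frn_base + frn_indiv + (p.frn_valence_effect if neg else 0.0) + (
            p.frn_late_shift if late else 0.0
        )
        p3a_amp = p.p3a_base + p3a_indiv + (p.p3a_valence_effect if neg else 0.0) + (
            p.p3a_late_shift if late else 0.0
        )
        data[i] += frn_amp * frn_shape + p3a_amp * p3a_shape
        rows.append(
            {
                "trial_index": r.trial_index,
                "feedback_valence": r.feedback_valence,
                "training_phase": "late" if late else "early",
            }
        )
    return EpochSet(
        data=data,
        times_ms=times,
        labels=pd.DataFrame(rows),
        sampling_rate=p.sampling_rate,
        participant_id=participant_id,
    )


def simulate_cohort_epochs(
    participants: list[Participant],
    group_params: dict[str, ErpParams] | None = None,
    master_seed: int = 0,
) -> dict[int, EpochSet]:
    """Epochs for every participant, with strategy-group-specific ERP params."""
    group_params = group_params or PAPER_COHORT_GROUP_ERP
    seeds = np.random.SeedSequence(master_seed).spawn(len(participants))
    out: dict[int, EpochSet] = {}
    for part, ss in zip(participants, seeds):
        params = group_params[part.spec.strategy_kind]
        out[part.participant_id] = simulate_epochs(
            part.feedback_training,
            params,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            participant_id=part.participant_id,
        )
    return out
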