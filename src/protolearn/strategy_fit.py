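"""Strategy analysis: response profiles, the 22-model bank, fit scores.

A participant's responses over a phase segment are summarised per
feature-value bin (20 bins: both values of each of 10 features) as the number
of trials in which the bin appeared (``n_presentations``) and the number of
B-responses on those trials (``b_actual``).  Each candidate strategy model
supplies an expected B-count per bin, and its fit score is the normalised sum
of squared deviations

    score(M) = sum_F (b_expected_F,M - b_actual_F)^2 / sum_F n_presentations_F^2

which lies in [0, 1] and is 0 exactly when the model reproduces the observed
counts in every bin.  The bank holds 22 models: one multi-cue model whose
expected rates equal the delivered training schedule's per-bin B-reinforcement
rates, twenty single-feature rules (one per feature and response direction,
applied trialwise to the evaluation segment), and one random model (0.5
everywhere).  The best-fitting (lowest-score) model classifies the segment.

Because the denominator does not depend on the model, the classification is
invariant to any positive model-independent normalisation; the alternative
(sum_F n_F)^2 grouping of the score formula is exposed as an option and cannot
change the argmin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus_design import Stimulus, TrialSchedule
from .synthetic_data import TrialRecord

__all__ = [
    "ResponseProfile",
    "StrategyModel",
    "FitResult",
    "extract_profile",
    "build_model_bank",
    "fit_score",
    "fit_score_from_counts",
    "classify",
    "split_phases",
    "strategy_proportions",
]

logger = logging.getLogger(__name__)


@dataclass
class ResponseProfile:
    """Per-bin presentation and B-response counts for one phase segment.

    Bin (f, v) counts the trials on which feature ``f`` showed value ``v``.
    The segment's stimuli and responses are retained so that trialwise models
    (the single-feature rules) can be evaluated against the same trials.
    """

    n_presentations: np.ndarray  # (n_features, 2) int
    b_actual: np.ndarray  # (n_features, 2) int
    stimuli: list[Stimulus] | None = None
    responses: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_presentations.shape != self.b_actual.shape:
            raise ValueError("count arrays must have matching shapes")
        if np.any(self.b_actual < 0) or np.any(self.b_actual > self.n_presentations):
            raise ValueError("b_actual must lie in [0, n_presentations] per bin")

    @property
    def n_features(self) -> int:
        return self.n_presentations.shape[0]

    @property
    def n_trials(self) -> int:
        # each trial contributes to exactly one bin per feature
        return int(self.n_presentations[0].sum())


def extract_profile(records: list[TrialRecord]) -> ResponseProfile:
    """Tally presentations and B-responses per feature-value bin.

    Every responded trial contributes to exactly one bin of each feature.
    Trials with missing responses are excluded (count logged).
    """
    responded = [r for r in records if r.response is not None]
    n_missing = len(records) - len(responded)
    if n_missing:
        logger.info("extract_profile: excluded %d trials with missing responses", n_missing)
    if not responded:
        raise ValueError("no responded trials to profile")
    n_feat = len(responded[0].stimulus.features)
    n_pres = np.zeros((n_feat, 2), dtype=int)
    b_act = np.zeros((n_feat, 2), dtype=int)
    for r in responded:
        feats = np.asarray(r.stimulus.features)
        n_pres[np.arange(n_feat), feats] += 1
        if r.response == "B":
            b_act[np.arange(n_feat), feats] += 1
    return ResponseProfile(
        n_presentations=n_pres,
        b_actual=b_act,
        stimuli=[r.stimulus for r in responded],
        responses=[r.response for r in responded],
    )


@dataclass(frozen=True)
class StrategyModel:
    """One candidate response model.

    * ``multi_cue``: per-bin expected B-rate = the delivered training
      schedule's B-reinforcement rate for that bin.
    * ``single_feature``: deterministic trialwise rule - respond
      ``keyed_direction`` whenever ``keyed_feature`` shows value 1, the
      opposite label otherwise; expected counts accumulate rule responses over
      the evaluation segment's actual trials.
    * ``random``: B-rate 0.5 in every bin.
    """

    model_id: str
    kind: str  # multi_cue | single_feature | random
    keyed_feature: int | None = None
    keyed_direction: str | None = None
    rates: tuple[tuple[float, float], ...] | None = None  # multi_cue per-bin rates
    order_index: int = 0  # deterministic tie-break rank

    def expected_counts(self, profile: ResponseProfile) -> np.ndarray:
        """Expected B-count per bin given the profile's trials.

        Bins never presented (n=0) contribute an expected count of 0, so they
        drop out of the score sums.
        """
        n_pres = profile.n_presentations
        if self.kind == "random":
            return n_pres / 2.0
        if self.kind == "multi_cue":
            rates = np.asarray(self.rates, dtype=float)
            rates = np.where(np.isnan(rates), 0.0, rates)  # unseen bins skipped
            return rates * n_pres
        # single_feature: trialwise application to the evaluation segment
        if profile.stimuli is None:
            raise ValueError("trialwise models need the profile's stimuli")
        n_feat = profile.n_features
        expected = np.zeros((n_feat, 2))
        for stim in profile.stimuli:
            keyed_on = stim.features[self.keyed_feature] == 1
            resp = self.keyed_direction if keyed_on else (
                "A" if self.keyed_direction == "B" else "B"
            )
            if resp == "B":
                feats = np.asarray(stim.features)
                expected[np.arange(n_feat), feats] += 1
        return expected


def build_model_bank(training: TrialSchedule) -> list[StrategyModel]:
    """The 22-model bank for a 10-feature task (1 + 20 + 1 models).

    Multi-cue rates come from the *delivered* training schedule: for each bin,
    the fraction of training trials containing that feature value whose
    correct label was B.  A bin never presented in training gets a NaN rate
    and is skipped during evaluation.
    """
    if "training" not in training.phase:
        raise ValueError("model bank must be built from a training schedule")
    n_feat = len(training.trials[0][0].features)
    n_pres = np.zeros((n_feat, 2))
    n_b = np.zeros((n_feat, 2))
    for stim, label in training.trials:
        feats = np.asarray(stim.features)
        n_pres[np.arange(n_feat), feats] += 1
        if label == "B":
            n_b[np.arange(n_feat), feats] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(n_pres > 0, n_b / np.maximum(n_pres, 1), np.nan)

    bank: list[StrategyModel] = [
        StrategyModel(model_id="random", kind="random", order_index=0)
    ]
    order = 1
    for f in range(n_feat):
        for direction in ("A", "B"):
            bank.append(
                StrategyModel(
                    model_id=f"single_feature_f{f}_{direction}",
                    kind="single_feature",
                    keyed_feature=f,
                    keyed_direction=direction,
                    order_index=order,
                )
            )
            order += 1
    bank.append(
        StrategyModel(
            model_id="multi_cue",
            kind="multi_cue",
            rates=tuple(map(tuple, rates)),
            order_index=order,
        )
    )
    return bank


def fit_score_from_counts(
    b_expected: np.ndarray,
    b_actual: np.ndarray,
    n_presentations: np.ndarray,
    denominator: str = "sum_of_squares",
) -> float:
    """Normalised squared deviation between expected and actual B-counts.

    ``denominator="sum_of_squares"`` (default) divides by sum_F n_F^2, which
    bounds the score in [0, 1]; ``"square_of_sum"`` divides by (sum_F n_F)^2.
    Both are model-independent, so classifications agree.
    """
    n = np.asarray(n_presentations, dtype=float)
    if not np.any(n > 0):
        raise ValueError("undefined score: no bin was ever presented")
    num = float(np.sum((np.asarray(b_expected, float) - np.asarray(b_actual, float)) ** 2))
    if denominator == "sum_of_squares":
        den = float(np.sum(n**2))
    elif denominator == "square_of_sum":
        den = float(np.sum(n) ** 2)
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    return num / den


def fit_score(
    profile: ResponseProfile,
    model: StrategyModel,
    denominator: str = "sum_of_squares",
) -> float:
    return fit_score_from_counts(
        model.expected_counts(profile),
        profile.b_actual,
        profile.n_presentations,
        denominator=denominator,
    )


@dataclass
class FitResult:
    """Scores for every model plus the winning classification."""

    scores: dict[str, float]
    best_model: str
    collapsed_class: str
    margin: float
    keyed_feature: int | None = None


def classify(
    profile: ResponseProfile,
    bank: list[StrategyModel],
    denominator: str = "sum_of_squares",
) -> FitResult:
    """Score all models; lowest score wins.

    Ties are broken deterministically by bank order: random, then
    single-feature models by feature index (A direction before B), then
    multi-cue.  Exact ties are essentially confined to tiny toy inputs.
    """
    if not bank:
        raise ValueError("model bank is empty")
    scored = sorted(
        ((fit_score(profile, m, denominator), m.order_index, m) for m in bank),
        key=lambda t: (t[0], t[1]),
    )
    best_score, _, best = scored[0]
    margin = (scored[1][0] - best_score) if len(scored) > 1 else math.inf
    return FitResult(
        scores={m.model_id: s for s, _, m in scored},
        best_model=best.model_id,
        collapsed_class=best.kind,
        margin=margin,
        keyed_feature=best.keyed_feature,
    )


def split_phases(
    records: list[TrialRecord],
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Early (trials 1-40) and late (41-80) feedback-training segments."""
    ordered = sorted(records, key=lambda r: r.trial_index)
    if len(ordered) != 80:
        raise ValueError(f"expected exactly 80 records, got {len(ordered)}")
    return ordered[:40], ordered[40:]


def strategy_proportions(results: list[FitResult]) -> pd.DataFrame:
    """Counts and display percentages per collapsed strategy class.

    Percentages are truncated to whole numbers for display (matching the
    reporting convention in which 4/38 appears as 10%).
    """
    if not results:
        raise ValueError("no classified participants")
    classes = ["multi_cue", "single_feature", "random"]
    counts = {c: sum(r.collapsed_class == c for r in results) for c in classes}
    n = len(results)
    return pd.DataFrame(
        {
            "strategy": classes,
            "count": [counts[c] for c in classes],
            "proportion": [counts[c] / n for c in classes],
            "percent": [int(math.floor(100.0 * counts[c] / n)) for c in classes],
        }
    )
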