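"""Feedback-locked ERP pipeline: preprocessing, temporal PCA, factor scores.

Epochs (one channel, -200..800 ms around feedback onset) are zero-phase
bandpass filtered (0.1-30 Hz), baseline-corrected against the -200..-100 ms
pre-feedback window, and rejected if any sample exceeds an amplitude
threshold.  Participants with fewer than ``min_negative_trials`` negative
feedback epochs in either the early or the late training segment are excluded
(too few trials to estimate a stable feedback ERP).

Condition-average waveforms (feedback valence x training phase, four cells
per participant) form the observation matrix for a temporal principal
component analysis: PCA of the time-point covariance, followed by varimax
rotation of the retained loadings.  Factors are labelled FRN or P3a by the
latency of their loading peak (FRN window 200-300 ms, P3a window 300-450 ms).
Factor loadings are peak-normalised so the regression-method factor scores
are on a microvolt scale: a waveform's score on a factor is the fitted
amplitude of that factor's time course within it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .synthetic_data import EpochSet

__all__ = [
    "PreprocessConfig",
    "FactorDecomposition",
    "preprocess",
    "baseline_correct",
    "exclude_low_trial_participants",
    "condition_average",
    "temporal_pca",
    "assign_components",
    "score_conditions",
    "run_erp_pipeline",
]

logger = logging.getLogger(__name__)

CELLS = [("positive", "early"), ("positive", "late"), ("negative", "early"), ("negative", "late")]


@dataclass(frozen=True)
class PreprocessConfig:
    bandpass_hz: tuple[float, float] = (0.1, 30.0)
    baseline_ms: tuple[float, float] = (-200.0, -100.0)
    rejection_threshold_uv: float = 100.0
    min_negative_trials: int = 6
    filter_order: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.bandpass_hz
        if not 0 < lo < hi:
            raise ValueError("bandpass must satisfy 0 < low < high")
        if self.rejection_threshold_uv <= 0:
            raise ValueError("rejection threshold must be positive")


def baseline_correct(epochs: EpochSet, baseline_ms: tuple[float, float]) -> EpochSet:
    """Subtract each epoch's mean over the baseline window (idempotent)."""
    lo, hi = baseline_ms
    t = epochs.times_ms
    if lo < t[0] or hi > t[-1]:
        raise ValueError("baseline window must lie inside the epoch window")
    mask = (t >= lo) & (t < hi)
    data = epochs.data - epochs.data[:, mask].mean(axis=1, keepdims=True)
    return replace_data(epochs, data, epochs.labels)


def replace_data(epochs: EpochSet, data: np.ndarray, labels: pd.DataFrame) -> EpochSet:
    return EpochSet(
        data=data,
        times_ms=epochs.times_ms,
        labels=labels.reset_index(drop=True),
        sampling_rate=epochs.sampling_rate,
        channel=epochs.channel,
        participant_id=epochs.participant_id,
    )


def preprocess(epochs: EpochSet, cfg: PreprocessConfig | None = None) -> tuple[EpochSet, dict]:
    """Zero-phase bandpass, baseline correction, amplitude-threshold rejection.

    Returns the retained epochs and a drop log.  If every epoch is rejected,
    an empty set is returned with ``report["all_rejected"] = True`` and a
    warning is emitted; downstream exclusion then flags the participant.
    """
    cfg = cfg or PreprocessConfig()
    sos = signal.butter(
        cfg.filter_order,
        cfg.bandpass_hz,
        btype="bandpass",
        fs=epochs.sampling_rate,
        output="sos",
    )
    # maximal padding: the 0.1 Hz highpass transient outlasts the 1 s epoch,
    # so short default padding would leave visible edge artifacts
    filtered = signal.sosfiltfilt(
        sos, epochs.data, axis=1, padlen=epochs.data.shape[1] - 1
    )
    corrected = baseline_correct(replace_data(epochs, filtered, epochs.labels), cfg.baseline_ms)
    keep = np.max(np.abs(corrected.data), axis=1) <= cfg.rejection_threshold_uv
    n_dropped = int((~keep).sum())
    report = {
        "n_input": len(keep),
        "n_rejected": n_dropped,
        "rejected_trials": corrected.labels.loc[~keep, "trial_index"].tolist(),
        "all_rejected": not keep.any(),
    }
    if report["all_rejected"]:
        warnings.warn(
            f"participant {epochs.participant_id}: all epochs rejected", stacklevel=2
        )
    retained = replace_data(corrected, corrected.data[keep], corrected.labels.loc[keep])
    return retained, report


def latency_align(epochs: EpochSet, max_shift_ms: float = 50.0) -> EpochSet:
    """Optional single-trial latency alignment by cross-correlation.

    Each epoch is shifted (within +/- ``max_shift_ms``) to the lag maximising
    its cross-correlation with the participant's average waveform; vacated
    samples are zero-filled.  Off by default in the pipeline: inter-trial
    latency jitter is not part of the default generator, and aligning noise
    biases component amplitudes upward.
    """
    if max_shift_ms <= 0:
        raise ValueError("max_shift_ms must be positive")
    max_lag = int(round(max_shift_ms * epochs.sampling_rate / 1000.0))
    template = epochs.data.mean(axis=0)
    template = template - template.mean()
    aligned = np.empty_like(epochs.data)
    n = epochs.data.shape[1]
    for i, row in enumerate(epochs.data):
        x = row - row.mean()
        corr = signal.correlate(x, template, mode="full")
        mid = n - 1
        window = corr[mid - max_lag : mid + max_lag + 1]
        lag = int(np.argmax(window)) - max_lag  # x leads template by `lag`
        shifted = np.zeros(n)
        if lag > 0:
            shifted[: n - lag] = row[lag:]
        elif lag < 0:
            shifted[-lag:] = row[: n + lag]
        else:
            shifted = row.copy()
        aligned[i] = shifted
    return replace_data(epochs, aligned, epochs.labels)


def exclude_low_trial_participants(
    cohort: dict[int, EpochSet], min_negative_trials: int = 6
) -> tuple[dict[int, EpochSet], pd.DataFrame]:
    """Drop participants with < min negative epochs in early or late training."""
    rows = []
    retained: dict[int, EpochSet] = {}
    for pid, ep in cohort.items():
        lab = ep.labels
        neg = lab["feedback_valence"] == "negative"
        n_early = int((neg & (lab["training_phase"] == "early")).sum())
        n_late = int((neg & (lab["training_phase"] == "late")).sum())
        excluded = n_early < min_negative_trials or n_late < min_negative_trials
        rows.append(
            {
                "participant_id": pid,
                "n_negative_early": n_early,
                "n_negative_late": n_late,
                "excluded": excluded,
            }
        )
        if not excluded:
            retained[pid] = ep
    return retained, pd.DataFrame(rows)


def condition_average(epochs: EpochSet) -> tuple[dict[tuple[str, str], np.ndarray], dict]:
    """Pointwise mean waveform for each feedback-valence x phase cell."""
    averages: dict[tuple[str, str], np.ndarray] = {}
    counts: dict[tuple[str, str], int] = {}
    lab = epochs.labels
    for valence, phase in CELLS:
        mask = (lab["feedback_valence"] == valence) & (lab["training_phase"] == phase)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(
                f"participant {epochs.participant_id}: empty cell ({valence}, {phase})"
            )
        averages[(valence, phase)] = epochs.data[mask.to_numpy()].mean(axis=0)
        counts[(valence, phase)] = n
    return averages, counts


# ---------------------------------------------------------------------------
# temporal PCA
# ---------------------------------------------------------------------------


@dataclass
class FactorDecomposition:
    """Varimax-rotated temporal PCA of condition-average waveforms.

    ``loadings`` columns are peak-normalised factor time courses (peak value
    +1), so regression scores are microvolt amplitudes.  ``scores`` rows align
    with the observation rows in ``observations``.
    """

    loadings: np.ndarray  # (n_times, n_factors), peak-normalised
    scores: np.ndarray  # (n_obs, n_factors), uV scale
    variance_explained: np.ndarray  # fraction of total variance per factor
    peak_latencies_ms: np.ndarray
    times_ms: np.ndarray
    observations: pd.DataFrame  # participant_id, feedback_valence, training_phase
    column_means: np.ndarray
    frn_factor: int | None = None
    p3a_factor: int | None = None


def _varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Kaiser's varimax rotation (orthogonal), returning rotated loadings."""
    L = loadings.copy()
    p, k = L.shape
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - (Lr * np.mean(Lr**2, axis=0))), full_matrices=False
        )
        R = u @ vt
        var_new = float(s.sum())
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new
    return L @ R


def temporal_pca(
    waveforms: np.ndarray,
    times_ms: np.ndarray,
    observations: pd.DataFrame,
    n_factors: int | None = 7,
    variance_criterion: float | None = None,
    rotate: bool = True,
) -> FactorDecomposition:
    """Covariance-based temporal PCA with optional varimax rotation.

    ``waveforms`` is (n_observations, n_times); rows are participant x
    condition averages.  Either a fixed ``n_factors`` or a cumulative
    ``variance_criterion`` in (0, 1] selects the retained factors.
    """
    X = np.asarray(waveforms, dtype=float)
    n_obs, n_times = X.shape
    mu = X.mean(axis=0)
    Xc = X - mu
    # SVD of the centered data gives the time-point covariance eigenstructure
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / max(n_obs - 1, 1)
    total_var = eigvals.sum()
    if variance_criterion is not None:
        cum = np.cumsum(eigvals) / total_var
        k = int(np.searchsorted(cum, variance_criterion) + 1)
    else:
        k = int(n_factors)
    if k < 1 or n_obs < 2 * k:
        raise ValueError(
            f"need at least 2 x n_factors observations (have {n_obs}, want {k} factors)"
        )
    # covariance-scaled loadings (time x factor)
    L = vt[:k].T * np.sqrt(eigvals[:k])
    if rotate and k > 1:
        L = _varimax(L)
    # order by rotated variance accounted for
    fac_var = (L**2).sum(axis=0)
    order = np.argsort(fac_var)[::-1]
    L = L[:, order]
    fac_var = fac_var[order]
    # sign convention: loading value at the absolute peak is positive
    peaks = np.argmax(np.abs(L), axis=0)
    flips = np.sign(L[peaks, np.arange(L.shape[1])])
    flips[flips == 0] = 1.0
    L = L * flips
    # peak-normalise so regression scores are in microvolts
    L = L / L[peaks, np.arange(L.shape[1])]
    scores, *_ = np.linalg.lstsq(L, Xc.T, rcond=None)
    return FactorDecomposition(
        loadings=L,
        scores=scores.T,
        variance_explained=fac_var / total_var,
        peak_latencies_ms=times_ms[peaks],
        times_ms=times_ms,
        observations=observations.reset_index(drop=True),
        column_means=mu,
    )


def assign_components(
    dec: FactorDecomposition,
    frn_window_ms: tuple[float, float] = (200.0, 300.0),
    p3a_window_ms: tuple[float, float] = (300.0, 450.0),
) -> FactorDecomposition:
    """Label the FRN and P3a factors by loading-peak latency.

    Within each window the factor explaining the most variance wins; the
    factor chosen as FRN is excluded from P3a candidacy.  A window with no
    candidate yields a null label and a warning.
    """
    lat = dec.peak_latencies_ms

    def pick(window: tuple[float, float], exclude: int | None) -> int | None:
        cands = [
            i
            for i in range(len(lat))
            if window[0] <= lat[i] <= window[1] and i != exclude
        ]
        if not cands:
            return None
        if len(cands) > 1:
            logger.info(
                "multiple factors peak in %s ms: %s; choosing largest variance",
                window,
                cands,
            )
        return max(cands, key=lambda i: dec.variance_explained[i])

    frn = pick(frn_window_ms, exclude=None)
    if frn is None:
        warnings.warn(f"no factor peaks inside the FRN window {frn_window_ms} ms", stacklevel=2)
    p3a = pick(p3a_window_ms, exclude=frn)
    if p3a is None:
        warnings.warn(f"no factor peaks inside the P3a window {p3a_window_ms} ms", stacklevel=2)
    dec.frn_factor = frn
    dec.p3a_factor = p3a
    return dec


def score_conditions(dec: FactorDecomposition) -> pd.DataFrame:
    """Tidy FRN/P3a factor scores per participant x valence x phase cell."""
    if dec.frn_factor is None and dec.p3a_factor is None:
        raise ValueError("no labelled components; run assign_components first")
    frames = []
    for name, idx in (("FRN", dec.frn_factor), ("P3a", dec.p3a_factor)):
        if idx is None:
            continue
        df = dec.observations.copy()
        df["component"] = name
        df["score"] = dec.scores[:, idx]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[["participant_id", "component", "feedback_valence", "training_phase", "score"]]


def run_erp_pipeline(
    cohort_epochs: dict[int, EpochSet],
    cfg: PreprocessConfig | None = None,
    n_factors: int = 7,
    rotate: bool = True,
) -> tuple[pd.DataFrame, FactorDecomposition, pd.DataFrame]:
    """Cohort epochs -> (condition scores, labelled decomposition, exclusions)."""
    cfg = cfg or PreprocessConfig()
    cleaned: dict[int, EpochSet] = {}
    for pid, ep in cohort_epochs.items():
        retained, _ = preprocess(ep, cfg)
        if len(retained.labels):
            cleaned[pid] = retained
    retained_cohort, exclusions = exclude_low_trial_participants(
        cleaned, cfg.min_negative_trials
    )
    if not retained_cohort:
        raise ValueError("no participants retained after exclusion")
    rows = []
    waves = []
    for pid, ep in retained_cohort.items():
        averages, _ = condition_average(ep)
        for (valence, phase), wave in averages.items():
            rows.append(
                {
                    "participant_id": pid,
                    "feedback_valence": valence,
                    "training_phase": phase,
                }
            )
            waves.append(wave)
    obs = pd.DataFrame(rows)
    dec = temporal_pca(
        np.vstack(waves),
        next(iter(retained_cohort.values())).times_ms,
        obs,
        n_factors=n_factors,
        rotate=rotate,
    )
    dec = assign_components(dec)
    return score_conditions(dec), dec, exclusions
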