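"""Pipeline configuration and stage runners tying the analyses together.

A run is a pure function of a :class:`RunConfig`: every source of randomness
derives from the single master seed, intermediate products are plain
CSV/TSV/JSON files with documented schemas, and a manifest records a SHA-256
checksum for every file a stage writes, so repeated runs from one config are
byte-identical and auditable.

Stage flow::

    simulate  -> trial_logs.csv, epochs_p<ID>.tsv (+ _labels.csv), epochs_meta.json
    fit       -> strategy_fits.csv, strategy_proportions_<segment>.csv
    erp       -> condition_scores.csv, factor_loadings.tsv, exclusion_report.csv
    stats     -> report.txt + per-section CSVs
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import erp_pipeline, stats_report, strategy_fit
from .stimulus_design import CategoryStructure, Stimulus, TrialSchedule
from .synthetic_data import (
    AgentSpec,
    EpochSet,
    ErpParams,
    TrialRecord,
    paper_cohort_mixture,
    records_to_frame,
    simulate_cohort,
    simulate_cohort_epochs,
)

__all__ = [
    "RunConfig",
    "SchemaError",
    "run_simulate",
    "run_fit",
    "run_erp",
    "run_stats",
    "run_all",
    "load_trial_logs",
    "load_epochs",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """An input file does not carry the columns a stage requires."""


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on."""

    seed: int = 0
    mixture: list[dict] = field(
        default_factory=lambda: [
            {"strategy_kind": "multi_cue", "count": 26, "acquisition": [0.3, 0.85]},
            {"strategy_kind": "single_feature", "count": 8},
            {"strategy_kind": "random", "count": 4},
        ]
    )
    n_features: int = 10
    reinforcement_window: tuple[float, float] = (0.70, 0.80)
    prototype_repetitions: int = 3
    erp_group_params: dict[str, dict] = field(
        default_factory=lambda: {"single_feature": {"frn_late_shift": 2.0}}
    )
    bandpass_hz: tuple[float, float] = (0.1, 30.0)
    baseline_ms: tuple[float, float] = (-200.0, -100.0)
    rejection_threshold_uv: float = 100.0
    min_negative_trials: int = 6
    n_factors: int = 7

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for tup_key in ("reinforcement_window", "bandpass_hz", "baseline_ms"):
            setattr(cfg, tup_key, tuple(getattr(cfg, tup_key)))
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for tup_key in ("reinforcement_window", "bandpass_hz", "baseline_ms"):
            d[tup_key] = list(d[tup_key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def agent_mixture(self) -> list[tuple[AgentSpec, int]]:
        if not self.mixture or sum(m.get("count", 0) for m in self.mixture) < 1:
            raise ValueError("mixture must contain at least one participant")
        out = []
        for m in self.mixture:
            m = dict(m)
            count = int(m.pop("count"))
            kind = m.pop("strategy_kind")
            if kind == "single_feature" and "keyed_feature" not in m:
                m["keyed_feature"] = 0  # reassigned per participant at simulation
            if "acquisition" in m:
                m["acquisition"] = tuple(m["acquisition"])
            out.append((AgentSpec(strategy_kind=kind, **m), count))
        return out

    def structure(self) -> CategoryStructure:
        return CategoryStructure(self.n_features, self.reinforcement_window)

    def preprocess_config(self) -> erp_pipeline.PreprocessConfig:
        return erp_pipeline.PreprocessConfig(
            bandpass_hz=self.bandpass_hz,
            baseline_ms=self.baseline_ms,
            rejection_threshold_uv=self.rejection_threshold_uv,
            min_negative_trials=self.min_negative_trials,
        )

    def group_erp_params(self) -> dict[str, ErpParams]:
        out = {}
        for kind in ("multi_cue", "single_feature", "random"):
            overrides = self.erp_group_params.get(kind, {})
            out[kind] = ErpParams(**overrides)
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, files: list[Path], stage: str) -> None:
    manifest_path = out_dir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest[stage] = {
        str(p.relative_to(out_dir)): _sha256(p) for p in sorted(files)
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

_LOG_COLUMNS = [
    "participant_id", "strategy_truth", "trial_index", "phase", "stimulus_id",
    "feature_bits", "distance", "response", "correct_label", "accuracy",
    "feedback_valence",
]


def run_simulate(config: RunConfig, out_dir) -> dict:
    """Simulate the cohort and write trial logs plus epoch matrices."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants = simulate_cohort(
        config.agent_mixture(), config.structure(), master_seed=config.seed
    )
    frames = []
    for p in participants:
        for records in (
            p.observational_training,
            p.observational_testing,
            p.feedback_training,
            p.feedback_testing,
        ):
            df = records_to_frame(records)
            # testing phases occur once per condition; disambiguate them
            if records is p.observational_testing:
                df["phase"] = "observational_testing"
            elif records is p.feedback_testing:
                df["phase"] = "feedback_testing"
            df.insert(0, "strategy_truth", p.spec.strategy_kind)
            df.insert(0, "participant_id", p.participant_id)
            frames.append(df)
    logs = pd.concat(frames, ignore_index=True)[_LOG_COLUMNS]
    written = []
    log_path = out / "trial_logs.csv"
    logs.to_csv(log_path, index=False)
    written.append(log_path)

    epochs = simulate_cohort_epochs(
        participants, config.group_erp_params(), master_seed=config.seed
    )
    meta = None
    for pid, ep in epochs.items():
        mat = out / f"epochs_p{pid:03d}.tsv"
        np.savetxt(mat, ep.data, fmt="%.6e", delimiter="\t")
        lab = out / f"epochs_p{pid:03d}_labels.csv"
        ep.labels.to_csv(lab, index=False)
        written += [mat, lab]
        if meta is None:
            meta = {
                "sampling_rate": ep.sampling_rate,
                "window_ms": [float(ep.times_ms[0]), float(ep.times_ms[-1])],
                "n_samples": int(ep.data.shape[1]),
                "channel": ep.channel,
            }
    meta_path = out / "epochs_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    written.append(meta_path)
    config.to_yaml(out / "config.yaml")
    written.append(out / "config.yaml")
    _write_manifest(out, written, "simulate")
    logger.info("simulate: %d participants, %d trials logged", len(participants), len(logs))
    return {"participants": len(participants), "files": [str(p) for p in written]}


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def load_trial_logs(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"feature_bits": str})
    missing = set(_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"trial log missing columns: {sorted(missing)}")
    return df


def _records_from_rows(rows: pd.DataFrame) -> list[TrialRecord]:
    phase = rows["phase"].iloc[0]
    core_phase = "testing" if phase.endswith("_testing") else phase
    return [
        TrialRecord(
            trial_index=int(r.trial_index),
            phase=core_phase,
            stimulus=Stimulus.from_bits(r.feature_bits),
            response=None if pd.isna(r.response) else r.response,
            correct_label=r.correct_label,
        )
        for r in rows.itertuples()
    ]


def _schedule_from_rows(rows: pd.DataFrame) -> TrialSchedule:
    return TrialSchedule(
        phase=rows["phase"].iloc[0],
        trials=[
            (Stimulus.from_bits(r.feature_bits), r.correct_label)
            for r in rows.itertuples()
        ],
    )


def load_epochs(out_dir) -> dict[int, EpochSet]:
    out = Path(out_dir)
    meta = json.loads((out / "epochs_meta.json").read_text())
    times = np.linspace(
        meta["window_ms"][0], meta["window_ms"][1], meta["n_samples"]
    )
    cohort = {}
    for mat in sorted(out.glob("epochs_p*.tsv")):
        pid = int(mat.stem.split("_p")[1])
        labels = pd.read_csv(out / f"{mat.stem}_labels.csv")
        need = {"trial_index", "feedback_valence", "training_phase"}
        if not need <= set(labels.columns):
            raise SchemaError(
                f"{mat.stem}_labels.csv missing columns: {sorted(need - set(labels.columns))}"
            )
        data = np.loadtxt(mat, delimiter="\t")
        cohort[pid] = EpochSet(
            data=np.atleast_2d(data),
            times_ms=times,
            labels=labels,
            sampling_rate=meta["sampling_rate"],
            channel=meta["channel"],
            participant_id=pid,
        )
    if not cohort:
        raise SchemaError(f"no epochs_p*.tsv files under {out}")
    return cohort


# ---------------------------------------------------------------------------
# fit / erp / stats
# ---------------------------------------------------------------------------

SEGMENTS = {
    "observational_testing": ("observational_testing", "observational_training"),
    "feedback_testing": ("feedback_testing", "feedback_training"),
    "early_training": ("feedback_training", "feedback_training"),
    "late_training": ("feedback_training", "feedback_training"),
}


def run_fit(out_dir) -> dict:
    """Classify every participant's strategy in each analysed phase segment."""
    out = Path(out_dir)
    logs = load_trial_logs(out / "trial_logs.csv")
    rows = []
    for pid, sub in logs.groupby("participant_id"):
        banks = {
            phase: strategy_fit.build_model_bank(
                _schedule_from_rows(sub[sub["phase"] == phase])
            )
            for phase in ("observational_training", "feedback_training")
        }
        fb_train = _records_from_rows(sub[sub["phase"] == "feedback_training"])
        early, late = strategy_fit.split_phases(fb_train)
        segments = {
            "observational_testing": _records_from_rows(
                sub[sub["phase"] == "observational_testing"]
            ),
            "feedback_testing": _records_from_rows(
                sub[sub["phase"] == "feedback_testing"]
            ),
            "early_training": early,
            "late_training": late,
        }
        truth = sub["strategy_truth"].iloc[0]
        for segment, records in segments.items():
            bank = banks[SEGMENTS[segment][1]]
            result = strategy_fit.classify(strategy_fit.extract_profile(records), bank)
            row = {
                "participant_id": pid,
                "segment": segment,
                "strategy_truth": truth,
                "best_model": result.best_model,
                "collapsed_class": result.collapsed_class,
                "margin": result.margin,
            }
            row.update({f"score_{mid}": s for mid, s in result.scores.items()})
            rows.append(row)
    fits = pd.DataFrame(rows)
    written = []
    fit_path = out / "strategy_fits.csv"
    fits.to_csv(fit_path, index=False)
    written.append(fit_path)
    for segment in SEGMENTS:
        seg = fits[fits["segment"] == segment]
        results = [
            strategy_fit.FitResult({}, r.best_model, r.collapsed_class, r.margin)
            for r in seg.itertuples()
        ]
        table = strategy_fit.strategy_proportions(results)
        p = out / f"strategy_proportions_{segment}.csv"
        table.to_csv(p, index=False)
        written.append(p)
    _write_manifest(out, written, "fit")
    return {"n_classified": fits["participant_id"].nunique()}


def run_erp(config: RunConfig, out_dir) -> dict:
    """Preprocess epochs, run the temporal PCA, write factor scores."""
    out = Path(out_dir)
    cohort = load_epochs(out)
    scores, dec, exclusions = erp_pipeline.run_erp_pipeline(
        cohort, config.preprocess_config(), n_factors=config.n_factors
    )
    written = []
    for name, obj in (
        ("condition_scores.csv", scores),
        ("exclusion_report.csv", exclusions),
    ):
        obj.to_csv(out / name, index=False)
        written.append(out / name)
    np.savetxt(out / "factor_loadings.tsv", dec.loadings, fmt="%.6e", delimiter="\t")
    written.append(out / "factor_loadings.tsv")
    summary = pd.DataFrame(
        {
            "factor": np.arange(dec.loadings.shape[1]),
            "variance_explained": dec.variance_explained,
            "peak_latency_ms": dec.peak_latencies_ms,
            "label": [
                "FRN" if i == dec.frn_factor else ("P3a" if i == dec.p3a_factor else "")
                for i in range(dec.loadings.shape[1])
            ],
        }
    )
    summary.to_csv(out / "factor_summary.csv", index=False)
    written.append(out / "factor_summary.csv")
    _write_manifest(out, written, "erp")
    return {
        "n_retained": scores["participant_id"].nunique(),
        "frn_latency_ms": (
            float(dec.peak_latencies_ms[dec.frn_factor])
            if dec.frn_factor is not None else None
        ),
        "p3a_latency_ms": (
            float(dec.peak_latencies_ms[dec.p3a_factor])
            if dec.p3a_factor is not None else None
        ),
    }


def run_stats(out_dir) -> dict:
    """Assemble the report from whichever stage outputs are present."""
    out = Path(out_dir)
    strategy_tables = None
    accuracy = None
    condition_scores = None
    exclusions = None
    group_labels = None

    fits_path = out / "strategy_fits.csv"
    if fits_path.exists():
        fits = pd.read_csv(fits_path)
        strategy_tables = {
            segment: pd.read_csv(out / f"strategy_proportions_{segment}.csv")
            for segment in SEGMENTS
            if (out / f"strategy_proportions_{segment}.csv").exists()
        }
        logs_path = out / "trial_logs.csv"
        if logs_path.exists():
            logs = load_trial_logs(logs_path)
            testing = logs[logs["phase"].isin(["observational_testing", "feedback_testing"])]
            acc = (
                testing.assign(correct=lambda d: (d["accuracy"] == "correct").astype(float))
                .groupby(["participant_id", "phase"])["correct"]
                .mean()
                .mul(100.0)
                .reset_index()
            )
            acc["condition"] = acc["phase"].str.replace("_testing", "", regex=False)
            seg_class = fits.set_index(["participant_id", "segment"])["collapsed_class"]
            acc["strategy"] = [
                seg_class.get((r.participant_id, f"{r.condition}_testing"))
                for r in acc.itertuples()
            ]
            accuracy = acc[["participant_id", "condition", "strategy", "correct"]].rename(
                columns={"correct": "accuracy"}
            )
        fb = fits[fits["segment"] == "feedback_testing"]
        group_labels = dict(zip(fb["participant_id"], fb["collapsed_class"]))

    scores_path = out / "condition_scores.csv"
    if scores_path.exists():
        condition_scores = pd.read_csv(scores_path)
    exc_path = out / "exclusion_report.csv"
    if exc_path.exists():
        exclusions = pd.read_csv(exc_path)

    report_dir = out / "report"
    sections = stats_report.build_report(
        report_dir,
        strategy_tables=strategy_tables,
        accuracy=accuracy,
        condition_scores=condition_scores,
        exclusions=exclusions,
        group_labels=group_labels,
    )
    _write_manifest(out, sorted(report_dir.glob("*")), "stats")
    return {"sections": sorted(k for k in sections if k != "report_text")}


def run_all(config: RunConfig, out_dir) -> dict:
    out = Path(out_dir)
    info = {"simulate": run_simulate(config, out)}
    info["fit"] = run_fit(out)
    info["erp"] = run_erp(config, out)
    info["stats"] = run_stats(out)
    return info
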