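"""Pipeline orchestration: simulate -> detect -> measure -> fit -> report.

Each stage writes its table under the output directory and logs row counts,
so the attrition funnel (attacks simulated -> buzzes found -> pauses
measurable -> observations modelled) can be audited.  A fixed seed makes
the whole chain deterministic, byte-for-byte, including the CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detect import DetectionParams, PulseDetector, SpectrogramParams, events_to_frame
from .figures import make_figures
from .glmm import ZeroTruncatedPoissonGLMM
from .inference import (
    estimated_means,
    lrt_vs_null,
    model_select,
    outcome_proportions,
    pairwise_contrasts,
    wald_type2,
)
from .segment import BuzzSegmenter, PhaseParams, attacks_to_frame
from .synth import (
    OutcomeModelParams,
    PulseSynthParams,
    Recording,
    SequenceTiming,
    render_dataset,
)

logger = logging.getLogger("buzzpause")

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "fit_models"]


class PipelineStageError(RuntimeError):
    """A stage failed; earlier stages' outputs remain on disk."""

    def __init__(self, stage, original):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _dc_from_dict(cls, d):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs, YAML-serialisable."""

    seed: int = 0
    n_bats: int = 8
    n_dates: int = 4
    n_attacks: int = 137
    noise_rms: float = 0.0087
    sample_rate: int = 500_000
    outcome: OutcomeModelParams = field(default_factory=OutcomeModelParams)
    timing: SequenceTiming = field(default_factory=SequenceTiming)
    pulse: PulseSynthParams = field(default_factory=PulseSynthParams)
    spectrogram: SpectrogramParams = field(default_factory=SpectrogramParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    phase: PhaseParams = field(default_factory=PhaseParams)
    models: tuple = (("outcome",), ("outcome", "weather"), ("outcome", "temperature"))
    method: str = "laplace"
    out_dir: str = "buzzpause_run"

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        for key, sub in [
            ("outcome", OutcomeModelParams), ("timing", SequenceTiming),
            ("pulse", PulseSynthParams), ("spectrogram", SpectrogramParams),
            ("detection", DetectionParams), ("phase", PhaseParams),
        ]:
            if key in d and isinstance(d[key], dict):
                d[key] = _dc_from_dict(sub, d[key])
        if "models" in d:
            d["models"] = tuple(tuple(m) for m in d["models"])
        if "spectrogram" in d and isinstance(getattr(d["spectrogram"], "band", None), list):
            d["spectrogram"].band = tuple(d["spectrogram"].band)
        return _dc_from_dict(cls, d)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def fit_models(observations, models=(("outcome",),), random=("date", "bat_id"),
               method="laplace"):
    """Fit the null and each candidate fixed-effect model to one table.

    Returns ``(fits, labels)`` with the null model first.  A candidate that
    cannot be fit on this data (e.g. a single-level factor) is skipped with
    a warning rather than aborting the run.
    """
    fits, labels = [], []
    null = ZeroTruncatedPoissonGLMM(fixed=(), random=random, method=method).fit(observations)
    fits.append(null)
    labels.append("null")
    for terms in models:
        try:
            est = ZeroTruncatedPoissonGLMM(
                fixed=tuple(terms), random=random, method=method
            ).fit(observations)
        except ValueError as err:
            logger.warning("skipping model %s: %s", "+".join(terms), err)
            continue
        fits.append(est)
        labels.append("+".join(terms))
    return fits, labels


def run_pipeline(config=None, out_dir=None):
    """Run the full chain and return the report dict.

    Writes recordings (WAV), ground truth, detected pulses, measured
    attacks, the model report (JSON) and both figures under ``out_dir``.
    """
    config = config if config is not None else PipelineConfig()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"seed": config.seed, "funnel": {}}

    stage = "simulate"
    try:
        recordings, truth_attacks, truth_pulses = render_dataset(
            n_bats=config.n_bats, n_dates=config.n_dates, n_attacks=config.n_attacks,
            params=config.outcome, timing=config.timing, synth=config.pulse,
            noise_rms=config.noise_rms, sample_rate=config.sample_rate, seed=config.seed,
        )
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for rec in recordings:
            rec.to_wav(rec_dir / f"{rec.recording_id}.wav")
        truth_attacks.to_csv(out / "ground_truth_attacks.csv", index=False)
        truth_pulses.to_csv(out / "ground_truth_pulses.csv", index=False)
        report["funnel"]["attacks_simulated"] = len(truth_attacks)
        report["proportions"] = outcome_proportions(truth_attacks) if len(truth_attacks) else {}
        logger.info("simulate: %d attacks, %d recordings", len(truth_attacks), len(recordings))
    except Exception as err:  # noqa: BLE001 - stage boundary
        raise PipelineStageError(stage, err) from err

    stage = "detect"
    try:
        detector = PulseDetector(spectrogram=config.spectrogram, detection=config.detection)
        pulse_frames = [
            events_to_frame(detector.detect(rec), recording_id=rec.recording_id)
            for rec in recordings
        ]
        pulses = (
            pd.concat(pulse_frames, ignore_index=True)
            if pulse_frames
            else events_to_frame([])
        )
        pulses.to_csv(out / "pulses.csv", index=False)
        report["funnel"]["pulses_detected"] = len(pulses)
        logger.info("detect: %d pulses", len(pulses))
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError(stage, err) from err

    stage = "measure"
    try:
        segmenter = BuzzSegmenter(phase=config.phase)
        ann = truth_attacks.set_index("recording_id") if len(truth_attacks) else None
        frames = []
        for rid, sub in pulses.groupby("recording_id", sort=True):
            annotation = None
            if ann is not None and rid in ann.index:
                row = ann.loc[rid]
                annotation = {"outcome": row["outcome"], "bat_id": row["bat_id"],
                              "date": row["date"]}
            records = segmenter.segment(sub.reset_index(drop=True), annotation=annotation)
            frames.append(attacks_to_frame(records, recording_id=rid))
        attacks = (
            pd.concat(frames, ignore_index=True) if frames else attacks_to_frame([])
        )
        if len(attacks) and len(truth_attacks):
            cov = truth_attacks[["recording_id", "attack_idx", "weather", "temperature"]]
            attacks = attacks.merge(cov, on="recording_id", how="left")
        attacks.to_csv(out / "attacks.csv", index=False)
        measurable = attacks["measurable"].sum() if len(attacks) else 0
        report["funnel"]["buzzes_found"] = len(attacks)
        report["funnel"]["pauses_measurable"] = int(measurable)
        logger.info("measure: %d buzzes, %d measurable", len(attacks), measurable)
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError(stage, err) from err

    stage = "fit"
    try:
        obs = attacks[attacks["measurable"] & attacks["outcome"].isin(
            ("captured", "dropped", "failed"))].copy() if len(attacks) else attacks
        if len(obs) and obs["outcome"].nunique() >= 2:
            obs["pause_ms"] = obs["pause_ms"].astype(int)
            fits, labels = fit_models(obs, models=config.models, method=config.method)
            table = model_select(fits, labels=labels)
            best_label = table.loc[table["model"] != "null", "model"].iloc[0]
            best = fits[labels.index(best_label)]
            null = fits[labels.index("null")]
            lrt = lrt_vs_null(best, null)
            wald = wald_type2(best, "outcome")
            contrasts = pairwise_contrasts(best, "outcome")
            means = estimated_means(best, "outcome")
            report["aicc_table"] = table.to_dict(orient="records")
            report["best_model"] = best_label
            report["lrt_vs_null"] = dataclasses.asdict(lrt)
            report["wald_type2_outcome"] = dataclasses.asdict(wald)
            report["contrasts"] = [dataclasses.asdict(c) for c in contrasts]
            report["estimated_means"] = means.to_dict(orient="records")
            report["pause_summaries"] = (
                obs.groupby("outcome")["pause_ms"]
                .agg(["count", "mean", "std"])
                .round(4)
                .reset_index()
                .to_dict(orient="records")
            )
            pd.DataFrame([dataclasses.asdict(c) for c in contrasts]).to_csv(
                out / "contrasts.csv", index=False
            )
            report["funnel"]["observations_modelled"] = len(obs)
            logger.info("fit: best model %s over %d observations", best_label, len(obs))
        else:
            report["funnel"]["observations_modelled"] = int(len(obs))
            means = None
            logger.info("fit: skipped (insufficient labelled observations)")
    except PipelineStageError:
        raise
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError(stage, err) from err

    stage = "report"
    try:
        if len(attacks):
            make_figures(attacks, means=report.get("estimated_means"), out_dir=out)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=2, default=float)
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError(stage, err) from err
    return report
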