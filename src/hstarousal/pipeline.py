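"""End-to-end glue: synthetic cohorts through training to recordwise scores.

This is the layer the incremental-selection driver and the command-line
interface sit on: it preprocesses a cohort once, then trains a detector
for any channel combination, optimizes the decision threshold on the
validation split, and scores the test split recordwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .events import EventList
from .evaluation import (
    MatchCriterion,
    RecordwiseReport,
    mask_wake,
    recordwise_metrics,
)
from .model import ArousalDetector, ModelConfig
from .postprocess import PostprocessConfig, optimize_threshold, postprocess
from .preprocess import PreprocessedRecord, preprocess_record
from .synthetic import SyntheticConfig, generate_cohort
from .train import TrainConfig, train

__all__ = ["PreparedCohort", "prepare_cohort", "fit_and_score", "make_train_eval"]


@dataclass
class PreparedCohort:
    """Preprocessed train/validation/test splits with ground-truth events."""

    train: list[tuple[PreprocessedRecord, EventList]]
    val: list[tuple[PreprocessedRecord, EventList]]
    test: list[tuple[PreprocessedRecord, EventList]]


def prepare_cohort(
    config: SyntheticConfig,
    n_train: int,
    n_val: int,
    n_test: int,
    channels: list[str] | None = None,
) -> PreparedCohort:
    """Generate and preprocess a synthetic cohort, split by record."""
    channels = channels or ["Thor", "DHR", "Snore", "Pos", "Pos_chg", "WS"]
    cohort = generate_cohort(n_train + n_val + n_test, config)
    prepared = [
        (preprocess_record(rec, hyp, ev, channels), ev) for rec, hyp, ev in cohort
    ]
    return PreparedCohort(
        train=prepared[:n_train],
        val=prepared[n_train : n_train + n_val],
        test=prepared[n_train + n_val :],
    )


@dataclass
class FitResult:
    model: ArousalDetector
    threshold: float
    report: RecordwiseReport
    mean_event_f1: float
    history: object


def fit_and_score(
    cohort: PreparedCohort,
    channels: list[str],
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    post_config: PostprocessConfig | None = None,
    crit: MatchCriterion | None = None,
    seed: int = 0,
) -> FitResult:
    """Train on a channel combination and score the test split recordwise.

    The decision threshold is optimized for event-based F1 on the
    validation split; detections and ground truth are wake-masked before
    matching.  The returned score is the mean recordwise event-based F1
    over test records that contain ground-truth events.
    """
    channels = sorted(channels)
    model_config = model_config or ModelConfig()
    model_config = replace(
        model_config, n_input_channels=len(channels), seed=seed
    )
    train_config = train_config or TrainConfig()
    train_config = replace(train_config, seed=seed)
    post_config = post_config or PostprocessConfig()
    crit = crit or MatchCriterion()

    model = ArousalDetector(model_config)
    train_recs = [r for r, _ in cohort.train]
    val_recs = [r for r, _ in cohort.val]
    model, history = train(model, train_recs, val_recs, train_config, channels)

    val_probs = [r.input_matrix(channels) for r, _ in cohort.val]
    val_probs = [model.predict(x) for x in val_probs]
    threshold = optimize_threshold(
        val_probs,
        [ev for _, ev in cohort.val],
        sleep_masks=[r.sleep_mask_1hz for r, _ in cohort.val],
        config=post_config,
        omega_min=crit.omega_min,
    )

    pairs = []
    ids = []
    for rec, gt in cohort.test:
        probs = model.predict(rec.input_matrix(channels))
        det = postprocess(probs, threshold, post_config).events
        det = mask_wake(det, rec.sleep_mask_1hz)
        gt_m = mask_wake(gt, rec.sleep_mask_1hz)
        pairs.append((gt_m, det))
        ids.append(rec.record_id)
    report = recordwise_metrics(pairs, crit, record_ids=ids)
    mean_f1 = report.mean("f1") if report.reports else 0.0
    return FitResult(
        model=model,
        threshold=threshold,
        report=report,
        mean_event_f1=float(mean_f1),
        history=history,
    )


def make_train_eval(
    cohort: PreparedCohort,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    post_config: PostprocessConfig | None = None,
    crit: MatchCriterion | None = None,
):
    """Adapter giving the selection driver a real training backend."""

    def fn(combo: frozenset, seed: int):
        res = fit_and_score(
            cohort,
            sorted(combo),
            model_config=model_config,
            train_config=train_config,
            post_config=post_config,
            crit=crit,
            seed=seed,
        )
        return res.mean_event_f1, res.report

    return fn
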