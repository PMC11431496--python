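"""Three-level evaluation of arousal detections.

Pointwise: precision/recall/F1 and AUPRC/AUROC over the concatenated
per-second predictions of all test records, restricted to sleep seconds.
Event-based: a ground-truth event counts as found when a detection covers
strictly more than ``omega_min`` of it (default 0.5); precision, recall
and F1 follow from the matched/unmatched counts.  Recordwise: the
event-based metrics per record, summarized as mean (SD), compared between
models with a bootstrap paired t-test under Holm–Bonferroni correction,
and complemented by relative confusion matrices and arousal-index
agreement (Pearson correlation, Bland–Altman limits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .events import EventList

__all__ = [
    "MatchCriterion",
    "PointwiseReport",
    "EventReport",
    "RecordwiseReport",
    "BootstrapResult",
    "ArIReport",
    "mask_wake",
    "match_events",
    "pointwise_metrics",
    "recordwise_metrics",
    "bootstrap_paired_test",
    "holm_bonferroni",
    "relative_confusion",
    "arousal_index",
    "bland_altman",
]


@dataclass(frozen=True)
class MatchCriterion:
    """Minimum ground-truth coverage a detection must strictly exceed."""

    omega_min: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.omega_min < 1.0:
            raise ValueError("omega_min must lie in (0, 1)")


def _f1(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


@dataclass
class PointwiseReport:
    precision: float
    recall: float
    f1: float
    auprc: float | None = None
    auroc: float | None = None
    recall_defined: bool = True


@dataclass
class EventReport:
    """Event-level confusion counts.

    ``tp`` counts detections that match at least one ground-truth event,
    ``fp`` detections matching none, ``fn`` ground-truth events no
    detection matches.  ``gt_matched`` counts ground-truth events found;
    it can exceed ``tp`` when one detection spans several ground-truth
    events, and it is the recall numerator.
    """

    tp: int
    fp: int
    fn: int
    gt_matched: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        total = self.gt_matched + self.fn
        return self.gt_matched / total if total else 0.0

    @property
    def f1(self) -> float:
        return _f1(self.precision, self.recall)

    @property
    def defined(self) -> bool:
        """False when there were no ground-truth events or no detections."""
        return (self.gt_matched + self.fn) > 0 and (self.tp + self.fp) >= 0


@dataclass
class RecordwiseReport:
    reports: list[EventReport]
    record_ids: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    def _values(self, metric: str) -> np.ndarray:
        return np.array([getattr(r, metric) for r in self.reports])

    def mean(self, metric: str) -> float:
        return float(self._values(metric).mean())

    def sd(self, metric: str) -> float:
        return float(self._values(metric).std(ddof=1)) if len(self.reports) > 1 else 0.0

    def per_record(self, metric: str) -> np.ndarray:
        return self._values(metric)


@dataclass
class BootstrapResult:
    p_value: float
    t_stat: float
    degenerate: bool = False

    def __float__(self) -> float:
        return self.p_value


@dataclass
class ArIReport:
    mean_bias: float
    loa_low: float
    loa_high: float
    pearson_r: float
    bias: np.ndarray


def mask_wake(events: EventList, sleep_mask_1hz: np.ndarray) -> EventList:
    """Drop events whose majority of covered seconds fall in wake.

    An event split exactly half-and-half is kept (removal requires a
    strict wake majority).  Kept events are returned intact.
    """
    mask = np.asarray(sleep_mask_1hz)
    n = mask.shape[0]
    kept = []
    for onset, offset in events:
        lo = max(int(np.floor(onset)), 0)
        hi = min(int(np.ceil(offset)), n)
        if hi <= lo:
            kept.append((onset, offset))
            continue
        seconds = mask[lo:hi]
        wake = int(np.sum(seconds == 0))
        if 2 * wake <= (hi - lo):
            kept.append((onset, offset))
    return EventList(kept)


def match_events(
    gt: EventList, det: EventList, crit: MatchCriterion | None = None
) -> EventReport:
    """Overlap-based event matching.

    ``Match(G, D) = 1`` iff ``|G ∩ D| / |G| > omega_min`` (strict).  A
    detection is a true positive when it matches at least one ground-truth
    event; a ground-truth event is found when at least one detection
    matches it.
    """
    crit = crit or MatchCriterion()
    g = gt.array
    d = det.array
    if len(g) == 0 or len(d) == 0:
        return EventReport(tp=0, fp=len(d), fn=len(g), gt_matched=0)
    # pairwise intersection lengths (n_gt, n_det)
    inter = np.clip(
        np.minimum(g[:, 1, None], d[None, :, 1])
        - np.maximum(g[:, 0, None], d[None, :, 0]),
        0.0,
        None,
    )
    ratio = inter / (g[:, 1] - g[:, 0])[:, None]
    matched = ratio > crit.omega_min
    gt_found = matched.any(axis=1)
    det_tp = matched.any(axis=0)
    return EventReport(
        tp=int(det_tp.sum()),
        fp=int((~det_tp).sum()),
        fn=int((~gt_found).sum()),
        gt_matched=int(gt_found.sum()),
    )


def pointwise_metrics(
    pred_labels: np.ndarray,
    true_labels: np.ndarray,
    sleep_mask: np.ndarray | None = None,
    probs: np.ndarray | None = None,
) -> PointwiseReport:
    """Per-second precision/recall/F1 (and AUPRC/AUROC when probabilities
    are supplied) over sleep seconds of the concatenated sequences."""
    pred = np.asarray(pred_labels).astype(bool)
    true = np.asarray(true_labels).astype(bool)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth lengths differ")
    if sleep_mask is not None:
        keep = np.asarray(sleep_mask).astype(bool)
        pred, true = pred[keep], true[keep]
        if probs is not None:
            probs = np.asarray(probs)[keep]
    tp = float(np.sum(pred & true))
    fp = float(np.sum(pred & ~true))
    fn = float(np.sum(~pred & true))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall_defined = bool(true.any())
    recall = tp / (tp + fn) if recall_defined else 0.0
    auprc = auroc = None
    if probs is not None and recall_defined and not true.all():
        auprc = float(average_precision_score(true, probs))
        auroc = float(roc_auc_score(true, probs))
    return PointwiseReport(
        precision=precision,
        recall=recall,
        f1=_f1(precision, recall),
        auprc=auprc,
        auroc=auroc,
        recall_defined=recall_defined,
    )


def recordwise_metrics(
    per_record_events: list[tuple[EventList, EventList]],
    crit: MatchCriterion | None = None,
    record_ids: list[str] | None = None,
) -> RecordwiseReport:
    """Per-record event metrics with mean/SD summaries.

    Records without any ground-truth event have undefined recall; they
    are flagged by id and excluded from the summaries.
    """
    if not per_record_events:
        raise ValueError("need at least one record")
    if record_ids is None:
        record_ids = [f"record-{i}" for i in range(len(per_record_events))]
    reports, kept_ids, excluded = [], [], []
    for rid, (gt, det) in zip(record_ids, per_record_events):
        if len(gt) == 0:
            excluded.append(rid)
            continue
        reports.append(match_events(gt, det, crit))
        kept_ids.append(rid)
    return RecordwiseReport(reports=reports, record_ids=kept_ids, excluded=excluded)


def bootstrap_paired_test(
    metric_a: np.ndarray,
    metric_b: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Two-sided bootstrap paired t-test.

    The observed paired t-statistic is compared against the distribution
    of t-statistics from resampling the mean-centered paired differences
    with replacement; the p-value is the proportion of bootstrap
    statistics at least as extreme.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length paired 1-D vectors with n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return BootstrapResult(p_value=1.0, t_stat=0.0, degenerate=True)
    t_obs = d.mean() / (sd / np.sqrt(n))

    rng = np.random.default_rng(seed)
    centered = d - d.mean()
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = centered[idx]
    means = samples.mean(axis=1)
    sds = samples.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_boot = means / (sds / np.sqrt(n))
    # resamples of a single repeated value: t is 0/0 -> not extreme unless
    # the mean is nonzero (then infinitely extreme)
    t_boot = np.where(np.isnan(t_boot), 0.0, t_boot)
    p = float(np.mean(np.abs(t_boot) >= abs(t_obs)))
    return BootstrapResult(p_value=p, t_stat=float(t_obs))


def holm_bonferroni(p_values, alpha: float = 0.05) -> list[bool]:
    """Holm step-down significance decisions for a family of p-values."""
    p = [float(v) for v in p_values]
    if not p:
        return []
    reject, _, _, _ = multipletests(p, alpha=alpha, method="holm")
    return [bool(r) for r in reject]


def relative_confusion(
    gt_lists: list[EventList],
    det_a_lists: list[EventList],
    det_b_lists: list[EventList],
    crit: MatchCriterion | None = None,
) -> dict[str, int]:
    """Classify every ground-truth event by which detector found it.

    Returns counts ``both`` / ``only_a`` / ``only_b`` / ``neither``; the
    four cells sum to the total number of ground-truth events.
    """
    crit = crit or MatchCriterion()
    cells = {"both": 0, "only_a": 0, "only_b": 0, "neither": 0}
    for gt, da, db in zip(gt_lists, det_a_lists, det_b_lists, strict=True):
        g = gt.array
        for onset, offset in g:
            single = EventList([(onset, offset)])
            in_a = match_events(single, da, crit).gt_matched > 0
            in_b = match_events(single, db, crit).gt_matched > 0
            if in_a and in_b:
                cells["both"] += 1
            elif in_a:
                cells["only_a"] += 1
            elif in_b:
                cells["only_b"] += 1
            else:
                cells["neither"] += 1
    return cells


def arousal_index(events: EventList, total_sleep_time_h: float) -> float:
    """Arousal events per hour of sleep."""
    if total_sleep_time_h <= 0:
        raise ValueError("total sleep time must be positive")
    return len(events) / total_sleep_time_h


def bland_altman(true_ari: np.ndarray, est_ari: np.ndarray) -> ArIReport:
    """Agreement between true and estimated arousal indices.

    Bias is ``estimated - true`` per record; the 95 % limits of agreement
    are mean bias ± 1.96 SD, and the Pearson correlation is computed
    between the two index vectors.
    """
    t = np.asarray(true_ari, dtype=float)
    e = np.asarray(est_ari, dtype=float)
    if t.shape != e.shape or t.ndim != 1 or t.size < 2:
        raise ValueError("need paired 1-D vectors with n >= 2")
    bias = e - t
    mean_bias = float(bias.mean())
    sd = float(bias.std(ddof=1))
    if np.ptp(t) == 0 or np.ptp(e) == 0:
        r = 1.0 if np.allclose(t, e - mean_bias) else float("nan")
    else:
        r = float(pearsonr(t, e)[0])
    return ArIReport(
        mean_bias=mean_bias,
        loa_low=mean_bias - 1.96 * sd,
        loa_high=mean_bias + 1.96 * sd,
        pearson_r=r,
        bias=bias,
    )
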