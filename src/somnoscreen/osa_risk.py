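"""Patient-level OSA risk detection from sleep-wake prediction behavior.

The screening model exploits the fact that an epoch-level sleep-wake
classifier trained on low-AHI patients becomes *uncertain* and *unstable*
on recordings with many apneas: apneas disturb the cardiorespiratory
patterns the network learned, producing low-confidence sleep predictions
and spurious sleep-wake flips. Two per-patient indices quantify this:

* ``% uncertain sleep epochs`` -- the share of sleep-predicted epochs
  whose p(sleep) falls below a confidence threshold ``T_sleep``
  (median minus SD of pooled p(sleep) over a reference cohort),
* ``% transitions`` -- the share of adjacent epoch pairs whose predicted
  label flips.

A patient is flagged *at risk of OSA* (AHI >= 15) when **either** index
exceeds its operating point; operating points are chosen by ROC analysis
at a high-specificity target (default 0.92). Screening performance is
summarized by Cohen's kappa, accuracy, sensitivity, specificity and the
diagnostic odds ratio DOR = Se*Sp / ((1-Se)(1-Sp)).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from somnoscreen.types import (
    ConfidenceThresholds,
    DetectionMetrics,
    IndexThresholds,
    PredictionSeries,
    RiskProfile,
    SLEEP,
    WAKE,
)

__all__ = [
    "fit_confidence_thresholds",
    "pct_uncertain_sleep",
    "pct_transitions",
    "roc_select_threshold",
    "classify_risk",
    "risk_profile",
    "detection_metrics",
    "dor_from_se_sp",
    "kappa_from_counts",
    "paired_index_test",
]

logger = logging.getLogger(__name__)


def fit_confidence_thresholds(series: Sequence[PredictionSeries]) -> ConfidenceThresholds:
    """Median-minus-SD confidence thresholds from a reference cohort.

    Pools the predicted-class probability over all epochs of all reference
    recordings: ``t_sleep = median(p_sleep | predicted sleep) - SD(same)``
    and analogously for wake.
    """
    p_sleep = np.concatenate([s.p_sleep[s.label == SLEEP] for s in series])
    p_wake = np.concatenate([s.p_wake[s.label == WAKE] for s in series])
    if p_sleep.size == 0 or p_wake.size == 0:
        raise ValueError("reference cohort lacks a predicted class; thresholds undefined")
    return ConfidenceThresholds(
        t_sleep=float(np.median(p_sleep) - np.std(p_sleep)),
        t_wake=float(np.median(p_wake) - np.std(p_wake)),
    )


def pct_uncertain_sleep(series: PredictionSeries, thresholds: ConfidenceThresholds) -> tuple[float, bool]:
    """Percentage of sleep-predicted epochs below the confidence threshold.

    Denominator: sleep-predicted epochs only. Returns ``(pct, flagged)``;
    when the recording has no sleep-predicted epochs the index is 0 and
    flagged.
    """
    if len(series) == 0:
        raise ValueError("empty prediction series")
    sleep_p = series.p_sleep[series.label == SLEEP]
    if sleep_p.size == 0:
        logger.warning("%s: no sleep-predicted epochs; %% uncertain sleep set to 0", series.patient_id)
        return 0.0, True
    return float(100.0 * np.mean(sleep_p < thresholds.t_sleep)), False


def pct_transitions(series: PredictionSeries) -> float:
    """Percentage of adjacent predicted-label changes.

    Computed over retained epochs in temporal order (rejected epochs are
    skipped, so their neighbours become adjacent); denominator is the
    number of adjacent pairs, ``n_epochs - 1``.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 epochs to count transitions")
    order = np.argsort(series.epoch_index)
    labels = series.label[order]
    return float(100.0 * np.mean(np.diff(labels) != 0))


def roc_select_threshold(
    values: np.ndarray,
    truth: np.ndarray,
    target_specificity: float = 0.92,
) -> tuple[float, float, float]:
    """Pick the index operating point by ROC analysis at high specificity.

    A patient is called positive when ``value > threshold``. Candidate
    thresholds are the observed values (plus one below the minimum); the
    smallest threshold whose specificity reaches ``target_specificity`` is
    returned (it has the highest sensitivity among those). If the target
    is infeasible the maximum-specificity threshold is returned with a
    warning. Returns ``(threshold, se, sp)`` with se/sp as fractions.
    """
    values = np.asarray(values, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if not truth.any() or truth.all():
        raise ValueError("ROC analysis needs both classes present")
    candidates = np.unique(values)
    candidates = np.concatenate(([candidates[0] - 1.0], candidates))
    pos, neg = values[truth], values[~truth]
    se = np.array([np.mean(pos > t) for t in candidates])
    sp = np.array([np.mean(neg <= t) for t in candidates])
    ok = np.flatnonzero(sp >= target_specificity)
    if ok.size:
        i = int(ok[0])  # candidates are sorted: smallest feasible threshold
    else:
        i = int(np.argmax(sp))
        logger.warning(
            "no threshold reaches specificity %.2f; returning max-specificity point (Sp=%.2f)",
            target_specificity,
            sp[i],
        )
    return float(candidates[i]), float(se[i]), float(sp[i])


def classify_risk(
    pct_uncertain: float, pct_trans: float, thresholds: IndexThresholds = IndexThresholds()
) -> bool:
    """Either-index rule: at risk iff at least one index exceeds its cut."""
    return pct_uncertain > thresholds.thr_uncertain or pct_trans > thresholds.thr_transitions


def risk_profile(
    series: PredictionSeries,
    conf: ConfidenceThresholds,
    thresholds: IndexThresholds = IndexThresholds(),
) -> RiskProfile:
    """Both indices plus the risk decision for one recording."""
    unc, flagged = pct_uncertain_sleep(series, conf)
    trans = pct_transitions(series)
    return RiskProfile(
        patient_id=series.patient_id,
        pct_uncertain_sleep=unc,
        pct_transitions=trans,
        at_risk=classify_risk(unc, trans, thresholds),
        no_sleep_predictions=flagged,
    )


def kappa_from_counts(tp: int, fp: int, fn: int, tn: int) -> float:
    """Cohen's kappa of a 2x2 table with marginal-product chance agreement."""
    n = tp + fp + fn + tn
    if n == 0:
        return float("nan")
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    if pe == 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def dor_from_se_sp(se: float, sp: float) -> float:
    """Diagnostic odds ratio Se*Sp / ((1-Se)(1-Sp)), se/sp as fractions."""
    denom = (1.0 - se) * (1.0 - sp)
    if denom == 0.0:
        return float("inf")
    return (se * sp) / denom


def detection_metrics(decisions: np.ndarray, truth: np.ndarray) -> DetectionMetrics:
    """Screening metrics of per-patient risk decisions against truth.

    ``acc``/``se``/``sp`` are percentages. With a degenerate truth vector
    the undefined rate (and the DOR) is reported as NaN. A DOR whose 2x2
    table has a zero cell is computed after a Haldane-Anscombe 0.5-count
    correction and flagged ``dor_corrected``.
    """
    decisions = np.asarray(decisions, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if decisions.shape != truth.shape:
        raise ValueError("decisions and truth must be aligned")
    tp = int(np.sum(decisions & truth))
    fp = int(np.sum(decisions & ~truth))
    fn = int(np.sum(~decisions & truth))
    tn = int(np.sum(~decisions & ~truth))
    n = tp + fp + fn + tn
    npos, nneg = tp + fn, fp + tn

    se = 100.0 * tp / npos if npos else float("nan")
    sp = 100.0 * tn / nneg if nneg else float("nan")
    acc = 100.0 * (tp + tn) / n if n else float("nan")
    kappa = kappa_from_counts(tp, fp, fn, tn)

    corrected = False
    if npos == 0 or nneg == 0:
        dor = float("nan")
    elif min(tp, fp, fn, tn) == 0:
        dor = ((tp + 0.5) * (tn + 0.5)) / ((fp + 0.5) * (fn + 0.5))
        corrected = True
        logger.warning("zero cell in confusion table; DOR uses a 0.5-count correction")
    else:
        dor = dor_from_se_sp(se / 100.0, sp / 100.0)
    return DetectionMetrics(
        kappa=kappa, acc=acc, se=se, sp=sp, dor=dor,
        tp=tp, fp=fp, fn=fn, tn=tn, dor_corrected=corrected,
    )


def paired_index_test(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-patient indices.

    Zero differences are dropped; the exact distribution is used for small
    samples (scipy's default policy). All-zero differences give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs for the signed-rank test")
    if np.allclose(a, b):
        return 1.0
    return float(sstats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided").pvalue)
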