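"""Evaluation layer: LOOCV, agreement statistics, sleep summary, screening.

Agreement between the automatic hypnogram and the reference is scored
with per-stage accuracy (percentage of each reference stage correctly
classified) and the unweighted Cohen kappa.  Sleep efficiency (SE),
total sleep time (TST), total wake time (TWT) and wake after sleep
onset (WASO) are derived from the 2-stage hypnogram, and subjects are
screened into SE groups (40/60/80% thresholds) with sensitivity,
specificity, predictive values, kappa and ROC/AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve

from .config import StagingConfig
from .io_core import Hypnogram
from .staging import (
    EpochFeatureMatrix,
    LinearDiscriminantStager,
    STAGE_SYSTEMS,
    StageSystem,
    map_stages,
    predict_stages,
    train_ld,
)

log = logging.getLogger(__name__)

__all__ = [
    "AgreementReport",
    "SleepSummary",
    "ScreeningReport",
    "LoocvResult",
    "confusion_matrix",
    "agreement_report",
    "cohen_kappa",
    "loocv",
    "sleep_summary",
    "se_group",
    "screening_metrics",
    "correlation_summary",
]

SE_GROUPS = ("0-39", "40-59", "60-79", ">=80")


@dataclass
class AgreementReport:
    """Confusion matrix (reference x predicted) and agreement scores."""

    labels: tuple[str, ...]
    confusion: np.ndarray
    per_stage_accuracy: dict[str, float]  # percent, per reference stage
    overall_accuracy: float  # percent
    kappa: float

    @property
    def n_epochs(self) -> int:
        return int(self.confusion.sum())


@dataclass
class SleepSummary:
    """Sleep time statistics of one night, all in minutes (SE in percent)."""

    SE: float
    TST: float
    TWT: float
    WASO: float
    time_in_bed: float


@dataclass
class ScreeningReport:
    """2x2 screening performance at one SE threshold, rates in percent."""

    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    kappa: float
    auc: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


@dataclass
class LoocvResult:
    """Leave-one-out cross-validation output."""

    system_id: str
    predictions: list[Hypnogram]
    references: list[Hypnogram]
    pooled: AgreementReport
    fold_reports: list[AgreementReport]
    per_stage_accuracy_mean: dict[str, float]  # averaged over folds
    flagged_folds: list[int] = field(default_factory=list)


def confusion_matrix(
    ref: list[str], pred: list[str], labels: tuple[str, ...]
) -> np.ndarray:
    if len(ref) != len(pred):
        raise ValueError("reference and prediction length mismatch")
    index = {l: i for i, l in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for r, p in zip(ref, pred):
        cm[index[r], index[p]] += 1
    return cm


def cohen_kappa(ref, pred) -> float:
    """Unweighted Cohen kappa: (p_o - p_e) / (1 - p_e).

    ``p_o`` is the observed agreement and ``p_e`` the chance agreement
    expected from the marginal label frequencies.  The degenerate case
    ``p_e = 1`` (both raters constant) returns 1 for perfect agreement
    and 0 otherwise, with a warning.
    """
    ref = list(ref)
    pred = list(pred)
    if len(ref) != len(pred):
        raise ValueError("reference and prediction length mismatch")
    if len(ref) == 0:
        raise ValueError("empty label sequences")
    labels = sorted(set(ref) | set(pred))
    cm = confusion_matrix(ref, pred, tuple(labels)).astype(float)
    n = cm.sum()
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) / n) @ (cm.sum(axis=0) / n))
    if p_e >= 1.0 - 1e-15:
        warnings.warn("chance agreement is 1 (constant labels); kappa degenerate")
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def agreement_report(ref: Hypnogram, pred: Hypnogram) -> AgreementReport:
    """Per-stage and overall accuracy plus kappa for one label pair."""
    if ref.alphabet_id != pred.alphabet_id:
        raise ValueError("hypnograms use different alphabets")
    from .io_core import STAGE_ALPHABETS

    labels = STAGE_ALPHABETS[ref.alphabet_id]
    cm = confusion_matrix(ref.labels, pred.labels, labels)
    row_tot = cm.sum(axis=1)
    per_stage = {
        l: (100.0 * cm[i, i] / row_tot[i]) if row_tot[i] else float("nan")
        for i, l in enumerate(labels)
    }
    overall = 100.0 * np.trace(cm) / cm.sum()
    return AgreementReport(
        labels=labels,
        confusion=cm,
        per_stage_accuracy=per_stage,
        overall_accuracy=float(overall),
        kappa=cohen_kappa(ref.labels, pred.labels),
    )


def loocv(
    cohort: list[tuple[EpochFeatureMatrix, Hypnogram]],
    system: StageSystem | str,
    cfg: StagingConfig | None = None,
) -> LoocvResult:
    """Leave-one-out cross-validation over a cohort.

    For each subject the classifier is trained on all other subjects and
    applied to the held-out one; per-stage accuracies are averaged over
    folds and a pooled confusion matrix over all epochs is also
    reported.  A fold whose training set misses a class of the system is
    flagged and excluded from that class's average.
    """
    if isinstance(system, str):
        system = STAGE_SYSTEMS[system]
    if len(cohort) < 3:
        raise ValueError("LOOCV needs a cohort of at least 3 subjects")
    cfg = cfg or StagingConfig()
    predictions: list[Hypnogram] = []
    references: list[Hypnogram] = []
    fold_reports: list[AgreementReport] = []
    flagged: list[int] = []
    for i in range(len(cohort)):
        train = [c for j, c in enumerate(cohort) if j != i]
        mats = [m for m, _ in train]
        hyps = [h for _, h in train]
        pooled_labels = {
            l for h in hyps for l in map_stages(h, system).labels
        }
        if not set(system.classes) <= pooled_labels:
            flagged.append(i)
            log.warning(
                "fold %d: class(es) %s absent from training; fold flagged",
                i,
                sorted(set(system.classes) - pooled_labels),
            )
        model = train_ld(mats, hyps, system, cfg, require_all_classes=False)
        test_m, test_h = cohort[i]
        pred, _ = predict_stages(
            model, test_m, system.id, cfg.median_filter_epochs
        )
        ref = map_stages(test_h, system)
        predictions.append(pred)
        references.append(ref)
        fold_reports.append(agreement_report(ref, pred))
    all_ref = [l for h in references for l in h.labels]
    all_pred = [l for h in predictions for l in h.labels]
    cm = confusion_matrix(all_ref, all_pred, system.classes)
    row_tot = cm.sum(axis=1)
    pooled = AgreementReport(
        labels=system.classes,
        confusion=cm,
        per_stage_accuracy={
            l: (100.0 * cm[i, i] / row_tot[i]) if row_tot[i] else float("nan")
            for i, l in enumerate(system.classes)
        },
        overall_accuracy=float(100.0 * np.trace(cm) / cm.sum()),
        kappa=cohen_kappa(all_ref, all_pred),
    )
    per_stage_mean: dict[str, float] = {}
    for l in system.classes:
        vals = [
            r.per_stage_accuracy[l]
            for i, r in enumerate(fold_reports)
            if i not in flagged and np.isfinite(r.per_stage_accuracy[l])
        ]
        per_stage_mean[l] = float(np.mean(vals)) if vals else float("nan")
    return LoocvResult(
        system_id=system.id,
        predictions=predictions,
        references=references,
        pooled=pooled,
        fold_reports=fold_reports,
        per_stage_accuracy_mean=per_stage_mean,
        flagged_folds=flagged,
    )


def sleep_summary(h: Hypnogram, onset_rule: str = "first") -> SleepSummary:
    """SE, TST, TWT and WASO from a 2-stage (wake/sleep) hypnogram.

    Each epoch contributes 0.5 min.  Sleep onset is the first sleep
    epoch (``onset_rule='first'``) or the first of three consecutive
    sleep epochs (``'first3'``); WASO counts wake minutes after onset.
    An all-wake night has WASO = 0.
    """
    if h.n_epochs == 0:
        raise ValueError("empty hypnogram")
    if h.alphabet_id != "s2":
        raise ValueError("sleep summary requires a 2-stage (W/S) hypnogram")
    is_sleep = np.array([l == "S" for l in h.labels])
    minutes = 0.5
    tst = float(is_sleep.sum() * minutes)
    twt = float((~is_sleep).sum() * minutes)
    tib = float(h.n_epochs * minutes)
    if onset_rule == "first":
        onset_idx = int(np.argmax(is_sleep)) if is_sleep.any() else None
    elif onset_rule == "first3":
        onset_idx = None
        runs = np.convolve(is_sleep.astype(int), np.ones(3, dtype=int), "valid")
        hits = np.flatnonzero(runs == 3)
        if hits.size:
            onset_idx = int(hits[0])
    else:
        raise ValueError("onset_rule must be 'first' or 'first3'")
    waso = (
        float((~is_sleep[onset_idx:]).sum() * minutes) if onset_idx is not None else 0.0
    )
    return SleepSummary(
        SE=100.0 * tst / tib, TST=tst, TWT=twt, WASO=waso, time_in_bed=tib
    )


def se_group(se: float) -> str:
    """SE group with half-open boundaries: 0-39, 40-59, 60-79, >=80."""
    if not 0 <= se <= 100:
        raise ValueError("SE must be in [0, 100] percent")
    if se < 40:
        return SE_GROUPS[0]
    if se < 60:
        return SE_GROUPS[1]
    if se < 80:
        return SE_GROUPS[2]
    return SE_GROUPS[3]


def screening_metrics(
    est_se: np.ndarray, psg_se: np.ndarray, threshold: float
) -> ScreeningReport:
    """Screening performance of estimated SE against reference SE groups.

    Subjects are dichotomized at the threshold (>= threshold is
    positive) on both the estimated and reference SE; sensitivity,
    specificity, PPV, NPV (percent) and the binary kappa follow from the
    2x2 table.  The ROC sweeps the *continuous* estimated SE against the
    fixed reference membership; AUC by trapezoid.  If all subjects fall
    on one side of the reference threshold the undefined rates and the
    AUC are reported as NaN.
    """
    est_se = np.asarray(est_se, dtype=float)
    psg_se = np.asarray(psg_se, dtype=float)
    if est_se.shape != psg_se.shape:
        raise ValueError("est and reference SE vectors must be paired")
    if threshold not in (40.0, 60.0, 80.0) and threshold not in (40, 60, 80):
        raise ValueError("threshold must be one of 40, 60, 80")
    est_pos = est_se >= threshold
    ref_pos = psg_se >= threshold
    tp = int(np.sum(est_pos & ref_pos))
    fp = int(np.sum(est_pos & ~ref_pos))
    fn = int(np.sum(~est_pos & ref_pos))
    tn = int(np.sum(~est_pos & ~ref_pos))
    nan = float("nan")
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else nan
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else nan
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) else nan
    npv = 100.0 * tn / (tn + fn) if (tn + fn) else nan
    if ref_pos.all() or (~ref_pos).all():
        auc_val = nan
        kappa = nan
    else:
        fpr, tpr, _ = roc_curve(ref_pos.astype(int), est_se)
        auc_val = float(sk_auc(fpr, tpr))
        kappa = cohen_kappa(ref_pos.astype(int), est_pos.astype(int))
    return ScreeningReport(
        threshold=float(threshold),
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        kappa=kappa,
        auc=auc_val,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


@dataclass
class CorrelationSummary:
    r2: float
    mean_diff: float
    sd_diff: float
    ci95: tuple[float, float]
    t_pvalue: float


def correlation_summary(est, ref) -> CorrelationSummary:
    """Least-squares r^2 and paired-difference t statistics.

    ``r2`` is the coefficient of determination of the least-squares line
    of est on ref; the paired differences est - ref are summarized by
    mean, SD, 95% CI and the paired t-test p-value.  Zero variance in
    either vector makes r^2 undefined (NaN).
    """
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if est.std() == 0 or ref.std() == 0:
        r2 = float("nan")
    else:
        r = stats.pearsonr(est, ref).statistic
        r2 = float(r * r)
    d = est - ref
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    n = d.size
    sem = sd_d / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    t_res = stats.ttest_rel(est, ref)
    return CorrelationSummary(
        r2=r2,
        mean_diff=mean_d,
        sd_diff=sd_d,
        ci95=(mean_d - tcrit * sem, mean_d + tcrit * sem),
        t_pvalue=float(t_res.pvalue),
    )
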