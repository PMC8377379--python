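"""Classification metrics, ROC/AUC, cross-validation and dataset analyses.

Metrics are sensitivity (Sn), specificity (Sp), accuracy (Ac) and the
Matthews correlation coefficient (MCC), with MCC defined as 0 whenever its
denominator vanishes.  The ROC is built over all distinct score
thresholds with the ``P >= t`` positive rule; AUC is the trapezoid area,
which equals the tie-corrected Mann-Whitney U statistic divided by
``n_pos * n_neg``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .profiles import PssmProfile
from .seqio import AMINO_ACIDS, GAP, LabeledDataset, PaddedPeptide


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    sn: float
    sp: float
    ac: float
    mcc: float
    auc: float | None = None


def confusion_counts(
    p: np.ndarray, labels: np.ndarray, threshold: float
) -> ConfusionCounts:
    """Tally the confusion table with the ``P >= threshold`` positive rule."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    call = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int((call & pos).sum()),
        tn=int((~call & ~pos).sum()),
        fp=int((call & ~pos).sum()),
        fn=int((~call & pos).sum()),
    )


def metrics(c: ConfusionCounts, auc: float | None = None) -> MetricSet:
    """Sn, Sp, Ac and MCC from a confusion table.

    Any zero denominator factor yields 0 for that metric (the standard
    convention for MCC; Sn/Sp are 0 when their class is empty).
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    ac = (c.tp + c.tn) / c.total
    denom = (
        (c.tn + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tp + c.fn)
    )
    mcc = (
        (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    )
    return MetricSet(sn=sn, sp=sp, ac=ac, mcc=mcc, auc=auc)


def roc_auc(
    p: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points (fpr, tpr) over all distinct thresholds and trapezoid AUC.

    Tied scores form a single ROC step whose trapezoid contributes half
    credit, so the returned AUC equals the Mann-Whitney U statistic (with
    0.5 per tie) over ``n_pos * n_neg``.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes")
    order = np.argsort(-p, kind="mergesort")
    ps, ys = p[order], y[order]
    # collapse tied scores into single threshold steps
    distinct = np.r_[np.nonzero(np.diff(ps))[0], len(ps) - 1]
    tp = np.cumsum(ys == 1)[distinct]
    fp = np.cumsum(ys == 0)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class CvResult:
    fold_metrics: list[MetricSet]
    mean: MetricSet
    fold_assignment: list[np.ndarray]
    seed: int


def cross_validate(
    trainer: Callable,
    ds: LabeledDataset,
    profiles: Mapping[str, PssmProfile] | None,
    folds: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> CvResult:
    """Stratified k-fold evaluation of an arbitrary pipeline.

    ``trainer(train_ds, profiles)`` must return a callable
    ``scorer(test_ds, profiles) -> probability vector``.  Per fold the
    metric set at ``threshold`` plus the fold AUC are recorded; the mean
    row is the arithmetic mean of the fold values.
    """
    from .models import stratified_folds

    y = ds.labels
    fold_pairs = stratified_folds(y, folds, seed)
    fold_metrics: list[MetricSet] = []
    assignment: list[np.ndarray] = []
    for tr, te in fold_pairs:
        scorer = trainer(ds.subset(tr), profiles)
        p = np.asarray(scorer(ds.subset(te), profiles), dtype=float)
        m = metrics(confusion_counts(p, y[te], threshold))
        _, _, auc = roc_auc(p, y[te])
        fold_metrics.append(
            MetricSet(sn=m.sn, sp=m.sp, ac=m.ac, mcc=m.mcc, auc=auc)
        )
        assignment.append(te)
    mean = MetricSet(
        sn=float(np.mean([m.sn for m in fold_metrics])),
        sp=float(np.mean([m.sp for m in fold_metrics])),
        ac=float(np.mean([m.ac for m in fold_metrics])),
        mcc=float(np.mean([m.mcc for m in fold_metrics])),
        auc=float(np.mean([m.auc for m in fold_metrics])),
    )
    return CvResult(
        fold_metrics=fold_metrics, mean=mean, fold_assignment=assignment, seed=seed
    )


def compare_auc_ttest(
    aucs_a: Sequence[float], aucs_b: Sequence[float], paired: bool = True
) -> float:
    """Two-tailed t-test p-value comparing two sets of AUCs.

    Identical paired vectors (all-zero differences) give p = 1 by
    convention.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two AUC values per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal lengths")
        if np.allclose(a, b):
            return 1.0
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


def oof_report(predictor, threshold: float = 0.5):
    """Out-of-fold metric table: one row per encoding plus the fused row.

    Sn/Sp/Ac/MCC are computed at ``threshold`` for the single encodings
    and at the moderate tier threshold for the fused probability; AUC is
    threshold-free.
    """
    import pandas as pd

    rep = predictor.report
    if rep is None:
        raise ValueError("predictor carries no training report")
    rows = []
    for enc in predictor.fusion.order:
        scores = rep.oof_scores[enc]
        m = metrics(
            confusion_counts(scores, rep.labels, threshold),
            auc=roc_auc(scores, rep.labels)[2],
        )
        rows.append((enc, m))
    fused_t = predictor.fusion.thresholds["moderate"]
    m = metrics(
        confusion_counts(rep.fused_p, rep.labels, fused_t),
        auc=roc_auc(rep.fused_p, rep.labels)[2],
    )
    rows.append(("fused", m))
    return pd.DataFrame(
        {
            "method": [r[0] for r in rows],
            "Sp": [r[1].sp for r in rows],
            "Sn": [r[1].sn for r in rows],
            "Ac": [r[1].ac for r in rows],
            "MCC": [r[1].mcc for r in rows],
            "AUC": [r[1].auc for r in rows],
        }
    )


def length_sweep(
    make_dataset: Callable[[int], tuple[LabeledDataset, Mapping[str, PssmProfile]]],
    lengths: Sequence[int] = (5, 10, 15, 20, 25),
    cfg=None,
    folds: int = 10,
    seed: int = 0,
):
    """Window-length experiment: CV AUC per (length, encoding) without
    feature selection.

    ``make_dataset(length)`` must return a dataset whose window width is
    ``length`` together with matching profiles.  For each length the four
    encodings are evaluated with all features (no rank-sum selection) and
    the fused model is fit on their out-of-fold scores.
    """
    import pandas as pd

    from .encoders import encode_dataset
    from .models import (
        FUSION_ORDER,
        RfConfig,
        SelectionMask,
        fit_fusion,
        oof_scores,
        predict_fusion,
    )

    cfg = cfg or RfConfig(seed=seed)
    records = []
    for length in lengths:
        ds, profiles = make_dataset(length)
        y = ds.labels
        oof = {}
        for enc in FUSION_ORDER:
            fm = encode_dataset(ds, enc, profiles=profiles)
            full = SelectionMask(encoding=enc, indices=tuple(range(fm.d)), k=fm.d)
            oof[enc] = oof_scores(fm, full, cfg, folds=folds, fold_seed=seed + 1)
            records.append((length, enc, roc_auc(oof[enc], y)[2]))
        sm = np.column_stack([oof[enc] for enc in FUSION_ORDER])
        fused = predict_fusion(fit_fusion(sm, y), sm)
        records.append((length, "fused", roc_auc(fused, y)[2]))
    return pd.DataFrame(records, columns=["length", "encoding", "auc"])


def positional_enrichment(
    pos: Sequence[PaddedPeptide],
    neg: Sequence[PaddedPeptide],
    positions: Sequence[int] = tuple(range(1, 16)),
    alpha: float = 0.05,
):
    """Per-(position, residue) frequency difference with a Welch-style
    unequal-variance two-sample test on residue indicators.

    Returns a DataFrame with one row per (position, residue):
    ``freq_pos``, ``freq_neg``, ``diff`` (positive - negative), ``p`` and
    ``significant`` (p < alpha).  Positions are 1-based; gap positions
    count as absence for every residue.
    """
    import pandas as pd

    if not pos or not neg:
        raise ValueError("both peptide sets must be non-empty")
    records = []
    for position in positions:
        pos_chars = [
            p.window[position - 1] if position <= p.width else GAP for p in pos
        ]
        neg_chars = [
            p.window[position - 1] if position <= p.width else GAP for p in neg
        ]
        for residue in AMINO_ACIDS:
            a = np.array([c == residue for c in pos_chars], dtype=float)
            b = np.array([c == residue for c in neg_chars], dtype=float)
            fa, fb = float(a.mean()), float(b.mean())
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                p_val = 1.0
            else:
                p_val = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
                if math.isnan(p_val):
                    p_val = 1.0
            records.append(
                (position, residue, fa, fb, fa - fb, p_val, p_val < alpha)
            )
    return pd.DataFrame(
        records,
        columns=["position", "residue", "freq_pos", "freq_neg", "diff", "p", "significant"],
    )
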