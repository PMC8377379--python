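"""Random-forest scoring per encoding and logistic score fusion.

One bagged random forest is trained per encoding on its rank-sum-selected
feature columns.  The *RF score* of an example is the fraction of trees
voting the positive class.  The four per-encoding scores are fused by a
logistic regression

    logit(P) = beta_PSSM * R_PSSM + beta_AIP * R_AIP
             + beta_PKAF * R_PKAF + beta_AFC * R_AFC + alpha

fit on out-of-fold scores so that the fusion layer never sees
resubstitution optimism.  Three decision tiers (high/moderate/low) cut the
fused probability at thresholds calibrated to target specificities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .aaindex import AAIndexTable, aaindex_table
from .encoders import FeatureMatrix, encode_dataset
from .profiles import PssmProfile
from .selection import SelectionMask, score_all_features, select_top_k
from .seqio import LabeledDataset

#: Order of the fused score vector and of the fusion coefficients.
FUSION_ORDER: tuple[str, ...] = ("PSSM", "AIP", "PKAF", "AFC")

#: Concatenation order of the sequential (single-forest) competitor.
SEQUENTIAL_ORDER: tuple[str, ...] = ("AFC", "AIP", "PSSM", "PKAF")

#: Default rank-sum selection sizes per encoding.
DEFAULT_KS: dict[str, int] = {"AIP": 170, "AFC": 510, "PSSM": 320, "PKAF": 490}

#: Default decision-tier thresholds on the fused probability.
DEFAULT_THRESHOLDS: dict[str, float] = {"high": 0.485, "moderate": 0.410, "low": 0.360}

#: Target specificities used when calibrating tier thresholds.
DEFAULT_TARGET_SP: tuple[float, float, float] = (0.866, 0.747, 0.636)

TIERS = ("high", "moderate", "low")

ARCHIVE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class RfConfig:
    """Forest settings: tree count, sqrt-features splits, fixed seed."""

    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class EncodingModel:
    encoding: str
    mask: SelectionMask
    forest: RandomForestClassifier
    n_train: int
    class_counts: tuple[int, int]
    seed: int

    def scores(self, values: np.ndarray) -> np.ndarray:
        """Vote-fraction RF score for each row of ``values`` (full-width
        feature rows; the mask is applied here)."""
        return _vote_fraction(self.forest, values[:, list(self.mask.indices)])


def _vote_fraction(forest: RandomForestClassifier, x: np.ndarray) -> np.ndarray:
    """Fraction of trees predicting the positive class, per example."""
    pos_col = int(np.where(forest.classes_ == 1)[0][0])
    votes = np.zeros(x.shape[0])
    for tree in forest.estimators_:
        votes += (tree.predict(x) == forest.classes_[pos_col]).astype(float)
    return votes / len(forest.estimators_)


def train_rf(fm: FeatureMatrix, mask: SelectionMask, cfg: RfConfig) -> EncodingModel:
    """Train one bagged forest on the mask-selected columns."""
    if fm.labels is None:
        raise ValueError("feature matrix carries no labels")
    y = np.asarray(fm.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    x = fm.values[:, list(mask.indices)]
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    forest.fit(x, y)
    return EncodingModel(
        encoding=fm.encoding,
        mask=mask,
        forest=forest,
        n_train=fm.n,
        class_counts=(int((y == 1).sum()), int((y == 0).sum())),
        seed=cfg.seed,
    )


def stratified_folds(
    labels: np.ndarray, folds: int, fold_seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified fold assignment (train_idx, test_idx) pairs."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def oof_scores(
    fm: FeatureMatrix,
    mask: SelectionMask,
    cfg: RfConfig,
    folds: int = 10,
    fold_seed: int = 0,
) -> np.ndarray:
    """Out-of-fold RF score for every row, aligned to row order.

    Each example is scored by the forest trained on the other folds.
    """
    if fm.labels is None:
        raise ValueError("feature matrix carries no labels")
    y = np.asarray(fm.labels)
    if folds < 2 or fm.n < folds:
        raise ValueError("need folds >= 2 and n >= folds")
    out = np.full(fm.n, np.nan)
    for tr, te in stratified_folds(y, folds, fold_seed):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a training split lost one class; use fewer folds")
        sub = FeatureMatrix(
            encoding=fm.encoding,
            values=fm.values[tr],
            columns=fm.columns,
            ids=tuple(fm.ids[i] for i in tr),
            labels=y[tr],
        )
        model = train_rf(sub, mask, cfg)
        out[te] = model.scores(fm.values[te])
    assert not np.isnan(out).any()
    return out


def oof_scores_nested(
    fm: FeatureMatrix,
    k: int,
    cfg: RfConfig,
    folds: int = 10,
    fold_seed: int = 0,
) -> np.ndarray:
    """Out-of-fold RF scores with feature selection nested in each fold.

    Rank-sum scoring and top-k selection are redone on every training
    split, so the held-out fold contributes nothing to the choice of
    columns — otherwise chance-correlated columns picked on the full data
    would leak label information into the out-of-fold scores.
    """
    if fm.labels is None:
        raise ValueError("feature matrix carries no labels")
    y = np.asarray(fm.labels)
    if folds < 2 or fm.n < folds:
        raise ValueError("need folds >= 2 and n >= folds")
    out = np.full(fm.n, np.nan)
    for tr, te in stratified_folds(y, folds, fold_seed):
        sub = FeatureMatrix(
            encoding=fm.encoding,
            values=fm.values[tr],
            columns=fm.columns,
            ids=tuple(fm.ids[i] for i in tr),
            labels=y[tr],
        )
        mask = select_top_k(score_all_features(sub), min(k, fm.d), fm.encoding)
        model = train_rf(sub, mask, cfg)
        out[te] = model.scores(fm.values[te])
    assert not np.isnan(out).any()
    return out


@dataclass
class FusionModel:
    """Logistic fusion coefficients over the four RF scores plus tiers.

    ``betas`` follow :data:`FUSION_ORDER` (PSSM, AIP, PKAF, AFC).
    """

    betas: np.ndarray
    alpha: float
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    order: tuple[str, ...] = FUSION_ORDER

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape != (len(self.order),):
            raise ValueError("one beta per fused encoding is required")
        if not np.all(np.isfinite(self.betas)) or not np.isfinite(self.alpha):
            raise ValueError("fusion coefficients must be finite")
        t = self.thresholds
        if not (t["high"] > t["moderate"] > t["low"]):
            raise ValueError("thresholds must satisfy high > moderate > low")
        if not all(0.0 < v < 1.0 for v in t.values()):
            raise ValueError("thresholds must lie in (0, 1)")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _irls_logistic(
    x: np.ndarray, y: np.ndarray, ridge: float, tol: float = 1e-10, max_iter: int = 100
) -> tuple[np.ndarray, bool]:
    """Newton/IRLS fit of a logistic model with an L2 penalty on all
    coefficients.  Returns (coefficients incl. trailing intercept,
    converged flag)."""
    xd = np.hstack([x, np.ones((x.shape[0], 1))])
    beta = np.zeros(xd.shape[1])
    penalty = ridge * np.eye(xd.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = xd @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = xd.T @ (y - mu) - ridge * beta
        hess = (xd * w[:, None]).T @ xd + penalty
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return beta, converged


def fit_fusion(
    oof_score_matrix: np.ndarray,
    labels: np.ndarray,
    ridge: float = 1e-8,
    order: tuple[str, ...] = FUSION_ORDER,
) -> FusionModel:
    """Maximum-likelihood logistic fit of labels on the fused scores.

    A tiny ridge keeps the Newton steps well-posed; on (quasi-)separation
    the fit is redone with ridge 1e-3 and a warning so it always
    terminates with finite coefficients.
    """
    x = np.asarray(oof_score_matrix, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(order):
        raise ValueError(f"score matrix must be n x {len(order)}")
    if x.shape[0] != y.shape[0]:
        raise ValueError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if x.min() < -1e-9 or x.max() > 1 + 1e-9:
        raise ValueError("RF scores must lie in [0, 1]")

    coef, converged = _irls_logistic(x, y, ridge)
    if not converged or np.max(np.abs(coef)) > 50.0:
        warnings.warn(
            "logistic fusion fit hit (quasi-)separation; refitting with "
            "ridge 1e-3",
            RuntimeWarning,
            stacklevel=2,
        )
        coef, _ = _irls_logistic(x, y, ridge=1e-3)
    return FusionModel(betas=coef[:-1], alpha=float(coef[-1]), order=order)


def predict_fusion(model: FusionModel, scores: np.ndarray) -> np.ndarray:
    """Fused probability P = sigmoid(sum beta_n R_n + alpha), elementwise."""
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    if x.shape[1] != len(model.order):
        raise ValueError(f"expected {len(model.order)} scores per example")
    if x.min() < -1e-9 or x.max() > 1 + 1e-9:
        raise ValueError("RF scores must lie in [0, 1]")
    p = _sigmoid(x @ model.betas + model.alpha)
    return p if np.asarray(scores).ndim == 2 else p[0]


def classify(p, tier: str, model: FusionModel):
    """Positive call iff P >= the tier's threshold (ties are positive)."""
    if tier not in model.thresholds:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
    return np.asarray(p) >= model.thresholds[tier]


def calibrate_thresholds(
    oof_p: np.ndarray,
    labels: np.ndarray,
    target_sp: Sequence[float] = DEFAULT_TARGET_SP,
    min_separation: float = 1e-9,
) -> dict[str, float]:
    """Smallest threshold per tier achieving Sp >= target on given scores.

    With the ``P >= t`` positive rule, Sp(t) is the fraction of negatives
    scoring strictly below t; the smallest achieving threshold sits just
    above the ceil(target * n_neg)-th smallest negative score.  Strictly
    decreasing tier thresholds are enforced with a minimal separation.
    """
    p = np.asarray(oof_p, dtype=float)
    y = np.asarray(labels)
    neg = np.sort(p[y == 0])
    if neg.size == 0 or (y == 1).sum() == 0:
        raise ValueError("both classes must be present")
    targets = list(target_sp)
    if sorted(targets, reverse=True) != targets:
        raise ValueError("target specificities must be given high to low")
    out: dict[str, float] = {}
    prev = 1.0
    for tier, sp in zip(TIERS, targets):
        need = int(np.ceil(sp * neg.size))
        if need == 0:
            t = min(float(neg[0]), 1.0) * 0.5  # any t <= min score works
        else:
            t = float(np.nextafter(neg[need - 1], np.inf))
        if t > 1.0:
            raise ValueError(
                f"target specificity {sp} for tier {tier!r} is unattainable "
                "(required threshold exceeds 1)"
            )
        if t >= prev:  # enforce strict decrease across tiers
            t = prev - min_separation
            if t <= 0.0:
                t = prev / 2.0
        out[tier] = t
        prev = t
    return out


@dataclass
class TrainingReport:
    """Out-of-fold scores gathered during pipeline training."""

    oof_scores: dict[str, np.ndarray]  # per encoding, dataset row order
    fused_p: np.ndarray
    labels: np.ndarray
    fold_seed: int


class EpitopePredictor:
    """Four per-encoding forests plus the logistic fusion layer."""

    def __init__(
        self,
        encoding_models: Mapping[str, EncodingModel],
        fusion: FusionModel,
        table: AAIndexTable,
        width: int,
        spacings: tuple[int, ...],
        report: TrainingReport | None = None,
    ):
        missing = set(FUSION_ORDER) - set(encoding_models)
        if missing:
            raise ValueError(f"missing encoding models: {sorted(missing)}")
        self.encoding_models = dict(encoding_models)
        self.fusion = fusion
        self.table = table
        self.width = width
        self.spacings = spacings
        self.report = report

    def score_matrix(
        self, ds: LabeledDataset, profiles: Mapping[str, PssmProfile]
    ) -> np.ndarray:
        """n x 4 RF-score matrix in :data:`FUSION_ORDER`."""
        cols = []
        for enc in self.fusion.order:
            fm = encode_dataset(
                ds, enc, profiles=profiles, table=self.table, spacings=self.spacings
            )
            cols.append(self.encoding_models[enc].scores(fm.values))
        return np.column_stack(cols)

    def predict(self, ds: LabeledDataset, profiles: Mapping[str, PssmProfile]):
        """Per-peptide scores, fused probability and tier calls."""
        import pandas as pd

        r = self.score_matrix(ds, profiles)
        p = predict_fusion(self.fusion, r)
        df = pd.DataFrame({"id": ds.ids})
        for j, enc in enumerate(self.fusion.order):
            df[f"R_{enc}"] = r[:, j]
        df["P"] = p
        for tier in TIERS:
            df[f"call_{tier}"] = classify(p, tier, self.fusion).astype(int)
        return df

    # -- persistence ------------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": ARCHIVE_FORMAT_VERSION,
            "width": self.width,
            "spacings": list(self.spacings),
            "fusion": {
                "order": list(self.fusion.order),
                "betas": [float(b) for b in self.fusion.betas],
                "alpha": float(self.fusion.alpha),
                "thresholds": self.fusion.thresholds,
            },
            "masks": {
                enc: list(m.mask.indices) for enc, m in self.encoding_models.items()
            },
            "seeds": {enc: m.seed for enc, m in self.encoding_models.items()},
            "aaindex_normalized": self.table.normalized,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        joblib.dump(
            {enc: m for enc, m in self.encoding_models.items()},
            outdir / "forests.joblib",
        )
        if self.report is not None:
            joblib.dump(self.report, outdir / "report.joblib")

    @classmethod
    def load(cls, outdir: str | Path) -> "EpitopePredictor":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        if manifest.get("format_version") != ARCHIVE_FORMAT_VERSION:
            raise ValueError(
                f"archive format version {manifest.get('format_version')} is not "
                f"supported (expected {ARCHIVE_FORMAT_VERSION})"
            )
        models = joblib.load(outdir / "forests.joblib")
        fus = manifest["fusion"]
        fusion = FusionModel(
            betas=np.array(fus["betas"]),
            alpha=fus["alpha"],
            thresholds=dict(fus["thresholds"]),
            order=tuple(fus["order"]),
        )
        report = None
        if (outdir / "report.joblib").exists():
            report = joblib.load(outdir / "report.joblib")
        return cls(
            encoding_models=models,
            fusion=fusion,
            table=aaindex_table(normalized=manifest["aaindex_normalized"]),
            width=manifest["width"],
            spacings=tuple(manifest["spacings"]),
            report=report,
        )


def train_predictor(
    ds: LabeledDataset,
    profiles: Mapping[str, PssmProfile],
    table: AAIndexTable | None = None,
    cfg: RfConfig = RfConfig(),
    ks: Mapping[str, int] | None = None,
    folds: int = 10,
    spacings: tuple[int, ...] = (0, 1),
    calibrate: bool = True,
) -> EpitopePredictor:
    """Full fused-pipeline training.

    Per encoding: encode, then collect out-of-fold RF scores with
    rank-sum selection nested inside each fold, and train the deployed
    forest on the full data with full-data selection.  The fusion layer
    is fit on the out-of-fold score matrix (leakage guard) and, if
    ``calibrate``, the tier thresholds are recalibrated on the fused
    out-of-fold probabilities.
    """
    table = table or aaindex_table()
    ks = dict(DEFAULT_KS) | dict(ks or {})
    labels = ds.labels
    models: dict[str, EncodingModel] = {}
    oof: dict[str, np.ndarray] = {}
    fold_seed = cfg.seed + 1
    for enc in FUSION_ORDER:
        fm = encode_dataset(ds, enc, profiles=profiles, table=table, spacings=spacings)
        k = min(ks[enc], fm.d)
        oof[enc] = oof_scores_nested(fm, k, cfg, folds=folds, fold_seed=fold_seed)
        mask = select_top_k(score_all_features(fm), k, encoding=enc)
        models[enc] = train_rf(fm, mask, cfg)
    score_matrix = np.column_stack([oof[enc] for enc in FUSION_ORDER])
    fusion = fit_fusion(score_matrix, labels)
    fused_p = predict_fusion(fusion, score_matrix)
    if calibrate:
        try:
            fusion.thresholds = calibrate_thresholds(fused_p, labels)
        except ValueError as exc:
            warnings.warn(
                f"threshold calibration failed ({exc}); keeping defaults",
                RuntimeWarning,
                stacklevel=2,
            )
    report = TrainingReport(
        oof_scores=oof, fused_p=fused_p, labels=labels, fold_seed=fold_seed
    )
    return EpitopePredictor(
        encoding_models=models,
        fusion=fusion,
        table=table,
        width=ds.width,
        spacings=spacings,
        report=report,
    )


@dataclass
class SequentialModel:
    """Single-forest competitor trained on the concatenated encodings."""

    model: EncodingModel
    columns: tuple[str, ...]
    oof: np.ndarray
    labels: np.ndarray
    order: tuple[str, ...] = SEQUENTIAL_ORDER


def train_sequential(
    ds: LabeledDataset,
    profiles: Mapping[str, PssmProfile],
    table: AAIndexTable | None = None,
    cfg: RfConfig = RfConfig(),
    top_k: int = 380,
    folds: int = 10,
    spacings: tuple[int, ...] = (0, 1),
) -> SequentialModel:
    """Concatenate all four encodings in a row (AFC, AIP, PSSM, PKAF),
    rank-sum select ``top_k`` columns and train a single forest."""
    table = table or aaindex_table()
    blocks = [
        encode_dataset(ds, enc, profiles=profiles, table=table, spacings=spacings)
        for enc in SEQUENTIAL_ORDER
    ]
    values = np.hstack([b.values for b in blocks])
    columns = tuple(
        f"{b.encoding.lower()}.{c}" for b in blocks for c in b.columns
    )
    fm = FeatureMatrix(
        encoding="SEQ",
        values=values,
        columns=columns,
        ids=tuple(ds.ids),
        labels=ds.labels,
    )
    k = min(top_k, fm.d)
    oof = oof_scores_nested(fm, k, cfg, folds=folds, fold_seed=cfg.seed + 1)
    mask = select_top_k(score_all_features(fm), k, encoding="SEQ")
    model = train_rf(fm, mask, cfg)
    return SequentialModel(
        model=model, columns=columns, oof=oof, labels=ds.labels
    )
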