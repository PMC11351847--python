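"""Cross-validation harness, confusion-matrix metric suite and the result grid.

Evaluation follows the study protocol: stratified tenfold cross-validation
with the diabetic class as positive.  Test-fold confusion matrices are
pooled (summed) into one matrix over all patients -- for 20/50 class sizes
this is the convention that makes the accuracy/F1/MCC/kappa of a row
mutually consistent -- and six metrics are computed from it: accuracy, F1,
Matthews correlation, Jaccard, error rate (= 1 - accuracy exactly) and
Cohen's kappa.

``run_pipeline`` assembles the full result grid: every combination of
feature extraction (STFT, RR, PCC), feature selection (none, BESO, RDO) and
the seven classifiers, each cell trained per fold with leakage-free PCC
templates and per-fold feature selection (a ``pooled_selection`` switch instead
selects once on all data, mimicking the likely original protocol).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from ._util import derive_seed
from .classify import CLASSIFIER_KINDS, RBFConfig, TargetCoding, encode_targets, train_classifier
from .featex import pcc_extract, block_templates, ridge_extract, stft_extract
from .featex import RidgeConfig, STFTConfig
from .metaopt import BesoParams, FitnessConfig, RdoParams, select_features
from .syndata import DIA, NONDIA, ExpressionMatrix, SynthConfig, generate_dataset, preprocess

FE_METHODS = ("STFT", "RR", "PCC")
FS_METHODS = ("none", "BESO", "RDO")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn, self.fp + other.fp, self.tn + other.tn
        )


@dataclass(frozen=True)
class MetricsRow:
    accuracy: float
    f1: float
    mcc: float
    jaccard: float
    error_rate: float
    kappa: float


@dataclass(frozen=True)
class CVPlan:
    k: int = 10
    stratified: bool = True
    seed: int = 0


def confusion(true_labels, pred_labels) -> ConfusionMatrix:
    """Count TP/FN/FP/TN with diabetic as the positive class."""
    true_labels = np.asarray(true_labels, dtype=object)
    pred_labels = np.asarray(pred_labels, dtype=object)
    if len(true_labels) != len(pred_labels):
        raise ValueError("label vectors must have equal length")
    for lab in np.concatenate([true_labels, pred_labels]):
        if lab not in (DIA, NONDIA):
            raise ValueError(f"unknown label {lab!r}")
    tp = int(np.sum((true_labels == DIA) & (pred_labels == DIA)))
    fn = int(np.sum((true_labels == DIA) & (pred_labels == NONDIA)))
    fp = int(np.sum((true_labels == NONDIA) & (pred_labels == DIA)))
    tn = int(np.sum((true_labels == NONDIA) & (pred_labels == NONDIA)))
    return ConfusionMatrix(tp, fn, fp, tn)


def metrics(cm: ConfusionMatrix) -> MetricsRow:
    """The six-metric suite; MCC and kappa return 0 on zero denominators."""
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")

    accuracy = (tp + tn) / n
    f1_den = 2 * tp + fp + fn
    f1 = 2 * tp / f1_den if f1_den else 0.0
    jac_den = tp + fp + fn
    jaccard = tp / jac_den if jac_den else 0.0

    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den == 0:
        warnings.warn("MCC denominator zero: returning 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den)

    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fp + tn) * (fn + tn)) / n**2
    if pe == 1.0:
        warnings.warn("kappa denominator zero: returning 0")
        kappa = 0.0
    else:
        kappa = (po - pe) / (1 - pe)

    return MetricsRow(
        accuracy=accuracy,
        f1=f1,
        mcc=float(mcc),
        jaccard=jaccard,
        error_rate=1.0 - accuracy,
        kappa=float(kappa),
    )


def recover_confusion(
    accuracy: float, f1: float, n_pos: int = 20, n_neg: int = 50, decimals: int = 4
) -> ConfusionMatrix:
    """Brute-force the integer confusion matrix behind printed accuracy + F1.

    Enumerates every (TP, FP) with the given class sizes and keeps the
    matrices whose accuracy and F1 round to the printed values at
    ``decimals`` places.  Raises if the solution is not unique -- for the
    published 20/50 cohort the printed pairs pin the matrix down exactly.
    Accuracy/F1 may be given on either the percent or the 0-1 scale.
    """
    if accuracy > 1:
        accuracy /= 100.0
    if f1 > 1:
        f1 /= 100.0
    tol = 0.5 * 10.0 ** (-decimals)
    hits = []
    for tp in range(n_pos + 1):
        fn = n_pos - tp
        for fp in range(n_neg + 1):
            tn = n_neg - fp
            acc = (tp + tn) / (n_pos + n_neg)
            f1_den = 2 * tp + fp + fn
            f1_val = 2 * tp / f1_den if f1_den else 0.0
            if abs(acc - accuracy) <= tol and abs(f1_val - f1) <= tol:
                hits.append(ConfusionMatrix(tp, fn, fp, tn))
    if len(hits) != 1:
        raise ValueError(
            f"confusion matrix not uniquely determined ({len(hits)} candidates)"
        )
    return hits[0]


def mse(outputs, targets) -> float:
    """Mean squared error (1/N) sum (O_j - T_j)^2."""
    outputs = np.asarray(outputs, dtype=float).ravel()
    targets = np.asarray(targets, dtype=float).ravel()
    if outputs.size == 0 or outputs.size != targets.size:
        raise ValueError("outputs and targets must be equal-length and non-empty")
    return float(np.mean((outputs - targets) ** 2))


def kfold_split(labels, plan: CVPlan = CVPlan()):
    """Seeded (stratified) k-fold test splits covering every patient once."""
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if n < plan.k:
        raise ValueError("fewer patients than folds")
    if plan.stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < plan.k:
            warnings.warn("a class is smaller than k: falling back to plain k-fold")
            splitter = KFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
            return list(splitter.split(np.zeros(n)))
        splitter = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
        return list(splitter.split(np.zeros(n), labels))
    splitter = KFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
    return list(splitter.split(np.zeros(n)))


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineConfig:
    """One end-to-end run: data conditions, methods, budgets, protocol flags."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    fe_methods: tuple = FE_METHODS
    fs_methods: tuple = FS_METHODS
    classifiers: tuple = CLASSIFIER_KINDS
    k_select: int = 287
    cv: CVPlan = field(default_factory=CVPlan)
    beso: BesoParams = field(default_factory=BesoParams)
    rdo: RdoParams = field(default_factory=RdoParams)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    stft: STFTConfig = field(default_factory=STFTConfig)
    ridge: RidgeConfig = field(default_factory=RidgeConfig)
    svm: RBFConfig = field(default_factory=RBFConfig)
    coding: TargetCoding = field(default_factory=TargetCoding)
    pooled_selection: bool = False
    seed: int = 0


def extract_features(m: ExpressionMatrix, method: str, cfg: PipelineConfig, train_columns=None):
    """Dispatch one extractor; PCC templates come from the training columns only.

    The PCC template is the mean block of the *non-diabetic* training
    patients (a healthy reference profile).  The pooled across-everyone
    mean is identically zero after per-gene standardization and would
    carry no signal.
    """
    method = method.upper()
    if method == "STFT":
        return stft_extract(m, cfg.stft)
    if method == "RR":
        return ridge_extract(m, cfg.ridge)
    if method == "PCC":
        ref = np.flatnonzero(m.labels == NONDIA)
        if train_columns is not None:
            ref = np.intersect1d(ref, np.asarray(train_columns, dtype=int))
        template = block_templates(m, columns=ref if len(ref) else train_columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return pcc_extract(m, template)
    raise ValueError(f"unknown feature-extraction method {method!r}")


def _fs_params(cfg: PipelineConfig, method: str, seed: int):
    if method == "BESO":
        p = cfg.beso
        return BesoParams(**{**p.__dict__, "seed": seed})
    p = cfg.rdo
    return RdoParams(**{**p.__dict__, "seed": seed})


def _select(cfg, method, features, labels, seed):
    if method == "none":
        return None
    result = select_features(
        features,
        labels,
        method=method,
        k=min(cfg.k_select, features.shape[0]),
        params=_fs_params(cfg, method, seed),
        fitness_cfg=FitnessConfig(
            n_folds=cfg.fitness.n_folds,
            sparsity_weight=cfg.fitness.sparsity_weight,
            seed=derive_seed(seed, "fs-folds"),
        ),
    )
    return result.indices


def run_pipeline(cfg: PipelineConfig, data: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Evaluate the full FE x FS x classifier grid under tenfold CV.

    Returns one row per grid cell with the pooled test confusion matrix,
    the six metrics, the mean per-fold training MSE and the pooled test MSE
    (plus the per-fold mean as ``test_mse_foldmean``).  A failing cell is
    reported with ``status=failed`` and the run continues.
    """
    if data is None:
        synth = SynthConfig(**{**cfg.synth.__dict__, "seed": derive_seed(cfg.seed, "synth")})
        data = generate_dataset(synth)
    m = data if data.is_standardized else preprocess(data)
    labels = m.labels
    folds = kfold_split(labels, CVPlan(cfg.cv.k, cfg.cv.stratified, derive_seed(cfg.seed, "cv")))
    targets_all = encode_targets(labels, cfg.coding)

    rows = []
    for fe in cfg.fe_methods:
        # STFT and RR are per-patient maps: extract once. PCC depends on a
        # training template, so it is redone inside every fold (unless
        # pooled_selection, which fits the template once on everyone).
        fe_static = None
        if fe.upper() != "PCC" or cfg.pooled_selection:
            fe_static = extract_features(m, fe, cfg, train_columns=None)

        fold_features = []
        for train_idx, test_idx in folds:
            fm = fe_static if fe_static is not None else extract_features(
                m, fe, cfg, train_columns=train_idx
            )
            fold_features.append(fm.values)

        for fs in cfg.fs_methods:
            fs_seed = derive_seed(cfg.seed, f"fs-{fe}-{fs}")
            if cfg.pooled_selection and fs != "none":
                global_sel = _select(cfg, fs, fold_features[0], labels, fs_seed)
            fold_selection = []
            for fold_i, (train_idx, _) in enumerate(folds):
                if fs == "none":
                    fold_selection.append(None)
                elif cfg.pooled_selection:
                    fold_selection.append(global_sel)
                else:
                    fold_selection.append(
                        _select(
                            cfg,
                            fs,
                            fold_features[fold_i][:, train_idx],
                            labels[train_idx],
                            derive_seed(fs_seed, f"fold{fold_i}"),
                        )
                    )

            for clf in cfg.classifiers:
                cell = {"fe": fe, "fs": fs, "classifier": clf}
                try:
                    pooled = ConfusionMatrix(0, 0, 0, 0)
                    train_mses, fold_test_mses = [], []
                    test_outputs = np.full(len(labels), np.nan)
                    for fold_i, (train_idx, test_idx) in enumerate(folds):
                        feats = fold_features[fold_i]
                        sel = fold_selection[fold_i]
                        x = feats.T if sel is None else feats[sel].T
                        clf_cfg = cfg.svm if clf.upper().startswith("SVM") else None
                        trained = train_classifier(
                            clf,
                            x[train_idx],
                            labels[train_idx],
                            coding=cfg.coding,
                            cfg=clf_cfg,
                            seed=derive_seed(cfg.seed, f"clf-{fe}-{fs}-{clf}-{fold_i}"),
                        )
                        train_mses.append(trained.training_mse)
                        out = trained.predict_continuous(x[test_idx])
                        test_outputs[test_idx] = out
                        fold_test_mses.append(mse(out, targets_all[test_idx]))
                        pooled = pooled + confusion(
                            labels[test_idx], cfg.coding.decode(out)
                        )
                    row_metrics = metrics(pooled)
                    cell.update(
                        status="ok",
                        TP=pooled.tp,
                        FN=pooled.fn,
                        FP=pooled.fp,
                        TN=pooled.tn,
                        accuracy=row_metrics.accuracy,
                        f1=row_metrics.f1,
                        mcc=row_metrics.mcc,
                        jaccard=row_metrics.jaccard,
                        error_rate=row_metrics.error_rate,
                        kappa=row_metrics.kappa,
                        train_mse=float(np.mean(train_mses)),
                        test_mse=mse(test_outputs, targets_all),
                        test_mse_foldmean=float(np.mean(fold_test_mses)),
                    )
                except Exception as exc:  # keep the grid going
                    warnings.warn(f"cell ({fe}, {fs}, {clf}) failed: {exc}")
                    cell.update(status=f"failed: {exc}")
                rows.append(cell)

    columns = [
        "fe", "fs", "classifier", "status", "TP", "FN", "FP", "TN",
        "accuracy", "f1", "mcc", "jaccard", "error_rate", "kappa",
        "train_mse", "test_mse", "test_mse_foldmean",
    ]
    return pd.DataFrame(rows).reindex(columns=columns)


def write_results(df: pd.DataFrame, path, run_meta: dict | None = None) -> None:
    """Deterministic CSV serialization (fixed float format) plus a JSON run log."""
    df.to_csv(path, index=False, float_format="%.10g")
    if run_meta is not None:
        with open(str(path) + ".log.json", "w") as fh:
            json.dump(run_meta, fh, indent=2, sort_keys=True, default=str)
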