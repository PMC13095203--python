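"""Single-sample classification with a multiclass SVM.

The feature pipeline is per-sample and therefore cohort-independent:
subset the expression matrix to the union of signature genes, rescale each
sample's subset values to a constant sum, and compute median signature
scores. An SVM (linear kernel, balanced class weights, standardized
features, pairwise Platt-coupled probabilities) is trained to recapture
decision-tree labels; predictions come with a confidence vector over the
four classes summing to 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .errors import (
    DegenerateSample,
    DegenerateSplit,
    EmptyInput,
    InvalidParameter,
    IOFailure,
    SampleMismatch,
)
from .io_formats import SignatureRegistry, normalize_gene
from .preprocess import ExpressionMatrix
from .signatures import SignatureScoreMatrix, score_all
from .classifier import SubtypeCall

DEFAULT_TARGET_SUM = 1e4


def rescale_constant_sum(values: np.ndarray,
                         target_sum: float = DEFAULT_TARGET_SUM) -> np.ndarray:
    """Scale each column (sample) so it sums to ``target_sum`` exactly."""
    if target_sum <= 0:
        raise InvalidParameter("target_sum must be positive")
    values = np.asarray(values, dtype=float)
    sums = values.sum(axis=0)
    if np.any(sums <= 0):
        bad = int(np.argmax(sums <= 0))
        raise DegenerateSample(
            f"sample at column {bad} has nonpositive sum over signature genes"
        )
    return values * (target_sum / sums)


def featurize(expr: ExpressionMatrix, registry: SignatureRegistry,
              target_sum: float = DEFAULT_TARGET_SUM,
              min_fraction: float = 0.5) -> SignatureScoreMatrix:
    """Sample x signature features from the rescaled signature-gene subset.

    Only genes in the signature union influence the output, so features are
    identical whether a sample is scored alone or within a larger matrix.
    """
    union = {normalize_gene(g) for g in registry.gene_union()}
    rows = [i for i, g in enumerate(expr.gene_ids)
            if normalize_gene(g) in union]
    if not rows:
        raise EmptyInput("no signature gene present in the expression matrix")
    sub = ExpressionMatrix(
        [expr.gene_ids[i] for i in rows],
        list(expr.sample_ids),
        rescale_constant_sum(expr.values[rows], target_sum),
        transform="precomputed",
    )
    return score_all(sub, registry, aggregator="median",
                     min_fraction=min_fraction)


@dataclass
class SVMBundle:
    """A trained model plus everything needed to reproduce its predictions."""

    gene_list: list[str]
    target_sum: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    feature_names: list[str]
    classes: list[str]
    svm: SVC
    seed: int
    split_fraction: float
    training_mcc: float

    # SVC attributes required to rebuild libsvm prediction state
    _SVC_STATE = (
        "support_", "support_vectors_", "_n_support", "_dual_coef_",
        "_intercept_", "_probA", "_probB", "classes_", "_gamma",
        "fit_status_", "shape_fit_", "class_weight_", "n_features_in_",
        "_sparse",
    )

    def save(self, path: str | Path) -> None:
        state = {}
        for name in self._SVC_STATE:
            val = getattr(self.svm, name)
            if isinstance(val, np.ndarray):
                state[name] = {"array": val.tolist(), "dtype": str(val.dtype)}
            elif isinstance(val, tuple):
                state[name] = {"tuple": list(val)}
            elif isinstance(val, (np.floating, np.integer)):
                state[name] = val.item()
            else:
                state[name] = val
        payload = {
            "format": "clearseq-svm-bundle-v1",
            "gene_list": self.gene_list,
            "target_sum": self.target_sum,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "feature_names": self.feature_names,
            "classes": self.classes,
            "svm_params": {
                k: v for k, v in self.svm.get_params().items()
                if isinstance(v, (str, int, float, bool, type(None)))
            },
            "svm_state": state,
            "seed": self.seed,
            "split_fraction": self.split_fraction,
            "training_mcc": self.training_mcc,
        }
        try:
            Path(path).write_text(json.dumps(payload, indent=1))
        except OSError as exc:
            raise IOFailure(f"cannot write {path}: {exc}") from exc

    @classmethod
    def load(cls, path: str | Path) -> "SVMBundle":
        try:
            payload = json.loads(Path(path).read_text())
        except OSError as exc:
            raise IOFailure(f"cannot read {path}: {exc}") from exc
        if payload.get("format") != "clearseq-svm-bundle-v1":
            raise InvalidParameter(f"{path} is not a clearseq SVM bundle")
        svm = SVC(**payload["svm_params"])
        for name, val in payload["svm_state"].items():
            if isinstance(val, dict) and "array" in val:
                setattr(svm, name, np.asarray(val["array"], dtype=val["dtype"]))
            elif isinstance(val, dict) and "tuple" in val:
                setattr(svm, name, tuple(val["tuple"]))
            else:
                setattr(svm, name, val)
        return cls(
            gene_list=payload["gene_list"],
            target_sum=payload["target_sum"],
            scaler_mean=np.asarray(payload["scaler_mean"], dtype=float),
            scaler_scale=np.asarray(payload["scaler_scale"], dtype=float),
            feature_names=payload["feature_names"],
            classes=payload["classes"],
            svm=svm,
            seed=payload["seed"],
            split_fraction=payload["split_fraction"],
            training_mcc=payload["training_mcc"],
        )


def mcc_multiclass(labels_true: Sequence[str], labels_pred: Sequence[str]) -> float:
    """Multiclass Matthews correlation coefficient (covariance form).

    Computed from the full K x K confusion matrix; reduces to the familiar
    binary formula at K = 2. Returns 0.0 with a ``DegenerateMccWarning``
    when either margin is concentrated in a single class (zero denominator).
    """
    if len(labels_true) != len(labels_pred):
        raise SampleMismatch("label vectors differ in length")
    if len(labels_true) == 0:
        raise EmptyInput("MCC of empty label vectors")
    classes = sorted({*labels_true, *labels_pred})
    idx = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    cm = np.zeros((k, k), dtype=float)
    for t, p in zip(labels_true, labels_pred):
        cm[idx[t], idx[p]] += 1
    n = cm.sum()
    t_row = cm.sum(axis=1)   # true-class totals
    p_col = cm.sum(axis=0)   # predicted-class totals
    cov_tp = np.trace(cm) * n - t_row @ p_col
    cov_tt = n**2 - t_row @ t_row
    cov_pp = n**2 - p_col @ p_col
    denom = np.sqrt(cov_tt * cov_pp)
    if denom == 0:
        warnings.warn(
            "degenerate confusion matrix (single-class margin); MCC set to 0",
            DegenerateMccWarning,
            stacklevel=2,
        )
        return 0.0
    return float(cov_tp / denom)


class DegenerateMccWarning(UserWarning):
    """All labels fall in one class; the MCC denominator is zero."""


def _stratified_split(labels: np.ndarray, split_fraction: float,
                      seed: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, train_size=split_fraction, random_state=seed, stratify=labels
    )
    return train_idx, test_idx


def train(features: SignatureScoreMatrix, labels: Sequence[str],
          split_fraction: float = 0.8, seed: int = 0,
          C: float = 1.0, kernel: str = "linear") -> tuple[SVMBundle, float]:
    """Train the SVM on a stratified split; returns (bundle, held-out MCC)."""
    labels = np.asarray([str(x) for x in labels])
    if len(labels) != features.n_samples:
        raise SampleMismatch("labels length does not match feature matrix")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise DegenerateSplit("training needs at least 2 classes")
    if counts.min() < 2:
        thin = classes[counts < 2].tolist()
        raise DegenerateSplit(f"classes with < 2 samples: {thin}")
    if not 0 < split_fraction < 1:
        raise InvalidParameter("split_fraction must be in (0, 1)")

    x = features.scores
    train_idx, test_idx = _stratified_split(labels, split_fraction, seed)
    if len(set(labels[train_idx])) < len(classes):
        raise DegenerateSplit("a class is absent from the training partition")

    mean = x[train_idx].mean(axis=0)
    scale = x[train_idx].std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    xs = (x - mean) / scale

    svm = SVC(
        kernel=kernel, C=C, probability=True, class_weight="balanced",
        random_state=seed, decision_function_shape="ovr",
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning)
        svm.fit(xs[train_idx], labels[train_idx])

    pred_train = svm.predict(xs[train_idx])
    training_mcc = mcc_multiclass(labels[train_idx].tolist(), pred_train.tolist())
    pred_test = svm.predict(xs[test_idx])
    heldout_mcc = mcc_multiclass(labels[test_idx].tolist(), pred_test.tolist())

    bundle = SVMBundle(
        gene_list=[],  # filled by train_from_expression; featurized training
        target_sum=DEFAULT_TARGET_SUM,
        scaler_mean=mean,
        scaler_scale=scale,
        feature_names=list(features.signature_names),
        classes=[str(c) for c in svm.classes_],
        svm=svm,
        seed=seed,
        split_fraction=split_fraction,
        training_mcc=training_mcc,
    )
    return bundle, heldout_mcc


def train_from_expression(expr: ExpressionMatrix, registry: SignatureRegistry,
                          labels: Sequence[str], split_fraction: float = 0.8,
                          seed: int = 0,
                          target_sum: float = DEFAULT_TARGET_SUM,
                          **svm_kwargs) -> tuple[SVMBundle, float]:
    """Featurize an expression matrix, then train; records the gene list."""
    features = featurize(expr, registry, target_sum)
    bundle, heldout = train(features, labels, split_fraction, seed, **svm_kwargs)
    bundle.gene_list = registry.gene_union()
    bundle.target_sum = target_sum
    return bundle, heldout


def predict_features(bundle: SVMBundle,
                     features: SignatureScoreMatrix) -> list[SubtypeCall]:
    """Predict from precomputed features; confidences sum to 1 per sample."""
    if list(features.signature_names)[: len(bundle.feature_names)] != bundle.feature_names:
        raise InvalidParameter("feature columns do not match the trained bundle")
    x = features.scores[:, : len(bundle.feature_names)]
    xs = (x - bundle.scaler_mean) / bundle.scaler_scale
    proba = bundle.svm.predict_proba(xs)
    order = [list(bundle.svm.classes_).index(c) for c in bundle.classes]
    calls = []
    for i, sid in enumerate(features.sample_ids):
        conf = {c: float(proba[i, j]) for c, j in zip(bundle.classes, order)}
        label = max(conf, key=conf.get)
        calls.append(
            SubtypeCall(
                sample_id=str(sid),
                label=label,
                rule_trace="svm: " + " ".join(
                    f"{c}={conf[c]:.4f}" for c in bundle.classes
                ),
                statistics=conf,
            )
        )
    return calls


def predict(bundle: SVMBundle, expr: ExpressionMatrix,
            registry: SignatureRegistry) -> list[SubtypeCall]:
    """Featurize and predict; valid for a single sample."""
    features = featurize(expr, registry, bundle.target_sum)
    return predict_features(bundle, features)
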