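"""Cancer-vs-normal screening: feature panels, split, training and metrics.

The diagnostic feature space is the de-duplicated union of the stage-salient
genes, the top linear-model genes and the genes that are both linear-top and
monotonically expressed; a fixed seven-gene consensus panel is shipped as
default configuration for the classifier. Metrics follow the standard
confusion-matrix formulas, reported as percentages to two decimals, with
undefined ratios reported as NaN rather than zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .datatypes import AnnotatedExpression, OncostageError

#: Consensus seven-gene diagnostic panel (default classifier configuration).
CONSENSUS_PANEL: tuple[str, ...] = (
    "ESM1", "DHRS7C", "OTOP3", "AADACL2", "LPHN3", "GABRD", "LPAR1",
)

_MODEL_KINDS = ("rf", "svm", "nnet1", "nnet2")


@dataclass(frozen=True)
class FeaturePanel:
    """Ordered gene list with a provenance tag per gene."""

    genes: tuple[str, ...]
    provenance: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise OncostageError("feature panel contains duplicate genes")
        if len(self.genes) == 0:
            raise OncostageError("empty feature panel")

    def __len__(self) -> int:
        return len(self.genes)


def consensus_panel() -> FeaturePanel:
    """The default seven-gene diagnostic panel."""
    return FeaturePanel(
        genes=CONSENSUS_PANEL,
        provenance={g: "consensus7" for g in CONSENSUS_PANEL},
    )


def assemble_feature_space(
    salient_genes, linear_top_genes, linear_monotone_genes
) -> FeaturePanel:
    """De-duplicated union of the three biomarker classes, with provenance.

    Order: stage-salient genes first, then top linear-model genes, then the
    linear-and-monotone genes; the first occurrence fixes the provenance tag.
    """
    genes: list[str] = []
    prov: dict[str, str] = {}
    for tag, group in (
        ("stage_salient", salient_genes),
        ("linear_top10", linear_top_genes),
        ("linear_and_monotone", linear_monotone_genes),
    ):
        for g in group:
            if g not in prov:
                prov[g] = tag
                genes.append(g)
    if not genes:
        raise OncostageError("feature space is empty")
    return FeaturePanel(genes=tuple(genes), provenance=prov)


# ---------------------------------------------------------------------------
# data split and training
# ---------------------------------------------------------------------------

def feature_matrix(
    ds: AnnotatedExpression, panel: FeaturePanel
) -> tuple[pd.DataFrame, pd.Series]:
    """Samples x panel-genes matrix and the tumor/control label vector."""
    missing = [g for g in panel.genes if g not in ds.gene_ids]
    if missing:
        raise OncostageError(f"panel genes missing from dataset: {missing[:5]}")
    X = ds.values.loc[list(panel.genes)].T
    y = ds.sample_class.reindex(X.index)
    return X, y


def split_stratified(
    X: pd.DataFrame, y: pd.Series, test_fraction: float = 0.2, seed: int = 42
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Class-stratified train/test split, deterministic under the seed."""
    counts = y.value_counts()
    if len(counts) < 2:
        raise OncostageError("both classes must be present for a stratified split")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise OncostageError(f"classes with fewer than 2 samples: {small}")
    return train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed
    )


@dataclass
class FittedClassifier:
    """A trained screening model plus the metadata needed to reuse it."""

    estimator: object
    panel: FeaturePanel
    kind: str
    seed: int
    positive_class: str = "tumor"

    def predict_with_confidence(self, sample) -> tuple[str, float]:
        """Predicted class and the model probability for that class.

        ``sample`` is a mapping/Series of gene -> expression covering every
        panel gene; in the binary setting the reported probability is at
        least 0.5.
        """
        if isinstance(sample, pd.DataFrame):
            row = sample.iloc[0]
        else:
            row = pd.Series(dict(sample)) if not isinstance(sample, pd.Series) else sample
        missing = [g for g in self.panel.genes if g not in row.index]
        if missing:
            raise OncostageError(f"missing panel feature(s): {missing}")
        x = row[list(self.panel.genes)].to_numpy(dtype=float).reshape(1, -1)
        proba = self.estimator.predict_proba(x)[0]
        classes = list(self.estimator.classes_)
        i = int(np.argmax(proba))
        return classes[i], float(proba[i])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(X[list(self.panel.genes)].to_numpy(dtype=float))

    def sidecar(self) -> dict:
        """JSON-serialisable description of the fitted model."""
        return {
            "kind": self.kind,
            "seed": self.seed,
            "panel": list(self.panel.genes),
            "provenance": dict(self.panel.provenance),
            "positive_class": self.positive_class,
        }

    def save_sidecar(self, path) -> None:
        Path(path).write_text(json.dumps(self.sidecar(), indent=2))


def _make_estimator(kind: str, seed: int, hyperparams: dict | None):
    hp = dict(hyperparams or {})
    if kind == "rf":
        return RandomForestClassifier(
            n_estimators=int(hp.pop("ntree", 500)),
            max_features=hp.pop("mtry", "sqrt"),
            random_state=seed,
            **hp,
        )
    if kind == "svm":
        return SVC(
            kernel="rbf",
            C=float(hp.pop("cost", 0.5)),
            gamma=float(hp.pop("gamma", 0.1)),
            probability=True,
            random_state=seed,
            **hp,
        )
    if kind == "nnet1":
        return MLPClassifier(
            hidden_layer_sizes=(int(hp.pop("size", 1)),),
            alpha=float(hp.pop("decay", 1.0)),
            max_iter=int(hp.pop("max_iter", 3000)),
            random_state=seed,
            **hp,
        )
    if kind == "nnet2":
        return MLPClassifier(
            hidden_layer_sizes=tuple(hp.pop("sizes", (4, 1))),
            max_iter=int(hp.pop("max_iter", 3000)),
            random_state=seed,
            **hp,
        )
    raise OncostageError(f"unknown model kind {kind!r}; supported: {_MODEL_KINDS}")


def train_classifier(
    train_X: pd.DataFrame,
    train_y: pd.Series,
    panel: FeaturePanel,
    kind: str = "rf",
    seed: int = 42,
    hyperparams: dict | None = None,
) -> FittedClassifier:
    """Train a screening classifier on the panel features.

    Supported kinds: ``rf`` (random forest, 500 trees, mtry ~ sqrt(p)),
    ``svm`` (radial kernel, cost 0.5, gamma 0.1), ``nnet1``/``nnet2``
    (1- and 2-layer networks). Deterministic under the seed.
    """
    missing = [g for g in panel.genes if g not in train_X.columns]
    if missing:
        raise OncostageError(f"panel genes missing from training data: {missing[:5]}")
    est = _make_estimator(kind, seed, hyperparams)
    est.fit(train_X[list(panel.genes)].to_numpy(dtype=float), train_y.to_numpy())
    return FittedClassifier(estimator=est, panel=panel, kind=kind, seed=seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierMetrics:
    """Confusion counts plus the derived percentage metrics (2 decimals).

    Undefined ratios (zero denominators) are NaN, never zero. Balanced
    accuracy is the mean of sensitivity and specificity.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    balanced_accuracy: float
    mcc: float

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "f1": self.f1,
            "balanced_accuracy": self.balanced_accuracy, "mcc": self.mcc,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(tp: int, fp: int, fn: int, tn: int) -> ClassifierMetrics:
    """Standard confusion-matrix metrics as percentages to two decimals."""
    for name, v in (("TP", tp), ("FP", fp), ("FN", fn), ("TN", tn)):
        if v < 0:
            raise OncostageError(f"negative count {name}={v}")
    if tp + fp + fn + tn == 0:
        raise OncostageError("empty confusion matrix")
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn)
    bal = (sens + spec) / 2.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else math.nan
    pct = lambda x: round(100.0 * x, 2) if not math.isnan(x) else math.nan
    return ClassifierMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=pct(sens), specificity=pct(spec), precision=pct(prec),
        f1=pct(f1), balanced_accuracy=pct(bal), mcc=pct(mcc),
    )


def evaluate_classifier(
    fitted: FittedClassifier, X: pd.DataFrame, y: pd.Series
) -> ClassifierMetrics:
    """Confusion-matrix metrics of the fitted model on labelled data."""
    pred = fitted.predict(X)
    pos = fitted.positive_class
    actual_pos = (y == pos).to_numpy()
    pred_pos = pred == pos
    tp = int((actual_pos & pred_pos).sum())
    fp = int((~actual_pos & pred_pos).sum())
    fn = int((actual_pos & ~pred_pos).sum())
    tn = int((~actual_pos & ~pred_pos).sum())
    return compute_metrics(tp, fp, fn, tn)
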