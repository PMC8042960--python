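"""Random-forest MSI classifier over marker peak vectors.

Each sample is a vector of peak values aligned to a fixed, ordered
marker list.  A random forest is trained on labelled MSI-H/MSS samples;
at prediction time the forest's MSI-H class probability is the sample's
*score*, and the call is MSI-H when score >= threshold (default 0.6,
inclusive), MSS otherwise.  Forest hyperparameters default to 500 trees
with sqrt-of-features splits, which keeps class-probability estimates
stable at panel-scale feature counts (tens of markers).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
import sklearn
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from . import __version__
from .errors import InputError, ModelFormatError
from .markers import MSI_H, MSS

DEFAULT_THRESHOLD = 0.6
DEFAULT_N_TREES = 500
DEFAULT_SEED = 42

MODEL_FORMAT_VERSION = 1


@dataclass
class FeatureMatrix:
    """Samples x ordered markers peak matrix, optionally labelled."""

    markers: list[str]
    X: pd.DataFrame                      # rows: sample_id, columns == markers
    labels: pd.Series | None = None      # sample_id -> MSI-H | MSS

    def __post_init__(self):
        if list(self.X.columns) != list(self.markers):
            raise InputError("matrix columns must equal the ordered marker list")
        if self.labels is not None:
            missing = set(self.X.index) - set(self.labels.index)
            if missing:
                raise InputError(f"samples without labels: {sorted(missing)[:5]}")
            self.labels = self.labels.loc[self.X.index]


@dataclass
class ModelBundle:
    """Trained forest plus everything needed to reapply it."""

    forest: RandomForestClassifier
    markers: list[str]
    threshold: float = DEFAULT_THRESHOLD
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PredictionResult:
    sample_id: str
    score: float
    call: str


def build_feature_matrix(
    peak_vectors: dict[str, dict[str, float]],
    markers: list[str],
    labels: pd.Series | None = None,
) -> FeatureMatrix:
    """Align per-sample site->peak maps to the marker order.

    A marker a sample has no value for (typically an uncovered locus)
    is imputed as peak 0 with a warning; a sample missing more than
    half the markers is refused as uninterpretable.
    """
    if not markers:
        raise InputError("marker list is empty")
    rows = {}
    for sample_id, vec in peak_vectors.items():
        missing = [m for m in markers if m not in vec]
        if len(missing) * 2 > len(markers):
            raise InputError(
                f"sample {sample_id}: {len(missing)}/{len(markers)} markers "
                "missing; refusing to impute a majority of the features"
            )
        if missing:
            warnings.warn(
                f"sample {sample_id}: {len(missing)} markers without coverage "
                "imputed as peak 0",
                stacklevel=2,
            )
        rows[sample_id] = [float(vec.get(m, 0)) for m in markers]
    X = pd.DataFrame.from_dict(rows, orient="index", columns=markers)
    return FeatureMatrix(markers=list(markers), X=X, labels=labels)


def call_from_score(score: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """MSI-H when score >= threshold (inclusive), MSS otherwise."""
    return MSI_H if score >= threshold else MSS


def train(
    matrix: FeatureMatrix,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = DEFAULT_SEED,
    threshold: float = DEFAULT_THRESHOLD,
    max_depth: int | None = None,
) -> ModelBundle:
    """Fit the forest on a labelled matrix; deterministic under ``seed``."""
    if matrix.labels is None:
        raise InputError("training requires a labelled matrix")
    if n_trees < 1:
        raise InputError("n_trees must be >= 1")
    classes = set(matrix.labels.unique())
    if classes != {MSI_H, MSS}:
        raise InputError(f"training needs both MSI-H and MSS samples, got {sorted(classes)}")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(matrix.X.to_numpy(), matrix.labels.to_numpy())
    metadata = {
        "format_version": MODEL_FORMAT_VERSION,
        "msipeaks_version": __version__,
        "sklearn_version": sklearn.__version__,
        "n_trees": n_trees,
        "seed": seed,
        "n_training_samples": int(matrix.X.shape[0]),
    }
    return ModelBundle(
        forest=forest, markers=list(matrix.markers),
        threshold=threshold, metadata=metadata,
    )


def predict(bundle: ModelBundle, matrix: FeatureMatrix) -> list[PredictionResult]:
    """Score samples with the bundled forest and call by threshold."""
    missing = sorted(set(bundle.markers) - set(matrix.markers))
    extra = sorted(set(matrix.markers) - set(bundle.markers))
    if missing or extra:
        raise InputError(
            f"marker mismatch with model: missing {missing or 'none'}, "
            f"extra {extra or 'none'}"
        )
    X = matrix.X.loc[:, bundle.markers].to_numpy()
    msih_col = list(bundle.forest.classes_).index(MSI_H)
    scores = bundle.forest.predict_proba(X)[:, msih_col]
    return [
        PredictionResult(
            sample_id=str(sid), score=float(s),
            call=call_from_score(float(s), bundle.threshold),
        )
        for sid, s in zip(matrix.X.index, scores)
    ]


def evaluate(
    predictions: list[PredictionResult], truth: pd.Series
) -> dict[str, float]:
    """Confusion-matrix metrics with MSI-H as the positive class.

    Ratios with a zero denominator come back as NaN, never as 0.  AUC
    is the rank statistic over scores (NaN when only one class is
    present in the truth labels).
    """
    missing = [p.sample_id for p in predictions if p.sample_id not in truth.index]
    if missing:
        raise InputError(f"truth labels missing for {missing[:5]}")
    tp = fp = tn = fn = 0
    for p in predictions:
        is_pos = truth.loc[p.sample_id] == MSI_H
        called_pos = p.call == MSI_H
        if called_pos and is_pos:
            tp += 1
        elif called_pos:
            fp += 1
        elif is_pos:
            fn += 1
        else:
            tn += 1

    def ratio(num, den):
        return num / den if den else math.nan

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    acc = ratio(tp + tn, tp + fp + tn + fn)
    f1 = (
        2 * ppv * sens / (ppv + sens)
        if not (math.isnan(ppv) or math.isnan(sens)) and (ppv + sens) > 0
        else math.nan
    )
    y = np.array([1 if truth.loc[p.sample_id] == MSI_H else 0 for p in predictions])
    scores = np.array([p.score for p in predictions])
    auc = float(roc_auc_score(y, scores)) if len(set(y)) == 2 else math.nan
    return {
        "sensitivity": sens, "specificity": spec, "accuracy": acc,
        "ppv": ppv, "f1": f1, "auc": auc,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }


def save_model(bundle: ModelBundle, path: str) -> None:
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "forest": bundle.forest,
            "markers": bundle.markers,
            "threshold": bundle.threshold,
            "metadata": bundle.metadata,
        },
        path,
    )


def load_model(path: str) -> ModelBundle:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # joblib raises a zoo of unpickling errors
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFormatError(f"{path} is not a msipeaks model bundle")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: format version {payload['format_version']} unsupported "
            f"(expected {MODEL_FORMAT_VERSION}); metadata: {payload.get('metadata')}"
        )
    return ModelBundle(
        forest=payload["forest"],
        markers=payload["markers"],
        threshold=payload["threshold"],
        metadata=payload["metadata"],
    )


def write_predictions(predictions: list[PredictionResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tscore\tcall\n")
        for p in predictions:
            fh.write(f"{p.sample_id}\t{p.score!r}\t{p.call}\n")


def read_predictions(path: str) -> list[PredictionResult]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "sample_id\t")):
                continue
            sid, score, call = line.split("\t")
            out.append(PredictionResult(sample_id=sid, score=float(score), call=call))
    return out
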