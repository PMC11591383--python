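"""Early feature fusion, the SVM classification protocol, and metrics.

Deep spectrogram features (FC1/FC2 taps per spectrogram kind) and selected
acoustic features are concatenated column-wise into one fused matrix (early
fusion), standardized with statistics fitted on the training split only,
and classified by an SVM tuned by grid search (kernels {linear, rbf} x
C in {0.1, 1, 10}) with stratified 5-fold cross-validation on weighted F1.
Evaluation reports per-class confusion counts and, per class,

    Accuracy  = (TP + TN) / (TP + TN + FP + FN)
    Recall    = TP / (TP + FN)
    Precision = TP / (TP + FP)
    F1        = 2 P R / (P + R)

with support-weighted averages expressed in percent.  On a full-coverage
multiclass evaluation the overall accuracy equals the weighted recall,
which is why published tables of this protocol show identical accuracy and
recall columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .acoustic_features import FEATURE_NAMES, Standardizer, feature_matrix
from .audio_io import LABELS, AudioSegment
from .deep_model import SheepVGGLite, TrainConfig, build_model, extract_deep_features, train
from .feature_selection import svm_rfecv
from .spectrograms import render_image, transform

KNOWN_BLOCKS = (
    "MEL_FC1", "MEL_FC2", "STFT_FC1", "STFT_FC2", "CQT_FC1", "CQT_FC2", "ACOUSTIC",
)


@dataclass
class FusedFeatureMatrix:
    values: np.ndarray  # (n, D)
    block_names: list[str]
    block_spans: dict[str, tuple[int, int]]  # name -> [start, stop) column span


@dataclass
class SVMConfig:
    kernels: tuple[str, ...] = ("linear", "rbf")
    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    gamma: str | float = "auto"  # "auto" = 1 / n_features
    cv_folds: int = 5
    seed: int = 0


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN per class; per class TP+TN+FP+FN = n."""

    classes: tuple[str, ...]
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    matrix: np.ndarray  # rows = true class, cols = predicted class


@dataclass
class ClassificationReport:
    accuracy: float  # overall accuracy, % (== weighted recall)
    recall: float
    precision: float
    f1: float
    per_class: dict[str, dict[str, float]]
    confusion: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "per_class": self.per_class,
            "class_order": list(self.confusion.classes),
            "confusion_matrix": self.confusion.matrix.tolist(),
        }


def early_fuse(blocks: Sequence[tuple[str, np.ndarray]]) -> FusedFeatureMatrix:
    """Column-wise concatenation of per-segment feature blocks.

    All blocks must agree on row count and row order (row i of every block
    describes the same segment).
    """
    if not blocks:
        raise ValueError("early_fuse requires at least one block")
    n = blocks[0][1].shape[0]
    spans: dict[str, tuple[int, int]] = {}
    mats = []
    col = 0
    for name, mat in blocks:
        mat = np.asarray(mat, dtype=np.float64)
        if mat.ndim != 2 or mat.shape[0] != n:
            raise ValueError(f"block {name!r} has shape {mat.shape}; expected ({n}, d)")
        spans[name] = (col, col + mat.shape[1])
        col += mat.shape[1]
        mats.append(mat)
    return FusedFeatureMatrix(
        values=np.hstack(mats), block_names=[b[0] for b in blocks], block_spans=spans
    )


def split_train_test(
    X: np.ndarray, y: np.ndarray, test_fraction: float = 0.2, seed: int = 0
):
    """Stratified disjoint 80/20 split (per-class counts within +/-1)."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members to stratify the split")
    idx_tr, idx_te = train_test_split(
        np.arange(y.size), test_size=test_fraction, stratify=y, random_state=seed
    )
    return (X[idx_tr], y[idx_tr], idx_tr), (X[idx_te], y[idx_te], idx_te)


def grid_search_svm(X: np.ndarray, y: np.ndarray, config: SVMConfig = SVMConfig()):
    """Grid-search an SVC over kernels x C, stratified 5-fold weighted F1.

    Returns the refitted best model, its hyperparameters, and the CV table
    (one row per grid point).
    """
    grid = {"kernel": list(config.kernels), "C": list(config.C_grid)}
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    search = GridSearchCV(
        SVC(gamma=config.gamma, random_state=config.seed),
        grid,
        scoring="f1_weighted",
        cv=cv,
        refit=True,
    )
    search.fit(X, y)
    table = [
        {
            "kernel": params["kernel"],
            "C": params["C"],
            "mean_cv_f1": float(score),
        }
        for params, score in zip(search.cv_results_["params"], search.cv_results_["mean_test_score"])
    ]
    best = {"kernel": search.best_params_["kernel"], "C": search.best_params_["C"]}
    return search.best_estimator_, best, table


def fixed_svm(config: SVMConfig = SVMConfig()) -> SVC:
    """The non-grid-searched setting: RBF kernel, C = 1, gamma 'auto'."""
    return SVC(kernel="rbf", C=1.0, gamma=config.gamma, random_state=config.seed)


def confusion_counts(
    predictions: Sequence[str], labels: Sequence[str], classes: tuple[str, ...] = LABELS
) -> ConfusionCounts:
    predictions = list(predictions)
    labels = list(labels)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    try:
        p_idx = np.array([index[p] for p in predictions])
        t_idx = np.array([index[t] for t in labels])
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}; classes: {classes}") from exc
    k = len(classes)
    matrix = np.zeros((k, k), dtype=np.int64)
    np.add.at(matrix, (t_idx, p_idx), 1)
    tp = np.diag(matrix).astype(np.int64)
    fp = matrix.sum(axis=0) - tp
    fn = matrix.sum(axis=1) - tp
    tn = matrix.sum() - tp - fp - fn
    return ConfusionCounts(classes=tuple(classes), tp=tp, tn=tn, fp=fp, fn=fn, matrix=matrix)


def _safe_ratio(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros(num.shape, dtype=np.float64)
    bad = den == 0
    np.divide(num, den, out=out, where=~bad)
    if np.any(bad):
        warnings.warn(f"zero denominator in {what}; reporting 0 by convention")
    return out


def evaluate(
    predictions: Sequence[str], labels: Sequence[str], classes: tuple[str, ...] = LABELS
) -> ClassificationReport:
    """Confusion-count metrics with support-weighted averages in percent."""
    cc = confusion_counts(predictions, labels, classes)
    n = cc.matrix.sum()
    support = cc.matrix.sum(axis=1)
    recall = _safe_ratio(cc.tp, cc.tp + cc.fn, "recall")
    precision = _safe_ratio(cc.tp, cc.tp + cc.fp, "precision")
    f1 = _safe_ratio(2 * precision * recall, precision + recall, "f1")
    class_acc = (cc.tp + cc.tn) / n
    w = support / n
    per_class = {
        c: {
            "accuracy": float(100 * class_acc[i]),
            "recall": float(100 * recall[i]),
            "precision": float(100 * precision[i]),
            "f1": float(100 * f1[i]),
            "support": int(support[i]),
        }
        for i, c in enumerate(cc.classes)
    }
    return ClassificationReport(
        accuracy=float(100 * cc.tp.sum() / n),
        recall=float(100 * (w * recall).sum()),
        precision=float(100 * (w * precision).sum()),
        f1=float(100 * (w * f1).sum()),
        per_class=per_class,
        confusion=cc,
    )


# ------------------------------------------------------------ pipeline


def parse_recipe(recipe: str) -> list[str]:
    blocks = [b.strip().upper() for b in recipe.split("+")]
    unknown = [b for b in blocks if b not in KNOWN_BLOCKS]
    if unknown:
        raise ValueError(f"unknown blocks {unknown}; valid blocks: {KNOWN_BLOCKS}")
    return blocks


@dataclass
class ExperimentResult:
    recipe: str
    seed: int
    report: ClassificationReport
    svm_params: dict
    block_spans: dict[str, tuple[int, int]]
    selection: Optional[dict] = None
    histories: dict[str, list[dict]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "recipe": self.recipe,
            "seed": self.seed,
            "svm_params": self.svm_params,
            "block_spans": {k: list(v) for k, v in self.block_spans.items()},
            "report": self.report.to_dict(),
            "selection": self.selection,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


class FusionPipeline:
    """Trains per-spectrogram CNNs once and evaluates fusion recipes.

    Holding the trained extractors lets several recipes (single blocks and
    their fusions) be scored against the same split without re-training,
    which is also how the fusion-versus-single comparison is made
    seed-for-seed fair.
    """

    def __init__(
        self,
        segments: list[AudioSegment],
        seed: int = 0,
        test_fraction: float = 0.2,
        train_config: Optional[TrainConfig] = None,
        use_grid: bool = True,
    ):
        if not segments or any(s.label is None for s in segments):
            raise ValueError("every corpus segment needs a label")
        self.segments = segments
        self.seed = seed
        self.use_grid = use_grid
        self.labels = np.array([s.label for s in segments])
        self.train_config = train_config or TrainConfig(seed=seed)
        (_, self.y_train, self.idx_train), (_, self.y_test, self.idx_test) = split_train_test(
            np.zeros((len(segments), 1)), self.labels, test_fraction, seed
        )
        self._deep: dict[str, np.ndarray] = {}
        self._acoustic: Optional[np.ndarray] = None
        self._selection: Optional[dict] = None
        self._selected_cols: Optional[np.ndarray] = None
        self.histories: dict[str, list[dict]] = {}
        self.models: dict[str, SheepVGGLite] = {}

    # -- feature providers ------------------------------------------

    def _images(self, kind: str) -> np.ndarray:
        return np.stack(
            [render_image(transform(s, kind)).pixels for s in self.segments]
        )

    def deep_block(self, name: str) -> np.ndarray:
        """n x d deep-feature block, training the CNN on first use."""
        if name not in self._deep:
            kind, layer = name.split("_")
            kind = kind.lower()
            images = self._images(kind)
            if kind not in self.models:
                model = build_model(seed=self.seed)
                model, hist = train(
                    model,
                    images[self.idx_train],
                    self.labels[self.idx_train],
                    self.train_config,
                )
                self.models[kind] = model
                self.histories[kind] = hist
            for lay in ("FC1", "FC2"):
                self._deep[f"{kind.upper()}_{lay}"] = extract_deep_features(
                    self.models[kind], images, lay
                ).values
        return self._deep[name]

    def acoustic_block(self) -> np.ndarray:
        """Selected acoustic columns (RFECV fitted on the training split)."""
        if self._acoustic is None:
            self._acoustic = feature_matrix(self.segments)
        if self._selected_cols is None:
            scaler = Standardizer().fit(self._acoustic[self.idx_train])
            sel = svm_rfecv(
                scaler.transform(self._acoustic[self.idx_train]),
                self.y_train,
                names=list(FEATURE_NAMES),
                seed=self.seed,
            )
            name_to_col = {nm: i for i, nm in enumerate(FEATURE_NAMES)}
            self._selected_cols = np.array([name_to_col[nm] for nm in sel.selected_names])
            self._selection = {
                "selected_names": sel.selected_names,
                "best_count": sel.best_count,
                "best_cv_f1": max(sel.cv_curve.values()),
            }
        return self._acoustic[:, self._selected_cols]

    # -- evaluation --------------------------------------------------

    def run(self, recipe: str) -> ExperimentResult:
        """Full protocol for one fusion recipe against the held-out test set."""
        block_names = parse_recipe(recipe)
        blocks = []
        for name in block_names:
            mat = self.acoustic_block() if name == "ACOUSTIC" else self.deep_block(name)
            blocks.append((name, mat))
        fused = early_fuse(blocks)
        scaler = Standardizer().fit(fused.values[self.idx_train])
        x_tr = scaler.transform(fused.values[self.idx_train])
        x_te = scaler.transform(fused.values[self.idx_test])
        cfg = SVMConfig(seed=self.seed)
        if self.use_grid:
            model, params, _ = grid_search_svm(x_tr, self.y_train, cfg)
        else:
            model = fixed_svm(cfg).fit(x_tr, self.y_train)
            params = {"kernel": "rbf", "C": 1.0}
        preds = model.predict(x_te)
        report = evaluate(list(preds), list(self.y_test))
        return ExperimentResult(
            recipe="+".join(block_names),
            seed=self.seed,
            report=report,
            svm_params=params,
            block_spans=fused.block_spans,
            selection=self._selection if "ACOUSTIC" in block_names else None,
            histories=self.histories,
        )


def run_experiment(
    segments: list[AudioSegment],
    recipe: str,
    seed: int = 0,
    test_fraction: float = 0.2,
    train_config: Optional[TrainConfig] = None,
    use_grid: bool = True,
) -> ExperimentResult:
    """One-shot pipeline: spectrograms -> CNN training -> deep features ->
    (optional) acoustic extraction + RFE selection -> early fusion ->
    train-fitted standardization -> grid-search SVM -> held-out evaluation."""
    pipe = FusionPipeline(segments, seed, test_fraction, train_config, use_grid)
    return pipe.run(recipe)
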