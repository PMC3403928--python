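"""Support-vector scoring of marker subsets.

A *marker set* is a subset of the heterogeneous parameters.  Its predictive
power is quantified by training a kernel support-vector machine restricted
to those parameters — a soft-margin classifier for the fate label, an
epsilon-insensitive regressor for the event time — and scoring it on a
held-out sample.  Good markers yield high true-positive / low
false-positive rates (equivalently a large area under the ROC curve) or
small relative prediction errors; uninformative markers score at chance.

Defaults follow common practice for RBF support-vector machines on
log-normally distributed inputs: natural-log transform of the features,
RBF width ``gamma = 0.25``, penalty ``C = 1``, regression tube
``epsilon = 0.01``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.svm import SVC, SVR

from .functionals import PropertySample

__all__ = [
    "MarkerSet",
    "SVSettings",
    "FateClassifier",
    "TimingRegressor",
    "ClassificationReport",
    "RegressionReport",
    "train_classifier",
    "classification_rates",
    "roc_and_auc",
    "train_regressor",
    "regression_errors",
    "evaluate_combinations",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerSet:
    """An ordered subset of parameter columns, resolved to names."""

    indices: tuple[int, ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise ValueError("marker set must contain at least one parameter")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("marker indices must be unique")
        if len(self.indices) != len(self.names):
            raise ValueError("indices and names disagree in length")

    @classmethod
    def from_names(cls, names: Sequence[str], all_names: Sequence[str]) -> "MarkerSet":
        all_names = list(all_names)
        return cls(tuple(all_names.index(n) for n in names), tuple(names))

    @property
    def size(self) -> int:
        return len(self.indices)

    def label(self) -> str:
        return "+".join(self.names)


@dataclass(frozen=True)
class SVSettings:
    """Kernel and optimizer settings shared by classifier and regressor."""

    gamma: float = 0.25
    C: float = 1.0
    epsilon: float = 0.01
    log_transform: bool = True
    standardize: bool = False
    cache_size: float = 500.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.C <= 0:
            raise ValueError("gamma and C must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


class _FeatureMap:
    """Column selection + optional log transform / training-set z-scoring."""

    def __init__(self, markers: MarkerSet, settings: SVSettings):
        self.markers = markers
        self.settings = settings
        self.center: np.ndarray | None = None
        self.scale: np.ndarray | None = None

    def fit(self, parameters: np.ndarray) -> np.ndarray:
        x = self._base(parameters)
        if self.settings.standardize:
            self.center = x.mean(axis=0)
            self.scale = x.std(axis=0)
            self.scale = np.where(self.scale > 0, self.scale, 1.0)
            x = (x - self.center) / self.scale
        return x

    def transform(self, parameters: np.ndarray) -> np.ndarray:
        x = self._base(parameters)
        if self.settings.standardize:
            if self.center is None:
                raise RuntimeError("feature map not fitted")
            x = (x - self.center) / self.scale
        return x

    def _base(self, parameters: np.ndarray) -> np.ndarray:
        x = np.asarray(parameters, dtype=float)[:, list(self.markers.indices)]
        if self.settings.log_transform:
            if np.any(x <= 0):
                raise ValueError("log transform requires strictly positive features")
            x = np.log(x)
        return x


@dataclass
class FateClassifier:
    """A trained soft-margin kernel classifier for the fate label.

    ``decision_value`` exposes the signed distance to the separating
    hyperplane in feature space; the predicted label is its sign.
    """

    svc: SVC
    markers: MarkerSet
    settings: SVSettings
    feature_map: _FeatureMap

    def decision_value(self, parameters: np.ndarray) -> np.ndarray:
        scores = self.svc.decision_function(self.feature_map.transform(parameters))
        # orient scores so positive always means the +1 class
        return scores if self.svc.classes_[1] == 1 else -scores

    def predict(self, parameters: np.ndarray) -> np.ndarray:
        return np.where(self.decision_value(parameters) >= 0, 1, -1)


@dataclass
class TimingRegressor:
    """A trained epsilon-insensitive kernel regressor for the event time."""

    svr: SVR
    markers: MarkerSet
    settings: SVSettings
    feature_map: _FeatureMap

    def predict(self, parameters: np.ndarray) -> np.ndarray:
        return self.svr.predict(self.feature_map.transform(parameters))


@dataclass
class ClassificationReport:
    markers: MarkerSet
    tp_rate: float
    fp_rate: float
    roc: np.ndarray  # (k, 2) columns (fp, tp), fp nondecreasing
    auc: float
    n_train: int
    n_test: int
    seed: int | None = None


@dataclass
class RegressionReport:
    """Relative prediction errors on held-out rows plus quantile summaries.

    Signed errors ``(phi - phi_hat) / phi`` are retained; the headline
    summaries (median, quartiles, 10th/90th percentiles, mean) are computed
    on the magnitudes ``|e|``.
    """

    markers: MarkerSet
    errors: np.ndarray
    n_excluded: int = 0
    n_train: int = 0
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.abs(self.errors)
        if a.size:
            q = np.percentile(a, [10, 25, 50, 75, 90])
            self.summary = {
                "mean": float(a.mean()),
                "median": float(q[2]),
                "q25": float(q[1]),
                "q75": float(q[3]),
                "p10": float(q[0]),
                "p90": float(q[4]),
            }


def _check_delta(sample: PropertySample) -> None:
    if sample.kind != "delta":
        raise ValueError("expected a qualitative (delta) sample")
    present = np.unique(sample.labels)
    if present.size < 2:
        raise ValueError(
            f"sample contains a single class ({present.tolist()}); "
            "both classes are required"
        )


def train_classifier(
    train: PropertySample, markers: MarkerSet, settings: SVSettings = SVSettings()
) -> FateClassifier:
    """Fit the soft-margin RBF classifier on the marker columns of ``train``."""
    _check_delta(train)
    fmap = _FeatureMap(markers, settings)
    x = fmap.fit(train.parameters)
    balance = float((train.labels == 1).mean())
    logger.info(
        "training classifier on %s: n=%d, positive fraction %.3f",
        markers.label(), len(train), balance,
    )
    svc = SVC(
        kernel="rbf",
        gamma=settings.gamma,
        C=settings.C,
        cache_size=settings.cache_size,
    )
    svc.fit(x, train.labels)
    return FateClassifier(svc, markers, settings, fmap)


def classification_rates(
    clf: FateClassifier, test: PropertySample
) -> tuple[float, float]:
    """(true-positive, false-positive) rates at the native threshold.

    TP = fraction of +1 test rows predicted +1; FP = fraction of -1 test
    rows predicted +1.  Both classes must be present in the test sample.
    """
    _check_delta(test)
    pred = clf.predict(test.parameters)
    pos = test.labels == 1
    tp = float((pred[pos] == 1).mean())
    fp = float((pred[~pos] == 1).mean())
    return tp, fp


def roc_and_auc(
    clf: FateClassifier, test: PropertySample, n_train: int | None = None
) -> ClassificationReport:
    """Trace the ROC by sweeping a threshold on the decision value.

    The curve starts at (0,0), ends at (1,1), and the AUC is its
    trapezoidal area.
    """
    _check_delta(test)
    scores = clf.decision_value(test.parameters)
    fpr, tpr, _ = roc_curve(test.labels, scores, pos_label=1)
    roc = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    tp, fp = classification_rates(clf, test)
    return ClassificationReport(
        clf.markers, tp, fp, roc, auc,
        n_train=n_train if n_train is not None else int(clf.svc.shape_fit_[0]),
        n_test=len(test),
    )


def train_regressor(
    train: PropertySample, markers: MarkerSet, settings: SVSettings = SVSettings()
) -> TimingRegressor:
    """Fit the epsilon-insensitive RBF regressor on the marker columns."""
    if train.kind != "phi":
        raise ValueError("expected a quantitative (phi) sample")
    if len(train) < 2:
        raise ValueError("need at least 2 rows to train a regressor")
    fmap = _FeatureMap(markers, settings)
    x = fmap.fit(train.parameters)
    svr = SVR(
        kernel="rbf",
        gamma=settings.gamma,
        C=settings.C,
        epsilon=settings.epsilon,
        cache_size=settings.cache_size,
    )
    svr.fit(x, train.values)
    return TimingRegressor(svr, markers, settings, fmap)


def regression_errors(
    reg: TimingRegressor, test: PropertySample, n_train: int = 0
) -> RegressionReport:
    """Relative errors ``(phi - phi_hat)/phi`` on held-out rows.

    Rows with ``phi == 0`` cannot be scored relatively and are excluded
    with a logged count.
    """
    if test.kind != "phi":
        raise ValueError("expected a quantitative (phi) sample")
    phi = test.values
    ok = phi != 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("excluding %d rows with zero event time", n_excluded)
    pred = reg.predict(test.parameters[ok])
    errors = (phi[ok] - pred) / phi[ok]
    return RegressionReport(reg.markers, errors, n_excluded=n_excluded, n_train=n_train)


def evaluate_combinations(
    train_delta: PropertySample,
    test_delta: PropertySample,
    sizes: Sequence[int],
    settings: SVSettings = SVSettings(),
    train_phi: PropertySample | None = None,
    test_phi: PropertySample | None = None,
    extra_sets: Sequence[MarkerSet] = (),
    max_subsets: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score every marker subset of the requested sizes on one shared split.

    Each subset of each size in ``sizes`` (plus any ``extra_sets``) gets a
    classification row (TP/FP at the native threshold and trapezoidal AUC);
    when a quantitative train/test pair is supplied, relative-error
    quantiles are added.  Rows are sorted by AUC (descending), ties broken
    lexicographically by marker names.  Evaluating more than ``max_subsets``
    subsets is refused: exhaustive search over large parameter sets is
    exactly what visual pre-selection is meant to avoid.
    """
    names = train_delta.parameter_names
    q = len(names)
    marker_sets: list[MarkerSet] = []
    for size in sizes:
        if not 1 <= size <= q:
            raise ValueError(f"subset size {size} out of range 1..{q}")
        for combo in combinations(range(q), size):
            marker_sets.append(
                MarkerSet(combo, tuple(names[j] for j in combo))
            )
    marker_sets.extend(extra_sets)
    if len(marker_sets) > max_subsets:
        raise ValueError(
            f"{len(marker_sets)} subsets requested (limit {max_subsets}); "
            "pre-select candidate markers or raise max_subsets explicitly"
        )
    do_regression = train_phi is not None and test_phi is not None
    rows = []
    for m in marker_sets:
        clf = train_classifier(train_delta, m, settings)
        report = roc_and_auc(clf, test_delta, n_train=len(train_delta))
        row = {
            "markers": m.label(),
            "size": m.size,
            "tp": report.tp_rate,
            "fp": report.fp_rate,
            "auc": report.auc,
            "n_train": len(train_delta),
            "n_test": len(test_delta),
            "seed": seed,
        }
        if do_regression:
            reg = train_regressor(train_phi, m, settings)
            rep = regression_errors(reg, test_phi, n_train=len(train_phi))
            row.update(
                median_abs_rel_err=rep.summary["median"],
                q25=rep.summary["q25"],
                q75=rep.summary["q75"],
                p10=rep.summary["p10"],
                p90=rep.summary["p90"],
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["auc", "markers"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
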