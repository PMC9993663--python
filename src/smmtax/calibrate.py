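"""Logistic calibration of raw Markov-model scores into probabilities.

One model per (taxonomic rank, model order) pair maps the pair
(raw score, read length) to the probability that the implied taxon
assignment at that rank is correct. Fitting goes through scikit-learn's
LogisticRegression (liblinear, penalized MLE); prediction is a
self-contained closed-form sigmoid on standardized features, so a model
persisted to JSON needs nothing but this module to score.

Hyperparameters are searched sequentially (log-uniform C and tolerance,
L1/L2 penalty, intercept on/off) under threefold cross-validated
accuracy, then the winner is refit on all data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .seqio import RANKS
from .trainset import TrainingExample

JSON_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ScoreModel:
    """Fitted per-(rank, order) logistic calibration model."""

    rank: str
    order: int
    intercept: float
    coef_score: float
    coef_length: float
    standardize_score: tuple[float, float]  # (mean, sd)
    standardize_length: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.standardize_score[1] <= 0 or self.standardize_length[1] <= 0:
            raise ValueError("standardization sds must be positive")


def predict_probability(model: ScoreModel, raw_score: float, read_length: float) -> float:
    """P(correct assignment) = sigmoid of the standardized linear predictor."""
    zs = (raw_score - model.standardize_score[0]) / model.standardize_score[1]
    zl = (read_length - model.standardize_length[0]) / model.standardize_length[1]
    eta = model.intercept + model.coef_score * zs + model.coef_length * zl
    if eta >= 0:
        return 1.0 / (1.0 + math.exp(-eta))
    e = math.exp(eta)  # overflow-safe branch for very negative eta
    return e / (1.0 + e)


@dataclass(frozen=True)
class HyperparameterSpace:
    """Search box for the calibration fit."""

    c_range: tuple[float, float] = (1e-6, 1e5)
    tol_range: tuple[float, float] = (1e-7, 1e-2)
    penalties: tuple[str, ...] = ("l1", "l2")
    fit_intercept_options: tuple[bool, ...] = (True, False)
    max_iter: int = 15_000

    def __post_init__(self) -> None:
        for lo, hi in (self.c_range, self.tol_range):
            if not 0 < lo <= hi:
                raise ValueError("ranges must be positive and ordered")

    def sample(self, rng: np.random.Generator) -> dict:
        def log_uniform(lo: float, hi: float) -> float:
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

        return {
            "C": log_uniform(*self.c_range),
            "tol": log_uniform(*self.tol_range),
            "penalty": self.penalties[int(rng.integers(len(self.penalties)))],
            "fit_intercept": bool(
                self.fit_intercept_options[int(rng.integers(len(self.fit_intercept_options)))]
            ),
        }


def _l1_ratio(penalty: str) -> int:
    if penalty not in ("l1", "l2"):
        raise ValueError(f"penalty must be 'l1' or 'l2', got {penalty!r}")
    return 1 if penalty == "l1" else 0


def _features(examples: Sequence[TrainingExample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[e.raw_score, e.read_length] for e in examples], dtype=np.float64)
    y = np.array([e.label for e in examples], dtype=np.int64)
    return X, y


def _validate_xy(X: np.ndarray, y: np.ndarray) -> None:
    if not np.isfinite(X).all():
        raise ValueError("non-finite features")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both labels")
    if len(y) < 20:
        raise ValueError(f"need at least 20 examples, got {len(y)}")


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def fit_logistic(
    examples: Sequence[TrainingExample],
    penalty: str = "l2",
    C: float = 1.0,
    tol: float = 1e-4,
    fit_intercept: bool = True,
    max_iter: int = 15_000,
    rank: str | None = None,
    order: int | None = None,
    seed: int = 0,
) -> ScoreModel:
    """Penalized maximum-likelihood logistic fit on standardized features."""
    X, y = _features(examples)
    _validate_xy(X, y)
    Z, mean, sd = _standardize(X)
    clf = LogisticRegression(
        l1_ratio=_l1_ratio(penalty),
        C=C,
        tol=tol,
        fit_intercept=fit_intercept,
        max_iter=max_iter,
        solver="liblinear",
        random_state=seed,
    )
    clf.fit(Z, y)
    meta = {
        "seed": seed,
        "n": int(len(y)),
        "penalty": penalty,
        "C": C,
        "tol": tol,
        "fit_intercept": fit_intercept,
        "converged": int(clf.n_iter_[0]) < max_iter,
    }
    return ScoreModel(
        rank=rank or examples[0].rank,
        order=order if order is not None else examples[0].order,
        intercept=float(clf.intercept_[0]) if fit_intercept else 0.0,
        coef_score=float(clf.coef_[0][0]),
        coef_length=float(clf.coef_[0][1]),
        standardize_score=(float(mean[0]), float(sd[0])),
        standardize_length=(float(mean[1]), float(sd[1])),
        meta=meta,
    )


def _cv_accuracy(X: np.ndarray, y: np.ndarray, params: dict, max_iter: int, n_folds: int, seed: int) -> float:
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in kf.split(X):
        if len(np.unique(y[train_idx])) < 2:
            accs.append(float((y[test_idx] == np.bincount(y[train_idx]).argmax()).mean()))
            continue
        Z, mean, sd = _standardize(X[train_idx])
        clf = LogisticRegression(
            solver="liblinear",
            max_iter=max_iter,
            random_state=seed,
            C=params["C"],
            tol=params["tol"],
            l1_ratio=_l1_ratio(params["penalty"]),
            fit_intercept=params["fit_intercept"],
        )
        clf.fit(Z, y[train_idx])
        Zt = (X[test_idx] - mean) / sd
        accs.append(float((clf.predict(Zt) == y[test_idx]).mean()))
    return float(np.mean(accs))


def cv_search(
    examples: Sequence[TrainingExample],
    space: HyperparameterSpace = HyperparameterSpace(),
    n_folds: int = 3,
    budget: int = 60,
    rng: np.random.Generator | int | None = 0,
    rank: str | None = None,
    order: int | None = None,
) -> tuple[ScoreModel, list[dict]]:
    """Sequential random search over the box; 3-fold CV accuracy objective.

    Returns the best model refit on all data and the search log (one
    dict per candidate with its parameters and CV accuracy). Ties break
    to the earlier candidate; reproducible under a fixed rng seed.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not examples:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(rng)
    X, y = _features(examples)
    _validate_xy(X, y)
    seed = int(rng.integers(2**31 - 1))
    log: list[dict] = []
    best_idx, best_acc = 0, -1.0
    for i in range(budget):
        params = space.sample(rng)
        acc = _cv_accuracy(X, y, params, space.max_iter, n_folds, seed)
        log.append({**params, "cv_accuracy": acc})
        if acc > best_acc:
            best_idx, best_acc = i, acc
    chosen = log[best_idx]
    model = fit_logistic(
        examples,
        penalty=chosen["penalty"],
        C=chosen["C"],
        tol=chosen["tol"],
        fit_intercept=chosen["fit_intercept"],
        max_iter=space.max_iter,
        rank=rank,
        order=order,
        seed=seed,
    )
    model.meta["cv_accuracy"] = best_acc
    model.meta["n_folds"] = n_folds
    return model, log


def save_model_json(model: ScoreModel, path) -> None:
    payload = {
        "version": JSON_FORMAT_VERSION,
        "rank": model.rank,
        "order": model.order,
        "intercept": model.intercept,
        "coefficients": {"score": model.coef_score, "length": model.coef_length},
        "standardize": {
            "score": list(model.standardize_score),
            "length": list(model.standardize_length),
        },
        "meta": model.meta,
    }
    with open(path, "w") as out:
        json.dump(payload, out, indent=1)


def load_model_json(path) -> ScoreModel:
    with open(path) as handle:
        payload = json.load(handle)
    version = payload.get("version")
    if version != JSON_FORMAT_VERSION:
        raise ValueError(
            f"unsupported score-model format version {version!r} (expected {JSON_FORMAT_VERSION})"
        )
    required = ("rank", "order", "intercept", "coefficients", "standardize")
    missing = [f for f in required if f not in payload]
    if missing:
        raise ValueError(f"score-model JSON missing field(s): {', '.join(missing)}")
    coef = payload["coefficients"]
    std = payload["standardize"]
    return ScoreModel(
        rank=payload["rank"],
        order=int(payload["order"]),
        intercept=float(payload["intercept"]),
        coef_score=float(coef["score"]),
        coef_length=float(coef["length"]),
        standardize_score=tuple(std["score"]),
        standardize_length=tuple(std["length"]),
        meta=payload.get("meta", {}),
    )


class ScoreCalibrator:
    """scikit-learn-style estimator wrapping the calibration fit.

    ``fit(X, y)`` takes X of shape (n, 2) — columns (raw_score,
    read_length) — and boolean y; ``predict_proba`` returns the usual
    (n, 2) column-stacked probabilities. The fitted closed-form model is
    exposed as ``model_``.
    """

    def __init__(
        self,
        rank: str = "genus",
        order: int = 10,
        penalty: str = "l2",
        C: float = 1.0,
        tol: float = 1e-4,
        fit_intercept: bool = True,
        max_iter: int = 15_000,
        seed: int = 0,
    ):
        self.rank = rank
        self.order = order
        self.penalty = penalty
        self.C = C
        self.tol = tol
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in ("rank", "order", "penalty", "C", "tol", "fit_intercept", "max_iter", "seed")
        }

    def set_params(self, **params) -> "ScoreCalibrator":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "ScoreCalibrator":
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        X = np.asarray(X, dtype=np.float64)
        examples = [
            TrainingExample(float(s), int(l), bool(lab), self.rank, self.order)
            for (s, l), lab in zip(X, y)
        ]
        self.model_ = fit_logistic(
            examples,
            penalty=self.penalty,
            C=self.C,
            tol=self.tol,
            fit_intercept=self.fit_intercept,
            max_iter=self.max_iter,
            rank=self.rank,
            order=self.order,
            seed=self.seed,
        )
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        p1 = np.array([predict_probability(self.model_, s, l) for s, l in X])
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y).astype(int)).mean())
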