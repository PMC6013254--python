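"""Machine-learning lane: RBF-SVM ensemble with PPV-rank grid search.

The classifier separates stabilizing (+1) from non-stabilizing (-1)
mutations in feature space with a support-vector machine (RBF kernel).
The two free parameters — regularization C and kernel width gamma —
are scanned on a grid of 250 x 250 = 62,500 cells (step 0.2 on
(0, 50]).  For each of 10 repeats, the benchmark is split into a 65%
training and 35% validation part, stratified to preserve the heavy
class imbalance; each cell's model is scored on validation by the
positive predictive value

    PPV = TPR / (TPR + FPR),

cells are ranked per repeat (rank 1 = highest PPV, ties get their
average rank), and a cell's final score is its rank sum over repeats
normalized by the maximum cell sum — lower is better.  Four models
from distinct grid regions are then refit on the full benchmark; each
carries held-out TPR/FPR estimates and a weight proportional to its
estimated PPV (weights normalized to 1).  A mutation's ML score is the
weighted sum of the models voting +1.

Features are standardized with training-split statistics only, and
class weights are inversely proportional to class frequency — with
~8% positives the SVM would otherwise collapse onto the majority
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES, extract_features
from .numbering import AMINO_ACIDS, Mutation, ReceptorAnnotation, ScoredMutation
from .structure import StructureModel

MODULE_NAME = "ml"

ARCHIVE_VERSION = 1


def default_grid_values(n: int = 250, step: float = 0.2) -> np.ndarray:
    """Grid axis {step, 2*step, ..., n*step}; zero is excluded since
    C = 0 and gamma = 0 are invalid for an RBF SVM."""
    return np.round(np.arange(1, n + 1) * step, 10)


def ppv(tpr: float, fpr: float) -> float:
    """Positive predictive value TPR / (TPR + FPR).

    Raises ``ZeroDivisionError`` when both rates are zero (the caller
    excludes such cells from ranking).
    """
    if not (0 <= tpr <= 1 and 0 <= fpr <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if tpr == 0 and fpr == 0:
        raise ZeroDivisionError("PPV undefined for TPR = FPR = 0")
    return tpr / (tpr + fpr)


@dataclass
class CVGrid:
    """Cross-validation grid with per-cell normalized rank scores."""

    c_values: np.ndarray
    gamma_values: np.ndarray
    repeats: int
    rank_scores: np.ndarray  # (n_c, n_gamma), normalized rank sums
    mean_tpr: np.ndarray
    mean_fpr: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.c_values) * len(self.gamma_values)


@dataclass
class PredictionModel:
    """One trained SVM with its grid cell, CV rates, and ensemble weight."""

    c_param: float
    gamma_param: float
    pipeline: Pipeline
    est_tpr: float
    est_fpr: float
    weight: float = field(default=0.0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(X)


def _fit_cell(X_train, y_train, c: float, gamma: float) -> Pipeline:
    """Standardize, then fit an RBF SVM at grid cell (C, gamma).

    The grid gamma is expressed per feature dimension (effective kernel
    width gamma / n_features on standardized inputs), so the same
    (0, 50] grid stays meaningful for any feature-space size.
    """
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel="rbf",
                    C=c,
                    gamma=gamma / X_train.shape[1],
                    class_weight="balanced",
                ),
            ),
        ]
    )
    pipe.fit(X_train, y_train)
    return pipe


def _rates(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    pos = y_true == 1
    neg = ~pos
    tpr = float(np.mean(y_pred[pos] == 1)) if pos.any() else 0.0
    fpr = float(np.mean(y_pred[neg] == 1)) if neg.any() else 0.0
    return tpr, fpr


def ppv_matrix_to_ranks(ppv_matrix: np.ndarray) -> np.ndarray:
    """Ranks over grid cells for one repeat: rank 1 = highest PPV, ties
    averaged; undefined cells (NaN) are excluded from the ranking and
    assigned rank ``n_valid + 1``."""
    flat = ppv_matrix.ravel()
    valid = np.isfinite(flat)
    ranks = np.full(flat.shape, np.count_nonzero(valid) + 1.0)
    ranks[valid] = rankdata(-flat[valid], method="average")
    return ranks.reshape(ppv_matrix.shape)


def rank_sums_to_scores(rank_sums: np.ndarray) -> np.ndarray:
    """Normalize per-cell rank sums by the maximum cell sum (lower is
    better)."""
    return rank_sums / rank_sums.max()


def cv_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    c_values: np.ndarray | None = None,
    gamma_values: np.ndarray | None = None,
    repeats: int = 10,
    seed: int = 0,
    validation_fraction: float = 0.35,
) -> CVGrid:
    """Repeated stratified-split grid search scored by PPV rank sums."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("benchmark must contain both classes")
    c_values = default_grid_values() if c_values is None else np.asarray(c_values)
    gamma_values = (
        default_grid_values() if gamma_values is None else np.asarray(gamma_values)
    )
    n_c, n_g = len(c_values), len(gamma_values)
    rng = np.random.default_rng(seed)
    rank_sums = np.zeros((n_c, n_g))
    tpr_sum = np.zeros((n_c, n_g))
    fpr_sum = np.zeros((n_c, n_g))
    for _ in range(repeats):
        split_seed = int(rng.integers(2**31 - 1))
        X_tr, X_val, y_tr, y_val = train_test_split(
            X,
            y,
            test_size=validation_fraction,
            stratify=y,
            random_state=split_seed,
        )
        ppv_mat = np.full((n_c, n_g), np.nan)
        for i, c in enumerate(c_values):
            for j, g in enumerate(gamma_values):
                pipe = _fit_cell(X_tr, y_tr, float(c), float(g))
                tpr, fpr = _rates(y_val, pipe.predict(X_val))
                tpr_sum[i, j] += tpr
                fpr_sum[i, j] += fpr
                if tpr > 0 or fpr > 0:
                    ppv_mat[i, j] = ppv(tpr, fpr)
        rank_sums += ppv_matrix_to_ranks(ppv_mat)
    return CVGrid(
        c_values=c_values,
        gamma_values=gamma_values,
        repeats=repeats,
        rank_scores=rank_sums_to_scores(rank_sums),
        mean_tpr=tpr_sum / repeats,
        mean_fpr=fpr_sum / repeats,
    )


def select_models(
    grid: CVGrid,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 4,
    min_spacing: int | None = None,
) -> list[PredictionModel]:
    """Pick ``k`` low-score cells in distinct grid regions and refit.

    Greedy selection by ascending rank score with a minimum Chebyshev
    index distance between picked cells (default: a tenth of the longer
    grid axis).  Each pick is refit on the full benchmark; held-out
    TPR/FPR come from the CV repeats, and weights are proportional to
    estimated PPV, normalized to sum 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_c, n_g = grid.rank_scores.shape
    if min_spacing is None:
        min_spacing = max(1, round(0.1 * max(n_c, n_g)))
    order = np.argsort(grid.rank_scores, axis=None, kind="stable")
    picked: list[tuple[int, int]] = []
    for flat in order:
        i, j = divmod(int(flat), n_g)
        if all(
            max(abs(i - pi), abs(j - pj)) >= min_spacing for pi, pj in picked
        ):
            picked.append((i, j))
        if len(picked) == k:
            break
    if len(picked) < k:
        raise ValueError(
            f"only {len(picked)} grid cells satisfy the spacing constraint"
        )
    models = []
    for i, j in picked:
        c = float(grid.c_values[i])
        g = float(grid.gamma_values[j])
        pipe = _fit_cell(X, y, c, g)
        est_tpr = float(grid.mean_tpr[i, j])
        est_fpr = float(grid.mean_fpr[i, j])
        models.append(
            PredictionModel(
                c_param=c,
                gamma_param=g,
                pipeline=pipe,
                est_tpr=est_tpr,
                est_fpr=est_fpr,
            )
        )
    raw = np.array(
        [
            ppv(m.est_tpr, m.est_fpr) if (m.est_tpr or m.est_fpr) else 0.0
            for m in models
        ]
    )
    if raw.sum() == 0:
        raw = np.ones(len(models))
    weights = raw / raw.sum()
    for m, w in zip(models, weights):
        m.weight = float(w)
    return models


def ml_score_features(X: np.ndarray, models: list[PredictionModel]) -> np.ndarray:
    """Weighted positive-vote score for each row of ``X``."""
    if not models:
        raise ValueError("need at least one prediction model")
    X = np.atleast_2d(X)
    score = np.zeros(len(X))
    for m in models:
        score += m.weight * (m.predict(X) == 1)
    return score


def ml_score(
    mutation: Mutation,
    models: list[PredictionModel],
    model_structure: StructureModel,
    seed: int = 0,
) -> float:
    """Weighted ensemble vote for one mutation on one structure."""
    fv = extract_features(model_structure, mutation, seed)
    return float(ml_score_features(fv.values[None, :], models)[0])


def enumerate_mutant_space(annotation: ReceptorAnnotation) -> list[Mutation]:
    """Every annotated TM position x all 19 non-identical substitutions."""
    out = []
    for pos in annotation.tm_positions():
        wt = annotation.residue(pos)
        gn = annotation.generic_number(pos)
        for aa in AMINO_ACIDS:
            if aa != wt:
                out.append(Mutation.single(pos, wt, aa, gn=gn))
    return out


def propose_ml_mutations(
    model_structure: StructureModel,
    annotation: ReceptorAnnotation,
    models: list[PredictionModel],
    seed: int = 0,
    min_score: float = 0.5,
) -> list[ScoredMutation]:
    """Score the full single-mutant space and keep weighted votes above
    ``min_score`` (default: a weighted majority)."""
    out = []
    for mutation in enumerate_mutant_space(annotation):
        s = ml_score(mutation, models, model_structure, seed)
        if s > min_score:
            out.append(
                ScoredMutation(
                    mutation=mutation,
                    module_scores={MODULE_NAME: s},
                    provenance=[MODULE_NAME],
                )
            )
    out.sort(key=lambda sm: -sm.module_scores[MODULE_NAME])
    return out


# -- persistence ---------------------------------------------------------


def save_ensemble(models: list[PredictionModel], grid: CVGrid, path) -> None:
    joblib.dump(
        {
            "version": ARCHIVE_VERSION,
            "feature_names": FEATURE_NAMES,
            "models": models,
            "grid": grid,
        },
        path,
    )


def load_ensemble(path) -> tuple[list[PredictionModel], CVGrid]:
    blob = joblib.load(path)
    if blob.get("version") != ARCHIVE_VERSION:
        raise ValueError(f"unsupported ensemble archive version {blob.get('version')}")
    return blob["models"], blob["grid"]


# -- scikit-learn estimator facade --------------------------------------


class EnsembleStabilityClassifier(BaseEstimator, ClassifierMixin):
    """Grid-CV SVM ensemble as a scikit-learn estimator.

    ``fit`` runs the PPV-rank grid search and model selection;
    ``predict`` is a weighted majority vote and ``decision_function``
    the weighted positive-vote score in [0, 1].
    """

    def __init__(
        self,
        grid_size: int = 25,
        grid_step: float = 2.0,
        repeats: int = 10,
        k_models: int = 4,
        min_spacing: int | None = None,
        seed: int = 0,
    ):
        self.grid_size = grid_size
        self.grid_step = grid_step
        self.repeats = repeats
        self.k_models = k_models
        self.min_spacing = min_spacing
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        values = default_grid_values(self.grid_size, self.grid_step)
        self.grid_ = cv_grid_search(
            X, y, values, values, repeats=self.repeats, seed=self.seed
        )
        self.models_ = select_models(
            self.grid_, X, y, k=self.k_models, min_spacing=self.min_spacing
        )
        self.classes_ = np.array([-1, 1])
        return self

    def decision_function(self, X):
        return ml_score_features(np.asarray(X, float), self.models_)

    def predict(self, X):
        return np.where(self.decision_function(X) > 0.5, 1, -1)
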