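"""Patient-wise splitting, SMOTE balancing, tuning and the experiment grid.

The classification study compares 3 algorithms (random forest, k-nearest
neighbors, logistic regression) across 3 muscle paradigms (all four muscles;
EXT vs APB within the upper limb; EXT vs TA across limbs) and 3 data
representations (raw 1650-sample traces; PCA at 95% explained variance;
7 engineered features).  Patients are split 28:8 so no patient contributes
to both sides; the two-muscle paradigms reuse the four-muscle split with the
other classes' rows dropped.  Class imbalance in the training set is
corrected with SMOTE applied to the raw training matrix (augment, then
compress), after which PCA is fitted and features are recomputed on the
balanced signals — the test set never influences any fitted transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors

from . import features as _features
from .preprocess import PreselectedTrace
from .synthetic import CUTOFF_MS, DEFAULT_SAMPLING_RATE, MuscleClass

logger = logging.getLogger(__name__)


class Paradigm(str, Enum):
    """Which muscles are being told apart."""

    FOUR_MUSCLE = "FOUR_MUSCLE"
    EXT_VS_APB = "EXT_VS_APB"  # within the upper extremity
    EXT_VS_TA = "EXT_VS_TA"  # across extremities

    @property
    def classes(self) -> Tuple[MuscleClass, ...]:
        return {
            Paradigm.FOUR_MUSCLE: (MuscleClass.EXT, MuscleClass.APB,
                                   MuscleClass.TA, MuscleClass.AH),
            Paradigm.EXT_VS_APB: (MuscleClass.EXT, MuscleClass.APB),
            Paradigm.EXT_VS_TA: (MuscleClass.EXT, MuscleClass.TA),
        }[self]


class Representation(str, Enum):
    RAW = "RAW"  # 1650 samples per trace
    PCA = "PCA"  # data-dependent dimension, 95% variance
    FE = "FE"  # 7 engineered features


class Algorithm(str, Enum):
    RF = "RF"
    KNN = "KNN"
    LOGREG = "LOGREG"


#: declared substitute grids (the study's exact grids are not published)
DEFAULT_GRIDS: Dict[Algorithm, Dict[str, list]] = {
    Algorithm.RF: {"n_estimators": [100, 300, 500], "max_depth": [None, 10, 20]},
    Algorithm.KNN: {"n_neighbors": [1, 3, 5, 11, 21],
                    "metric": ["euclidean", "manhattan"]},
    Algorithm.LOGREG: {"C": [0.01, 0.1, 1, 10, 100]},
}


@dataclass
class ModelSpec:
    """One classifier family plus its hyperparameter grid and CV settings."""

    algorithm: Algorithm
    grid: Mapping[str, list] = None  # type: ignore[assignment]
    tuned: Optional[Dict[str, object]] = None
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.algorithm].items()}
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def make_estimator(spec: ModelSpec):
    params = dict(spec.tuned or {})
    if spec.algorithm is Algorithm.RF:
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **params)
    if spec.algorithm is Algorithm.KNN:
        return KNeighborsClassifier(**params)
    # iteration cap raised for high-dimensional raw traces; non-convergence
    # is logged by sklearn as a warning, not fatal
    return LogisticRegression(max_iter=2000, random_state=spec.seed, **params)


# ---------------------------------------------------------------------------
# patient-disjoint splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientSplit:
    train_patients: Tuple[int, ...]
    test_patients: Tuple[int, ...]
    seed: int


@dataclass
class TrainTestSplit:
    """Matrices and labels for one representation, patient-disjoint."""

    X_train: np.ndarray
    y_train: np.ndarray
    patients_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    patients_test: np.ndarray
    representation: Representation
    seed: int


def split_by_patient(
    traces: Sequence[PreselectedTrace],
    n_train: int = 28,
    n_test: int = 8,
    seed: int = 0,
) -> PatientSplit:
    """Assign whole patients to train/test uniformly at random by seed."""
    patients = sorted({t.patient_id for t in traces})
    if n_train + n_test != len(patients):
        raise ValueError(
            f"n_train + n_test = {n_train + n_test} but cohort has "
            f"{len(patients)} patients"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(patients)
    return PatientSplit(
        train_patients=tuple(int(p) for p in sorted(perm[:n_train])),
        test_patients=tuple(int(p) for p in sorted(perm[n_train:])),
        seed=seed,
    )


def raw_split(
    traces: Sequence[PreselectedTrace],
    assignment: PatientSplit,
) -> TrainTestSplit:
    """Stack post-cutoff samples into patient-disjoint raw matrices."""
    tr = [t for t in traces if t.patient_id in set(assignment.train_patients)]
    te = [t for t in traces if t.patient_id in set(assignment.test_patients)]
    return TrainTestSplit(
        X_train=np.vstack([t.samples for t in tr]),
        y_train=np.array([t.muscle.value for t in tr]),
        patients_train=np.array([t.patient_id for t in tr]),
        X_test=np.vstack([t.samples for t in te]),
        y_test=np.array([t.muscle.value for t in te]),
        patients_test=np.array([t.patient_id for t in te]),
        representation=Representation.RAW,
        seed=assignment.seed,
    )


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Oversample every minority class up to the majority count.

    Each synthetic row is ``x + u * (x' - x)`` with ``u ~ U[0, 1)`` and
    ``x'`` one of the ``k`` nearest same-class neighbors of ``x`` — i.e. an
    exact convex combination of two original same-class rows.  Original rows
    are preserved and come first in the output.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < 2:
            raise ValueError(
                f"class {cls!r} has {cnt} training sample(s); SMOTE needs >= 2"
            )
    target = int(counts.max())
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [y]
    for cls, cnt in zip(classes, counts):
        need = target - int(cnt)
        if need == 0:
            continue
        Xc = X[y == cls]
        k = min(k_neighbors, len(Xc) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)  # column 0 is the point itself
        base = rng.integers(0, len(Xc), size=need)
        pick = rng.integers(1, k + 1, size=need)
        gaps = rng.random(need)
        neigh = idx[base, pick]
        synth = Xc[base] + gaps[:, None] * (Xc[neigh] - Xc[base])
        new_X.append(synth)
        new_y.append(np.full(need, cls, dtype=y.dtype))
    Xb = np.vstack(new_X)
    yb = np.concatenate(new_y)
    logger.info("SMOTE: %d -> %d rows (%d classes balanced to %d)",
                len(X), len(Xb), len(classes), target)
    return Xb, yb


# ---------------------------------------------------------------------------
# tuning and training
# ---------------------------------------------------------------------------

def tune_hyperparameters(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> ModelSpec:
    """Exhaustive grid search scored by mean stratified k-fold CV accuracy.

    Ties are broken by first-in-grid order (the search keeps the first
    configuration achieving the best rank).
    """
    if not spec.grid or any(len(v) == 0 for v in spec.grid.values()):
        raise ValueError("hyperparameter grid must be non-degenerate")
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(make_estimator(replace(spec, tuned=None)),
                          param_grid=dict(spec.grid), scoring="accuracy",
                          cv=cv, n_jobs=1, error_score="raise")
    search.fit(X, y)
    tuned = {k: v for k, v in search.best_params_.items()}
    logger.info("%s tuned: %s (CV accuracy %.3f)", spec.algorithm.value, tuned,
                search.best_score_)
    out = replace(spec, tuned=tuned)
    out.cv_accuracy_ = float(search.best_score_)  # type: ignore[attr-defined]
    return out


@dataclass
class Predictions:
    y_pred: np.ndarray
    scores: np.ndarray  # (n, n_classes), rows sum to 1
    classes: Tuple[str, ...]


def train_and_predict(spec: ModelSpec, split: TrainTestSplit) -> Predictions:
    """Fit the tuned estimator on the training side, score the test side."""
    if split.X_train.shape[1] != split.X_test.shape[1]:
        raise ValueError(
            f"train dimension {split.X_train.shape[1]} != test dimension "
            f"{split.X_test.shape[1]}"
        )
    est = make_estimator(spec)
    est.fit(split.X_train, split.y_train)
    scores = est.predict_proba(split.X_test)
    return Predictions(
        y_pred=est.predict(split.X_test),
        scores=scores,
        classes=tuple(str(c) for c in est.classes_),
    )


# ---------------------------------------------------------------------------
# the 3 x 3 x 3 experiment grid
# ---------------------------------------------------------------------------

def _drop_rows(X, y, patients, keep: Tuple[MuscleClass, ...]):
    mask = np.isin(y, [m.value for m in keep])
    return X[mask], y[mask], patients[mask]


def _fe_matrix(X_raw: np.ndarray, sampling_rate: float, t_start_ms: float) -> np.ndarray:
    return np.vstack([
        _features.extract_features(row, sampling_rate=sampling_rate,
                                   t_start_ms=t_start_ms).to_array()
        for row in X_raw
    ])


def run_experiment(
    traces: Sequence[PreselectedTrace],
    paradigms: Sequence[Paradigm] = tuple(Paradigm),
    representations: Sequence[Representation] = tuple(Representation),
    algorithms: Sequence[Algorithm] = tuple(Algorithm),
    seed: int = 0,
    n_train: int = 28,
    n_test: int = 8,
    cv_folds: int = 10,
    grids: Optional[Mapping[Algorithm, Mapping[str, list]]] = None,
    k_neighbors_smote: int = 5,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    t_start_ms: float = CUTOFF_MS,
) -> Dict[Tuple[str, str, str], "EvaluationReport"]:  # noqa: F821
    """Run the full grid; returns reports keyed (algorithm, paradigm, rep).

    One patient assignment is drawn per seed and shared by every cell; the
    two-class paradigms drop rows of that same split rather than re-splitting.
    """
    from .evaluation import evaluate_cell  # deferred to avoid a cycle

    assignment = split_by_patient(traces, n_train, n_test, seed)
    base = raw_split(traces, assignment)
    reports: Dict[Tuple[str, str, str], "EvaluationReport"] = {}

    for paradigm in paradigms:
        Xtr, ytr, ptr = _drop_rows(base.X_train, base.y_train,
                                   base.patients_train, paradigm.classes)
        Xte, yte, pte = _drop_rows(base.X_test, base.y_test,
                                   base.patients_test, paradigm.classes)
        Xtr_bal, ytr_bal = smote_balance(Xtr, ytr, k_neighbors_smote, seed)

        rep_matrices: Dict[Representation, Tuple[np.ndarray, np.ndarray]] = {}
        for rep in representations:
            if rep is Representation.RAW:
                rep_matrices[rep] = (Xtr_bal, Xte)
            elif rep is Representation.PCA:
                model = _features.fit_pca(Xtr_bal)
                rep_matrices[rep] = (
                    _features.apply_pca(model, Xtr_bal),
                    _features.apply_pca(model, Xte),
                )
            else:
                rep_matrices[rep] = (
                    _fe_matrix(Xtr_bal, sampling_rate, t_start_ms),
                    _fe_matrix(Xte, sampling_rate, t_start_ms),
                )

        for rep in representations:
            Xtr_rep, Xte_rep = rep_matrices[rep]
            split = TrainTestSplit(
                X_train=Xtr_rep, y_train=ytr_bal, patients_train=ptr,
                X_test=Xte_rep, y_test=yte, patients_test=pte,
                representation=rep, seed=seed,
            )
            for algo in algorithms:
                grid = dict(grids[algo]) if grids is not None else None
                spec = ModelSpec(algorithm=algo, grid=grid,
                                 cv_folds=cv_folds, seed=seed)
                logger.info("cell %s / %s / %s: tuning",
                            algo.value, paradigm.value, rep.value)
                tuned = tune_hyperparameters(spec, Xtr_rep, ytr_bal)
                preds = train_and_predict(tuned, split)
                report = evaluate_cell(
                    preds, split.y_test,
                    algorithm=algo, paradigm=paradigm, representation=rep,
                    tuned_params=tuned.tuned,
                    dimension=int(Xtr_rep.shape[1]),
                )
                reports[(algo.value, paradigm.value, rep.value)] = report
    return reports
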