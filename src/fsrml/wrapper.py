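"""Feature self-recognition wrapper: ISTOA over binary feature masks.

The wrapper searches continuous positions of dimension = number of
predictors; each position is binarised into a retain/delete mask (sigmoid
transfer, threshold 0.5, i.e. bit = 1 iff the component is positive), and
the objective is ``1 - mean stratified k-fold accuracy`` of a base
classifier trained on the retained columns only.  Minimising the objective
therefore maximises cross-validated accuracy.  Mask evaluations are
memoised: many positions binarise to the same mask, and the classifier fits
dominate the cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .optimizer import OptimizerConfig, OptimizationTrace, optimize

__all__ = [
    "BASE_MODELS",
    "FSRMLResult",
    "make_base_model",
    "mask_columns",
    "binarize_position",
    "mask_objective",
    "fit_fsrml",
    "train_test_split_counts",
]

BASE_MODELS = ("LR", "DT", "KNN", "BP", "SVM", "RF", "XGBoost")

# Wrapper search budget for cohort-scale problems.  The wrapper's cost is
# dominated by classifier fits, so its default budget is much smaller than
# the benchmark budget; both are plain OptimizerConfig fields.
DEFAULT_WRAPPER_CONFIG = OptimizerConfig(population_size=16, max_iterations=30)

# positions live in a symmetric box; the sigmoid transfer only uses the sign
POSITION_BOUND = 4.0


def make_base_model(name: str, seed: int = 0):
    """Instantiate one of the base classifiers with library defaults.

    Scale-sensitive learners (LR, KNN, BP, SVM) are wrapped in a
    standardising pipeline; tree ensembles are scale-free and run raw.
    """
    if name == "LR":
        est = LogisticRegression(max_iter=1000, solver="liblinear",
                                 random_state=seed)
        return make_pipeline(StandardScaler(), est)
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if name == "KNN":
        return make_pipeline(StandardScaler(), KNeighborsClassifier())
    if name == "BP":
        est = MLPClassifier(hidden_layer_sizes=(16,), max_iter=300,
                            random_state=seed)
        return make_pipeline(StandardScaler(), est)
    if name == "SVM":
        return make_pipeline(StandardScaler(), SVC(random_state=seed))
    if name == "RF":
        return RandomForestClassifier(random_state=seed)
    if name == "XGBoost":
        from xgboost import XGBClassifier

        return XGBClassifier(n_estimators=100, max_depth=3,
                             random_state=seed, verbosity=0,
                             eval_metric="logloss")
    raise ValueError(f"unknown base model {name!r}; valid names: {BASE_MODELS}")


@dataclass
class FSRMLResult:
    best_mask: np.ndarray
    feature_names: list[str]
    best_cv_accuracy: float
    base_model_name: str
    trace: OptimizationTrace
    fitted_model: object
    folds: int
    seed: int

    @property
    def selected_features(self) -> list[str]:
        return [n for n, b in zip(self.feature_names, self.best_mask) if b]


def binarize_position(position, threshold_rule: str = "sigmoid") -> np.ndarray:
    """Map a continuous position to a retain/delete mask.

    ``sigmoid``: bit = 1 iff S(x) = 1/(1+e^-x) > 0.5, i.e. iff x > 0.
    ``half``: bit = 1 iff x > 0.5 (for positions already living in [0, 1]).
    An all-zero mask is repaired by forcing the bit with the largest
    transfer value to 1 (the empty feature set is infeasible).
    """
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position components must be finite")
    if threshold_rule == "sigmoid":
        transfer = 1.0 / (1.0 + np.exp(-position))
    elif threshold_rule == "half":
        transfer = position
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    bits = (transfer > 0.5).astype(int)
    if not bits.any():
        bits[int(np.argmax(transfer))] = 1
    return bits


def mask_columns(cohort, mask) -> np.ndarray:
    """Retained-column design matrix as a float array."""
    mask = np.asarray(mask, dtype=int)
    if mask.shape[0] != len(cohort.feature_names):
        raise ValueError(
            f"mask length {mask.shape[0]} != predictor count "
            f"{len(cohort.feature_names)}"
        )
    if not mask.any():
        raise ValueError("empty feature mask is infeasible")
    cols = [n for n, b in zip(cohort.feature_names, mask) if b]
    return cohort.X[cols].to_numpy(dtype=float)


def mask_objective(mask, cohort, base_model: str, folds: int = 5,
                   seed: int = 0) -> float:
    """``1 - mean stratified k-fold accuracy`` for the retained columns.

    Fold assignment depends only on (cohort, folds, seed), so the objective
    is a deterministic function of the mask.
    """
    X = mask_columns(cohort, mask)
    y = np.asarray(cohort.y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < folds:
        raise ValueError("cohort needs at least `folds` subjects per class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, va in skf.split(X, y):
        model = make_base_model(base_model, seed=seed)
        model.fit(X[tr], y[tr])
        accs.append(float(np.mean(model.predict(X[va]) == y[va])))
    return 1.0 - float(np.mean(accs))


def fit_fsrml(cohort, base_model: str,
              optimizer_config: OptimizerConfig | None = None,
              folds: int = 5, threshold_rule: str = "sigmoid") -> FSRMLResult:
    """Run the full wrapper and refit the final model on the whole cohort.

    ISTOA searches continuous positions; every evaluation binarises the
    position and scores the mask by cross-validated accuracy.  The returned
    ``best_cv_accuracy`` is the objective re-evaluated at the best mask with
    the same folds and seed.
    """
    if base_model not in BASE_MODELS:
        raise ValueError(
            f"unknown base model {base_model!r}; valid names: {BASE_MODELS}"
        )
    config = optimizer_config or DEFAULT_WRAPPER_CONFIG
    dim = len(cohort.feature_names)
    cache: dict[bytes, float] = {}

    def score_mask(bits: np.ndarray) -> float:
        key = bits.tobytes()
        if key not in cache:
            cache[key] = mask_objective(bits, cohort, base_model,
                                        folds=folds, seed=config.seed)
        return cache[key]

    def objective(X: np.ndarray) -> np.ndarray:
        return np.array(
            [score_mask(binarize_position(row, threshold_rule)) for row in X]
        )

    trace = optimize(objective, (-POSITION_BOUND, POSITION_BOUND), dim,
                     config=config, variant="ISTOA")
    best_mask = binarize_position(trace.best_position, threshold_rule)
    best_cv_accuracy = 1.0 - score_mask(best_mask)

    final = make_base_model(base_model, seed=config.seed)
    final.fit(mask_columns(cohort, best_mask), np.asarray(cohort.y, dtype=int))
    return FSRMLResult(
        best_mask=best_mask,
        feature_names=list(cohort.feature_names),
        best_cv_accuracy=best_cv_accuracy,
        base_model_name=base_model,
        trace=trace,
        fitted_model=final,
        folds=folds,
        seed=config.seed,
    )


def train_test_split_counts(n: int, train_fraction: float) -> tuple[int, int]:
    """Rounded (train, test) sizes for an n-subject cohort."""
    if n < 2:
        raise ValueError("need at least 2 subjects to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    n_train = int(round(n * train_fraction))
    return n_train, n - n_train
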