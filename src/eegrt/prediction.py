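"""Tuning and evaluation of reaction-time regressors under repeated splits.

Protocol, per subject: the trial set is randomly partitioned into 75% train /
25% test, eleven times. Within each repetition every candidate hyperparameter
combination is scored by 3-fold cross-validation on the training rows with
mean absolute error (MAE) as the criterion; the winner is refit on the full
training set and scored on the held-out trials. The subject-level score is

    MAE_s = (1/R) * sum_r mean(|yhat - y| over test trials of repetition r)

i.e. the unweighted mean of per-repetition mean absolute errors.

Four regressors are compared — LASSO, its LARS variant, RBF kernel ridge, and
RBF support-vector regression — plus a shuffled-label SVR control in which the
training targets are permuted before tuning, approximating a predict-the-mean
baseline. The SVR variants additionally rank features by absolute Pearson
correlation with the training targets and tune the number kept as one more
grid axis; the ranking is recomputed inside every cross-validation fold, so
no validation row influences the selection it is evaluated with.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import Lasso, LassoLars
from sklearn.svm import SVR

from .features import FeatureMatrix, apply_standardizer, fit_standardizer

__all__ = [
    "ModelSpec",
    "SplitScheme",
    "RepResult",
    "EvalResult",
    "default_model_specs",
    "make_splits",
    "tune_and_fit",
    "evaluate_subject",
    "shuffled_baseline",
    "summarize_selected_features",
]

ALGORITHMS = ("lasso", "lasso_lars", "kernel_ridge_rbf", "svr_rbf", "shuffled_svr_rbf")


@dataclass
class ModelSpec:
    """One regressor plus its hyperparameter grid.

    ``feature_selection_k_grid`` (SVR variants only) adds the number of
    correlation-ranked features kept as an extra grid axis; ``None`` disables
    selection and uses every column.
    """

    algorithm: str
    hyperparameter_grid: dict[str, list] = field(default_factory=dict)
    feature_selection_k_grid: list[int] | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        for name, values in self.hyperparameter_grid.items():
            if len(values) == 0:
                raise ValueError(f"empty grid for hyperparameter {name!r}")
        if self.feature_selection_k_grid is not None and not self.feature_selection_k_grid:
            raise ValueError("feature_selection_k_grid must be None or non-empty")

    @property
    def uses_selection(self) -> bool:
        return self.feature_selection_k_grid is not None


def default_model_specs(n_features: int = 140) -> list[ModelSpec]:
    """Plausible default grids (deliberately modest; all overridable).

    The SVR selection-count grid is clipped to the actual feature count.
    """
    alphas = np.logspace(-4, 1, 7).tolist()
    gammas = np.logspace(-4, 1, 6).tolist()
    k_grid = sorted({min(k, n_features) for k in (5, 10, 20, 40, 140)})
    return [
        ModelSpec("lasso", {"alpha": alphas}),
        ModelSpec("lasso_lars", {"alpha": alphas}),
        ModelSpec("kernel_ridge_rbf",
                  {"alpha": np.logspace(-3, 2, 6).tolist(), "gamma": gammas}),
        ModelSpec("svr_rbf",
                  {"C": np.logspace(-2, 3, 6).tolist(), "gamma": gammas,
                   "epsilon": [0.01, 0.05, 0.1]},
                  feature_selection_k_grid=k_grid),
    ]


def _make_estimator(algorithm: str, params: dict):
    if algorithm == "lasso":
        return Lasso(max_iter=50000, **params)
    if algorithm == "lasso_lars":
        return LassoLars(**params)
    if algorithm == "kernel_ridge_rbf":
        return KernelRidge(kernel="rbf", **params)
    if algorithm in ("svr_rbf", "shuffled_svr_rbf"):
        return SVR(kernel="rbf", **params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class SplitScheme:
    """Repeated random train/test splits with inner cross-validation."""

    n_repetitions: int = 11
    train_fraction: float = 0.75
    inner_cv_folds: int = 3
    base_seed: int = 0

    def validate(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_repetitions < 1 or self.inner_cv_folds < 2:
            raise ValueError("need >= 1 repetition and >= 2 inner folds")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def make_splits(n_trials: int, scheme: SplitScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic list of (train_idx, test_idx) pairs.

    Repetition ``r`` draws its permutation from seed ``base_seed + r``.
    ``|train| = round(train_fraction * n)`` with half rounded away from zero.
    """
    scheme.validate()
    if n_trials < 8:
        raise ValueError(f"too few trials ({n_trials}) for a meaningful split")
    n_train = _round_half_away(scheme.train_fraction * n_trials)
    if n_train < scheme.inner_cv_folds:
        raise ValueError(
            f"{n_train} training trials cannot fill {scheme.inner_cv_folds} inner folds"
        )
    if n_train >= n_trials:
        raise ValueError("train fraction leaves no test trials")
    splits = []
    for r in range(scheme.n_repetitions):
        rng = np.random.default_rng(scheme.base_seed + r)
        perm = rng.permutation(n_trials)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return splits


def _inner_folds(n: int, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold partition of range(n), deterministic given seed."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    chunks = np.array_split(perm, k)
    folds = []
    for i in range(k):
        val = np.sort(chunks[i])
        tr = np.sort(np.concatenate([chunks[j] for j in range(k) if j != i]))
        folds.append((tr, val))
    return folds


def _rank_features(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column indices sorted by decreasing |Pearson r| with y (stable ties)."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (Xc * yc[:, None]).sum(axis=0) / denom, 0.0)
    return np.argsort(-np.abs(r), kind="stable")


@dataclass
class TunedModel:
    model: object
    params: dict
    selected_idx: np.ndarray | None
    selected_labels: list[str] | None
    cv_mae: float


def tune_and_fit(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    inner_cv_folds: int = 3,
    cv_seed: int = 0,
    column_labels: Sequence[str] | None = None,
) -> TunedModel:
    """Exhaustive grid search scored by inner-CV mean MAE; first-wins ties.

    ``X``/``y`` are the (already standardized) training rows. Every grid
    point is scored by the mean MAE over the inner folds; the point with the
    strictly lowest mean wins, ties resolving to the earlier point in grid
    order (selection count axis outermost, then hyperparameters in grid
    insertion order). The winner is refit on all training rows.
    """
    n = len(y)
    folds = _inner_folds(n, inner_cv_folds, cv_seed)
    if min(len(v) for _, v in folds) < 1 or min(len(t) for t, _ in folds) < 2:
        raise ValueError("an inner fold has fewer than 2 training samples")

    names = list(spec.hyperparameter_grid)
    combos = list(itertools.product(*(spec.hyperparameter_grid[k] for k in names)))
    k_values: list[int | None] = (
        list(spec.feature_selection_k_grid) if spec.uses_selection else [None]
    )

    fold_rankings = {}
    if spec.uses_selection:
        fold_rankings = {f: _rank_features(X[tr], y[tr]) for f, (tr, _) in enumerate(folds)}

    best: tuple[float, int | None, dict] | None = None
    for k in k_values:
        for combo in combos:
            params = dict(zip(names, combo))
            maes = []
            for f, (tr, val) in enumerate(folds):
                cols = fold_rankings[f][:k] if k is not None else slice(None)
                est = _make_estimator(spec.algorithm, params)
                est.fit(X[tr][:, cols], y[tr])
                pred = est.predict(X[val][:, cols])
                maes.append(np.mean(np.abs(pred - y[val])))
            score = float(np.mean(maes))
            if best is None or score < best[0]:
                best = (score, k, params)

    assert best is not None
    cv_mae, k_best, params_best = best
    if k_best is not None:
        ranking = _rank_features(X, y)
        selected_idx = ranking[:k_best]
        cols = selected_idx
    else:
        selected_idx, cols = None, slice(None)
    model = _make_estimator(spec.algorithm, params_best)
    model.fit(X[:, cols], y)
    labels = None
    if selected_idx is not None and column_labels is not None:
        labels = [column_labels[i] for i in selected_idx]
    params_out = dict(params_best)
    if k_best is not None:
        params_out["n_selected_features"] = k_best
    return TunedModel(model=model, params=params_out,
                      selected_idx=selected_idx, selected_labels=labels,
                      cv_mae=cv_mae)


@dataclass
class RepResult:
    repetition: int
    seed: int
    abs_errors: np.ndarray
    params: dict
    selected_labels: list[str] | None
    test_trial_ids: np.ndarray


@dataclass
class EvalResult:
    """Per-repetition absolute errors and subject-level aggregates."""

    per_rep: dict[str, list[RepResult]]

    def algorithms(self) -> list[str]:
        return list(self.per_rep)

    def mae_s(self, algorithm: str) -> float:
        """Unweighted mean over repetitions of the per-repetition mean AE."""
        reps = self.per_rep[algorithm]
        return float(np.mean([r.abs_errors.mean() for r in reps]))

    def pooled_abs_errors(self, algorithm: str) -> np.ndarray:
        return np.concatenate([r.abs_errors for r in self.per_rep[algorithm]])

    def aggregates(self) -> pd.DataFrame:
        rows = []
        for alg in self.per_rep:
            pooled = self.pooled_abs_errors(alg)
            rows.append({
                "algorithm": alg,
                "mae_s": self.mae_s(alg),
                "ae_sd_s": float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0,
                "ae_max_s": float(pooled.max()),
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {}
        for alg, reps in self.per_rep.items():
            out[alg] = {
                "aggregates": {
                    "mae_s": self.mae_s(alg),
                    "ae_sd_s": float(self.pooled_abs_errors(alg).std(ddof=1)),
                    "ae_max_s": float(self.pooled_abs_errors(alg).max()),
                },
                "repetitions": [
                    {
                        "repetition": r.repetition,
                        "seed": r.seed,
                        "abs_errors_s": r.abs_errors.tolist(),
                        "params": {k: (v if isinstance(v, (int, str)) else float(v))
                                   for k, v in r.params.items()},
                        "selected_features": r.selected_labels,
                        "test_trials": np.asarray(r.test_trial_ids).tolist(),
                    }
                    for r in reps
                ],
            }
        return out


def _evaluate(
    fm: FeatureMatrix,
    specs: Sequence[ModelSpec],
    scheme: SplitScheme,
    shuffle_train_targets: bool,
) -> EvalResult:
    if not specs:
        raise ValueError("no model specs given")
    scheme.validate()
    splits = make_splits(fm.n_trials, scheme)
    per_rep: dict[str, list[RepResult]] = {s.algorithm: [] for s in specs}
    for r, (train_idx, test_idx) in enumerate(splits):
        seed = scheme.base_seed + r
        try:
            std = fit_standardizer(fm, train_idx)
            fz = apply_standardizer(std, fm)
            X_train, X_test = fz.values[train_idx], fz.values[test_idx]
            y_train, y_test = fz.y[train_idx], fz.y[test_idx]
            if shuffle_train_targets:
                # separate stream so the permutation never aliases the split
                perm_rng = np.random.default_rng(scheme.base_seed + 100_000 + r)
                y_train = perm_rng.permutation(y_train)
            for spec in specs:
                tuned = tune_and_fit(
                    spec, X_train, y_train,
                    inner_cv_folds=scheme.inner_cv_folds, cv_seed=seed,
                    column_labels=fm.column_labels,
                )
                cols = tuned.selected_idx if tuned.selected_idx is not None else slice(None)
                pred = tuned.model.predict(X_test[:, cols])
                per_rep[spec.algorithm].append(RepResult(
                    repetition=r, seed=seed,
                    abs_errors=np.abs(pred - y_test),
                    params=tuned.params,
                    selected_labels=tuned.selected_labels,
                    test_trial_ids=fm.trial_ids[test_idx],
                ))
        except Exception as exc:
            raise RuntimeError(f"evaluation failed in repetition {r}: {exc}") from exc
    return EvalResult(per_rep=per_rep)


def evaluate_subject(
    fm: FeatureMatrix, specs: Sequence[ModelSpec], scheme: SplitScheme
) -> EvalResult:
    """Run the full repeated-split protocol for one subject."""
    return _evaluate(fm, specs, scheme, shuffle_train_targets=False)


def shuffled_baseline(
    fm: FeatureMatrix, scheme: SplitScheme, spec: ModelSpec | None = None
) -> EvalResult:
    """SVR control with permuted training targets (test targets stay true)."""
    if spec is None:
        svr = next(s for s in default_model_specs(fm.n_features)
                   if s.algorithm == "svr_rbf")
        spec = ModelSpec("shuffled_svr_rbf", svr.hyperparameter_grid,
                         svr.feature_selection_k_grid)
    return _evaluate(fm, [spec], scheme, shuffle_train_targets=True)


def summarize_selected_features(
    results: dict[str, EvalResult] | EvalResult,
    algorithm: str = "svr_rbf",
    top_n: int | None = None,
) -> pd.DataFrame:
    """Selection-frequency table for the SVR's ranked-and-kept features.

    Accepts one subject's :class:`EvalResult` or a ``{subject: EvalResult}``
    map; returns per-subject counts plus a pooled ``all`` row set, sorted by
    count (descending) then label. Subjects without the requested algorithm
    contribute nothing; if no repetition selected features the table is empty.
    """
    if isinstance(results, EvalResult):
        results = {"subject": results}
    rows = []
    pooled: dict[str, int] = {}
    for subject, res in results.items():
        counts: dict[str, int] = {}
        for rep in res.per_rep.get(algorithm, []):
            for label in rep.selected_labels or []:
                counts[label] = counts.get(label, 0) + 1
                pooled[label] = pooled.get(label, 0) + 1
        for label, count in counts.items():
            rows.append({"subject": subject, "feature": label, "count": count})
    for label, count in pooled.items():
        rows.append({"subject": "all", "feature": label, "count": count})
    frame = pd.DataFrame(rows, columns=["subject", "feature", "count"])
    if frame.empty:
        return frame
    frame = frame.sort_values(["subject", "count", "feature"],
                              ascending=[True, False, True], kind="stable")
    if top_n is not None:
        frame = frame.groupby("subject", group_keys=False).head(top_n)
    return frame.reset_index(drop=True)
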