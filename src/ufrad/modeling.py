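"""Stability-LASSO feature selection and class-weighted logistic models.

The selection procedure repeats an L1-penalized logistic fit over
reshuffled five-fold splits: in each of 25 repeats a predictor counts as
"selected" when its coefficient is nonzero in every training-fold fit of
that repeat's cross-validation.  Predictors selected in at least 20 of the
25 repeats survive the count filter; a relaxed (lightly ridge-stabilized)
logistic refit on the survivors then supplies the standardized
coefficients to which the 0.6 magnitude threshold applies — raw LASSO
coefficients are unsuitable for an absolute threshold because the L1
budget at fixed lambda caps their total magnitude regardless of effect
size.  Survivors
are ranked by (count, |refit coefficient|) and truncated to the top
seven.  The final classifier is a maximum-likelihood
logistic regression on the surviving predictors with per-sample weights
inversely proportional to class frequency, N / (2 * N_class).

``StabilityLogit`` packages the procedure as a model object built from a
feature table whose ``fit()`` returns a ``StabilityLogitResults`` with
coefficients, standard errors, selection diagnostics and a ``summary()``
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

TASKS = ("hr", "her2", "luminal", "her2_overexpressed", "triple_negative")


def task_labels(table: pd.DataFrame, task: str) -> np.ndarray:
    """Binary target for one classification task.

    ``hr`` / ``her2`` use the receptor labels directly; the three subtype
    tasks are one-vs-rest dichotomizations of the St. Gallen subtype.
    """
    task = task.lower()
    if task == "hr":
        y = table["HR"].to_numpy(dtype=int)
    elif task == "her2":
        y = table["HER2"].to_numpy(dtype=int)
    elif task in ("luminal", "her2_overexpressed", "triple_negative"):
        y = (table["subtype"] == task).to_numpy(dtype=int)
    else:
        raise ValueError(f"unknown task {task!r}")
    if y.min() == y.max():
        raise ValueError(f"task {task!r}: only one class present")
    return y


def zscore_features(table: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Z-score every column; constant columns are dropped (logged).

    Missing values are imputed with the column median before scaling.
    Population-SD convention (ddof=0).
    """
    out = {}
    dropped = []
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            med = np.nanmedian(x)
            if np.isnan(med):
                dropped.append(col)
                continue
            x = np.where(np.isnan(x), med, x)
        sd = x.std(ddof=ddof)
        if sd == 0:
            dropped.append(col)
            continue
        out[col] = (x - x.mean()) / sd
    if dropped:
        logger.info("dropped %d constant/empty columns: %s", len(dropped), dropped[:5])
    if not out:
        raise ValueError("all feature columns are constant")
    return pd.DataFrame(out, index=table.index)


@dataclass
class StabilityConfig:
    """Selection hyperparameters (defaults follow the reference protocol)."""

    lasso_lambda: float = 0.05
    n_folds: int = 5
    n_repeats: int = 25
    selection_count_threshold: int = 20
    coef_threshold: float = 0.6
    max_features: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection_count_threshold > self.n_repeats:
            raise ValueError("selection_count_threshold cannot exceed n_repeats")
        if min(self.lasso_lambda, self.coef_threshold, self.max_features) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class SelectionResult:
    """Per-predictor stability-selection outcome."""

    predictor_names: list[str]
    counts: np.ndarray  # repeats in which all fold fits kept the predictor
    mean_abs_coef: np.ndarray  # mean |fold-averaged LASSO coef| (diagnostic)
    refit_abs_coef: np.ndarray  # |relaxed refit coef| (NaN for non-survivors)
    selected: list[str]  # final ordered survivor set

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictor_names,
                "count": self.counts,
                "mean_abs_coef": self.mean_abs_coef,
                "refit_abs_coef": self.refit_abs_coef,
            }
        ).sort_values(["count", "mean_abs_coef"], ascending=False)


def _lasso_logistic(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """L1 logistic with glmnet-style penalty scaling: C = 1 / (n * lambda)."""
    model = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (len(y) * lam),
        solver="liblinear",
        max_iter=500,
        tol=1e-6,
    )
    model.fit(X, y)
    return model.coef_[0]


def stability_select(
    X: pd.DataFrame, y: np.ndarray, cfg: StabilityConfig | None = None
) -> SelectionResult:
    """Repeated cross-validated LASSO selection.

    ``X`` must already be standardized (see :func:`zscore_features`); the
    0.6 coefficient threshold is meaningful only on standardized
    predictors.  An empty survivor set is a valid outcome.
    """
    cfg = cfg or StabilityConfig()
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) != 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 lesions in each class")
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    ss = np.random.SeedSequence(cfg.seed)
    repeat_seeds = ss.generate_state(cfg.n_repeats) % (2**31 - 1)

    counts = np.zeros(len(names), dtype=int)
    abs_coef_sum = np.zeros(len(names))
    for r in range(cfg.n_repeats):
        skf = StratifiedKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=int(repeat_seeds[r])
        )
        fold_coefs = np.zeros((cfg.n_folds, len(names)))
        for k, (train, _) in enumerate(skf.split(Xv, y)):
            fold_coefs[k] = _lasso_logistic(Xv[train], y[train], cfg.lasso_lambda)
        counts += np.all(np.abs(fold_coefs) > 1e-12, axis=0)
        abs_coef_sum += np.abs(fold_coefs.mean(axis=0))
    mean_abs = abs_coef_sum / cfg.n_repeats

    refit_abs = np.full(len(names), np.nan)
    survivors = np.flatnonzero(counts >= cfg.selection_count_threshold)
    selected: list[str] = []
    if survivors.size:
        # relaxed refit supplies the thresholded coefficients; a unit ridge
        # keeps them identified when the survivors nearly separate the classes
        refit = LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000, tol=1e-8)
        refit.fit(Xv[:, survivors], y)
        refit_abs[survivors] = np.abs(refit.coef_[0])
        keep = [i for i in survivors if refit_abs[i] >= cfg.coef_threshold]
        keep.sort(key=lambda i: (-counts[i], -refit_abs[i], names[i]))
        selected = [names[i] for i in keep[: cfg.max_features]]
    if not selected:
        logger.info("stability selection returned an empty set")
    return SelectionResult(names, counts, mean_abs, refit_abs, selected)


@dataclass
class FitResult:
    """Fitted class-weighted logistic model on the selected predictors."""

    predictor_names: list[str]
    coef: np.ndarray
    intercept: float
    bse: np.ndarray | None
    class_weights: dict[int, float]
    converged: bool
    penalized_fallback: bool = False

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.predictor_names].to_numpy(dtype=float)
        eta = self.intercept + X @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))


def class_weights(y: np.ndarray) -> dict[int, float]:
    """Inverse-frequency weights, N / (2 * N_class)."""
    y = np.asarray(y, dtype=int)
    n = len(y)
    return {c: n / (2.0 * np.sum(y == c)) for c in (0, 1)}


def fit_weighted_logistic(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    predictor_names: list[str] | None = None,
) -> FitResult:
    """Maximum-likelihood logistic fit with inverse-frequency sample weights.

    Falls back to a lightly L2-penalized fit when the MLE does not exist
    (complete separation), flagged in the result.
    """
    if isinstance(X, pd.DataFrame):
        predictor_names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if predictor_names is None:
            predictor_names = [f"x{i}" for i in range(Xv.shape[1])]
    if Xv.shape[1] == 0:
        raise ValueError("need at least one selected predictor")
    y = np.asarray(y, dtype=int)
    cw = class_weights(y)
    w = np.where(y == 1, cw[1], cw[0])
    design = sm.add_constant(Xv, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, design, family=sm.families.Binomial(), freq_weights=w).fit(
                tol=1e-8, maxiter=200
            )
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
        # exploding standard errors flag a non-identified (separated) MLE
        ok = (
            res.converged
            and np.all(np.isfinite(params))
            and np.all(np.isfinite(bse))
            and np.max(np.abs(params)) < 1e3
            and np.max(bse) < 1e3
        )
    except Exception:  # PerfectSeparation or singular information
        ok = False
    if not ok:
        logger.warning("MLE unstable (separation?); refitting with tiny L2 penalty")
        clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=2000, tol=1e-8)
        clf.fit(Xv, y, sample_weight=w)
        return FitResult(
            predictor_names,
            clf.coef_[0].copy(),
            float(clf.intercept_[0]),
            None,
            cw,
            converged=True,
            penalized_fallback=True,
        )
    return FitResult(
        predictor_names,
        params[1:].copy(),
        float(params[0]),
        bse,
        cw,
        converged=bool(res.converged),
    )


class StabilityLogit:
    """Stability-LASSO selected, class-weighted logistic model.

    Parameters
    ----------
    X : DataFrame of predictors (standardized internally).
    y : binary target array.
    config : StabilityConfig, selection hyperparameters.

    Examples
    --------
    >>> model = StabilityLogit.from_dataframe(df, label_col="label")
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: np.ndarray,
        config: StabilityConfig | None = None,
    ) -> None:
        self.config = config or StabilityConfig()
        self.exog = zscore_features(X)
        self.endog = np.asarray(y, dtype=int)
        if len(self.exog) != len(self.endog):
            raise ValueError("X and y length mismatch")

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        label_col: str = "label",
        predictors: list[str] | None = None,
        config: StabilityConfig | None = None,
    ) -> "StabilityLogit":
        if predictors is None:
            from ufrad.features import predictor_columns

            predictors = [c for c in predictor_columns(table) if c != label_col]
        return cls(table[predictors], table[label_col].to_numpy(), config)

    def fit(self) -> "StabilityLogitResults":
        selection = stability_select(self.exog, self.endog, self.config)
        cols = selection.selected
        fallback_all = not cols
        if fallback_all:
            # empty selection: fit on all predictors so a score always exists
            logger.info("empty selection; fitting weighted logistic on all predictors")
            cols = list(self.exog.columns)
        fit = fit_weighted_logistic(self.exog[cols], self.endog)
        return StabilityLogitResults(self, selection, fit, fallback_all)


class StabilityLogitResults:
    """Estimates, selection diagnostics and prediction for StabilityLogit."""

    def __init__(
        self,
        model: StabilityLogit,
        selection: SelectionResult,
        fit: FitResult,
        used_all_predictors: bool,
    ) -> None:
        self.model = model
        self.selection = selection
        self.fit_result = fit
        self.used_all_predictors = used_all_predictors

    @property
    def params(self) -> pd.Series:
        vals = np.concatenate([[self.fit_result.intercept], self.fit_result.coef])
        return pd.Series(vals, index=["intercept"] + self.fit_result.predictor_names)

    @property
    def bse(self) -> pd.Series | None:
        if self.fit_result.bse is None:
            return None
        return pd.Series(
            self.fit_result.bse, index=["intercept"] + self.fit_result.predictor_names
        )

    @property
    def selected_features(self) -> list[str]:
        return self.selection.selected

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        """Predicted probabilities; in-sample when X is None."""
        if X is None:
            X = self.model.exog
        return self.fit_result.predict_proba(X)

    def summary(self) -> str:
        lines = [
            "Stability-LASSO weighted logistic regression",
            "=" * 60,
            f"n obs: {len(self.model.endog)}   "
            f"positives: {int(self.model.endog.sum())}   "
            f"lambda: {self.model.config.lasso_lambda}   "
            f"repeats: {self.model.config.n_repeats}",
            "class weights: "
            + ", ".join(
                f"{c}: {w:.3f}" for c, w in sorted(self.fit_result.class_weights.items())
            ),
            f"selected {len(self.selection.selected)} predictors"
            + (" (empty selection; model uses all predictors)"
               if self.used_all_predictors else "")
            + (" [L2 fallback: separation detected]"
               if self.fit_result.penalized_fallback else ""),
            "-" * 60,
            f"{'predictor':<34}{'coef':>9}{'se':>8}{'count':>6}",
        ]
        bse = self.bse
        name_to_idx = {n: i for i, n in enumerate(self.selection.predictor_names)}
        for name in ["intercept"] + self.fit_result.predictor_names:
            coef = self.params[name]
            se = f"{bse[name]:8.3f}" if bse is not None else "      --"
            cnt = (
                f"{self.selection.counts[name_to_idx[name]]:6d}"
                if name in name_to_idx
                else "    --"
            )
            lines.append(f"{name:<34}{coef:9.3f}{se}{cnt}")
        lines.append("=" * 60)
        return "\n".join(lines)


@dataclass
class TaskResult:
    """Out-of-fold evaluation of one classification task."""

    task: str
    scores: np.ndarray  # per-lesion mean out-of-fold probability
    repeat_scores: np.ndarray  # (n_eval_repeats, n) out-of-fold probabilities
    labels: np.ndarray
    selection: SelectionResult
    fit: FitResult


def run_task(
    table: pd.DataFrame,
    task: str,
    cfg: StabilityConfig | None = None,
    seed: int = 0,
    n_eval_repeats: int = 5,
    n_eval_folds: int = 5,
    predictors: list[str] | None = None,
) -> TaskResult:
    """Full modeling protocol for one task with honest out-of-fold scores.

    Features are z-scored and the stability selection is run once on the
    full table (mirroring the reference protocol); evaluation scores come
    from repeated stratified cross-validation in which only the weighted
    logistic is refit per training fold, so each lesion's score is always
    out-of-fold for the classifier.
    """
    cfg = cfg or StabilityConfig(seed=seed)
    y = task_labels(table, task)
    if predictors is None:
        from ufrad.features import predictor_columns

        predictors = predictor_columns(table)
    X = zscore_features(table[predictors])

    selection = stability_select(X, y, cfg)
    cols = selection.selected or list(X.columns)
    fit_full = fit_weighted_logistic(X[cols], y)

    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_eval_repeats) % (2**31 - 1)
    n = len(y)
    repeat_scores = np.full((n_eval_repeats, n), np.nan)
    Xs = X[cols].to_numpy(dtype=float)
    for r in range(n_eval_repeats):
        skf = StratifiedKFold(
            n_splits=n_eval_folds, shuffle=True, random_state=int(rep_seeds[r])
        )
        for train, test in skf.split(Xs, y):
            fold_fit = fit_weighted_logistic(Xs[train], y[train], cols)
            repeat_scores[r, test] = fold_fit.predict_proba(Xs[test])
    return TaskResult(task, repeat_scores.mean(axis=0), repeat_scores, y, selection, fit_full)
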