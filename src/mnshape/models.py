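"""Model fitting and evaluation: half splits, forests, boosting, logistic
regression, ROC/R-squared metrics with repeat ranges, Spearman matrices, and
the adjustable-RBE photon-equivalent-dose fit.

The evaluation protocol mirrors a repeated random-split design: each repeat
draws a fresh stratified half split, fits on the training half, and scores
the testing half; binary outcomes are summarised by ROC AUC and continuous
outcomes by R-squared, with the mean / min / max over repeats reported.

The "multivariate" random forest is realised as independent regression
forests per outcome sharing the same predictor set — the per-outcome metrics
are what gets reported, and binary outcomes are predicted as continuous
scores usable for ROC analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES

__all__ = [
    "MultiOutcomeForest",
    "PhotonEquivalentDoseFitter",
    "EvaluationResult",
    "RBEFitResult",
    "split_half",
    "fit_predict_rf",
    "fit_predict_gbm",
    "fit_predict_logistic",
    "roc_auc",
    "r_squared",
    "repeat_evaluate",
    "fit_rbe",
    "spearman_matrix",
    "backward_eliminate",
]


# ---------------------------------------------------------------------------
# splitting


def split_half(items, stratify=None, seed=None, rng=None):
    """Random disjoint half split, optionally stratified on a binary label.

    Parameters
    ----------
    items : sequence or DataFrame
        What to split; DataFrames are split by row.
    stratify : array-like or None
        Class label per item; each class is divided as evenly as possible
        between the halves so both classes appear in both.
    seed, rng : int / Generator
        Exactly reproducible given either.

    Returns
    -------
    (train, test) of the same type as ``items``, sizes differing by at most 1.
    """
    n = len(items)
    if n < 4:
        raise ValueError(f"need at least 4 items to split, got {n}")
    rng = np.random.default_rng(seed) if rng is None else rng

    if stratify is None:
        classes = {None: np.arange(n)}
    else:
        stratify = np.asarray(stratify)
        classes = {c: np.flatnonzero(stratify == c) for c in np.unique(stratify)}
        for c, idx in classes.items():
            if len(idx) < 2:
                raise ValueError(f"class {c!r} has fewer than 2 items; cannot stratify")

    train_idx, test_idx, leftovers = [], [], []
    for c in sorted(classes, key=str):
        idx = rng.permutation(classes[c])
        h = len(idx) // 2
        train_idx.extend(idx[:h])
        test_idx.extend(idx[h : 2 * h])
        if len(idx) % 2:
            leftovers.append(idx[-1])
    for extra in rng.permutation(np.asarray(leftovers, dtype=int)):
        side = train_idx if len(train_idx) <= len(test_idx) else test_idx
        side.append(int(extra))

    train_idx, test_idx = sorted(train_idx), sorted(test_idx)
    if isinstance(items, pd.DataFrame):
        return items.iloc[train_idx], items.iloc[test_idx]
    return [items[i] for i in train_idx], [items[i] for i in test_idx]


# ---------------------------------------------------------------------------
# estimators


class MultiOutcomeForest(RegressorMixin, BaseEstimator):
    """Independent regression forests per outcome over a shared predictor set.

    Binary outcomes are fitted as regressions too, so their predictions are
    scores in [0, 1] directly usable for ROC curves. An outcome that is
    constant in the training data is flagged and predicted as that constant;
    the other outcomes are unaffected.

    Parameters
    ----------
    n_estimators : trees per forest (default 500).
    max_features : features tried per split; "third" means ceil(p / 3).
    random_state : seed for the forests.
    """

    def __init__(self, n_estimators=500, max_features="third", random_state=None):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def _resolve_max_features(self, p):
        if self.max_features == "third":
            return max(1, math.ceil(p / 3))
        return self.max_features

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("predictors must be finite")
        Y = pd.DataFrame(y)
        self.outcome_names_ = list(Y.columns)
        self.n_features_in_ = X.shape[1]
        self.estimators_ = {}
        self.constant_outcomes_ = {}
        rs = np.random.RandomState(self.random_state)
        mf = self._resolve_max_features(X.shape[1])
        for name in self.outcome_names_:
            yv = Y[name].to_numpy(dtype=float)
            if np.ptp(yv) == 0:
                self.constant_outcomes_[name] = float(yv[0])
                continue
            forest = RandomForestRegressor(
                n_estimators=self.n_estimators,
                max_features=mf,
                random_state=rs.randint(2**31),
            )
            self.estimators_[name] = forest.fit(X, yv)
        return self

    def predict(self, X) -> pd.DataFrame:
        check_is_fitted(self, "outcome_names_")
        X = np.asarray(X, dtype=float)
        out = {}
        for name in self.outcome_names_:
            if name in self.constant_outcomes_:
                out[name] = np.full(X.shape[0], self.constant_outcomes_[name])
            else:
                out[name] = self.estimators_[name].predict(X)
        return pd.DataFrame(out)


def _design(df: pd.DataFrame, terms) -> np.ndarray:
    """Design matrix from feature names and pairwise-product terms.

    A term is a column name, a tuple of names (elementwise product), or a
    string like ``"A*B"``.
    """
    cols = []
    for t in terms:
        if isinstance(t, str) and "*" in t:
            t = tuple(s.strip() for s in t.split("*"))
        if isinstance(t, tuple):
            v = np.ones(len(df))
            for name in t:
                v = v * df[name].to_numpy(dtype=float)
            cols.append(v)
        else:
            cols.append(df[t].to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_predict_rf(train, test, outcomes, features=None, n_estimators=500, seed=None):
    """Fit per-outcome regression forests on ``train``; predict on ``test``.

    ``train``/``test`` are DataFrames holding both the predictor columns and
    the outcome columns. Returns a DataFrame of continuous predictions (one
    column per outcome), indexed like ``test``.
    """
    features = FEATURE_NAMES if features is None else features
    model = MultiOutcomeForest(n_estimators=n_estimators, random_state=seed)
    model.fit(train[features], train[list(outcomes)])
    pred = model.predict(test[features])
    pred.index = test.index
    return pred


def fit_predict_gbm(
    train,
    test,
    outcome,
    features=None,
    n_estimators=1000,
    max_depth=3,
    learning_rate=0.01,
    seed=None,
):
    """Gradient boosting (Bernoulli deviance) scores for one binary outcome."""
    features = FEATURE_NAMES if features is None else features
    y = train[outcome].to_numpy()
    if np.ptp(y) == 0:
        return pd.Series(np.full(len(test), float(y[0])), index=test.index, name=outcome)
    gbm = GradientBoostingClassifier(
        loss="log_loss",
        n_estimators=n_estimators,
        max_depth=max_depth,
        learning_rate=learning_rate,
        random_state=seed,
    )
    gbm.fit(train[features].to_numpy(dtype=float), y)
    scores = gbm.predict_proba(test[features].to_numpy(dtype=float))[:, 1]
    return pd.Series(scores, index=test.index, name=outcome)


def fit_predict_logistic(train, test, outcome, terms=None, ridge_alpha=1e-6, return_params=False):
    """Maximum-likelihood logistic scores for one binary outcome.

    ``terms`` may include pairwise products (``"A*B"`` or tuples). Complete
    separation or a degenerate design triggers a ridge-penalised fallback
    (penalty weight ``ridge_alpha``) with a warning rather than a failure.
    With ``return_params`` the fitted coefficient vector (intercept first) is
    returned alongside the scores.
    """
    import statsmodels.api as sm

    terms = FEATURE_NAMES if terms is None else terms
    y = train[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        scores = pd.Series(np.full(len(test), float(y[0])), index=test.index, name=outcome)
        return (scores, None) if return_params else scores
    Xtr = _design(train, terms)
    Xte = _design(test, terms)

    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, sm.add_constant(Xtr, has_constant="add")).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.all(np.isfinite(res.params)):
                params = np.asarray(res.params)
        except Exception:
            params = None
    if params is not None:
        eta = sm.add_constant(Xte, has_constant="add") @ params
        scores = 1.0 / (1.0 + np.exp(-eta))
    else:
        warnings.warn("logistic MLE failed (separation or degenerate design); using ridge fallback")
        clf = LogisticRegression(C=1.0 / ridge_alpha, max_iter=5000)
        clf.fit(Xtr, y.astype(int))
        scores = clf.predict_proba(Xte)[:, 1]
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    scores = pd.Series(scores, index=test.index, name=outcome)
    return (scores, params) if return_params else scores


# ---------------------------------------------------------------------------
# metrics


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve: P(score+ > score-) + 0.5 P(score+ = score-)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) != 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, scores))


def r_squared(actual, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (can be negative)."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.size < 2:
        raise ValueError("need at least 2 values")
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("actual values are constant; R^2 undefined")
    ss_res = float(np.sum((actual - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# repeated evaluation


@dataclass
class OutcomeSummary:
    metric: str  # "auc" or "r2"
    mean: float
    min: float
    max: float
    n_repeats: int
    values: list[float] = field(repr=False, default_factory=list)


@dataclass
class EvaluationResult:
    """Per-outcome test-set metrics with repeat ranges and last-repeat predictions."""

    model: str
    summaries: dict[str, OutcomeSummary]
    predictions: pd.DataFrame  # last repeat: actual + predicted per test sample

    def to_json_dict(self) -> dict:
        return {
            name: {
                "metric": s.metric,
                "mean": s.mean,
                "min": s.min,
                "max": s.max,
                "n_repeats": s.n_repeats,
            }
            for name, s in self.summaries.items()
        }


def _is_binary(series: pd.Series) -> bool:
    vals = set(pd.unique(series.dropna()))
    return vals <= {0, 1, 0.0, 1.0} and len(vals) == 2


def repeat_evaluate(
    table: pd.DataFrame,
    model: str,
    outcomes,
    n_repeats: int = 300,
    seed: int | None = None,
    features=None,
    stratify_col: str = "mix_index",
    **model_kw,
) -> EvaluationResult:
    """Repeated half-split evaluation.

    Each repeat draws a fresh stratified half split (on ``stratify_col`` when
    present), fits the chosen model on the training half and scores the test
    half. Binary outcomes get ROC AUC; continuous ones get R-squared. Fully
    reproducible from ``seed``.

    ``model`` is one of ``"rf"`` (all outcomes at once), ``"gbm"`` or ``"lr"``
    (binary outcomes only).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if model not in ("rf", "gbm", "lr"):
        raise ValueError(f"unknown model {model!r}")
    features = FEATURE_NAMES if features is None else features
    outcomes = list(outcomes)
    rng = np.random.default_rng(seed)
    strat = table[stratify_col].to_numpy() if stratify_col in table.columns else None

    collected: dict[str, list[float]] = {o: [] for o in outcomes}
    metric_kind: dict[str, str] = {o: ("auc" if _is_binary(table[o]) else "r2") for o in outcomes}
    predictions = None

    for _ in range(n_repeats):
        split_seed = int(rng.integers(2**31))
        fit_seed = int(rng.integers(2**31))
        train, test = split_half(table, stratify=strat, seed=split_seed)

        if model == "rf":
            pred = fit_predict_rf(train, test, outcomes, features=features, seed=fit_seed, **model_kw)
        else:
            cols = {}
            for o in outcomes:
                if metric_kind[o] != "auc":
                    raise ValueError(f"model {model!r} handles binary outcomes only; {o!r} is continuous")
                if model == "gbm":
                    cols[o] = fit_predict_gbm(train, test, o, features=features, seed=fit_seed, **model_kw)
                else:
                    cols[o] = fit_predict_logistic(train, test, o, terms=model_kw.get("terms", features))
            pred = pd.DataFrame(cols)

        for o in outcomes:
            actual = test[o]
            if metric_kind[o] == "auc":
                if actual.nunique() < 2 or np.ptp(train[o].to_numpy()) == 0:
                    continue  # degenerate half for this outcome: skip repeat
                collected[o].append(roc_auc(pred[o], actual))
            else:
                if actual.nunique() < 2:
                    continue
                collected[o].append(r_squared(actual, pred[o]))

        predictions = pd.concat(
            [test[outcomes].add_prefix("actual_"), pred.add_prefix("pred_")], axis=1
        )

    summaries = {}
    for o in outcomes:
        vals = collected[o]
        if not vals:
            summaries[o] = OutcomeSummary(metric_kind[o], float("nan"), float("nan"), float("nan"), 0)
        else:
            summaries[o] = OutcomeSummary(
                metric_kind[o],
                float(np.mean(vals)),
                float(np.min(vals)),
                float(np.max(vals)),
                len(vals),
                list(vals),
            )
    return EvaluationResult(model=model, summaries=summaries, predictions=predictions)


# ---------------------------------------------------------------------------
# photon-equivalent dose / RBE fit


@dataclass
class RBEFitResult:
    rbe_grid: np.ndarray
    score_profile: np.ndarray  # mean test R^2 per candidate RBE
    best_rbe: float
    unidentifiable: bool

    def to_json_dict(self) -> dict:
        return {
            "rbe_grid": [float(r) for r in self.rbe_grid],
            "score_profile": [float(s) for s in self.score_profile],
            "best_rbe": float(self.best_rbe),
            "unidentifiable": bool(self.unidentifiable),
        }


class PhotonEquivalentDoseFitter(BaseEstimator):
    """Estimate the neutron RBE by scanning the photon-equivalent dose scale.

    For each candidate RBE the regression target is
    ``photon_dose + RBE * neutron_dose``; a random forest is trained on the
    shape predictors over repeated half splits and the mean test R-squared is
    recorded. The candidate with the highest mean R-squared (ties broken
    toward the smaller RBE) is the best-fit RBE: the dose scale on which the
    biological signal is most coherent.

    ``fit(X, y)`` takes the predictor matrix and ``y`` of shape (n, 2) with
    columns (photon dose, neutron dose). Splits are shared across candidates
    so the profile comparison is paired. If every neutron dose is zero the
    target does not depend on RBE, the profile is exactly flat, and
    ``unidentifiable_`` is set.
    """

    def __init__(self, rbe_grid=None, n_repeats=10, n_estimators=200, random_state=None):
        self.rbe_grid = rbe_grid
        self.n_repeats = n_repeats
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must have two columns: photon dose, neutron dose")
        grid = np.arange(1.0, 8.0 + 1e-9, 0.1) if self.rbe_grid is None else np.asarray(self.rbe_grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("rbe_grid must be strictly increasing")
        photon, neutron = y[:, 0], y[:, 1]
        rng = np.random.default_rng(self.random_state)

        scores = np.zeros((self.n_repeats, len(grid)))
        idx = np.arange(len(X))
        for rep in range(self.n_repeats):
            split_seed = int(rng.integers(2**31))
            fit_seed = int(rng.integers(2**31))
            tr, te = split_half(idx, seed=split_seed)
            tr, te = np.asarray(tr), np.asarray(te)
            for j, rbe in enumerate(grid):
                target = photon + rbe * neutron
                forest = RandomForestRegressor(
                    n_estimators=self.n_estimators,
                    max_features=max(1, math.ceil(X.shape[1] / 3)),
                    random_state=fit_seed,
                )
                forest.fit(X[tr], target[tr])
                scores[rep, j] = r_squared(target[te], forest.predict(X[te]))

        self.rbe_grid_ = grid
        self.score_profile_ = scores.mean(axis=0)
        self.unidentifiable_ = bool(np.all(neutron == 0) or np.ptp(self.score_profile_) < 1e-9)
        self.best_rbe_ = float(grid[int(np.argmax(self.score_profile_))])
        return self

    def result(self) -> RBEFitResult:
        check_is_fitted(self, "best_rbe_")
        return RBEFitResult(self.rbe_grid_, self.score_profile_, self.best_rbe_, self.unidentifiable_)


def fit_rbe(
    table: pd.DataFrame,
    rbe_grid=None,
    n_repeats: int = 10,
    seed: int | None = None,
    features=None,
    n_estimators: int = 200,
) -> RBEFitResult:
    """Adjustable-RBE photon-equivalent-dose fit on a features+doses table."""
    features = FEATURE_NAMES if features is None else features
    fitter = PhotonEquivalentDoseFitter(
        rbe_grid=rbe_grid, n_repeats=n_repeats, n_estimators=n_estimators, random_state=seed
    )
    fitter.fit(
        table[features].to_numpy(dtype=float),
        table[["photon_dose_gy", "neutron_dose_gy"]].to_numpy(dtype=float),
    )
    return fitter.result()


# ---------------------------------------------------------------------------
# correlations and predictor reduction


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlations and uncorrected p-values.

    Constant columns give undefined correlations, reported as NaN. The
    correlation matrix is symmetric with unit diagonal (where defined).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 samples")
    arr = table.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.spearmanr(arr, axis=0)
        rho = np.atleast_2d(res.statistic)
        pval = np.atleast_2d(res.pvalue)
        if rho.shape == (1, 1):  # scipy collapses the two-column case to a scalar
            r, p = float(rho[0, 0]), float(pval[0, 0])
            rho = np.array([[1.0, r], [r, 1.0]])
            pval = np.array([[np.nan, p], [p, np.nan]])
    constant = np.ptp(arr, axis=0) == 0
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    pval[constant, :] = np.nan
    pval[:, constant] = np.nan
    for i in np.flatnonzero(~constant):
        rho[i, i] = 1.0
        pval[i, i] = np.nan
    cols = list(table.columns)
    return pd.DataFrame(rho, index=cols, columns=cols), pd.DataFrame(pval, index=cols, columns=cols)


def backward_eliminate(
    train: pd.DataFrame,
    outcome: str,
    model: str = "gbm",
    features=None,
    cv: int = 5,
    seed: int | None = None,
    n_estimators: int = 200,
) -> list[str]:
    """Greedy backward elimination on cross-validated AUC within the training half.

    Starting from the full predictor set, repeatedly drop the predictor whose
    removal gives the best (non-decreasing) cross-validated AUC; stop when
    every removal hurts. Returns the retained predictors.
    """
    features = list(FEATURE_NAMES if features is None else features)
    y = train[outcome].to_numpy(dtype=int)

    def cv_auc(feats):
        X = train[list(feats)].to_numpy(dtype=float)
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        aucs = []
        for tr, te in skf.split(X, y):
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            if model == "gbm":
                est = GradientBoostingClassifier(
                    n_estimators=n_estimators, max_depth=3, learning_rate=0.01, random_state=seed
                )
            else:
                est = LogisticRegression(C=1e6, max_iter=5000)
            est.fit(X[tr], y[tr])
            aucs.append(roc_auc(est.predict_proba(X[te])[:, 1], y[te]))
        return float(np.mean(aucs)) if aucs else float("nan")

    current = list(features)
    best = cv_auc(current)
    while len(current) > 1:
        candidates = [(cv_auc([f for f in current if f != drop]), drop) for drop in current]
        cand_best, drop = max(candidates, key=lambda t: t[0])
        if math.isnan(cand_best) or cand_best < best:
            break
        best = cand_best
        current = [f for f in current if f != drop]
    return current
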