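"""Cross-validated stacked ensemble (Super Learner) for nuisance estimation.

Base learners implement a minimal fit/predict contract (conditional means;
probabilities in [0, 1] for the binary family) and are combined by a convex
meta-learner: non-negative least squares on held-out predictions,
renormalised to the simplex, with a candidate-set safeguard so the
ensemble's cross-validated risk never exceeds the best single learner's.

The stock library mirrors the four standard archetypes for this kind of
workflow — an adaptive spline regression, an L1-penalised GLM (lasso), a
GLM with main terms and two-way interactions, and gradient boosting — plus
a mean-only learner and a plain GLM for fast configurations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import nnls
from sklearn.linear_model import LinearRegression, LogisticRegression, LassoCV, LogisticRegressionCV
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.linear_model import Ridge

logger = logging.getLogger(__name__)

_EPS_DEFAULT = 1e-3


class LearnerError(RuntimeError):
    """Raised when no base learner could be fit."""


# ---------------------------------------------------------------------------
# base learners


class _MeanLearner:
    """Marginal mean (continuous) or base rate (binary)."""

    def fit(self, X, y):
        self.value_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.value_)


class _SKContinuous:
    def __init__(self, factory):
        self._factory = factory

    def fit(self, X, y):
        self.model_ = self._factory()
        self.model_.fit(X, y)
        return self

    def predict(self, X):
        return np.asarray(self.model_.predict(X), dtype=float)


class _SKBinary:
    """Wraps a sklearn classifier; predicts P(y=1)."""

    def __init__(self, factory):
        self._factory = factory

    def fit(self, X, y):
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("constant binary outcome; classifier undefined")
        self.model_ = self._factory()
        self.model_.fit(X, y.astype(int))
        return self

    def predict(self, X):
        return np.asarray(self.model_.predict_proba(X)[:, 1], dtype=float)


@dataclass(frozen=True)
class LearnerSpec:
    """A named base learner: ``make()`` returns a fresh fit/predict object."""

    name: str
    family: str  # {"continuous", "binary"}
    make: Callable[[], object]


def _interaction_glm_continuous():
    return make_pipeline(
        PolynomialFeatures(degree=2, interaction_only=True, include_bias=False),
        LinearRegression(),
    )


def _interaction_glm_binary():
    return make_pipeline(
        PolynomialFeatures(degree=2, interaction_only=True, include_bias=False),
        StandardScaler(),
        LogisticRegression(C=np.inf, max_iter=2000),
    )


def _spline_continuous():
    return make_pipeline(SplineTransformer(n_knots=5, degree=3), Ridge(alpha=1.0))


def _spline_binary():
    return make_pipeline(
        SplineTransformer(n_knots=5, degree=3),
        LogisticRegression(max_iter=2000, C=10.0),
    )


def _lasso_continuous():
    return make_pipeline(StandardScaler(), LassoCV(cv=10, alphas=30, random_state=0))


def _lasso_binary():
    return make_pipeline(
        StandardScaler(),
        LogisticRegressionCV(Cs=10, cv=10, l1_ratios=(1.0,), solver="saga",
                             max_iter=500, random_state=0),
    )


def _gbm_continuous():
    import lightgbm as lgb

    return lgb.LGBMRegressor(verbosity=-1, random_state=0)


def _gbm_binary():
    import lightgbm as lgb

    class _P:
        def fit(s, X, y):
            s.m = lgb.LGBMClassifier(verbosity=-1, random_state=0)
            s.m.fit(X, y)
            return s

        def predict_proba(s, X):
            return s.m.predict_proba(X)

    return _P()


_REGISTRY: dict[tuple[str, str], Callable[[], object]] = {
    ("mean", "continuous"): lambda: _MeanLearner(),
    ("mean", "binary"): lambda: _MeanLearner(),
    ("glm", "continuous"): lambda: _SKContinuous(LinearRegression),
    ("glm", "binary"): lambda: _SKBinary(lambda: LogisticRegression(C=np.inf, max_iter=2000)),
    ("glm_interactions", "continuous"): lambda: _SKContinuous(_interaction_glm_continuous),
    ("glm_interactions", "binary"): lambda: _SKBinary(_interaction_glm_binary),
    ("lasso", "continuous"): lambda: _SKContinuous(_lasso_continuous),
    ("lasso", "binary"): lambda: _SKBinary(_lasso_binary),
    ("spline", "continuous"): lambda: _SKContinuous(_spline_continuous),
    ("spline", "binary"): lambda: _SKBinary(_spline_binary),
    ("gbm", "continuous"): lambda: _SKContinuous(_gbm_continuous),
    ("gbm", "binary"): lambda: _SKBinary(_gbm_binary),
}

#: Named library presets.  "default" mirrors the four-archetype stacking
#: library; "glmnet" is the no-stacking sensitivity mode (lasso alone);
#: "fast" is a plain GLM for large simulation studies.
LIBRARIES: dict[str, tuple[str, ...]] = {
    "default": ("spline", "lasso", "glm_interactions", "gbm"),
    "glmnet": ("lasso",),
    "fast": ("glm",),
    "fast_stack": ("glm", "mean"),
}


def get_learner(name: str, family: str) -> LearnerSpec:
    try:
        factory = _REGISTRY[(name, family)]
    except KeyError:
        raise KeyError(f"unknown learner {name!r} for family {family!r}") from None
    return LearnerSpec(name=name, family=family, make=factory)


def resolve_library(library: Sequence[str | LearnerSpec] | str, family: str) -> list[LearnerSpec]:
    if isinstance(library, str):
        library = LIBRARIES[library]
    return [get_learner(l, family) if isinstance(l, str) else l for l in library]


# ---------------------------------------------------------------------------
# folds


def make_folds(
    n: int,
    K: int,
    stratify_labels: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Fold assignment in ``{0..K-1}`` with fold sizes differing by at most
    one, and — under stratification — each label's per-fold counts differing
    by at most one.

    Implemented as a single cyclic deal over shuffled label groups: the deal
    pointer continues across groups, so both the per-label and the overall
    balance constraints hold simultaneously.  A stratum smaller than ``K``
    cannot appear in every fold; it is spread over a random subset of folds
    (and a warning is logged), which is the unstratified behaviour for that
    stratum.
    """
    if not 2 <= K <= n:
        raise ValueError(f"need 2 <= K <= n (got K={K}, n={n})")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=np.int64)
    fold_order = rng.permutation(K)
    if stratify_labels is None:
        groups = [np.arange(n)]
    else:
        labels = np.asarray(stratify_labels)
        if labels.shape[0] != n:
            raise ValueError("stratify_labels length must equal n")
        uniq = np.unique(labels)
        groups = [np.flatnonzero(labels == u) for u in uniq]
        for u, g in zip(uniq, groups):
            if g.size < K:
                logger.warning(
                    "stratum %r has %d members (< K=%d); falling back to unstratified assignment for it",
                    u, g.size, K,
                )
    ptr = 0
    for g in groups:
        g = rng.permutation(g)
        folds[g] = fold_order[(ptr + np.arange(g.size)) % K]
        ptr += g.size
    return folds


# ---------------------------------------------------------------------------
# super learner


@dataclass
class SLFit:
    """A fitted Super Learner.

    ``weights`` lie on the simplex; ``cv_risks`` are per-learner
    cross-validated risks (MSE for the continuous family, mean negative
    log-likelihood for binary); ``ensemble_cv_risk`` never exceeds
    ``min(cv_risks) + 1e-8``.
    """

    learner_names: list[str]
    family: str
    weights: np.ndarray
    cv_risks: np.ndarray
    ensemble_cv_risk: float
    folds: np.ndarray
    full_fits: list[object]
    dropped: list[str]
    clip_eps: float
    n_features: int

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        assert np.all(w >= -1e-12) and abs(w.sum() - 1.0) < 1e-8, "meta-weights must be convex"
        assert self.ensemble_cv_risk <= float(np.min(self.cv_risks)) + 1e-8, (
            "ensemble CV risk exceeds best single learner"
        )


def _clip01(p: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def _risk(y: np.ndarray, pred: np.ndarray, family: str, eps: float) -> float:
    if family == "binary":
        p = _clip01(pred, eps)
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))
    return float(np.mean((y - pred) ** 2))


def fit_superlearner(
    X,
    y,
    library: Sequence[str | LearnerSpec] | str = "default",
    K: int = 10,
    family: str = "continuous",
    seed: int = 0,
    clip_eps: float = _EPS_DEFAULT,
    folds: np.ndarray | None = None,
) -> SLFit:
    """Fit the stacked ensemble.

    Held-out predictions for every base learner are assembled over ``K``
    folds (stratified on ``y`` for the binary family); convex meta-weights
    are chosen by NNLS against the held-out predictions, renormalised, and
    compared on cross-validated risk against every single-learner vertex —
    the risk minimiser wins, with ties broken toward the NNLS stack and then
    toward earlier learners in library order.  Learners that fail to fit on
    any fold are dropped with a warning.  Base learners are refit on the
    full data for prediction (:func:`sl_predict`).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("X and y must be complete (no missing values)")
    if family not in ("continuous", "binary"):
        raise ValueError(f"unknown family {family!r}")
    n = X.shape[0]
    specs = resolve_library(library, family)
    if not specs:
        raise LearnerError("empty learner library")

    if folds is None:
        strat = y.astype(int) if family == "binary" else None
        folds = make_folds(n, min(K, n), stratify_labels=strat, seed=seed)
    K_eff = int(folds.max()) + 1

    Z = np.full((n, len(specs)), np.nan)
    ok = np.ones(len(specs), dtype=bool)
    for j, spec in enumerate(specs):
        try:
            for k in range(K_eff):
                tr, te = folds != k, folds == k
                Z[te, j] = spec.make().fit(X[tr], y[tr]).predict(X[te])
            if not np.all(np.isfinite(Z[:, j])):
                raise ValueError("non-finite held-out predictions")
        except Exception as err:  # noqa: BLE001 - drop-and-warn policy
            ok[j] = False
            logger.warning("dropping learner %r: %s", spec.name, err)
    if not ok.any():
        raise LearnerError("all base learners failed")
    dropped = [s.name for s, keep in zip(specs, ok) if not keep]
    specs = [s for s, keep in zip(specs, ok) if keep]
    Z = Z[:, ok]

    cv_risks = np.array([_risk(y, Z[:, j], family, clip_eps) for j in range(Z.shape[1])])
    L = Z.shape[1]

    if L == 1:
        weights = np.array([1.0])
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                w, _ = nnls(Z, y)
            except Exception:
                w = np.zeros(L)
        if w.sum() <= 0:
            w = np.zeros(L)
            w[int(np.argmin(cv_risks))] = 1.0
        w = w / w.sum()
        # candidate set: NNLS stack first (preferred on ties), then vertices
        # in library order
        candidates = [w] + [np.eye(L)[j] for j in range(L)]
        risks = np.array([_risk(y, Z @ c, family, clip_eps) for c in candidates])
        best = int(np.flatnonzero(risks <= risks.min() + 1e-12)[0])
        weights = candidates[best]

    ensemble_cv_risk = _risk(y, Z @ weights, family, clip_eps)
    full_fits = [spec.make().fit(X, y) for spec in specs]
    return SLFit(
        learner_names=[s.name for s in specs],
        family=family,
        weights=weights,
        cv_risks=cv_risks,
        ensemble_cv_risk=ensemble_cv_risk,
        folds=folds,
        full_fits=full_fits,
        dropped=dropped,
        clip_eps=clip_eps,
        n_features=X.shape[1],
    )


def sl_predict(fit: SLFit, X) -> np.ndarray:
    """Weighted combination of the full-data base-learner refits; binary
    output clipped to ``[eps, 1-eps]``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != fit.n_features:
        raise ValueError(f"expected {fit.n_features} feature columns, got {X.shape[1]}")
    pred = np.zeros(X.shape[0])
    for w, m in zip(fit.weights, fit.full_fits):
        if w != 0.0:
            pred += w * m.predict(X)
    if fit.family == "binary":
        pred = _clip01(pred, fit.clip_eps)
    return pred
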