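"""One-step efficient estimators of total, natural direct and indirect effects.

Estimands (binary exposure ``A``, mediator ``M``, confounders ``W``, outcome
``Y``), written through the counterfactual means ``psi(a, a') =
E[Y(a, M(a'))]``:

* ``NDE = psi(1, 0) - psi(0, 0)`` — effect through all paths not involving
  the mediator;
* ``NIE = psi(1, 1) - psi(1, 0)`` — effect transmitted through the mediator;
* ``TE  = psi(1, 1) - psi(0, 0) = NDE + NIE``.

Each counterfactual mean is estimated by the one-step estimator: the sample
mean of the (uncentered) efficient influence function evaluated at estimated
nuisances,

``D = 1{A=a}/g(a|W) * r(M, W) * (Y - mu(a, M, W))
    + 1{A=a'}/g(a'|W) * (mu(a, M, W) - eta(a'; a, W))
    + eta(a'; a, W)``,

where ``g`` is the exposure propensity, ``mu(a, m, w) = E[Y|A=a, M=m, W=w]``,
``eta(a'; a, w) = E[mu(a, M, W) | A=a', W=w]`` and the mediator density
ratio is handled through the Bayes propensity-ratio reparameterisation
``r = [e(a'|M,W)/e(a|M,W)] * [g(a|W)/g(a'|W)]`` with the
mediator-conditional propensity ``e(a|m,w) = P(A=a|M=m,W=w)`` — avoiding
conditional density estimation for the continuous mediator.  ``r`` is
identically 1 when ``a = a'``, in which case the estimator reduces to AIPW
for ``E[Y(a)]``.

Standard errors come from the sample variance of the influence values
(Wald inference); with cross-fitting (default) every subject's nuisance
predictions come from fits that exclude that subject's fold, which is what
licenses Wald intervals around adaptively estimated nuisances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from medscreen.learners import fit_superlearner, make_folds, sl_predict

logger = logging.getLogger(__name__)

Z975 = float(stats.norm.ppf(0.975))


class EstimationError(RuntimeError):
    """Raised when an effect cannot be estimated on the given cohort."""


@dataclass
class EffectEstimate:
    """One estimand's point estimate with influence-function inference."""

    estimand: str
    point: float
    eif_values: np.ndarray  # centered influence values, one per subject
    se: float
    ci95: tuple[float, float]
    z: float
    p: float
    n_used: int


@dataclass
class NuisanceFits:
    """Per-subject nuisance predictions aligned with the estimation sample.

    ``g1``/``e1`` are (truncated) probabilities ``P(A=1|W)`` and
    ``P(A=1|M,W)``; ``mu[a]`` is ``E[Y|A=a, M_i, W_i]``; ``eta[(a, ap)]`` is
    ``E[mu(a, M, W)|A=ap, W_i]``; ``b[a]`` is ``E[Y|A=a, W_i]`` (used by the
    AIPW total-effect estimator).  ``A`` and ``y`` are the observed exposure
    and outcome, so estimation needs no further access to the cohort.
    """

    A: np.ndarray
    y: np.ndarray
    g1: np.ndarray
    e1: np.ndarray
    mu: dict = field(default_factory=dict)
    eta: dict = field(default_factory=dict)
    b: dict = field(default_factory=dict)
    folds: np.ndarray | None = None
    delta: float = 0.025

    @property
    def n(self) -> int:
        return int(self.A.shape[0])


def wald_inference(point: float, eif_values: np.ndarray) -> tuple[float, tuple[float, float], float, float]:
    """Wald inference from centered influence values.

    ``se = sd(eif, ddof=1)/sqrt(n)``; two-sided p from the standard normal.
    Constant influence values yield ``se = 0`` and a degenerate-inference
    warning, with p reported as 0.
    """
    eif_values = np.asarray(eif_values, dtype=float)
    n = eif_values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 influence values for Wald inference")
    se = float(np.std(eif_values, ddof=1) / np.sqrt(n))
    if se == 0.0:
        logger.warning("degenerate inference: influence values constant (se = 0)")
        z = 0.0 if point == 0.0 else float(np.sign(point)) * np.inf
        p = 1.0 if point == 0.0 else 0.0
    else:
        z = point / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    ci = (point - Z975 * se, point + Z975 * se)
    return se, ci, z, p


def _estimate_from_uncentered(estimand: str, D: np.ndarray) -> EffectEstimate:
    point = float(np.mean(D))
    eif = D - point
    se, ci, z, p = wald_inference(point, eif)
    return EffectEstimate(estimand, point, eif, se, ci, z, p, D.shape[0])


# ---------------------------------------------------------------------------
# nuisance fitting


def _truncate(p: np.ndarray, delta: float) -> np.ndarray:
    return np.clip(p, delta, 1.0 - delta)


def _saturated_nuisances(W, A, M, y, delta):
    """Exact empirical-frequency (NPMLE) nuisances for all-discrete data.

    Keys cells by the tuple of discrete values; every required cell must be
    populated.  At these nuisances the one-step correction averages to zero
    and the estimator coincides with nonparametric g-computation.
    """
    n = A.shape[0]
    Wkey = [tuple(row) for row in np.atleast_2d(np.asarray(W, dtype=float))]
    Mkey = np.asarray(M, dtype=float)

    def cell_mean(values, keys):
        df = pd.DataFrame({"v": values, "k": keys})
        return df.groupby("k", sort=False)["v"].transform("mean").to_numpy()

    g1 = cell_mean(A.astype(float), pd.Series(Wkey))
    wm_key = pd.Series([w + (m,) for w, m in zip(Wkey, Mkey)])
    e1 = cell_mean(A.astype(float), wm_key)

    w_series = pd.Series(Wkey)
    mu = {}
    for a in (0, 1):
        sub = A == a
        if not sub.any():
            raise EstimationError(f"saturated fit: no subjects with A={a}")
        tab = pd.Series(y[sub]).groupby(wm_key[sub].to_numpy()).mean()
        mapped = wm_key.map(tab)
        if mapped.isna().any():
            raise EstimationError(f"saturated fit: empty (W,M) cells for A={a}")
        mu[a] = mapped.to_numpy(dtype=float)

    eta, b = {}, {}
    for a in (0, 1):
        for ap in (0, 1):
            sub = A == ap
            tab = pd.Series(mu[a][sub]).groupby(w_series[sub].to_numpy()).mean()
            mapped = w_series.map(tab)
            if mapped.isna().any():
                raise EstimationError(f"saturated fit: empty W cells for A={ap}")
            eta[(a, ap)] = mapped.to_numpy(dtype=float)
        sub = A == a
        tab = pd.Series(y[sub]).groupby(w_series[sub].to_numpy()).mean()
        b[a] = w_series.map(tab).to_numpy(dtype=float)

    return NuisanceFits(
        A=A, y=y, g1=_truncate(g1, delta), e1=_truncate(e1, delta),
        mu=mu, eta=eta, b=b, folds=np.zeros(n, dtype=np.int64), delta=delta,
    )


def fit_nuisances(
    cohort: pd.DataFrame,
    trait: str,
    mediator: str,
    confounders: list[str],
    library="fast",
    K: int = 5,
    seed: int = 0,
    cross_fit: bool = True,
    delta: float = 0.025,
    saturated: bool = False,
    stratum: str = "combined",
    eta_pairs: tuple[tuple[int, int], ...] = ((1, 1), (1, 0), (0, 0)),
    fit_b: bool = True,
) -> NuisanceFits:
    """Fit all nuisance functions on a complete-case cohort.

    With ``cross_fit`` on (default) predictions for each subject come from
    Super Learners trained on the other ``K - 1`` folds; fold assignment is
    stratified on the exposure.  ``g`` and ``e`` are truncated to
    ``[delta, 1 - delta]``.  ``saturated=True`` switches to exact empirical
    conditional frequencies (all variables must be discrete), the oracle
    regime in which the one-step equals g-computation.
    """
    fits = fit_nuisances_multi(
        cohort, [trait], mediator, confounders, library=library, K=K, seed=seed,
        cross_fit=cross_fit, delta=delta, saturated=saturated, stratum=stratum,
        eta_pairs=eta_pairs, fit_b=fit_b,
    )
    return fits[trait]


def fit_nuisances_multi(
    cohort: pd.DataFrame,
    traits: list[str],
    mediator: str,
    confounders: list[str],
    library="fast",
    K: int = 5,
    seed: int = 0,
    cross_fit: bool = True,
    delta: float = 0.025,
    saturated: bool = False,
    stratum: str = "combined",
    eta_pairs: tuple[tuple[int, int], ...] = ((1, 1), (1, 0), (0, 0)),
    fit_b: bool = True,
) -> dict[str, NuisanceFits]:
    """As :func:`fit_nuisances`, for several traits over one complete-case
    sample: the exposure propensities ``g`` and ``e`` depend only on
    ``(A, M, W)`` and are fit once per fold, shared across traits."""
    cols = [*confounders, "A", mediator, *traits]
    sub = cohort.loc[:, cols]
    if sub.isna().any().any():
        raise EstimationError("cohort must be complete-case filtered before nuisance fitting")
    W = sub[confounders].to_numpy(dtype=float)
    A = sub["A"].to_numpy(dtype=np.int64)
    M = sub[mediator].to_numpy(dtype=float)
    n = A.shape[0]
    if (A == 1).sum() == 0:
        raise EstimationError(f"stratum {stratum!r}: no cases (A=1)")
    if (A == 0).sum() == 0:
        raise EstimationError(f"stratum {stratum!r}: no controls (A=0)")
    ys = {t: sub[t].to_numpy(dtype=float) for t in traits}

    if saturated:
        return {t: _saturated_nuisances(W, A, M, y, delta) for t, y in ys.items()}

    MW = np.column_stack([M, W])
    if cross_fit:
        folds = make_folds(n, min(K, n), stratify_labels=A, seed=seed)
    else:
        folds = np.zeros(n, dtype=np.int64)
    K_eff = int(folds.max()) + 1

    g1 = np.empty(n)
    e1 = np.empty(n)
    mu = {t: {0: np.empty(n), 1: np.empty(n)} for t in traits}
    eta = {t: {pair: np.empty(n) for pair in eta_pairs} for t in traits}
    b = {t: ({0: np.empty(n), 1: np.empty(n)} if fit_b else {}) for t in traits}
    mu_arms = sorted({a for a, _ in eta_pairs} | ({0, 1} if fit_b else set()))

    for k in range(K_eff):
        tr = folds != k if cross_fit else np.ones(n, dtype=bool)
        te = folds == k if cross_fit else np.ones(n, dtype=bool)
        s = seed + 1000 * k + 1

        g_fit = fit_superlearner(W[tr], A[tr].astype(float), library, K, "binary", seed=s)
        g1[te] = sl_predict(g_fit, W[te])
        e_fit = fit_superlearner(MW[tr], A[tr].astype(float), library, K, "binary", seed=s + 1)
        e1[te] = sl_predict(e_fit, MW[te])

        for a in mu_arms:
            if (tr & (A == a)).sum() < 2:
                raise EstimationError(f"stratum {stratum!r}: too few A={a} subjects in a training fold")

        for ti, t in enumerate(traits):
            y = ys[t]
            st = s + 100 * ti
            mu_tr = {}
            for a in mu_arms:
                arm = tr & (A == a)
                m_fit = fit_superlearner(MW[arm], y[arm], library, K, "continuous", seed=st + 2 + a)
                mu[t][a][te] = sl_predict(m_fit, MW[te])
                mu_tr[a] = sl_predict(m_fit, MW[tr])

            for a, ap in eta_pairs:
                arm = (A == ap)[tr]
                pseudo = mu_tr[a][arm]
                e_fit2 = fit_superlearner(W[tr][arm], pseudo, library, K, "continuous", seed=st + 10 + 2 * a + ap)
                eta[t][(a, ap)][te] = sl_predict(e_fit2, W[te])

            if fit_b:
                for a in (0, 1):
                    arm = tr & (A == a)
                    b_fit = fit_superlearner(W[arm], y[arm], library, K, "continuous", seed=st + 20 + a)
                    b[t][a][te] = sl_predict(b_fit, W[te])

    g1 = _truncate(g1, delta)
    e1 = _truncate(e1, delta)
    return {
        t: NuisanceFits(A=A, y=ys[t], g1=g1, e1=e1, mu=mu[t], eta=eta[t], b=b[t],
                        folds=folds, delta=delta)
        for t in traits
    }


# ---------------------------------------------------------------------------
# estimators


def _uncentered_eif_psi(nuis: NuisanceFits, a: int, ap: int) -> np.ndarray:
    A, y = nuis.A, nuis.y
    g_a = nuis.g1 if a == 1 else 1.0 - nuis.g1
    g_ap = nuis.g1 if ap == 1 else 1.0 - nuis.g1
    if np.any(g_a <= 0) or np.any(g_ap <= 0):
        raise EstimationError("zero propensity encountered; truncation should prevent this")
    mu_a = nuis.mu[a]
    eta_ap = nuis.eta[(a, ap)]
    if a == ap:
        r = 1.0
    else:
        e_a = nuis.e1 if a == 1 else 1.0 - nuis.e1
        e_ap = nuis.e1 if ap == 1 else 1.0 - nuis.e1
        if np.any(e_a <= 0):
            raise EstimationError("zero mediator-conditional propensity; truncation should prevent this")
        r = (e_ap / e_a) * (g_a / g_ap)
    return (
        (A == a) / g_a * r * (y - mu_a)
        + (A == ap) / g_ap * (mu_a - eta_ap)
        + eta_ap
    )


def counterfactual_mean_onestep(a: int, ap: int, nuisances: NuisanceFits) -> EffectEstimate:
    """One-step estimate of ``psi(a, a') = E[Y(a, M(a'))]``."""
    if a not in (0, 1) or ap not in (0, 1):
        raise ValueError("a and a' must be 0 or 1")
    D = _uncentered_eif_psi(nuisances, a, ap)
    return _estimate_from_uncentered(f"psi({a},{ap})", D)


def _contrast(name: str, hi: EffectEstimate, lo: EffectEstimate) -> EffectEstimate:
    point = hi.point - lo.point
    eif = hi.eif_values - lo.eif_values
    se, ci, z, p = wald_inference(point, eif)
    return EffectEstimate(name, point, eif, se, ci, z, p, hi.n_used)


def estimate_nde_nie(nuisances: NuisanceFits) -> tuple[EffectEstimate, EffectEstimate, EffectEstimate]:
    """NDE, NIE and the mediation-formula total effect from shared nuisances.

    The three estimates share ``psi(1, 0)``, so the decomposition identity
    ``NDE + NIE = TE`` holds to floating-point rounding on any input.
    """
    psi11 = counterfactual_mean_onestep(1, 1, nuisances)
    psi10 = counterfactual_mean_onestep(1, 0, nuisances)
    psi00 = counterfactual_mean_onestep(0, 0, nuisances)
    nde = _contrast("NDE", psi10, psi00)
    nie = _contrast("NIE", psi11, psi10)
    te = _contrast("TE_mediation", psi11, psi00)
    return nde, nie, te


def te_aipw_from_nuisances(nuisances: NuisanceFits) -> EffectEstimate:
    """AIPW (doubly robust one-step) total effect from fitted ``g`` and
    ``b(a, W) = E[Y|A=a, W]``."""
    A, y = nuisances.A, nuisances.y
    g1, g0 = nuisances.g1, 1.0 - nuisances.g1
    b1, b0 = nuisances.b[1], nuisances.b[0]
    b_obs = np.where(A == 1, b1, b0)
    D = (A / g1 - (1 - A) / g0) * (y - b_obs) + b1 - b0
    return _estimate_from_uncentered("TE", D)


def estimate_te_aipw(
    cohort: pd.DataFrame,
    trait: str,
    confounders: list[str],
    library="fast",
    K: int = 5,
    seed: int = 0,
    cross_fit: bool = True,
    delta: float = 0.025,
    stratum: str = "combined",
) -> EffectEstimate:
    """AIPW total effect on the TE-eligible sample (complete cases on
    confounders, exposure and outcome only — the mediator is not required,
    which maximises n)."""
    cols = [*confounders, "A", trait]
    sub = cohort.loc[:, cols].dropna()
    if sub.empty:
        raise EstimationError(f"stratum {stratum!r}: no complete cases for trait {trait!r}")
    W = sub[confounders].to_numpy(dtype=float)
    A = sub["A"].to_numpy(dtype=np.int64)
    y = sub[trait].to_numpy(dtype=float)
    n = A.shape[0]
    if (A == 1).sum() == 0 or (A == 0).sum() == 0:
        raise EstimationError(f"stratum {stratum!r}: need both cases and controls for trait {trait!r}")

    if cross_fit:
        folds = make_folds(n, min(K, n), stratify_labels=A, seed=seed)
    else:
        folds = np.zeros(n, dtype=np.int64)
    K_eff = int(folds.max()) + 1
    g1 = np.empty(n)
    b = {0: np.empty(n), 1: np.empty(n)}
    for k in range(K_eff):
        tr = folds != k if cross_fit else np.ones(n, dtype=bool)
        te = folds == k if cross_fit else np.ones(n, dtype=bool)
        s = seed + 1000 * k + 500
        g_fit = fit_superlearner(W[tr], A[tr].astype(float), library, K, "binary", seed=s)
        g1[te] = sl_predict(g_fit, W[te])
        for a in (0, 1):
            arm = tr & (A == a)
            if arm.sum() < 2:
                raise EstimationError(f"stratum {stratum!r}: too few A={a} subjects in a training fold")
            b_fit = fit_superlearner(W[arm], y[arm], library, K, "continuous", seed=s + 1 + a)
            b[a][te] = sl_predict(b_fit, W[te])
    nuis = NuisanceFits(A=A, y=y, g1=_truncate(g1, delta), e1=np.full(n, 0.5), b=b, folds=folds, delta=delta)
    return te_aipw_from_nuisances(nuis)
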