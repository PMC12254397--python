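"""Synthetic cohorts from a linear structural equation model with known effects.

The generator emulates the structure of a biobank-style mediation study:

* confounders ``W`` = (age, sex) affecting exposure, mediator and outcomes;
* a binary exposure ``A`` (case status) with configurable — typically strong
  — case/control imbalance;
* a non-negative continuous activity mediator ``M`` (minutes/day scale)
  shifted downward in cases;
* many continuous trait outcomes ``Y_t`` with small-to-medium effects;
* MCAR missingness and special questionnaire response codes ("do not know" /
  "prefer not to answer") encoded as negative sentinels in the mediator.

Because the structural model is linear, the true total, natural direct and
natural indirect effect of ``A`` on each trait have closed forms
(``closed_form_effects``); a brute-force counterfactual simulator
(``monte_carlo_effects``) provides an independent route to the same truths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

logger = logging.getLogger(__name__)

#: Sentinel values for "do not know" / "prefer not to answer" mediator
#: responses.  Negative by construction so they are disjoint from valid
#: (non-negative) activity durations.
DEFAULT_SPECIAL_CODES = (-1.0, -3.0)


class ConfigError(ValueError):
    """Raised for an invalid generative configuration."""


@dataclass(frozen=True)
class TraitModel:
    """Linear outcome model for one trait:

    ``Y = b0 + bA*A + bM*M + b_age*age + b_sex*sex + Normal(0, sigma_y^2)``.
    """

    name: str
    b0: float = 0.0
    bA: float = 0.0
    bM: float = 0.0
    b_age: float = 0.0
    b_sex: float = 0.0
    sigma_y: float = 1.0


@dataclass(frozen=True)
class SEMConfig:
    """Generative structural-equation parameters for one synthetic cohort.

    Exposure:  ``A ~ Bernoulli(expit(g0 + g_age*age + g_sex*sex))``.
    Mediator:  ``M = a0 + aA*A + a_age*age + a_sex*sex + Normal(0, sigma_m^2)``,
    floored at 0 when ``floor_mediator`` is set (observed data only; truths
    are computed from the unfloored linear model).
    Outcomes:  one :class:`TraitModel` per trait.

    Either ``n_total`` (exposure left to the logistic model) or both
    ``n_cases``/``n_controls`` (rejection-sampled to fixed margins, retaining
    the confounding structure) must be given.
    """

    traits: tuple[TraitModel, ...]
    n_total: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    # exposure model
    g0: float = -0.85
    g_age: float = 0.0
    g_sex: float = 0.0
    # mediator model (minutes/day scale)
    a0: float = 60.8
    aA: float = -11.3
    a_age: float = -0.1
    a_sex: float = 0.0
    sigma_m: float = 14.0
    floor_mediator: bool = True
    # confounder distributions
    age_low: float = 40.0
    age_high: float = 69.0
    female_prevalence: float = 0.73  # sex: 1 = female, 0 = male
    # response-code / missingness structure
    special_codes: tuple[float, ...] = DEFAULT_SPECIAL_CODES
    special_code_rate: float = 0.0
    missing_rates: dict = field(default_factory=dict)
    pem_flag_rate: float | None = None  # P(pem_flag=1 | case); None = no flag
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_m <= 0:
            raise ConfigError("sigma_m must be positive")
        for t in self.traits:
            if t.sigma_y <= 0:
                raise ConfigError(f"sigma_y must be positive (trait {t.name})")
        if self.n_total is None and (self.n_cases is None or self.n_controls is None):
            raise ConfigError("give n_total, or both n_cases and n_controls")
        n = self.n_total if self.n_total is not None else self.n_cases + self.n_controls
        if n < 2:
            raise ConfigError("cohort must have at least 2 subjects")
        if self.n_cases is not None and (self.n_cases < 1 or self.n_controls < 1):
            raise ConfigError("n_cases and n_controls must each be >= 1")
        for p in (self.female_prevalence, self.special_code_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if not self.traits:
            raise ConfigError("at least one trait model is required")
        if any(c >= 0 for c in self.special_codes):
            raise ConfigError("special codes must be negative (disjoint from valid durations)")


def default_trait_models(
    n_traits: int = 20,
    seed: int = 0,
    n_mediated: int = 4,
    d_range: tuple[float, float] = (0.2, 0.5),
) -> tuple[TraitModel, ...]:
    """Trait models whose case/control shifts land at small-to-medium
    standardised effect sizes (Cohen's d in ``d_range``).

    The first ``n_mediated`` traits carry a nonzero mediator coefficient, so
    a small part of their total effect flows through activity; the rest are
    direct-only.  Outcome noise is unit scale, so a direct coefficient of
    ``d`` yields a standardised shift close to ``d``.
    """
    rng = np.random.default_rng(seed)
    models = []
    for i in range(n_traits):
        d = rng.uniform(*d_range) * rng.choice([-1.0, 1.0])
        bM = 0.004 * rng.choice([-1.0, 1.0]) if i < n_mediated else 0.0
        models.append(
            TraitModel(
                name=f"trait_{i:02d}",
                b0=float(rng.normal(0.0, 1.0)),
                bA=float(d),
                bM=float(bM),
                b_age=float(rng.normal(0.0, 0.01)),
                b_sex=float(rng.normal(0.0, 0.1)),
                sigma_y=1.0,
            )
        )
    return tuple(models)


def study_like_config(
    n_cases: int = 1455,
    n_controls: int = 131303,
    n_traits: int = 20,
    seed: int = 0,
) -> SEMConfig:
    """Preset emulating the motivating study's structure: fixed case/control
    margins with strong imbalance, age confounding of exposure, and mediator
    means near 44 (cases) vs 55 (controls) minutes/day."""
    return SEMConfig(
        traits=default_trait_models(n_traits, seed=seed),
        n_cases=n_cases,
        n_controls=n_controls,
        g0=-6.5,
        g_age=0.04,
        g_sex=0.5,
        seed=seed,
    )


def validation_config(
    n_total: int = 5000,
    n_traits: int = 1,
    seed: int = 0,
    **overrides,
) -> SEMConfig:
    """Preset for estimator validation: moderate exposure prevalence (~0.3)
    so propensities stay well inside the default truncation bounds and
    bias/coverage measure the estimator itself."""
    cfg = SEMConfig(
        traits=default_trait_models(n_traits, seed=seed, n_mediated=n_traits),
        n_total=n_total,
        g0=-1.95,
        g_age=0.02,
        g_sex=0.2,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def closed_form_effects(config: SEMConfig) -> pd.DataFrame:
    """True per-trait effects implied by the linear SEM (flooring disabled).

    With ``Y`` linear in ``(A, M, W)`` and no exposure-mediator interaction,
    the mediation decomposition is exact:

    * ``NDE = bA`` (all paths not through the mediator),
    * ``NIE = bM * aA`` (exposure shifts the mediator by ``aA``, which moves
      the outcome by ``bM`` per unit),
    * ``TE = NDE + NIE``.

    Returns a frame indexed by trait with columns ``TE, NDE, NIE``.
    """
    rows = []
    for t in config.traits:
        nde = t.bA
        nie = t.bM * config.aA
        rows.append({"trait": t.name, "TE": nde + nie, "NDE": nde, "NIE": nie})
    return pd.DataFrame(rows).set_index("trait")


def _draw_confounders(config: SEMConfig, n: int, rng: np.random.Generator):
    age = rng.uniform(config.age_low, config.age_high, size=n)
    sex = (rng.random(n) < config.female_prevalence).astype(np.int64)
    return age, sex


def _draw_mediator(config, A, age, sex, rng, floor=None):
    m = (
        config.a0
        + config.aA * A
        + config.a_age * age
        + config.a_sex * sex
        + rng.normal(0.0, config.sigma_m, size=A.shape[0])
    )
    if config.floor_mediator if floor is None else floor:
        m = np.maximum(m, 0.0)
    return m


def _draw_outcome(t: TraitModel, A, M, age, sex, rng):
    return (
        t.b0
        + t.bA * A
        + t.bM * M
        + t.b_age * age
        + t.b_sex * sex
        + rng.normal(0.0, t.sigma_y, size=A.shape[0])
    )


def monte_carlo_effects(config: SEMConfig, n: int = 1_000_000, seed: int = 1, apply_floor: bool = False) -> pd.DataFrame:
    """Brute-force counterfactual truths: simulate ``Y(1, M(0))``,
    ``Y(0, M(0))`` and ``Y(1, M(1))`` directly from the SEM and difference
    the means.  Used as the independent oracle for
    :func:`closed_form_effects`, and as the (flagged) fallback truth when
    flooring is left on and no closed form applies.
    """
    rng = np.random.default_rng(seed)
    age, sex = _draw_confounders(config, n, rng)
    ones = np.ones(n)
    zeros = np.zeros(n)
    m0 = _draw_mediator(config, zeros, age, sex, rng, floor=apply_floor)
    m1 = _draw_mediator(config, ones, age, sex, rng, floor=apply_floor)
    rows = []
    for t in config.traits:
        # shared outcome noise across counterfactual worlds: the contrasts
        # are means, so only the systematic parts matter, but sharing noise
        # reduces Monte-Carlo variance of the differences
        eps = rng.normal(0.0, t.sigma_y, size=n)
        y_1_m0 = t.b0 + t.bA + t.bM * m0 + t.b_age * age + t.b_sex * sex + eps
        y_0_m0 = t.b0 + t.bM * m0 + t.b_age * age + t.b_sex * sex + eps
        y_1_m1 = t.b0 + t.bA + t.bM * m1 + t.b_age * age + t.b_sex * sex + eps
        nde = float(np.mean(y_1_m0 - y_0_m0))
        nie = float(np.mean(y_1_m1 - y_1_m0))
        rows.append({"trait": t.name, "TE": nde + nie, "NDE": nde, "NIE": nie})
    return pd.DataFrame(rows).set_index("trait")


def generate_cohort(config: SEMConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort table plus its true-effect sidecar.

    Returns ``(cohort, truth)`` where ``cohort`` has columns
    ``subject_id, age, sex, A, M, <trait columns>`` (and ``pem_flag`` when
    configured) and ``truth`` is :func:`closed_form_effects` of the config.
    Deterministic given the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    if config.n_total is not None:
        n = config.n_total
        age, sex = _draw_confounders(config, n, rng)
        A = (rng.random(n) < expit(config.g0 + config.g_age * age + config.g_sex * sex)).astype(np.int64)
        if A.sum() == 0 or A.sum() == n:
            raise ConfigError("degenerate cohort: all cases or all controls drawn")
    else:
        age, sex, A = _rejection_sample_margins(config, rng)
        n = A.shape[0]

    M = _draw_mediator(config, A, age, sex, rng)
    cohort = pd.DataFrame(
        {
            "subject_id": np.arange(1, n + 1, dtype=np.int64),
            "age": age,
            "sex": sex,
            "A": A,
            "M": M,
        }
    )
    for t in config.traits:
        cohort[t.name] = _draw_outcome(t, A, M, age, sex, rng)

    if config.pem_flag_rate is not None:
        flag = np.zeros(n, dtype=float)
        cases = A == 1
        flag[cases] = (rng.random(cases.sum()) < config.pem_flag_rate).astype(float)
        flag[~cases] = np.nan  # subgroup flag defined for cases only
        cohort["pem_flag"] = flag

    if config.special_code_rate > 0:
        hit = rng.random(n) < config.special_code_rate
        codes = rng.choice(np.asarray(config.special_codes), size=int(hit.sum()))
        cohort.loc[hit, "M"] = codes

    return cohort, closed_form_effects(config)


def _rejection_sample_margins(config: SEMConfig, rng: np.random.Generator):
    """Draw subjects from the joint (W, A) model until the fixed case and
    control margins are reached; keeps W|A consistent with the exposure
    model (case-control sampling of the same population)."""
    need_case, need_ctrl = config.n_cases, config.n_controls
    ages, sexes, As = [], [], []
    got_case = got_ctrl = 0
    batch = max(4 * (need_case + need_ctrl), 1000)
    for _ in range(1000):  # hard cap; prevalence ~1e-3 still converges fast
        age, sex = _draw_confounders(config, batch, rng)
        A = (rng.random(batch) < expit(config.g0 + config.g_age * age + config.g_sex * sex)).astype(np.int64)
        for arm in (1, 0):
            need = need_case - got_case if arm == 1 else need_ctrl - got_ctrl
            if need <= 0:
                continue
            idx = np.flatnonzero(A == arm)[:need]
            ages.append(age[idx])
            sexes.append(sex[idx])
            As.append(A[idx])
            if arm == 1:
                got_case += idx.size
            else:
                got_ctrl += idx.size
        if got_case >= need_case and got_ctrl >= need_ctrl:
            break
    else:
        raise ConfigError("could not reach requested case/control margins; exposure model too extreme")
    age = np.concatenate(ages)
    sex = np.concatenate(sexes)
    A = np.concatenate(As)
    perm = rng.permutation(A.shape[0])
    return age[perm], sex[perm], A[perm]


def inject_missingness(
    table: pd.DataFrame,
    rates: dict[str, float],
    mechanism: str = "MCAR",
    seed: int = 0,
) -> pd.DataFrame:
    """Mask values completely at random, column by column.

    ``rates`` maps column name to the per-entry missingness probability.
    The exposure column ``A`` is never masked.
    """
    if mechanism != "MCAR":
        raise ValueError(f"unsupported missingness mechanism: {mechanism}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for {col} outside [0, 1]: {rate}")
        if col == "A":
            raise ValueError("exposure column A may not be masked")
        if col not in out.columns:
            raise KeyError(f"no such column: {col}")
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Tab-separated with header; missing values as empty fields."""
    cohort.to_csv(path, sep="\t", index=False, na_rep="")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.reset_index().to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
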