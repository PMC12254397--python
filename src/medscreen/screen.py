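"""Multi-trait, multi-stratum, multi-mediator screening workflow.

Orchestrates filtering, effect estimation, Benjamini-Hochberg FDR control,
z-score concordance between strata, NDE/NIE decomposition fractions, the
matched case-subgroup (PEM-style) comparison and the definition-stringency
sensitivity analysis.

The output :class:`TraitResultTable` is a tidy frame with one row per
(trait x stratum x mediator x estimand), mirroring the per-analysis results
datasets such screens publish.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from medscreen.effects import (
    EstimationError,
    estimate_nde_nie,
    estimate_te_aipw,
    fit_nuisances,
)
from medscreen.traits import (
    TraitSpec,
    add_composite_columns,
    cohens_d,
    complete_case_filter,
    mediator_response_filter,
)
from medscreen.synthetic import DEFAULT_SPECIAL_CODES

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "trait", "stratum", "mediator", "estimand", "n_cases", "n_controls",
    "estimate", "se", "ci_lo", "ci_hi", "z", "p", "p_adj", "significant",
    "cohens_d", "nde_fraction", "nie_fraction",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Run-level knobs for the screening workflow."""

    library: str | tuple = "default"
    K: int = 10
    cross_fit: bool = True
    delta: float = 0.025  # propensity truncation
    fdr_threshold: float = 0.05
    family_mode: str = "per-analysis"  # or "global"
    special_codes: tuple[float, ...] = DEFAULT_SPECIAL_CODES
    te_fraction_floor: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("FDR threshold must lie in (0, 1)")
        if self.family_mode not in ("per-analysis", "global"):
            raise ValueError("family_mode must be 'per-analysis' or 'global'")


def _derived_seed(base: int, *labels) -> int:
    """Stable sub-seed from a base seed and string labels (below 2**31)."""
    h = zlib.crc32("|".join(str(l) for l in labels).encode())
    return int((base * 2654435761 + h) % (2**31 - 1))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries are excluded from the family and reinserted as missing.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        if np.any((p[mask] < 0) | (p[mask] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def effect_fractions(te: float, nde: float, nie: float, floor: float = 1e-8) -> tuple[float, float]:
    """NDE and NIE as fractions of the (shared-nuisance) total effect;
    undefined when |TE| is below ``floor``.  When defined, the fractions sum
    to 1 because NDE + NIE = TE by construction."""
    if not np.isfinite(te) or abs(te) < floor:
        return (np.nan, np.nan)
    return (nde / te, nie / te)


_STRATA_FILTERS = {
    "combined": lambda df: df,
    "female": lambda df: df[df["sex"] == 1],
    "male": lambda df: df[df["sex"] == 0],
}


def _stratum_frame(cohort: pd.DataFrame, stratum: str) -> tuple[pd.DataFrame, list[str]]:
    """Within a sex stratum, sex is constant and leaves the confounder set;
    in the combined analysis it is a confounder."""
    if stratum not in _STRATA_FILTERS:
        raise ValueError(f"unknown stratum {stratum!r}")
    sub = _STRATA_FILTERS[stratum](cohort)
    confounders = ["age", "sex"] if stratum == "combined" else ["age"]
    return sub, confounders


def run_screen(
    cohort: pd.DataFrame,
    trait_specs: list[TraitSpec],
    mediators: list[str] = ("M",),
    strata: list[str] = ("combined",),
    estimands: list[str] = ("TE", "NDE", "NIE"),
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Screen every trait in every stratum for every mediator and estimand.

    Per (trait, stratum): the total effect uses the AIPW estimator on the
    larger TE-eligible sample (complete cases on confounders, exposure,
    outcome); NDE/NIE use the one-step mediation estimator after the
    mediator response-code filter and the stricter complete-case
    restriction.  BH adjustment is applied within each multiplicity family —
    (stratum x estimand x mediator) by default, or globally.  Decomposition
    fractions come from the shared-nuisance mediation run, where
    NDE + NIE = TE exactly.  Deterministic given the config seed.
    """
    cohort = add_composite_columns(cohort, trait_specs)
    want_mediation = bool({"NDE", "NIE"} & set(estimands))
    rows = []
    for stratum in strata:
        sub_all, confounders = _stratum_frame(cohort, stratum)
        for mediator in mediators:
            for spec in trait_specs:
                trait = spec.name
                base = {"trait": trait, "stratum": stratum, "mediator": mediator}
                seed = _derived_seed(config.seed, trait, stratum, mediator)
                # descriptive effect size on the TE-eligible raw values
                te_cc, _ = complete_case_filter(sub_all, [*confounders, "A", trait])
                try:
                    d = cohens_d(te_cc.loc[te_cc.A == 1, trait], te_cc.loc[te_cc.A == 0, trait])
                except ValueError:
                    d = np.nan

                nde = nie = te_med = None
                if want_mediation:
                    med_cc, _ = mediator_response_filter(sub_all, mediator, config.special_codes)
                    med_cc, _ = complete_case_filter(med_cc, [*confounders, "A", mediator, trait])
                    try:
                        nuis = fit_nuisances(
                            med_cc, trait, mediator, confounders,
                            library=config.library, K=config.K, seed=seed,
                            cross_fit=config.cross_fit, delta=config.delta,
                            stratum=stratum, fit_b=False,
                        )
                        nde, nie, te_med = estimate_nde_nie(nuis)
                    except EstimationError as err:
                        logger.warning("mediation estimate unavailable for %s: %s", base, err)

                if te_med is not None:
                    fr_nde, fr_nie = effect_fractions(
                        te_med.point, nde.point, nie.point, config.te_fraction_floor
                    )
                else:
                    fr_nde = fr_nie = np.nan

                for estimand in estimands:
                    est = None
                    n_cases = n_controls = 0
                    if estimand == "TE":
                        try:
                            est = estimate_te_aipw(
                                sub_all, trait, confounders, library=config.library,
                                K=config.K, seed=seed, cross_fit=config.cross_fit,
                                delta=config.delta, stratum=stratum,
                            )
                            n_cases = int((te_cc.A == 1).sum())
                            n_controls = int((te_cc.A == 0).sum())
                        except EstimationError as err:
                            logger.warning("TE estimate unavailable for %s: %s", base, err)
                    elif estimand in ("NDE", "NIE"):
                        est = nde if estimand == "NDE" else nie
                        if want_mediation and est is not None:
                            n_cases = int((med_cc.A == 1).sum())
                            n_controls = int((med_cc.A == 0).sum())
                    else:
                        raise ValueError(f"unknown estimand {estimand!r}")
                    row = dict(base, estimand=estimand, n_cases=n_cases, n_controls=n_controls,
                               cohens_d=d, nde_fraction=fr_nde, nie_fraction=fr_nie)
                    if est is None:
                        row.update(estimate=np.nan, se=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                                   z=np.nan, p=np.nan)
                    else:
                        row.update(estimate=est.point, se=est.se, ci_lo=est.ci95[0],
                                   ci_hi=est.ci95[1], z=est.z, p=est.p)
                    rows.append(row)

    table = pd.DataFrame(rows)
    table = _apply_fdr(table, config)
    return table.loc[:, RESULT_COLUMNS]


def _apply_fdr(table: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    table = table.copy()
    if config.family_mode == "global":
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    else:
        table["p_adj"] = np.nan
        for _, idx in table.groupby(["stratum", "estimand", "mediator"]).groups.items():
            table.loc[idx, "p_adj"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    table["significant"] = table["p_adj"] < config.fdr_threshold
    table.loc[table["p_adj"].isna(), "significant"] = False
    return table


def zscore_concordance(
    results_stratum1: pd.DataFrame,
    results_stratum2: pd.DataFrame,
    labels: tuple[str, str] = ("stratum1", "stratum2"),
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of paired per-trait z-scores across two result
    tables, plus a per-trait significance class.

    Both tables must cover the same traits (one estimand family each, e.g.
    the female and male NDE rows).  Returns ``(r, p, classes)`` where
    ``classes`` has one row per trait with class in {both, <label1>_only,
    <label2>_only, neither}.
    """
    t1 = results_stratum1.set_index("trait")
    t2 = results_stratum2.set_index("trait")
    common = t1.index.intersection(t2.index)
    if len(common) != len(t1.index) or len(common) != len(t2.index):
        raise ValueError("trait sets do not match between the two result tables")
    if len(common) < 3:
        raise ValueError("need at least 3 paired traits for a correlation")
    z1 = t1.loc[common, "z"].to_numpy(dtype=float)
    z2 = t2.loc[common, "z"].to_numpy(dtype=float)
    ok = np.isfinite(z1) & np.isfinite(z2)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 finite paired z-scores")
    r, p = stats.pearsonr(z1[ok], z2[ok])
    s1 = t1.loc[common, "significant"].fillna(False).to_numpy(dtype=bool)
    s2 = t2.loc[common, "significant"].fillna(False).to_numpy(dtype=bool)
    cls = np.where(s1 & s2, "both",
          np.where(s1, f"{labels[0]}_only",
          np.where(s2, f"{labels[1]}_only", "neither")))
    classes = pd.DataFrame({"trait": common, "z1": z1, "z2": z2, "class": cls})
    return float(r), float(p), classes


def pem_split_comparison(
    cohort: pd.DataFrame,
    trait_specs: list[TraitSpec],
    config: ScreenConfig = ScreenConfig(),
    seed: int | None = None,
    flag_col: str = "pem_flag",
    mediator: str = "M",
) -> dict:
    """Matched comparison of a flagged case subgroup against its complement.

    The larger of the two case subgroups is subsampled without replacement
    to the smaller's size; controls are partitioned into two disjoint random
    halves of equal size; the total effect is estimated per trait in each
    arm (combined stratum) with BH adjustment per arm.  Returns the two
    result tables, per-arm significant counts, the cross-arm z concordance
    and a count of traits significant in both arms with opposite signs.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(_derived_seed(seed, "pem_split"))
    cases = cohort[cohort["A"] == 1]
    controls = cohort[cohort["A"] == 0]
    flagged = cases[cases[flag_col] == 1]
    unflagged = cases[cases[flag_col] == 0]
    if flagged.empty or unflagged.empty:
        raise ValueError("both case subgroups must be non-empty")
    n_arm = min(len(flagged), len(unflagged))
    if len(flagged) > n_arm:
        flagged = flagged.iloc[rng.choice(len(flagged), n_arm, replace=False)]
    if len(unflagged) > n_arm:
        unflagged = unflagged.iloc[rng.choice(len(unflagged), n_arm, replace=False)]
    perm = rng.permutation(len(controls))
    half = len(controls) // 2
    ctrl1 = controls.iloc[perm[:half]]
    ctrl2 = controls.iloc[perm[half:2 * half]]

    arm_tables = []
    for arm_cases, arm_ctrl, label in ((flagged, ctrl1, "flagged"), (unflagged, ctrl2, "unflagged")):
        arm = pd.concat([arm_cases, arm_ctrl], ignore_index=True)
        res = run_screen(
            arm, trait_specs, mediators=[mediator], strata=["combined"],
            estimands=["TE"], config=replace(config, seed=_derived_seed(seed, "pem_arm", label)),
        )
        arm_tables.append(res)
    res1, res2 = arm_tables
    r, p, classes = zscore_concordance(res1, res2, labels=("flagged", "unflagged"))
    sign_conflicts = int(
        ((classes["class"] == "both")
         & (np.sign(classes["z1"]) != np.sign(classes["z2"]))).sum()
    )
    return {
        "flagged": res1,
        "unflagged": res2,
        "n_cases_per_arm": n_arm,
        "n_controls_per_arm": half,
        "n_significant": {"flagged": int(res1["significant"].sum()),
                          "unflagged": int(res2["significant"].sum())},
        "concordance_r": r,
        "concordance_p": p,
        "classes": classes,
        "opposite_sign_significant": sign_conflicts,
    }


def stringency_sensitivity(
    cohort_variants: dict[str, pd.DataFrame],
    trait_specs: list[TraitSpec],
    config: ScreenConfig = ScreenConfig(),
    estimand: str = "TE",
    mediator: str = "M",
) -> dict:
    """Paired per-trait z-scores across case/control definition variants.

    Runs the combined-stratum screen on each cohort variant and reports the
    per-trait z-score table plus the Pearson correlation (with p-value) of
    every variant against the first (reference) variant.
    """
    if len(cohort_variants) < 2:
        raise ValueError("need at least 2 cohort variants")
    tables = {}
    for name, variant in cohort_variants.items():
        # same seed for every variant: the comparison is paired, so fold
        # randomness should not differ between definitions
        res = run_screen(
            variant, trait_specs, mediators=[mediator], strata=["combined"],
            estimands=[estimand], config=config,
        )
        tables[name] = res.set_index("trait")
    names = list(tables)
    ref = tables[names[0]]
    z = pd.DataFrame({name: t.loc[ref.index, "z"] for name, t in tables.items()})
    if z.isna().all().any():
        raise ValueError("mismatched trait sets across variants")
    correlations = {}
    for name in names[1:]:
        ok = np.isfinite(z[names[0]]) & np.isfinite(z[name])
        r, p = stats.pearsonr(z.loc[ok, names[0]], z.loc[ok, name])
        correlations[name] = {"r": float(r), "p": float(p)}
    return {"z_scores": z, "reference": names[0], "correlations": correlations,
            "tables": {k: v.reset_index() for k, v in tables.items()}}
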