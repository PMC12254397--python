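"""Screening workflow: FDR control, concordance, subgroup and sensitivity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from medscreen.screen import (
    ScreenConfig,
    bh_adjust,
    effect_fractions,
    pem_split_comparison,
    run_screen,
    stringency_sensitivity,
    zscore_concordance,
)
from medscreen.synthetic import generate_cohort, validation_config
from medscreen.traits import TraitSpec


def bh_bruteforce(p):
    """Independent step-up oracle straight from the definition:
    p_adj(i) = min_{j >= i} (m * p(j) / j) at sorted positions, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * sorted_p[i] / (i + 1))
        adj[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_evaluated_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_bruteforce_stepup(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_missing_p_excluded_then_reinserted(self):
        p = np.array([0.01, np.nan, 0.04])
        out = bh_adjust(p)
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], bh_bruteforce([0.01, 0.04]))

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(1)
        p = rng.random(30)
        assert np.all(bh_adjust(p) >= p - 1e-12)

    def test_rejection_count_matches_stepup_rule(self):
        """Within a family, #(p_adj < q) equals the largest k with
        p_(k) <= q k/m."""
        rng = np.random.default_rng(2)
        p = np.sort(rng.random(40) ** 2)
        q = 0.05
        k_star = max([k + 1 for k in range(40) if p[k] <= q * (k + 1) / 40], default=0)
        assert (bh_adjust(p) < q).sum() == k_star


class TestEffectFractions:
    def test_pure_direct(self):
        assert effect_fractions(2.0, 2.0, 0.0) == (1.0, 0.0)

    def test_three_quarters(self):
        nde, nie = effect_fractions(1.0, 0.75, 0.25)
        assert (nde, nie) == (0.75, 0.25)

    def test_fractions_sum_to_one_when_defined(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            nde = rng.normal()
            nie = rng.normal()
            te = nde + nie
            fr = effect_fractions(te, nde, nie)
            if np.isfinite(fr[0]):
                assert fr[0] + fr[1] == pytest.approx(1.0)

    def test_near_null_te_undefined(self):
        assert np.isnan(effect_fractions(1e-12, 1e-12, 0.0)[0])


@pytest.fixture(scope="module")
def screen_result():
    cfg = validation_config(n_total=1200, n_traits=3, seed=17)
    cohort, truth = generate_cohort(cfg)
    specs = [TraitSpec(name=t.name) for t in cfg.traits]
    config = ScreenConfig(library="fast", K=4, seed=5)
    table = run_screen(cohort, specs, mediators=["M"], strata=["combined", "female", "male"],
                       estimands=["TE", "NDE", "NIE"], config=config)
    return cohort, specs, config, table


class TestRunScreen:
    def test_row_cardinality(self, screen_result):
        _, specs, _, table = screen_result
        assert len(table) == len(specs) * 3 * 1 * 3  # traits x strata x mediators x estimands

    def test_deterministic_given_seed(self, screen_result):
        cohort, specs, config, table = screen_result
        again = run_screen(cohort, specs, mediators=["M"], strata=["combined", "female", "male"],
                           estimands=["TE", "NDE", "NIE"], config=config)
        pd.testing.assert_frame_equal(table, again)

    def test_significance_flag_consistent_with_padj(self, screen_result):
        _, _, config, table = screen_result
        ok = table.p_adj.notna()
        assert (table.loc[ok, "significant"] == (table.loc[ok, "p_adj"] < config.fdr_threshold)).all()
        assert not table.loc[~ok, "significant"].any()
        assert (table.loc[ok, "p_adj"] >= table.loc[ok, "p"] - 1e-12).all()

    def test_decomposition_fractions_sum_to_one(self, screen_result):
        _, _, _, table = screen_result
        sub = table[np.isfinite(table.nde_fraction)]
        np.testing.assert_allclose(sub.nde_fraction + sub.nie_fraction, 1.0)

    def test_mediation_sample_not_larger_than_te_sample(self):
        """The NDE/NIE complete-case set additionally requires the mediator
        (and drops special response codes), so its n never exceeds TE's."""
        cfg = validation_config(n_total=1500, n_traits=1, seed=19, special_code_rate=0.05)
        cohort, _ = generate_cohort(cfg)
        from medscreen.synthetic import inject_missingness
        cohort = inject_missingness(cohort, {"M": 0.1, "trait_00": 0.05}, seed=3)
        table = run_screen(cohort, [TraitSpec(name="trait_00")], config=ScreenConfig(library="fast", K=4, seed=2))
        n_te = table.loc[table.estimand == "TE", ["n_cases", "n_controls"]].sum(axis=1).iloc[0]
        n_nde = table.loc[table.estimand == "NDE", ["n_cases", "n_controls"]].sum(axis=1).iloc[0]
        assert 0 < n_nde < n_te

    def test_power_and_level_separation(self):
        """Traits with a real direct effect and a null mediated path at
        large n: NDE rows significant, NIE rows not."""
        from medscreen.synthetic import SEMConfig, TraitModel
        traits = tuple(TraitModel(f"t{i}", bA=0.6, bM=0.0) for i in range(4))
        cfg = SEMConfig(traits=traits, n_total=4000, g0=-0.85, seed=23)
        cohort, _ = generate_cohort(cfg)
        table = run_screen(cohort, [TraitSpec(name=t.name) for t in traits],
                           config=ScreenConfig(library="fast", K=4, seed=7))
        nde = table[table.estimand == "NDE"]
        nie = table[table.estimand == "NIE"]
        assert nde.significant.all()
        assert not nie.significant.any()

    def test_stratum_without_cases_yields_missing_row(self):
        cfg = validation_config(n_total=800, n_traits=1, seed=29)
        cohort, _ = generate_cohort(cfg)
        cohort = cohort[(cohort.sex == 0) | (cohort.A == 0)]  # no female cases
        table = run_screen(cohort, [TraitSpec(name="trait_00")], strata=["female", "male"],
                           config=ScreenConfig(library="fast", K=4, seed=3))
        female = table[table.stratum == "female"]
        assert female.estimate.isna().all()
        assert not female.significant.any()
        male = table[table.stratum == "male"]
        assert male.estimate.notna().all()


class TestZScoreConcordance:
    def _table(self, z, sig, trait_prefix="t"):
        m = len(z)
        return pd.DataFrame({
            "trait": [f"{trait_prefix}{i}" for i in range(m)],
            "z": z,
            "significant": sig,
        })

    def test_identical_tables_perfect_correlation(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=10)
        t = self._table(z, z > 1.5)
        r, p, classes = zscore_concordance(t, t)
        assert r == pytest.approx(1.0)
        assert set(classes["class"]) <= {"both", "neither"}

    def test_independent_null_zscores_weak_correlation(self):
        """|r| < 0.3 with >= 95% probability at m=100; checked over seeded
        replicates."""
        rng = np.random.default_rng(1)
        hits = sum(
            abs(zscore_concordance(self._table(rng.normal(size=100), np.zeros(100, bool)),
                                   self._table(rng.normal(size=100), np.zeros(100, bool)))[0]) < 0.3
            for _ in range(40)
        )
        assert hits >= 36

    def test_shared_effects_positive_correlation(self):
        rng = np.random.default_rng(2)
        mu = rng.normal(0, 3, size=60)
        z1 = mu + rng.normal(size=60)
        z2 = mu + rng.normal(size=60)
        r, p, _ = zscore_concordance(self._table(z1, np.abs(z1) > 2), self._table(z2, np.abs(z2) > 2))
        assert r > 0.5
        assert p < 1e-6

    def test_class_assignment(self):
        t1 = self._table([3.0, 3.0, 0.1, 0.1], [True, True, False, False])
        t2 = self._table([3.0, 0.1, 3.0, 0.1], [True, False, True, False])
        _, _, classes = zscore_concordance(t1, t2, labels=("f", "m"))
        assert list(classes["class"]) == ["both", "f_only", "m_only", "neither"]

    def test_mismatched_traits_rejected(self):
        t1 = self._table([1.0, 2.0, 3.0], [False] * 3)
        t2 = self._table([1.0, 2.0, 3.0], [False] * 3, trait_prefix="x")
        with pytest.raises(ValueError):
            zscore_concordance(t1, t2)

    def test_too_few_traits_rejected(self):
        t = self._table([1.0, 2.0], [False, False])
        with pytest.raises(ValueError):
            zscore_concordance(t, t)


@pytest.fixture(scope="module")
def flagged_cohort():
    """Flagged cases carry systematically larger direct effects."""
    cfg = validation_config(n_total=3000, n_traits=4, seed=31, pem_flag_rate=0.55)
    cohort, truth = generate_cohort(cfg)
    boost = cohort.pem_flag.fillna(0).to_numpy()
    for t in ("trait_00", "trait_01", "trait_02", "trait_03"):
        # amplify each trait's effect in the flagged subgroup without
        # changing its sign
        cohort[t] = cohort[t] + 0.8 * np.sign(truth.loc[t, "NDE"]) * boost
    return cohort


class TestPemSplit:

    def test_arm_sizes_matched_and_controls_disjoint(self, flagged_cohort):
        specs = [TraitSpec(name=f"trait_0{i}") for i in range(4)]
        out = pem_split_comparison(flagged_cohort, specs,
                                   config=ScreenConfig(library="fast", K=4, seed=3))
        cases = flagged_cohort[flagged_cohort.A == 1]
        n_small = int(min((cases.pem_flag == 1).sum(), (cases.pem_flag == 0).sum()))
        assert out["n_cases_per_arm"] == n_small
        n_controls = (flagged_cohort.A == 0).sum()
        assert out["n_controls_per_arm"] == n_controls // 2
        assert 2 * out["n_controls_per_arm"] <= n_controls

    def test_stronger_subgroup_has_more_hits_and_no_sign_flips(self, flagged_cohort):
        specs = [TraitSpec(name=f"trait_0{i}") for i in range(4)]
        out = pem_split_comparison(flagged_cohort, specs,
                                   config=ScreenConfig(library="fast", K=4, seed=3))
        assert out["n_significant"]["flagged"] >= out["n_significant"]["unflagged"]
        assert out["opposite_sign_significant"] == 0

    def test_empty_subgroup_rejected(self):
        cfg = validation_config(n_total=500, n_traits=1, seed=37, pem_flag_rate=1.0)
        cohort, _ = generate_cohort(cfg)
        with pytest.raises(ValueError):
            pem_split_comparison(cohort, [TraitSpec(name="trait_00")],
                                 config=ScreenConfig(library="fast", K=4, seed=1))


class TestStringencySensitivity:
    def test_identical_variants_on_diagonal(self):
        cfg = validation_config(n_total=1000, n_traits=3, seed=41)
        cohort, _ = generate_cohort(cfg)
        specs = [TraitSpec(name=f"trait_0{i}") for i in range(3)]
        out = stringency_sensitivity({"strict": cohort, "lenient": cohort.copy()}, specs,
                                     config=ScreenConfig(library="fast", K=4, seed=2))
        assert out["correlations"]["lenient"]["r"] == pytest.approx(1.0)
        np.testing.assert_allclose(out["z_scores"]["strict"], out["z_scores"]["lenient"])

    def test_attenuated_variant_smaller_z(self):
        """A variant whose case/control contrast is diluted (cases relabeled
        into controls) shows systematically smaller |z|."""
        from medscreen.synthetic import SEMConfig, TraitModel
        traits = tuple(TraitModel(f"t{i}", bA=0.7) for i in range(3))
        cfg = SEMConfig(traits=traits, n_total=2500, g0=-0.85, seed=43)
        strict, _ = generate_cohort(cfg)
        lenient = strict.copy()
        rng = np.random.default_rng(7)
        # dilute: half the true effect for a random half of the cases
        half = rng.random(len(lenient)) < 0.5
        for t in ("t0", "t1", "t2"):
            lenient.loc[half & (lenient.A == 1), t] -= 0.5
        specs = [TraitSpec(name=f"t{i}") for i in range(3)]
        out = stringency_sensitivity({"strict": strict, "lenient": lenient}, specs,
                                     config=ScreenConfig(library="fast", K=4, seed=4))
        z = out["z_scores"]
        assert (z["lenient"].abs() < z["strict"].abs()).all()
        assert "p" in out["correlations"]["lenient"]

    def test_single_variant_rejected(self):
        with pytest.raises(ValueError):
            stringency_sensitivity({"only": pd.DataFrame()}, [])
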