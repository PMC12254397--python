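import dataclasses

import numpy as np
import pandas as pd
import pytest

from medscreen.synthetic import SEMConfig, TraitModel, generate_cohort, validation_config


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate-prevalence linear-SEM cohort used across estimation tests."""
    cfg = validation_config(n_total=2000, n_traits=2, seed=11)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


def make_binary_cohort(n=500, seed=0):
    """All-binary (W, A, M, Y) cohort for the saturated-nuisance oracle:
    every conditional probability stays well inside the truncation bounds."""
    rng = np.random.default_rng(seed)
    W = rng.integers(0, 2, n)
    A = (rng.random(n) < 0.3 + 0.3 * W).astype(np.int64)
    M = (rng.random(n) < 0.4 + 0.2 * A + 0.1 * W).astype(np.int64)
    Y = (rng.random(n) < 0.2 + 0.3 * A + 0.2 * M + 0.1 * W).astype(float)
    return pd.DataFrame({"w": W, "A": A, "M": M, "Y": Y})


def gcomp_psi(df, a, ap):
    """Exhaustive-sum g-computation oracle over the discrete table:
    psi(a, a') = sum_w sum_m E[Y|a, m, w] P(m|a', w) P(w)."""
    total = 0.0
    for w in sorted(df["w"].unique()):
        pw = (df["w"] == w).mean()
        sub_ap = df[(df.A == ap) & (df.w == w)]
        for m in sorted(df["M"].unique()):
            pm = (sub_ap.M == m).mean()
            ey = df[(df.A == a) & (df.M == m) & (df.w == w)]["Y"].mean()
            total += ey * pm * pw
    return total


@pytest.fixture(scope="session")
def binary_cohort():
    return make_binary_cohort(n=500, seed=0)
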