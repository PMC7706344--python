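"""Variance components, repeatability, BLUPs, correlations, regression."""

import math
import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

import phenolidar as pl
from phenolidar.errors import PhenolidarError, ValidationError
from phenolidar.varcomp import (
    correlate_blups,
    fit_random_effects,
    icc_between_events,
    regress_raw,
    repeatability,
    significance_stars,
)


# -------------------------------------------------------- repeatability


def test_repeatability_formula_cases():
    assert repeatability(1.0, 1.0, 2.0) == pytest.approx(2 / 3, abs=1e-15)
    assert repeatability(0.0, 1.0, 2.0) == 0.0
    assert repeatability(1.0, 0.0, 2.0) == 1.0
    assert repeatability(0.0, 0.0, 2.0) == 0.0  # 0/0 defined as 0


def test_repeatability_invalid_inputs():
    with pytest.raises(ValidationError):
        repeatability(1.0, 1.0, 0.0)
    with pytest.raises(ValidationError):
        repeatability(-0.1, 1.0, 2.0)


def test_repeatability_monotonicity_grid():
    s2g_grid = [0.1, 0.5, 1.0, 2.0, 5.0]
    s2e_grid = [0.1, 0.5, 1.0, 2.0, 5.0]
    nrep_grid = [1.0, 1.6, 2.45, 3.0]
    for s2e in s2e_grid:
        for nrep in nrep_grid:
            rhos = [repeatability(g, s2e, nrep) for g in s2g_grid]
            assert all(a < b for a, b in zip(rhos, rhos[1:]))
    for s2g in s2g_grid:
        for nrep in nrep_grid:
            rhos = [repeatability(s2g, e, nrep) for e in s2e_grid]
            assert all(a > b for a, b in zip(rhos, rhos[1:]))
    for s2g in s2g_grid:
        for s2e in s2e_grid:
            rhos = [repeatability(s2g, s2e, n) for n in nrep_grid]
            assert all(a < b for a, b in zip(rhos, rhos[1:]))
            assert all(0.0 <= r <= 1.0 for r in rhos)


# ------------------------------------------------------------- EM REML


def _one_way(values_by_genotype):
    rows = []
    for g, values in values_by_genotype.items():
        for i, v in enumerate(values):
            rows.append({"plot_id": f"{g}{i}", "genotype": g, "value": v})
    return pd.DataFrame(rows)


def test_constant_data_degenerate_fit():
    df = _one_way({"A": [5.0, 5.0], "B": [5.0, 5.0], "C": [5.0, 5.0]})
    vc = fit_random_effects(df, factors=("genotype",))
    assert vc.degenerate
    assert vc.sigma2_g == 0.0 and vc.sigma2_e == 0.0
    assert (vc.blups == 0.0).all()
    assert vc.rho == 0.0


def test_single_genotype_degenerate_not_error():
    df = _one_way({"A": [1.0, 2.0, 3.0]})
    vc = fit_random_effects(df, factors=("genotype",))
    assert vc.degenerate and vc.sigma2_g == 0.0


def test_balanced_one_way_matches_ems_oracle():
    # 3 genotypes × 2 reps; closed-form ANOVA/REML solution computed by
    # hand: MSE = 2, MSB = 8 → σ²e = 2, σ²g = (8 − 2)/2 = 3
    df = _one_way({"A": [9.0, 11.0], "B": [11.0, 13.0], "C": [13.0, 15.0]})
    vc = fit_random_effects(df, factors=("genotype",))
    assert vc.sigma2_e == pytest.approx(2.0, rel=1e-5)
    assert vc.sigma2_g == pytest.approx(3.0, rel=1e-5)
    assert vc.rho == pytest.approx(3.0 / (3.0 + 2.0 / 2.0), rel=1e-5)
    # BLUPs shrink the genotype means by s2g/(s2g + s2e/r) = 3/4
    np.testing.assert_allclose(vc.blups.values, [-1.5, 0.0, 1.5], atol=1e-4)


def test_blups_shrink_and_sum_to_zero(rcbd_design):
    df = pl.simulate_trait(rcbd_design, 2.0, 1.0, rng_seed=42)
    vc = fit_random_effects(df)
    assert abs(vc.blups.sum()) < 1e-8 * df.value.abs().max()
    raw_means = df.groupby("genotype").value.mean()
    assert vc.blups.var() <= raw_means.var()


def test_nrep_arithmetic_and_harmonic():
    df = _one_way({"A": [1.0, 2.0], "B": [3.0], "C": [1.5, 2.5, 0.5]})
    vc_a = fit_random_effects(df, factors=("genotype",))
    assert vc_a.nrep == pytest.approx(2.0)
    vc_h = fit_random_effects(df, factors=("genotype",), nrep_method="harmonic")
    assert vc_h.nrep == pytest.approx(3 / (1 / 2 + 1 / 1 + 1 / 3))


def test_reml_matches_lme4_on_crossed_design(tmp_path):
    """Independent oracle: lme4's REML fit of the same crossed model."""
    design = pl.simulate_design(15, "rcbd", 3, rng_seed=5)
    rng = np.random.default_rng(9)
    df = design.to_frame()[["plot_id", "genotype", "row", "col"]].copy()
    g = dict(zip(design.genotypes, 1.2 * rng.standard_normal(len(design.genotypes))))
    re_ = {r: 0.6 * rng.standard_normal() for r in df.row.unique()}
    ce = {c: 0.5 * rng.standard_normal() for c in df.col.unique()}
    df["value"] = [
        10 + g[r.genotype] + re_[r.row] + ce[r.col] + 0.8 * rng.standard_normal()
        for r in df.itertuples()
    ]
    csv = tmp_path / "d.csv"
    out = tmp_path / "vc.csv"
    df.to_csv(csv, index=False)
    rscript = textwrap.dedent(
        f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(value ~ 1 + (1|genotype) + (1|row) + (1|col), data=d, REML=TRUE)
        vc <- as.data.frame(VarCorr(m))
        write.csv(vc[, c("grp", "vcov")], "{out}", row.names=FALSE)
        """
    )
    subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
    ref = pd.read_csv(out).set_index("grp")["vcov"]
    vc = fit_random_effects(df)
    assert vc.sigma2_g == pytest.approx(ref["genotype"], rel=1e-3, abs=1e-4)
    assert vc.sigma2_row == pytest.approx(ref["row"], rel=1e-3, abs=1e-4)
    assert vc.sigma2_col == pytest.approx(ref["col"], rel=1e-3, abs=1e-4)
    assert vc.sigma2_e == pytest.approx(ref["Residual"], rel=1e-3, abs=1e-4)


def test_spatial_trend_option_requires_columns():
    df = _one_way({"A": [1.0, 2.0], "B": [3.0, 4.0]})
    with pytest.raises(ValidationError):
        fit_random_effects(df, factors=("genotype",), include_trend=True)


# -------------------------------------------------------- correlations


def test_blup_correlation_perfect_relations():
    a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("ABCD"))
    up = correlate_blups(a, 2.0 * a)
    assert up.r == pytest.approx(1.0)
    down = correlate_blups(a, -a)
    assert down.r == pytest.approx(-1.0)


def test_blup_correlation_needs_three_shared():
    a = pd.Series([1.0, 2.0], index=["A", "B"])
    b = pd.Series([1.0, 2.0], index=["A", "B"])
    with pytest.raises(ValidationError):
        correlate_blups(a, b)


def test_correlation_uses_shared_genotypes_only():
    a = pd.Series([1.0, 2.0, 3.0, 9.0], index=list("ABCX"))
    b = pd.Series([2.0, 4.0, 6.0, -5.0], index=list("ABCY"))
    res = correlate_blups(a, b)
    assert res.n == 3
    assert res.r == pytest.approx(1.0)


def test_pvalue_matches_t_density_quadrature(rng):
    """Two-sided p equals direct numerical integration of the t density."""
    a = pd.Series(rng.standard_normal(20), index=[f"G{i}" for i in range(20)])
    b = pd.Series(
        0.5 * a.values + rng.standard_normal(20), index=a.index
    )
    res = correlate_blups(a, b)
    n = 20
    t_obs = abs(res.r) * math.sqrt((n - 2) / (1 - res.r**2))
    df_ = n - 2

    def t_pdf(x):
        c = math.gamma((df_ + 1) / 2) / (math.sqrt(df_ * math.pi) * math.gamma(df_ / 2))
        return c * (1 + x * x / df_) ** (-(df_ + 1) / 2)

    tail, _ = integrate.quad(t_pdf, t_obs, np.inf)
    assert res.p_value == pytest.approx(2 * tail, rel=1e-6)


def test_star_thresholds():
    assert significance_stars(5e-5) == "****"
    assert significance_stars(5e-4) == "***"
    assert significance_stars(5e-3) == "**"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.06) == ""


# ----------------------------------------------------------------- ICC


def _event_table(design, seed, n_events=2, rho_shared=True):
    """Long trait table over events; values share or don't share signal."""
    rng = np.random.default_rng(seed)
    frames = []
    base = {g: rng.standard_normal() for g in design.genotypes}
    for e in range(n_events):
        df = design.to_frame()[["plot_id", "genotype", "row", "col"]].copy()
        if rho_shared:
            sig = base
        else:
            sig = {g: rng.standard_normal() for g in design.genotypes}
        df["value"] = [
            sig[r.genotype] + 0.3 * rng.standard_normal() for r in df.itertuples()
        ]
        df["date"] = f"2016-09-{10 + 10 * e:02d}"
        df["trait"] = "x"
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def test_icc_identical_values_is_one(small_design):
    table = _event_table(small_design, 3)
    dup = table[table.date == "2016-09-10"].copy()
    dup["date"] = "2016-09-20"
    both = pd.concat([table[table.date == "2016-09-10"], dup], ignore_index=True)
    res = icc_between_events(both, "x", "2016-09-10", "2016-09-20")
    assert res.r == pytest.approx(1.0, abs=1e-9)


def test_icc_missing_event_keyed_error(small_design):
    table = _event_table(small_design, 3)
    with pytest.raises(PhenolidarError):
        icc_between_events(table, "x", "2016-09-10", "2016-12-25")
    with pytest.raises(PhenolidarError):
        icc_between_events(table, "nope", "2016-09-10", "2016-09-20")


def test_icc_null_small_for_independent_traits():
    """Independent noise traits at two events: |ICC| < 0.2 in ≥95% of seeds."""
    design = pl.simulate_design(200, "partial_rep", (400, 2, 2), rng_seed=1)
    hits = 0
    seeds = range(20)
    for seed in seeds:
        table = _event_table(design, seed, rho_shared=False)
        res = icc_between_events(
            table, "x", "2016-09-10", "2016-09-20", factors=("genotype",)
        )
        hits += abs(res.r) < 0.2
    assert hits >= 0.95 * len(seeds)


# ------------------------------------------------------------ regression


def test_regression_recovers_exact_line(rng):
    x = rng.uniform(0, 1, 30)
    res = regress_raw(2.0 * x + 1.0, x)
    assert res.slope == pytest.approx(2.0)
    assert res.intercept == pytest.approx(1.0)
    assert res.r == pytest.approx(1.0)


def test_regression_constant_response_zero_slope(rng):
    x = rng.uniform(0, 1, 20)
    res = regress_raw(np.full(20, 3.3), x)
    assert res.slope == pytest.approx(0.0, abs=1e-12)


def test_regression_zero_variance_index_rejected():
    with pytest.raises(ValidationError):
        regress_raw([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


def test_regression_matches_normal_equations(rng):
    x = rng.uniform(0, 2, 50)
    y = 1.5 * x + 0.8 + 0.2 * rng.standard_normal(50)
    res = regress_raw(y, x)
    A = np.column_stack([x, np.ones(50)])
    slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
    assert res.slope == pytest.approx(slope, rel=1e-10)
    assert res.intercept == pytest.approx(intercept, rel=1e-10)
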