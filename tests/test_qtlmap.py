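import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from endoqtl import expression, qtlmap, synthdata
from endoqtl.errors import ConfigError
from endoqtl.expression import DetectionCalls
from endoqtl.qtlmap import (
    ScanConfig,
    bh_adjust,
    bh_threshold,
    bonferroni_threshold,
    classify_cis_trans,
    conditional_scan,
    ebtl_scan,
    eqtl_scan,
    firth_logistic,
    interaction_test,
    select_sentinels,
)


def _samples(n, stages=("M", "P", "ES", "MS", "LS"), seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "stage": rng.choice(stages, size=n),
            "disease": rng.choice(["case", "control"], size=n),
        }
    )


def _geno(dosage, chrom="1", pos_start=1000):
    from endoqtl.genotypes import GenotypeMatrix

    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": chrom,
            "pos": np.arange(pos_start, pos_start + m),
            "a1": "A",
            "a2": "G",
        }
    ).set_index("variant_id")
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, dosage)


# ------------------------------------------------------------------ classification


@pytest.mark.parametrize(
    "p_chrom,v_chrom,v_pos,expect_klass,expect_dist",
    [
        ("1", "1", 350_000, "cis", 250_000),  # boundary inclusive
        ("1", "1", 350_001, "other", 250_001),
        ("1", "2", 350_000, "trans", None),
        ("1", "1", 99_000, "cis", -1_000),
    ],
)
def test_classify_cis_trans(p_chrom, v_chrom, v_pos, expect_klass, expect_dist):
    probe = {"chromosome": p_chrom, "probe_start": 100_000}
    variant = {"chrom": v_chrom, "pos": v_pos}
    klass, dist = classify_cis_trans(probe, variant, cis_window=250_000)
    assert klass == expect_klass
    assert dist == expect_dist


# ------------------------------------------------------------------ linear scan


def test_eqtl_exact_fit_recovers_coefficient():
    rng = np.random.default_rng(0)
    g = _geno(rng.integers(0, 3, size=(50, 1)))
    y = 0.8 * g.dosage[:, 0] + 3.0  # no noise
    expr = pd.DataFrame({"p0": y}, index=g.sample_ids)
    res = eqtl_scan(expr, g, _samples(50), ScanConfig(covariates=(), maf_floor=0.0))
    assert res.effect[0, 0] == pytest.approx(0.8)
    assert res.p[0, 0] < 1e-30


def test_eqtl_matches_statsmodels_ols():
    """Residualised scan equals the full OLS Wald test (independent route)."""
    rng = np.random.default_rng(1)
    samples = _samples(120, seed=1)
    g = _geno(rng.integers(0, 3, size=(120, 3)))
    y = 0.4 * g.dosage[:, 1] + rng.normal(0, 1, 120)
    expr = pd.DataFrame({"p0": y}, index=g.sample_ids)
    cfg = ScanConfig(maf_floor=0.0)
    res = eqtl_scan(expr, g, samples, cfg)
    C, _ = qtlmap.covariate_matrix(samples, cfg)
    for j in range(3):
        X = np.column_stack([C, g.dosage[:, j]])
        fit = sm.OLS(y, X).fit()
        assert res.effect[0, j] == pytest.approx(fit.params[-1], rel=1e-9)
        assert res.se[0, j] == pytest.approx(fit.bse[-1], rel=1e-9)
        assert res.p[0, j] == pytest.approx(fit.pvalues[-1], rel=1e-6)


def test_eqtl_sample_order_invariance():
    rng = np.random.default_rng(2)
    samples = _samples(80, seed=2)
    g = _geno(rng.integers(0, 3, size=(80, 2)))
    y = rng.normal(0, 1, 80)
    expr = pd.DataFrame({"p0": y}, index=g.sample_ids)
    cfg = ScanConfig(maf_floor=0.0)
    res1 = eqtl_scan(expr, g, samples, cfg)
    perm = rng.permutation(80)
    res2 = eqtl_scan(expr.iloc[perm], g, samples, cfg)
    np.testing.assert_allclose(res1.effect, res2.effect, rtol=1e-10)
    np.testing.assert_allclose(res1.p, res2.p, rtol=1e-8)


def test_eqtl_allele_flip_negates_effect():
    rng = np.random.default_rng(3)
    samples = _samples(100, seed=3)
    g = _geno(rng.integers(0, 3, size=(100, 1)))
    y = 0.3 * g.dosage[:, 0] + rng.normal(0, 1, 100)
    expr = pd.DataFrame({"p0": y}, index=g.sample_ids)
    cfg = ScanConfig(maf_floor=0.0)
    res1 = eqtl_scan(expr, g, samples, cfg)
    g2 = _geno(2.0 - g.dosage)
    res2 = eqtl_scan(expr, g2, samples, cfg)
    assert res2.effect[0, 0] == pytest.approx(-res1.effect[0, 0])
    assert res2.p[0, 0] == pytest.approx(res1.p[0, 0], rel=1e-9)


def test_eqtl_null_type_one_calibration():
    """500 null probe-SNP pairs at n=200: p < 0.01 fraction within 3 SDs."""
    rng = np.random.default_rng(4)
    samples = _samples(200, seed=4)
    g = _geno(rng.binomial(2, 0.3, size=(200, 500)))
    expr = pd.DataFrame(
        rng.normal(0, 1, size=(200, 1)), index=g.sample_ids, columns=["p0"]
    )
    res = eqtl_scan(expr, g, samples, ScanConfig(maf_floor=0.0))
    frac = (res.p < 0.01).mean()
    assert abs(frac - 0.01) < 3 * np.sqrt(0.01 * 0.99 / 500)


# ------------------------------------------------------------------ logistic scan


def test_ebtl_matches_statsmodels_logit():
    rng = np.random.default_rng(5)
    samples = _samples(200, seed=5)
    g = _geno(rng.binomial(2, 0.4, size=(200, 2)))
    lo = -0.3 + 0.8 * g.dosage[:, 0]
    y = rng.random(200) < 1 / (1 + np.exp(-lo))
    calls = DetectionCalls(g.sample_ids, ["p0"], y[:, None], 0.05)
    cfg = ScanConfig(maf_floor=0.0)
    res = ebtl_scan(calls, g, samples, cfg)
    C, _ = qtlmap.covariate_matrix(samples, cfg)
    for j in range(2):
        X = np.column_stack([C, g.dosage[:, j]])
        fit = sm.Logit(y.astype(float), X).fit(disp=0)
        assert res.effect[0, j] == pytest.approx(fit.params[-1], rel=1e-4)
        assert res.se[0, j] == pytest.approx(fit.bse[-1], rel=1e-3)


def test_ebtl_null_odds_ratio_near_one():
    rng = np.random.default_rng(6)
    samples = _samples(300, seed=6)
    g = _geno(rng.binomial(2, 0.3, size=(300, 1)))
    y = rng.random(300) < 0.5
    calls = DetectionCalls(g.sample_ids, ["p0"], y[:, None], 0.05)
    res = ebtl_scan(calls, g, samples, ScanConfig(maf_floor=0.0))
    assert abs(res.effect[0, 0]) < 3 * res.se[0, 0]


def test_ebtl_separation_handled_by_firth():
    """An allele perfectly predicting expression still yields a finite
    penalised estimate with p < 0.05 (the unpenalised MLE diverges)."""
    n = 60
    g = _geno(np.repeat([0.0, 2.0], n // 2)[:, None])
    y = g.dosage[:, 0] > 0  # perfect separation
    samples = _samples(n, stages=("ES",), seed=7)
    calls = DetectionCalls(g.sample_ids, ["p0"], y[:, None], 0.05)
    res = ebtl_scan(calls, g, samples, ScanConfig(covariates=("disease",), maf_floor=0.0))
    assert np.isfinite(res.effect[0, 0]) and abs(res.effect[0, 0]) < 10
    assert res.p[0, 0] < 0.05
    # direct Firth route agrees
    X = np.column_stack([np.ones(n), g.dosage[:, 0]])
    beta, se, conv = firth_logistic(X, y.astype(float))
    assert conv and np.isfinite(beta[-1])


def test_ebtl_screen_matches_exact_on_passing_pairs():
    """The score-screen path reproduces the exact Wald results for pairs
    passing the screen and valid score p-values elsewhere."""
    rng = np.random.default_rng(8)
    samples = _samples(400, seed=8)
    g = _geno(rng.binomial(2, 0.4, size=(400, 30)))
    lo = -0.8 + 1.5 * g.dosage[:, 3]
    y = rng.random(400) < 1 / (1 + np.exp(-lo))
    calls = DetectionCalls(g.sample_ids, ["p0"], y[:, None], 0.05)
    exact = ebtl_scan(calls, g, samples, ScanConfig(maf_floor=0.0))
    screened = ebtl_scan(calls, g, samples, ScanConfig(maf_floor=0.0, screen_p=0.01))
    hit = np.isfinite(screened.effect[0])
    assert hit[3]
    np.testing.assert_allclose(screened.effect[0, hit], exact.effect[0, hit], rtol=1e-6)
    np.testing.assert_allclose(screened.p[0, hit], exact.p[0, hit], rtol=1e-4)


def test_ebtl_rejects_degenerate_probes():
    g = _geno(np.tile([0.0, 1.0], 10)[:, None])
    calls = DetectionCalls(g.sample_ids, ["p0"], np.ones((20, 1), dtype=bool), 0.05)
    samples = _samples(20, stages=("ES", "MS"), seed=0)
    with pytest.raises(ConfigError, match="excluded"):
        ebtl_scan(calls, g, samples, ScanConfig(maf_floor=0.0))


# ------------------------------------------------------------------ sentinels


def test_select_sentinels_rules():
    tbl = pd.DataFrame(
        {
            "probe_id": ["a", "a", "a", "b"],
            "klass": ["cis", "cis", "cis", "cis"],
            "variant_id": ["v3", "v1", "v2", "v9"],
            "p": [1e-6, 1e-8, 1e-8, 0.01],
            "effect": [1.0, 0.3, 0.5, 0.2],
        }
    )
    out = select_sentinels(tbl).set_index("probe_id")
    # p tie at 1e-8 broken by larger |effect| (v2)
    assert out.loc["a", "variant_id"] == "v2"
    assert out.loc["b", "variant_id"] == "v9"
    tie = tbl.copy()
    tie.loc[:, "effect"] = [1.0, 0.5, 0.5, 0.2]
    assert (
        select_sentinels(tie).set_index("probe_id").loc["a", "variant_id"] == "v1"
    )  # then lexicographic


# ------------------------------------------------------------------ conditional


def _region(n, n_var, seed, rho=0.0):
    cfg = synthdata.SimConfig(
        n_samples=n, n_variants=n_var, n_chromosomes=1,
        ld_block_size=n_var if rho else 1, ld_rho=rho, maf_range=(0.3, 0.4), seed=seed,
    )
    return synthdata.simulate_genotypes(cfg)


def test_conditional_single_causal_gives_one_signal():
    g = _region(400, 12, seed=9)
    rng = np.random.default_rng(90)
    y = 0.8 * g.column("rs5") + rng.normal(0, 1, 400)
    samples = _samples(400, seed=9)
    res = conditional_scan("p0", y, g, samples, ScanConfig(maf_floor=0.0), threshold=1e-4)
    assert res.n_independent == 1
    assert res.signals.iloc[0]["variant_id"] == "rs5"
    assert abs(res.signals.iloc[0]["effect"] - 0.8) < 3 * res.signals.iloc[0]["se"]


def test_conditional_two_causal_gives_two_signals():
    g = _region(400, 12, seed=10, rho=0.32)  # dosage r^2 ~ 0.1
    rng = np.random.default_rng(100)
    y = 0.8 * g.column("rs3") + 0.8 * g.column("rs9") + rng.normal(0, 1, 400)
    samples = _samples(400, seed=10)
    res = conditional_scan("p0", y, g, samples, ScanConfig(maf_floor=0.0), threshold=1e-4)
    assert res.n_independent == 2
    assert set(res.signals["variant_id"]) == {"rs3", "rs9"}
    for _, s in res.signals.iterrows():
        assert abs(s["effect"] - 0.8) < 3 * s["se"]
        assert s["p_conditional"] < 1e-4  # mutually independent at threshold


def test_conditional_null_region_empty():
    g = _region(200, 10, seed=11)
    rng = np.random.default_rng(110)
    y = rng.normal(0, 1, 200)
    res = conditional_scan("p0", y, g, _samples(200, seed=11), ScanConfig(maf_floor=0.0), 1e-4)
    assert res.n_independent == 0
    assert len(res.signals) == 0


# ------------------------------------------------------------------ interaction


def test_interaction_df_equals_levels_minus_one():
    rng = np.random.default_rng(12)
    samples = _samples(240, stages=("M", "P", "ES", "MS"), seed=12)
    g = rng.binomial(2, 0.4, 240).astype(float)
    y = 0.5 * g + rng.normal(0, 1, 240)
    res = interaction_test(y, g, samples)
    assert res.testable and res.df == 3


def test_interaction_untestable_designs():
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(8)],
            "stage": ["M"] * 4 + ["ES"] * 4,
            "disease": "control",
        }
    )
    g = np.array([0, 1, 2, 0, 1, 1, 1, 1], dtype=float)  # ES has no variation
    res = interaction_test(np.zeros(8), g, samples)
    assert not res.testable and res.p is None and "ES" in res.reason
    one = samples.copy()
    one.loc[7, "stage"] = "LS"  # a stage with a single sample
    res2 = interaction_test(np.zeros(8), g, one)
    assert not res2.testable


def test_interaction_detects_stage_specific_effect():
    rng = np.random.default_rng(13)
    stages = np.repeat(["M", "P", "ES", "MS"], 60)
    samples = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(240)], "stage": stages, "disease": "control"}
    )
    g = rng.binomial(2, 0.4, 240).astype(float)
    beta = np.where(stages == "ES", 1.0, 0.0)
    y = beta * g + rng.normal(0, 1, 240)
    res = interaction_test(y, g, samples)
    assert res.testable and res.p < 0.05


# ------------------------------------------------------------------ multiple testing


def test_bh_hand_step_up():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
    with pytest.raises(ConfigError):
        bh_adjust([0.5, 1.2])


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
def test_bh_monotone_in_p_ranking(pvals):
    q = bh_adjust(pvals)
    order = np.argsort(pvals, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()
    assert (q >= 0).all() and (q <= 1).all()


def test_bh_null_fdr_control():
    """Independent uniform nulls: discoveries at q < 0.05 are <= 3 in at
    least 95% of replicates."""
    rng = np.random.default_rng(14)
    excess = sum(
        (bh_adjust(rng.random(1000)) < 0.05).sum() > 3 for _ in range(100)
    )
    assert excess <= 5


def test_bonferroni_threshold_values():
    assert f"{bonferroni_threshold(0.05, 453):.1e}" == "1.1e-04"
    assert bonferroni_threshold(0.05, 1) == 0.05
    with pytest.raises(ConfigError):
        bonferroni_threshold(0.05, 0)


def test_bh_threshold_matches_adjust():
    rng = np.random.default_rng(15)
    p = np.concatenate([rng.uniform(0, 1e-4, 20), rng.random(500)])
    cut = bh_threshold(p, 0.05)
    q = bh_adjust(p)
    assert ((p <= cut) == (q < 0.05)).all() or ((p <= cut) == (q <= 0.05)).all()
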