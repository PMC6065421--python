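import numpy as np
import pandas as pd
import pytest
from scipy import stats

from endoqtl import integrate, synthdata
from endoqtl.errors import ConfigError, ParseError, UntestableError

from endoqtl.integrate import (
    harmonize_gwas,
    heidi_test,
    overlap_by_ld,
    overlap_chisq,
    overlap_features,
    read_bed,
    read_gwas_ma,
    run_smr,
    smr_test,
    smr_threshold,
    write_gwas_ma,
)


# ------------------------------------------------------------------ .ma IO


def test_gwas_ma_round_trip(tmp_path):
    g = synthdata.simulate_genotypes(synthdata.SimConfig(n_samples=10, n_variants=5, seed=1))
    gwas = synthdata.simulate_gwas_summary(g, "null", 0.0, n_gwas=100, seed=2)
    path = tmp_path / "x.ma"
    write_gwas_ma(gwas, path)
    back = read_gwas_ma(path)
    pd.testing.assert_frame_equal(back, gwas, check_exact=False, rtol=1e-12)


def test_gwas_ma_validation(tmp_path):
    path = tmp_path / "bad.ma"
    path.write_text("SNP A1 A2 freq b se p N\nrs1 A G 0.3 0.1 0.0 0.5 100\n")
    with pytest.raises(ParseError, match="SE"):
        read_gwas_ma(path)
    path.write_text("SNP A1 A2 freq b\nrs1 A G 0.3 0.1\n")
    with pytest.raises(ParseError, match="missing columns"):
        read_gwas_ma(path)


# ------------------------------------------------------------------ LD overlap


def test_overlap_by_ld_identical_and_boundary(cohort):
    g = cohort["g"]
    pairs = overlap_by_ld(["rs1"], ["rs1"], g)
    assert len(pairs) == 1 and pairs.iloc[0]["r2"] == 1.0
    # strict '>' boundary: a pair exactly at the threshold is not matched
    from endoqtl.genotypes import ld_r2

    r, r2 = ld_r2(g, "rs1", "rs2")
    at = overlap_by_ld(["rs1"], ["rs2"], g, r2_min=r2)
    assert len(at) == 0
    below = overlap_by_ld(["rs1"], ["rs2"], g, r2_min=r2 * 0.999)
    assert len(below) == 1


def test_overlap_by_ld_block_pair():
    """Variants from one high-LD block match; unresolvable ids are skipped."""
    # matched MAFs: thresholded copulas with very different allele
    # frequencies cannot reach dosage r^2 > 0.7
    cfg = synthdata.SimConfig(
        n_samples=500, n_variants=10, n_chromosomes=1, ld_block_size=10,
        ld_rho=0.97, maf_range=(0.3, 0.31), seed=4,
    )
    g = synthdata.simulate_genotypes(cfg)
    pairs = overlap_by_ld(["rs1", "nope"], ["rs2"], g, r2_min=0.7)
    assert list(pairs["esnp"]) == ["rs1"]
    assert pairs.iloc[0]["r2"] > 0.7


def test_overlap_by_ld_empty_reference(cohort):
    with pytest.raises(ConfigError):
        overlap_by_ld(["rs1"], ["rs2"], cohort["g"].subset_variants([]))


# ------------------------------------------------------------------ interval overlap


def test_overlap_features_coordinate_contract(tmp_path):
    bed = tmp_path / "x.bed"
    bed.write_text("1\t99\t100\n")
    intervals = read_bed(bed)
    snps = pd.DataFrame(
        {"variant_id": ["a", "b"], "chrom": ["1", "1"], "pos": [100, 101]}
    )
    out = overlap_features(snps, intervals, flank=0)
    assert out["in_feature"].tolist() == [True, False]


def test_overlap_features_flank_window():
    """flank 50 kb on a width-1 TSS interval covers 100,001 bases."""
    intervals = pd.DataFrame({"chrom": ["1"], "start": [499_999], "end": [500_000]})
    snps = pd.DataFrame(
        {
            "variant_id": ["lo", "in_lo", "tss", "in_hi", "hi"],
            "chrom": "1",
            "pos": [449_999, 450_000, 500_000, 550_000, 550_001],
        }
    )
    out = overlap_features(snps, intervals, flank=50_000)
    assert out["in_feature"].tolist() == [False, True, True, True, False]


def test_read_bed_errors(tmp_path):
    bad = tmp_path / "bad.bed"
    bad.write_text("1\t10\n")
    with pytest.raises(ParseError, match="bad.bed:1"):
        read_bed(bad)


# ------------------------------------------------------------------ chi-square overlap


def test_overlap_chisq_exact_independence():
    universe = {f"g{i}" for i in range(100)}
    a = {f"g{i}" for i in range(30)}
    b = {f"g{i}" for i in range(18, 30)} | {f"g{i}" for i in range(30, 58)}
    chi2, p, obs, exp = overlap_chisq(a, b, universe)
    assert obs == 12 and exp == pytest.approx(12.0)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_overlap_chisq_hand_table():
    """Cells (20,10,20,50): chi2 = 100*(20*50-10*20)^2/(30*70*40*60)."""
    universe = {f"g{i}" for i in range(100)}
    a = {f"g{i}" for i in range(30)}
    b = {f"g{i}" for i in range(20)} | {f"g{i}" for i in range(30, 50)}
    chi2, p, obs, exp = overlap_chisq(a, b, universe)
    expect_chi2 = 100 * (20 * 50 - 10 * 20) ** 2 / (30 * 70 * 40 * 60)
    assert chi2 == pytest.approx(expect_chi2)
    assert p == pytest.approx(stats.chi2.sf(expect_chi2, 1))
    assert obs == 20


def test_overlap_chisq_equals_squared_two_proportion_z():
    universe = {f"g{i}" for i in range(200)}
    a = {f"g{i}" for i in range(60)}
    b = {f"g{i}" for i in range(40, 120)}
    chi2, _, _, _ = overlap_chisq(a, b, universe)
    # two-proportion z on P(in B | in A) vs P(in B | not in A)
    n1, n2 = 60, 140
    x1, x2 = len(a & b), len(b - a)
    p1, p2, pp = x1 / n1, x2 / n2, (x1 + x2) / 200
    z = (p1 - p2) / np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
    assert chi2 == pytest.approx(z**2, abs=1e-9)


def test_overlap_chisq_degenerate():
    universe = {"a", "b"}
    with pytest.raises(ConfigError):
        overlap_chisq(universe, {"a"}, universe)  # A = U -> zero margin
    with pytest.raises(ConfigError):
        overlap_chisq({"a"}, {"b"}, set())


# ------------------------------------------------------------------ SMR


def test_smr_ratio_and_chi2_tail():
    b_xy, t, p = smr_test(0.5, 0.05, 0.1, 0.02)
    assert b_xy == pytest.approx(0.2)
    b_xy, t, p = smr_test(1.0, 0.1, 0.5, 0.1)  # z_zx=10, z_zy=5
    assert t == pytest.approx(2500 / 125)
    assert p == pytest.approx(stats.chi2.sf(20, 1), rel=1e-9)
    assert p == pytest.approx(7.7e-6, rel=0.01)


def test_smr_null_and_errors():
    b_xy, t, p = smr_test(0.5, 0.05, 0.0, 0.02)
    assert b_xy == 0.0 and t == 0.0 and p == 1.0
    with pytest.raises(UntestableError, match="weak instrument"):
        smr_test(0.1, 0.05, 0.1, 0.02)
    with pytest.raises(ConfigError):
        smr_test(0.5, -1.0, 0.1, 0.02)


def test_smr_sign_symmetry():
    a = smr_test(0.5, 0.05, 0.1, 0.02)
    b = smr_test(-0.5, 0.05, -0.1, 0.02)
    assert a == pytest.approx(b)


def test_smr_threshold_values():
    assert f"{smr_threshold(453):.1e}" == "1.1e-04"
    assert smr_threshold(1) == 0.05
    assert smr_threshold(100) == pytest.approx(5e-4)
    with pytest.raises(ConfigError):
        smr_threshold(0)


# ------------------------------------------------------------------ HEIDI


def _homogeneous_region(m=6, r=0.6):
    ids = [f"v{j}" for j in range(m)]
    b_zx = np.linspace(0.8, 0.5, m)
    region = pd.DataFrame(
        {
            "variant_id": ids,
            "effect": b_zx,
            "se": 0.05,
            "p": np.concatenate([[1e-20], np.full(m - 1, 1e-8)]),
        }
    )
    gwas = pd.DataFrame(
        {"SNP": ids, "b": 0.2 * b_zx, "se": 0.01, "p": 1e-8, "A1": "A", "A2": "G",
         "freq": 0.3, "N": 10000}
    )
    R = np.full((m, m), r)
    np.fill_diagonal(R, 1.0)
    ld = pd.DataFrame(R, index=ids, columns=ids)
    return region, gwas, ld


def test_heidi_homogeneous_limit():
    """Identical b_xy across the region: all deviations are zero, p ~ 1."""
    region, gwas, ld = _homogeneous_region()
    p, n = heidi_test(region, gwas, ld)
    assert p > 0.99
    assert n == 6


def test_heidi_order_invariance():
    region, gwas, ld = _homogeneous_region()
    gwas2 = gwas.copy()
    gwas2.loc[3, "b"] = 0.4  # introduce heterogeneity so p is interior
    p1, _ = heidi_test(region, gwas2, ld)
    perm = np.random.default_rng(0).permutation(len(region))
    p2, _ = heidi_test(
        region.iloc[perm].reset_index(drop=True),
        gwas2.iloc[perm].reset_index(drop=True),
        ld,
    )
    assert p1 == pytest.approx(p2, rel=1e-9)


def test_heidi_untestable_when_too_few_snps():
    region, gwas, ld = _homogeneous_region(m=2)
    with pytest.raises(UntestableError):
        heidi_test(region, gwas, ld)


def test_heidi_proxy_exclusion():
    region, gwas, ld = _homogeneous_region(m=6, r=0.95)  # all near-perfect proxies
    with pytest.raises(UntestableError):
        heidi_test(region, gwas, ld)


def test_allele_harmonization_flip_invariance():
    """Flipping GWAS A1/A2 with b -> -b leaves SMR/HEIDI unchanged."""
    region, gwas, g = synthdata.simulate_smr_region("pleiotropy", seed=77)
    res = run_smr("p", region, harmonize_gwas(g.variants, gwas), g, n_probes_tested=1)
    flipped = gwas.copy()
    flipped["A1"], flipped["A2"] = gwas["A2"], gwas["A1"]
    flipped["b"] = -gwas["b"]
    flipped["freq"] = 1 - gwas["freq"]
    res2 = run_smr("p", region, harmonize_gwas(g.variants, flipped), g, n_probes_tested=1)
    assert res2.b_xy == pytest.approx(res.b_xy)
    assert res2.p_smr == pytest.approx(res.p_smr)
    assert res2.p_heidi == pytest.approx(res.p_heidi)


def test_harmonize_drops_ambiguous_and_unknown():
    variants = pd.DataFrame(
        {"a1": ["A", "A"], "a2": ["G", "T"]}, index=["rs1", "rs2"]
    )
    gwas = pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3"],
            "A1": ["G", "A", "A"],
            "A2": ["A", "T", "G"],
            "freq": [0.3, 0.4, 0.5],
            "b": [0.1, 0.2, 0.3],
            "se": [0.01, 0.01, 0.01],
            "p": [0.5] * 3,
            "N": [100] * 3,
        }
    )
    out = harmonize_gwas(variants, gwas)
    assert list(out["SNP"]) == ["rs1"]  # rs2 ambiguous (A/T), rs3 unknown
    assert out.iloc[0]["b"] == pytest.approx(-0.1)  # flipped to eQTL A1
    assert out.iloc[0]["freq"] == pytest.approx(0.7)
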