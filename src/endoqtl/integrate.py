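"""Integration of eQTL signals with external evidence: LD-based overlap with
GWAS/eQTL catalogues, genomic-interval overlap, gene-set overlap chi-square,
and summary-data-based Mendelian randomisation (SMR) with the HEIDI
heterogeneity test.

SMR uses the top cis-eSNP as an instrument: with z = b/se,
b_xy = b_zy / b_zx and T_SMR = z_zx^2 z_zy^2 / (z_zx^2 + z_zy^2) ~ chi2(1).
HEIDI asks whether b_xy is homogeneous across the cis region: under a single
shared causal variant (pleiotropy) every SNP in LD estimates the same b_xy;
distinct causal variants in LD (linkage) produce heterogeneity. We form
d_i = b_xy(i) - b_xy(top) for the eligible SNPs, build cov(d) by the delta
method from the per-SNP sampling variances and the LD correlations, and
refer T = d' cov(d)^{-1} d to chi2 with (n_snps - 1) df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ParseError, UntestableError
from .genotypes import GenotypeMatrix, UndefinedLdError, ld_matrix

GWAS_MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]
STRAND_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def read_gwas_ma(path) -> pd.DataFrame:
    """Read COJO-style whitespace-delimited GWAS summary statistics
    (SNP A1 A2 freq b se p N)."""
    df = pd.read_csv(path, sep=r"\s+")
    missing = set(GWAS_MA_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"GWAS .ma file missing columns {sorted(missing)}")
    if (df["se"] <= 0).any():
        raise ParseError("GWAS .ma file contains non-positive SE")
    if ((df["freq"] <= 0) | (df["freq"] >= 1)).any():
        raise ParseError("GWAS .ma allele frequencies must lie in (0, 1)")
    return df


def write_gwas_ma(df: pd.DataFrame, path) -> None:
    df[GWAS_MA_COLUMNS].to_csv(path, sep=" ", index=False)


def harmonize_gwas(
    eqtl_variants: pd.DataFrame, gwas: pd.DataFrame, drop_ambiguous: bool = True
) -> pd.DataFrame:
    """Orient GWAS effects to the eQTL A1 allele.

    Records whose alleles cannot be matched are dropped; records with swapped
    A1/A2 get b -> -b and freq -> 1-freq; strand-ambiguous (A/T, C/G) SNPs
    are dropped by default. ``eqtl_variants`` is indexed by variant id with
    columns a1, a2.
    """
    rows = []
    for _, rec in gwas.iterrows():
        vid = rec["SNP"]
        if vid not in eqtl_variants.index:
            continue
        a1, a2 = eqtl_variants.at[vid, "a1"], eqtl_variants.at[vid, "a2"]
        pair = frozenset((str(rec["A1"]).upper(), str(rec["A2"]).upper()))
        if drop_ambiguous and pair in STRAND_AMBIGUOUS:
            continue
        if (rec["A1"], rec["A2"]) == (a1, a2):
            rows.append(rec)
        elif (rec["A1"], rec["A2"]) == (a2, a1):
            flipped = rec.copy()
            flipped["A1"], flipped["A2"] = a1, a2
            flipped["b"] = -rec["b"]
            flipped["freq"] = 1.0 - rec["freq"]
            rows.append(flipped)
        # unmatched allele pair: dropped
    return pd.DataFrame(rows).reset_index(drop=True)


# ---------------------------------------------------------------- overlaps


def overlap_by_ld(
    esnps, catalogue_snps, g_reference: GenotypeMatrix, r2_min: float = 0.7
) -> pd.DataFrame:
    """Match eSNPs to catalogue SNPs that are identical or in LD r^2 > r2_min
    (strict) in the reference genotypes. Unresolvable ids are skipped."""
    if g_reference.n_variants == 0:
        raise ConfigError("empty reference genotype panel")
    known = set(g_reference.variants.index)
    es = [v for v in esnps if v in known]
    cs = [v for v in catalogue_snps if v in known]
    rows = []
    for e in es:
        xe = g_reference.column(e)
        for c in cs:
            if e == c:
                rows.append((e, c, 1.0))
                continue
            ok = ~(np.isnan(xe) | np.isnan(g_reference.column(c)))
            x, ycol = xe[ok], g_reference.column(c)[ok]
            if len(x) < 2 or x.std() == 0 or ycol.std() == 0:
                continue
            r2 = float(np.corrcoef(x, ycol)[0, 1] ** 2)
            if r2 > r2_min:
                rows.append((e, c, r2))
    return pd.DataFrame(rows, columns=["esnp", "catalogue_snp", "r2"])


def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED (0-based, half-open) with line-numbered errors."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED line needs >= 3 fields")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinate") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def overlap_features(
    snps: pd.DataFrame, intervals: pd.DataFrame, flank: int = 0
) -> pd.DataFrame:
    """Flag SNPs (1-based positions, columns variant_id/chrom/pos) lying in
    any BED interval (0-based half-open) expanded by ``flank`` on both sides.

    A 1-based position P occupies 0-based coordinate P-1, so the hit rule is
    start - flank <= P-1 < end + flank.
    """
    out = snps.copy()
    hit = np.zeros(len(out), dtype=bool)
    by_chrom = {str(c): grp for c, grp in intervals.groupby("chrom")}
    pos0 = out["pos"].to_numpy() - 1
    for i, (chrom, p0) in enumerate(zip(out["chrom"].astype(str), pos0)):
        grp = by_chrom.get(chrom)
        if grp is None:
            continue
        hit[i] = bool(
            ((grp["start"].to_numpy() - flank <= p0) & (p0 < grp["end"].to_numpy() + flank)).any()
        )
    out["in_feature"] = hit
    return out


def overlap_chisq(set_a, set_b, universe, yates: bool = False):
    """2x2 chi-square (1 df) for the overlap of two gene sets in a universe.

    Returns (chi2, p, observed_overlap, expected_overlap). A zero margin
    (either set empty or equal to the universe) is degenerate and raises.
    """
    universe = set(universe)
    if not universe:
        raise ConfigError("empty universe")
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ConfigError("sets must be subsets of the universe")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe) - n11 - n12 - n21
    table = np.array([[n11, n12], [n21, n22]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ConfigError("degenerate 2x2 table (zero margin)")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    expected = len(a) * len(b) / len(universe)
    return float(chi2), float(p), n11, float(expected)


# ---------------------------------------------------------------- SMR / HEIDI


def smr_threshold(n_probes_tested: int) -> float:
    if n_probes_tested < 1:
        raise ConfigError("n_probes_tested must be >= 1")
    return 0.05 / n_probes_tested


@dataclass
class SmrResult:
    probe_id: str
    top_variant: str
    b_zx: float
    se_zx: float
    b_zy: float
    se_zy: float
    b_xy: float
    t_smr: float
    p_smr: float
    p_heidi: float | None = None  # None = untestable
    n_heidi_snps: int = 0
    passes: bool = False


def smr_test(
    b_zx: float, se_zx: float, b_zy: float, se_zy: float, z_instrument_min: float = 5.45
) -> tuple[float, float, float]:
    """Ratio estimate and SMR test for one instrument.

    Returns (b_xy, t_smr, p_smr). Raises UntestableError when the instrument
    is weak (|b_zx/se_zx| < z_instrument_min, default ~ genome-wide
    significance)."""
    if se_zx <= 0 or se_zy <= 0:
        raise ConfigError("standard errors must be positive")
    z_zx = b_zx / se_zx
    if abs(z_zx) < z_instrument_min:
        raise UntestableError(f"weak instrument: |z_zx| = {abs(z_zx):.2f} < {z_instrument_min}")
    z_zy = b_zy / se_zy
    b_xy = b_zy / b_zx
    denom = z_zx**2 + z_zy**2
    t_smr = (z_zx**2 * z_zy**2) / denom if denom > 0 else 0.0
    p_smr = float(stats.chi2.sf(t_smr, df=1))
    return float(b_xy), float(t_smr), p_smr


@dataclass
class HeidiSettings:
    p_eqtl_max: float = 1.57e-3  # eligibility: SNPs with eQTL p below this
    r2_top_max: float = 0.9  # drop near-perfect proxies of the top SNP
    r2_top_min: float = 0.05  # drop SNPs essentially unlinked to the top SNP
    max_snps: int = 20
    min_snps: int = 3
    ridge: float = 1e-6


def heidi_test(
    region: pd.DataFrame,
    gwas: pd.DataFrame,
    ld: pd.DataFrame,
    settings: HeidiSettings | None = None,
) -> tuple[float, int]:
    """Heterogeneity-in-dependent-instruments test over a cis region.

    ``region``: per-SNP eQTL records (variant_id, effect, se, p) including
    the top SNP (minimum p). ``gwas``: harmonised per-SNP GWAS effects
    (SNP, b, se). ``ld``: signed-r matrix covering the SNPs. Returns
    (p_heidi, n_snps_used); raises UntestableError when fewer than min_snps
    eligible SNPs remain or the covariance is singular.
    """
    st = settings or HeidiSettings()
    eq = region[["variant_id", "effect", "se", "p"]].rename(
        columns={"effect": "b_zx", "se": "se_zx"}
    )
    gw = gwas[["SNP", "b", "se"]].rename(
        columns={"SNP": "variant_id", "b": "b_zy", "se": "se_zy"}
    )
    merged = eq.merge(gw, on="variant_id")
    merged = merged[np.isfinite(merged["b_zx"]) & np.isfinite(merged["b_zy"])]
    if merged.empty:
        raise UntestableError("no SNPs shared between eQTL region and GWAS")
    top = merged.sort_values("p", kind="stable").iloc[0]
    r_top = ld.loc[merged["variant_id"], top["variant_id"]].to_numpy(dtype=float)
    eligible = (
        (merged["p"].to_numpy() <= st.p_eqtl_max)
        & (r_top**2 <= st.r2_top_max)
        & (r_top**2 >= st.r2_top_min)
        & (merged["variant_id"] != top["variant_id"]).to_numpy()
    )
    sub = merged[eligible]
    if len(sub) > st.max_snps - 1:
        sub = sub.sort_values("p", kind="stable").head(st.max_snps - 1)
    if len(sub) + 1 < st.min_snps:
        raise UntestableError(f"only {len(sub) + 1} eligible SNPs (< {st.min_snps})")
    snps = [top["variant_id"]] + list(sub["variant_id"])
    bzx = np.concatenate(([top["b_zx"]], sub["b_zx"].to_numpy(float)))
    sezx = np.concatenate(([top["se_zx"]], sub["se_zx"].to_numpy(float)))
    bzy = np.concatenate(([top["b_zy"]], sub["b_zy"].to_numpy(float)))
    sezy = np.concatenate(([top["se_zy"]], sub["se_zy"].to_numpy(float)))
    R = ld.loc[snps, snps].to_numpy(dtype=float)
    bxy = bzy / bzx
    d = bxy[1:] - bxy[0]
    cov = _cov_bxy(bzx, sezx, bzy, sezy, R)
    cov_d = cov[1:, 1:] - cov[1:, [0]] - cov[[0], 1:] + cov[0, 0]
    cov_d = cov_d + st.ridge * np.eye(len(d))
    try:
        chol = np.linalg.cholesky(cov_d)
    except np.linalg.LinAlgError as exc:
        raise UntestableError("singular HEIDI covariance after ridge") from exc
    z = np.linalg.solve(chol, d)
    stat = float(z @ z)
    dfree = len(d)
    return float(stats.chi2.sf(stat, df=dfree)), len(snps)


def _cov_bxy(bzx, sezx, bzy, sezy, R) -> np.ndarray:
    """Delta-method covariance of the per-SNP ratio estimates b_xy.

    eQTL and GWAS samples are independent; within each, effect estimates at
    SNPs i and j correlate approximately as the LD r_ij."""
    cov_zy = R * np.outer(sezy, sezy)
    cov_zx = R * np.outer(sezx, sezx)
    inv_bzx = 1.0 / bzx
    ratio = bzy / bzx**2
    return (
        np.outer(inv_bzx, inv_bzx) * cov_zy
        + np.outer(ratio, ratio) * cov_zx
    )


def run_smr(
    probe_id: str,
    region: pd.DataFrame,
    gwas: pd.DataFrame,
    g_reference: GenotypeMatrix,
    n_probes_tested: int,
    n_smr_significant: int = 1,
    z_instrument_min: float = 5.45,
    heidi_settings: HeidiSettings | None = None,
    heidi_alpha: float | None = None,
) -> SmrResult:
    """SMR + HEIDI for one probe's cis region.

    ``region``: per-SNP eQTL records with variant_id, effect, se, p (the top
    SNP becomes the instrument). GWAS effects must already be harmonised to
    the eQTL A1 orientation. ``passes`` requires p_smr below 0.05 /
    n_probes_tested and p_heidi at or above heidi_alpha (default 0.05 /
    n_smr_significant)."""
    gw = gwas[["SNP", "b", "se"]].rename(
        columns={"SNP": "variant_id", "b": "b_gwas", "se": "se_gwas"}
    )
    merged = region.merge(gw, on="variant_id")
    if merged.empty:
        raise UntestableError(f"{probe_id}: no region SNPs present in GWAS")
    top = merged.sort_values("p", kind="stable").iloc[0]
    b_xy, t_smr, p_smr = smr_test(
        top["effect"], top["se"], top["b_gwas"], top["se_gwas"], z_instrument_min
    )
    thr = smr_threshold(n_probes_tested)
    heidi_alpha = heidi_alpha if heidi_alpha is not None else 0.05 / max(n_smr_significant, 1)
    try:
        ld = ld_matrix(g_reference, list(merged["variant_id"]))
        p_heidi, n_snps = heidi_test(region, gwas, ld, heidi_settings)
    except (UntestableError, UndefinedLdError):
        p_heidi, n_snps = None, 0
    passes = p_smr < thr and p_heidi is not None and p_heidi >= heidi_alpha
    return SmrResult(
        probe_id=probe_id,
        top_variant=str(top["variant_id"]),
        b_zx=float(top["effect"]),
        se_zx=float(top["se"]),
        b_zy=float(top["b_gwas"]),
        se_zy=float(top["se_gwas"]),
        b_xy=b_xy,
        t_smr=t_smr,
        p_smr=p_smr,
        p_heidi=p_heidi,
        n_heidi_snps=n_snps,
        passes=passes,
    )
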