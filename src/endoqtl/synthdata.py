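"""Synthetic endometrial expression-genetics cohorts with known truth.

The generator emulates the structure of an Illumina HT-12-style study of 229
women staged across the menstrual cycle: blockwise-LD diploid genotypes under
Hardy-Weinberg proportions, probe intensities with detection p-values, two
probe classes (always-expressed vs. variably-expressed, plus silent array
probes so that ~43% of probes are detected per sample), cycle-stage effects
on both mean expression and expression probability, genetic effects in cis
and trans on mean level (beta_mean) and on silencing log-odds
(alpha_silencing), and GWAS summary statistics under pleiotropy, linkage or
null scenarios. Every probe carries a truth record, so downstream scans can
be scored for recovery and calibration.

Default sample composition follows the study it emulates: stage counts
M=11, EP=5, MP=69, LP=20, ES=50, MS=51, LS=23 (total 229) and 133 cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .expression import STAGES_7, ExpressionDataset
from .genotypes import GenotypeMatrix, VARIANT_COLUMNS

STUDY_STAGE_COUNTS = {"M": 11, "EP": 5, "MP": 69, "LP": 20, "ES": 50, "MS": 51, "LS": 23}
STUDY_STAGE_PROPORTIONS = {k: v / 229 for k, v in STUDY_STAGE_COUNTS.items()}
STUDY_CASE_FRACTION = 133 / 229

MU_COLS = [f"mu_{s}" for s in STAGES_7]
LO_COLS = [f"lo_{s}" for s in STAGES_7]


@dataclass
class SimConfig:
    """Genotype/sample-level generator settings."""

    n_samples: int = 229
    n_variants: int = 2000
    n_chromosomes: int = 5
    variant_spacing: int = 25_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.8
    stage_proportions: dict = field(default_factory=lambda: dict(STUDY_STAGE_PROPORTIONS))
    case_fraction: float = STUDY_CASE_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_variants < 1:
            raise ConfigError("need n_samples >= 2 and n_variants >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigError("ld_rho must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        total = sum(self.stage_proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ConfigError(f"stage proportions sum to {total}, not 1")
        unknown = set(self.stage_proportions) - set(STAGES_7)
        if unknown:
            raise ConfigError(f"unknown stages in proportions: {sorted(unknown)}")
        if not 0.0 <= self.case_fraction <= 1.0:
            raise ConfigError("case_fraction must be in [0, 1]")


# ---------------------------------------------------------------- genotypes


def _simulate_haplotypes(af, block, rho, n, rng) -> np.ndarray:
    """One haplotype layer: blockwise equicorrelated Gaussian copula
    thresholded at the allele-frequency quantile."""
    m = len(af)
    n_blocks = int(block.max()) + 1 if m else 0
    shared = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, m))
    latent = np.sqrt(rho)[None, :] * shared[:, block] + np.sqrt(1.0 - rho)[None, :] * eps
    return (latent < stats.norm.ppf(af)[None, :]).astype(float)


def _simulate_dosage(af, block, rho, n, rng) -> np.ndarray:
    af = np.asarray(af, float)
    block = np.asarray(block, int)
    rho = np.asarray(rho, float)
    h1 = _simulate_haplotypes(af, block, rho, n, rng)
    h2 = _simulate_haplotypes(af, block, rho, n, rng)
    return h1 + h2


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Diploid dosages under HWE with blockwise constant-correlation LD.

    Variants are laid out contiguously along ``n_chromosomes`` chromosomes at
    ``variant_spacing`` bp intervals; LD blocks never span a chromosome
    boundary. The returned variants table carries af / block / ld_rho columns
    so that an independent cohort (e.g. a GWAS panel) can be drawn from the
    same population.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_variants
    af = rng.uniform(*config.maf_range, size=m)
    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chrom_idx = np.arange(m) // per_chrom
    within = np.arange(m) % per_chrom
    # block ids: contiguous runs of ld_block_size within each chromosome
    block = chrom_idx * int(np.ceil(per_chrom / config.ld_block_size)) + (
        within // config.ld_block_size
    )
    _, block = np.unique(block, return_inverse=True)
    rho = np.full(m, config.ld_rho)
    dosage = _simulate_dosage(af, block, rho, config.n_samples, rng)
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{j + 1}" for j in range(m)],
            "chrom": [str(c + 1) for c in chrom_idx],
            "pos": (within + 1) * config.variant_spacing,
            "a1": "A",
            "a2": "G",
        }
    ).set_index("variant_id")
    variants["af"] = af
    variants["block"] = block
    variants["ld_rho"] = rho
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    return GenotypeMatrix(sample_ids=samples, variants=variants, dosage=dosage)


def simulate_samples(config: SimConfig) -> pd.DataFrame:
    """Sample metadata with stage counts matching the configured proportions
    exactly (largest-remainder rounding) and a Bernoulli disease label."""
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_samples
    stages = list(config.stage_proportions)
    raw = np.array([config.stage_proportions[s] * n for s in stages])
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    for i in np.argsort(raw - np.floor(raw))[::-1][:rem]:
        counts[i] += 1
    labels = np.repeat(stages, counts)
    rng.shuffle(labels)
    disease = np.where(rng.random(n) < config.case_fraction, "case", "control")
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n)],
            "stage": labels,
            "disease": disease,
        }
    )


# ---------------------------------------------------------------- truth


def make_truth(
    genotypes: GenotypeMatrix,
    n_probes: int,
    seed: int,
    frac_quant: float = 0.323,
    frac_variable: float = 0.204,
    frac_cis: float = 0.05,
    frac_trans: float = 0.01,
    frac_silencing: float = 0.08,
    frac_stage_mean: float = 0.25,
    frac_stage_logodds: float = 0.30,
    beta_mean: float = 0.8,
    alpha_silencing: float = 2.0,
    stage_mean_shift: float = 1.0,
    stage_logodds_shift: float = 2.0,
    noise_sd: float = 1.0,
    cis_offset_max: int = 100_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-probe truth table plus probe annotation.

    Probe classes: 'quant' (always expressed, baseline log-odds +6, so
    expression probability >= 0.9975 in every stage), 'variable' (baseline
    log-odds spread over roughly (-2.5, 1.6), optionally shifted by stage or
    silenced per A1 allele copy), 'silent' (baseline -6; array probes never
    above background). Genetic effects: a fraction of quant probes get a cis
    (same chromosome, probe placed within ``cis_offset_max`` of the causal
    variant) or trans (different chromosome) effect of ``beta_mean`` per
    allele on log2 intensity; a fraction of variable probes get a cis
    silencing effect of ``alpha_silencing`` on the expression log-odds.
    Stage effects (secretory shift) hit a fraction of each class.
    """
    if frac_quant + frac_variable > 1.0:
        raise ConfigError("frac_quant + frac_variable must be <= 1")
    rng = np.random.default_rng(seed)
    var = genotypes.variants
    n_quant = int(round(n_probes * frac_quant))
    n_varb = int(round(n_probes * frac_variable))
    klass = np.array(
        ["quant"] * n_quant
        + ["variable"] * n_varb
        + ["silent"] * (n_probes - n_quant - n_varb)
    )

    baseline_lo = np.full(n_probes, -6.0)
    baseline_lo[klass == "quant"] = 6.0
    baseline_lo[klass == "variable"] = np.clip(
        rng.normal(0.0, 1.25, size=n_varb), -2.5, 1.6
    )
    base_mu = rng.normal(8.0, 1.0, size=n_probes)

    mu = np.tile(base_mu[:, None], (1, len(STAGES_7)))
    lo = np.tile(baseline_lo[:, None], (1, len(STAGES_7)))
    secretory = np.isin(STAGES_7, ("ES", "MS", "LS"))
    # stage effects: shift secretory stages up or down for a fraction of probes
    for rows, cols, shift, pool in (
        (mu, secretory, stage_mean_shift, klass == "quant"),
        (lo, secretory, stage_logodds_shift, klass == "variable"),
    ):
        frac = frac_stage_mean if rows is mu else frac_stage_logodds
        hit = pool & (rng.random(n_probes) < frac)
        sign = rng.choice([-1.0, 1.0], size=n_probes)
        rows[np.ix_(hit, cols)] += (sign[hit] * shift)[:, None]

    causal = np.array([""] * n_probes, dtype=object)
    qtl_type = np.array([""] * n_probes, dtype=object)
    beta = np.zeros(n_probes)
    alpha = np.zeros(n_probes)
    quant_idx = np.flatnonzero(klass == "quant")
    varb_idx = np.flatnonzero(klass == "variable")
    n_cis = int(round(len(quant_idx) * frac_cis))
    n_trans = int(round(len(quant_idx) * frac_trans))
    n_sil = int(round(len(varb_idx) * frac_silencing))
    picks = rng.choice(quant_idx, size=n_cis + n_trans, replace=False)
    cis_picks, trans_picks = picks[:n_cis], picks[n_cis:]
    sil_picks = rng.choice(varb_idx, size=n_sil, replace=False)
    all_snps = np.array(var.index)
    for idx, kind in ((cis_picks, "cis"), (trans_picks, "trans"), (sil_picks, "cis")):
        snps = rng.choice(all_snps, size=len(idx), replace=False)
        causal[idx] = snps
        qtl_type[idx] = kind
    beta[cis_picks] = beta_mean * rng.choice([-1.0, 1.0], size=n_cis)
    beta[trans_picks] = beta_mean * rng.choice([-1.0, 1.0], size=n_trans)
    alpha[sil_picks] = alpha_silencing * rng.choice([-1.0, 1.0], size=n_sil)

    # probe placement: cis probes near their causal variant, trans probes on
    # a different chromosome, everything else uniform over the variant span
    chroms = var["chrom"].unique()
    span = {c: int(var.loc[var["chrom"] == c, "pos"].max()) for c in chroms}
    probe_chrom = rng.choice(chroms, size=n_probes)
    probe_pos = np.array(
        [rng.integers(1, span[c] + 1) for c in probe_chrom], dtype=int
    )
    for i in range(n_probes):
        if not causal[i]:
            continue
        c_chrom = var.at[causal[i], "chrom"]
        c_pos = int(var.at[causal[i], "pos"])
        if qtl_type[i] == "cis":
            probe_chrom[i] = c_chrom
            probe_pos[i] = max(1, c_pos + int(rng.integers(-cis_offset_max, cis_offset_max + 1)))
        else:
            others = [c for c in chroms if c != c_chrom]
            probe_chrom[i] = rng.choice(others)
            probe_pos[i] = int(rng.integers(1, span[probe_chrom[i]] + 1))

    probe_ids = [f"PRB_{i + 1:06d}" for i in range(n_probes)]
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "klass": klass,
            "causal_snp": causal,
            "qtl_type": qtl_type,
            "beta_mean": beta,
            "alpha_silencing": alpha,
            "baseline_logodds": baseline_lo,
            "noise_sd": float(noise_sd),
        }
    )
    truth[MU_COLS] = mu
    truth[LO_COLS] = lo
    if noise_sd <= 0:
        raise ConfigError("noise_sd must be > 0")
    probes = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_symbol": [f"GENE{i + 1}" for i in range(n_probes)],
            "chromosome": probe_chrom,
            "probe_start": probe_pos,
            "tss": probe_pos,
        }
    )
    return truth, probes


# ---------------------------------------------------------------- expression


def simulate_expression(
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    truth: pd.DataFrame,
    probes: pd.DataFrame,
    seed: int,
    disease_effect: float = 0.0,
    background_log2_mean: float = 5.0,
) -> ExpressionDataset:
    """Draw intensities and detection p-values from the truth model.

    Per sample x probe: expressed ~ Bernoulli(logistic(baseline + stage
    log-odds + alpha_silencing * dosage)). If expressed, detection
    p ~ U(0, 0.05] and log2 intensity = stage mean + beta_mean * dosage +
    disease_effect * case + N(0, noise_sd); if not, detection p ~ U(0.05, 1]
    and log2 intensity ~ N(background_log2_mean, noise_sd). Raw (2**log2)
    intensities are returned so normalisation runs on positive raw values.
    """
    rng = np.random.default_rng(seed)
    unknown = set(samples["stage"]) - set(STAGES_7)
    if unknown:
        raise ConfigError(f"unknown stage labels: {sorted(unknown)}")
    used = set(truth.loc[truth["causal_snp"] != "", "causal_snp"])
    missing = used - set(genotypes.variants.index)
    if missing:
        raise ConfigError(f"truth references variants absent from genotypes: {sorted(missing)[:5]}")
    if list(truth["probe_id"]) != list(probes["probe_id"]):
        raise ConfigError("truth and probe annotation probe_id order mismatch")

    order = {s: i for i, s in enumerate(genotypes.sample_ids)}
    samples = samples.copy()
    rows = np.array([order[s] for s in samples["sample_id"]])
    n, p = len(samples), len(truth)
    stage_idx = samples["stage"].map({s: i for i, s in enumerate(STAGES_7)}).to_numpy()
    is_case = (samples["disease"] == "case").to_numpy(dtype=float)

    mu_stage = truth[MU_COLS].to_numpy()  # (p, 7)
    lo_stage = truth[LO_COLS].to_numpy()
    mu = mu_stage[:, stage_idx].T  # (n, p)
    lo = lo_stage[:, stage_idx].T

    has_qtl = truth["causal_snp"].to_numpy() != ""
    if has_qtl.any():
        cols = [genotypes.variants.index.get_loc(v) for v in truth.loc[has_qtl, "causal_snp"]]
        g_causal = genotypes.dosage[np.ix_(rows, cols)]
        g_causal = np.nan_to_num(g_causal)  # missing causal dosage: no effect
        mu[:, has_qtl] += g_causal * truth.loc[has_qtl, "beta_mean"].to_numpy()[None, :]
        lo[:, has_qtl] += g_causal * truth.loc[has_qtl, "alpha_silencing"].to_numpy()[None, :]
    mu += disease_effect * is_case[:, None]

    prob = 1.0 / (1.0 + np.exp(-lo))
    expressed = rng.random((n, p)) < prob
    u = rng.random((n, p))
    detection = np.where(expressed, 0.05 * (1.0 - u), 0.05 + 0.95 * (1.0 - u))
    noise = rng.normal(0.0, 1.0, size=(n, p)) * truth["noise_sd"].to_numpy()[None, :]
    log2_level = np.where(expressed, mu + noise, background_log2_mean + noise)
    return ExpressionDataset(
        sample_ids=list(samples["sample_id"]),
        probes=probes.set_index("probe_id"),
        intensity=np.exp2(log2_level),
        detection_p=detection,
    )


# ---------------------------------------------------------------- GWAS

# Study conditions for SMR/HEIDI simulations: a 15-SNP cis block
# (equicorrelated latent rho 0.71, i.e. dosage r ~ 0.6 between the two
# causal SNPs in the linkage scenario), an eQTL cohort large enough for the
# delta-method null distribution of HEIDI to hold (the test was designed
# for consortium-scale expression panels), and a meta-analysis-scale GWAS.
SMR_SIM_DEFAULTS = dict(
    n_eqtl=2000,
    n_gwas=50_000,
    n_block=15,
    ld_rho=0.71,
    b_zx=0.5,
    b_xy_true=0.2,
    causal_variant="rs8",
    linkage_variant="rs2",
)


def simulate_smr_region(scenario: str, seed: int, **overrides):
    """One SMR/HEIDI replicate: a cis region's eQTL summary statistics, a
    matched GWAS summary table, and the eQTL genotype panel (for LD).

    Returns (region, gwas, genotypes) where ``region`` has columns
    variant_id, effect, se, p from a covariate-free linear scan of the
    simulated expression trait. Defaults are ``SMR_SIM_DEFAULTS``.
    """
    from .qtlmap import ScanConfig, eqtl_scan

    st = dict(SMR_SIM_DEFAULTS, **overrides)
    cfg = SimConfig(
        n_samples=st["n_eqtl"],
        n_variants=st["n_block"],
        n_chromosomes=1,
        ld_block_size=st["n_block"],
        ld_rho=st["ld_rho"],
        seed=seed,
    )
    g = simulate_genotypes(cfg)
    rng = np.random.default_rng(seed + 500)
    x = st["b_zx"] * g.column(st["causal_variant"]) + rng.normal(0.0, 1.0, st["n_eqtl"])
    expr = pd.DataFrame({"PROBE": x}, index=g.sample_ids)
    samples = pd.DataFrame(
        {"sample_id": g.sample_ids, "stage": "ES", "disease": "control"}
    )
    scan = eqtl_scan(expr, g, samples, ScanConfig(covariates=(), maf_floor=0.0))
    region = scan.frame(classes=("cis", "trans", "other"))[
        ["variant_id", "effect", "se", "p"]
    ]
    gwas = simulate_gwas_summary(
        g,
        scenario,
        b_xy_true=st["b_xy_true"],
        n_gwas=st["n_gwas"],
        seed=seed + 900,
        causal_variant=st["causal_variant"],
        b_zx=st["b_zx"],
        linkage_variant=st["linkage_variant"] if scenario == "linkage" else None,
    )
    return region, gwas, g


def simulate_gwas_summary(
    genotypes: GenotypeMatrix,
    scenario: str,
    b_xy_true: float,
    n_gwas: int,
    seed: int,
    causal_variant: str | None = None,
    b_zx: float = 0.8,
    linkage_variant: str | None = None,
    expression_noise_sd: float = 1.0,
    trait_noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-SNP GWAS summary statistics from an independent simulated cohort.

    Scenarios: 'pleiotropy' (the trait depends on the eQTL causal SNP through
    expression, so b_zy ~ b_zx * b_xy_true), 'linkage' (the trait depends on
    ``linkage_variant``, a different SNP in LD with the causal SNP), 'null'.
    The cohort is drawn from the same allele-frequency/LD model recorded in
    the genotype matrix; effects come from single-SNP OLS on the trait.
    Columns follow the COJO .ma layout: SNP A1 A2 freq b se p N.
    """
    if n_gwas < 2:
        raise ConfigError("n_gwas must be >= 2")
    if scenario not in ("pleiotropy", "linkage", "null"):
        raise ConfigError(f"unknown scenario {scenario!r}")
    var = genotypes.variants
    for col in ("af", "block", "ld_rho"):
        if col not in var.columns:
            raise ConfigError("genotype matrix lacks simulation metadata (af/block/ld_rho)")
    if scenario in ("pleiotropy", "linkage") and causal_variant is None:
        raise ConfigError(f"{scenario} scenario needs causal_variant")
    if scenario == "linkage":
        if linkage_variant is None or linkage_variant == causal_variant:
            raise ConfigError("linkage scenario needs a distinct linkage_variant")

    rng = np.random.default_rng(seed)
    G = _simulate_dosage(
        var["af"].to_numpy(), var["block"].to_numpy(), var["ld_rho"].to_numpy(), n_gwas, rng
    )
    if scenario == "pleiotropy":
        g = G[:, var.index.get_loc(causal_variant)]
        x = b_zx * g + rng.normal(0.0, expression_noise_sd, n_gwas)
        y = b_xy_true * x + rng.normal(0.0, trait_noise_sd, n_gwas)
    elif scenario == "linkage":
        g = G[:, var.index.get_loc(linkage_variant)]
        y = b_zx * b_xy_true * g + rng.normal(0.0, trait_noise_sd, n_gwas)
    else:
        y = rng.normal(0.0, trait_noise_sd, n_gwas)

    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    ssx = (gc**2).sum(axis=0)
    ssx_safe = np.where(ssx > 0, ssx, np.nan)
    b = gc.T @ yc / ssx_safe
    rss = (yc**2).sum() - b**2 * ssx_safe
    se = np.sqrt(rss / (n_gwas - 2) / ssx_safe)
    tstat = b / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n_gwas - 2)
    return pd.DataFrame(
        {
            "SNP": var.index,
            "A1": var["a1"].to_numpy(),
            "A2": var["a2"].to_numpy(),
            "freq": G.mean(axis=0) / 2.0,
            "b": b,
            "se": se,
            "p": pvals,
            "N": n_gwas,
        }
    ).reset_index(drop=True)
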