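"""Simulation studies: null calibration, parameter recovery, conditional
signal counting, and SMR/HEIDI operating characteristics.

These are the experiments the package runs over its own synthetic cohorts to
demonstrate that every scan is calibrated under the null and recovers the
effects the generator planted. Problem sizes follow the study they emulate
(n = 229 for recovery; n = 200 for calibration) except the SMR/HEIDI
experiments, which use the larger cohorts that test's asymptotics require
(see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import integrate, qtlmap, synthdata
from .errors import UntestableError
from .expression import DetectionCalls

_STAGES = ("M", "P", "ES", "MS", "LS")


def _samples(n: int, rng) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "stage": rng.choice(_STAGES, size=n),
            "disease": rng.choice(["case", "control"], size=n),
            "quality": rng.uniform(0.40, 0.46, size=n),
        }
    )


def _geno_col(n: int, maf: float, rng, n_var: int = 1):
    from .genotypes import GenotypeMatrix

    dosage = rng.binomial(2, maf, size=(n, n_var)).astype(float)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(n_var)],
            "chrom": "1",
            "pos": np.arange(1, n_var + 1) * 1000,
            "a1": "A",
            "a2": "G",
        }
    ).set_index("variant_id")
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, dosage)


# ---------------------------------------------------------------- calibration


def null_pvalues_eqtl(n_reps: int = 500, n: int = 200, maf: float = 0.3, seed: int = 0):
    """Null linear-scan p-values: one independent expression draw per
    replicate against a shared genotype column (covariates included)."""
    rng = np.random.default_rng(seed)
    samples = _samples(n, rng)
    g = _geno_col(n, maf, rng)
    y = rng.normal(0.0, 1.0, size=(n, n_reps))
    expr = pd.DataFrame(y, index=g.sample_ids, columns=[f"r{k}" for k in range(n_reps)])
    res = qtlmap.eqtl_scan(expr, g, samples, qtlmap.ScanConfig(maf_floor=0.0))
    return res.p[:, 0]


def null_pvalues_ebtl(n_reps: int = 500, n: int = 200, maf: float = 0.3, seed: int = 0):
    """Null logistic-scan p-values (expressed status independent of dosage)."""
    rng = np.random.default_rng(seed)
    samples = _samples(n, rng)
    g = _geno_col(n, maf, rng)
    expressed = rng.random((n, n_reps)) < 0.5
    calls = DetectionCalls(g.sample_ids, [f"r{k}" for k in range(n_reps)], expressed, 0.05)
    res = qtlmap.ebtl_scan(calls, g, samples, qtlmap.ScanConfig(maf_floor=0.0))
    return res.p[:, 0]


def null_pvalues_prop(n_reps: int = 500, n: int = 200, seed: int = 0):
    """Null activation/repression p-values: equal expressed proportions in
    both stage groups, disease and quality covariates present."""
    from .cyclestage import StageContrast, prop_test

    rng = np.random.default_rng(seed)
    samples = _samples(n, rng)
    samples["stage"] = np.where(np.arange(n) % 2 == 0, "P", "ES")
    expressed = rng.random((n, n_reps)) < 0.5
    calls = DetectionCalls(
        list(samples["sample_id"]), [f"r{k}" for k in range(n_reps)], expressed, 0.05
    )
    res = prop_test(calls, samples, StageContrast(("P",), ("ES",)))
    return res["p"].to_numpy()


def null_pvalues_interaction(n_reps: int = 500, n: int = 200, seed: int = 0):
    """Null interaction p-values: a constant genotype effect across stages."""
    rng = np.random.default_rng(seed)
    n_stage = len(_STAGES)
    per = n // n_stage
    stages = np.repeat(_STAGES, per)
    samples = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(len(stages))], "stage": stages,
         "disease": "control"}
    )
    out = np.empty(n_reps)
    for k in range(n_reps):
        g = rng.binomial(2, 0.3, len(stages)).astype(float)
        y = 0.5 * g + rng.normal(0.0, 1.0, len(stages))
        res = qtlmap.interaction_test(y, g, samples)
        out[k] = res.p if res.testable else np.nan
    return out[np.isfinite(out)]


# ---------------------------------------------------------------- recovery


def recovery_linear(
    n_reps: int = 200, n: int = 229, beta: float = 0.5, maf: float = 0.3, seed: int = 0
):
    """Replicated cis-eQTL recovery: returns (estimates, ses)."""
    rng = np.random.default_rng(seed)
    samples = _samples(n, rng)
    g = _geno_col(n, maf, rng)
    y = beta * g.dosage[:, [0]] + rng.normal(0.0, 1.0, size=(n, n_reps))
    expr = pd.DataFrame(y, index=g.sample_ids, columns=[f"r{k}" for k in range(n_reps)])
    res = qtlmap.eqtl_scan(expr, g, samples, qtlmap.ScanConfig(maf_floor=0.0))
    return res.effect[:, 0], res.se[:, 0]


def recovery_logistic(
    n_reps: int = 200, n: int = 229, alpha: float = 1.5, maf: float = 0.3, seed: int = 0
):
    """Replicated silencing-eBTL recovery: returns (estimates, ses)."""
    rng = np.random.default_rng(seed)
    samples = _samples(n, rng)
    g = _geno_col(n, maf, rng)
    logodds = -1.0 + alpha * g.dosage[:, [0]]
    expressed = rng.random((n, n_reps)) < 1.0 / (1.0 + np.exp(-logodds))
    calls = DetectionCalls(g.sample_ids, [f"r{k}" for k in range(n_reps)], expressed, 0.05)
    res = qtlmap.ebtl_scan(calls, g, samples, qtlmap.ScanConfig(maf_floor=0.0))
    return res.effect[:, 0], res.se[:, 0]


def conditional_signal_counts(
    n_causal: int, n_reps: int = 10, n: int = 400, beta: float = 0.8,
    threshold: float = 1e-4, seed: int = 0,
):
    """Independent-signal counts from the stepwise conditional scan over a
    12-SNP region with one or two planted causal variants (r^2 ~ 0.1
    between them in the two-causal case)."""
    counts = []
    for k in range(n_reps):
        cfg = synthdata.SimConfig(
            n_samples=n, n_variants=12, n_chromosomes=1, ld_block_size=12,
            ld_rho=0.32 if n_causal == 2 else 0.0, maf_range=(0.3, 0.4),
            seed=seed + 101 * k,
        )
        g = synthdata.simulate_genotypes(cfg)
        rng = np.random.default_rng(seed + 101 * k + 50)
        y = beta * g.column("rs3") + rng.normal(0.0, 1.0, n)
        if n_causal == 2:
            y = y + beta * g.column("rs9")
        samples = _samples(n, rng)
        res = qtlmap.conditional_scan(
            "p", y, g, samples, qtlmap.ScanConfig(maf_floor=0.0), threshold
        )
        counts.append(res.n_independent)
    return counts


# ---------------------------------------------------------------- SMR / HEIDI


def smr_heidi_study(scenario: str, n_reps: int = 200, seed: int = 0, alpha: float = 0.05):
    """Replicated SMR/HEIDI under pleiotropy, linkage or null scenarios.

    Returns a dict with the b_xy estimates, the HEIDI rejection count among
    testable replicates, and the untestable count.
    """
    b_xy, rejected, untestable = [], 0, 0
    for k in range(n_reps):
        region, gwas, g = synthdata.simulate_smr_region(scenario, seed=seed + 7919 * k)
        try:
            res = integrate.run_smr(
                "p", region, integrate.harmonize_gwas(g.variants, gwas), g,
                n_probes_tested=1,
            )
        except UntestableError:
            untestable += 1
            continue
        b_xy.append(res.b_xy)
        if res.p_heidi is None:
            untestable += 1
        elif res.p_heidi < alpha:
            rejected += 1
    n_testable = n_reps - untestable
    return {
        "b_xy": np.array(b_xy),
        "rejected": rejected,
        "untestable": untestable,
        "n_testable": n_testable,
        "rejection_rate": rejected / n_testable if n_testable else np.nan,
    }
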