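"""Cycle-stage analyses: differential expression on the quantitative track,
activation/repression (expressed vs. not) on the variable track, and gene-set
enrichment.

The quantitative track is tested probe-by-probe with a linear model and an
empirical-Bayes moderated t: per-probe residual variances s_g^2 are shrunk
toward a prior (d0, s0^2) estimated by moment-matching the distribution of
log s_g^2 against its scaled-F form, giving
s_tilde^2 = (d0*s0^2 + d*s^2) / (d0 + d) and a t statistic on d0 + d df.

The variable track is tested with per-probe logistic regression of
expressed-status on a stage indicator plus disease status and the per-sample
quality covariate (proportion of all probes expressed):

    ln(p / (1 - p)) = b0 + b1*stage + b2*disease + b3*quality

with a Wald test on b1; b1 > 0 toward group_b is labelled 'activated'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats

from .errors import ConfigError, ParseError
from .expression import DetectionCalls

STAGE_MERGE_DEFAULT = {
    "M": "M", "EP": "P", "MP": "P", "LP": "P", "ES": "ES", "MS": "MS", "LS": "LS",
}
MERGED_STAGES = ("M", "P", "ES", "MS", "LS")
SUCCESSIVE_CONTRASTS = (("M", "P"), ("P", "ES"), ("ES", "MS"), ("MS", "LS"))


@dataclass(frozen=True)
class StageContrast:
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ConfigError("contrast groups must be disjoint")
        if not self.group_a or not self.group_b:
            raise ConfigError("contrast groups must be non-empty")
        if not self.label:
            object.__setattr__(
                self, "label", "+".join(self.group_a) + " vs " + "+".join(self.group_b)
            )


def combine_stages(samples: pd.DataFrame, mapping: dict | None = None) -> pd.DataFrame:
    """Rewrite stage labels (default: EP/MP/LP -> P); counts are conserved."""
    mapping = STAGE_MERGE_DEFAULT if mapping is None else mapping
    observed = set(samples["stage"])
    unmapped = observed - set(mapping)
    if unmapped:
        raise ConfigError(f"stage mapping omits observed stages: {sorted(unmapped)}")
    out = samples.copy()
    out["stage"] = out["stage"].map(mapping)
    return out


# ---------------------------------------------------------------- eBayes


@dataclass
class EBayesParams:
    d0: float  # prior df (may be inf)
    s0_sq: float  # prior variance
    s_sq: np.ndarray  # per-probe residual variances
    d: float  # residual df per probe
    s_tilde_sq: np.ndarray  # moderated variances


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(s_sq: np.ndarray, d: float) -> EBayesParams:
    """Estimate (d0, s0^2) by matching mean and variance of log s_g^2 to the
    scaled-F distribution of sample variances, then shrink."""
    s_sq = np.asarray(s_sq, dtype=float)
    if d <= 0:
        raise ConfigError("residual df must be positive")
    z = np.log(np.maximum(s_sq, 1e-300))
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    n = len(e)
    evar = ((e - emean) ** 2).sum() / max(n - 1, 1) - special.polygamma(1, d / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s_tilde = (d0 * s0_sq + d * s_sq) / (d0 + d)
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
        s_tilde = np.full_like(s_sq, s0_sq)
    return EBayesParams(d0=d0, s0_sq=s0_sq, s_sq=s_sq, d=d, s_tilde_sq=s_tilde)


def de_test(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: StageContrast,
    fc_threshold: float = 1.5,
    fdr: float = 0.05,
    sd_based: bool = False,
) -> pd.DataFrame:
    """Moderated-t differential expression between two stage groups.

    ``expr`` is a samples x probes matrix of normalised log2 intensities.
    log2_fc > 0 means higher in group_b. 'significant' requires both the
    fold-change criterion (|log2_fc| >= log2(fc_threshold), or, with
    ``sd_based``, |log2_fc| >= fc_threshold * pooled residual SD) and
    BH-adjusted q < ``fdr``.
    """
    from .qtlmap import bh_adjust

    samp = samples.set_index("sample_id").loc[expr.index]
    in_a = samp["stage"].isin(contrast.group_a).to_numpy()
    in_b = samp["stage"].isin(contrast.group_b).to_numpy()
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ConfigError(f"contrast {contrast.label}: both groups need >= 2 samples")
    y = expr.to_numpy()[in_a | in_b]
    grp = in_b[in_a | in_b].astype(float)
    na, nb = int((grp == 0).sum()), int((grp == 1).sum())
    d = na + nb - 2
    if d <= 0:
        raise ConfigError(f"contrast {contrast.label}: zero residual df")
    mean_a = y[grp == 0].mean(axis=0)
    mean_b = y[grp == 1].mean(axis=0)
    log2_fc = mean_b - mean_a
    rss = ((y[grp == 0] - mean_a) ** 2).sum(axis=0) + ((y[grp == 1] - mean_b) ** 2).sum(axis=0)
    s_sq = rss / d
    eb = moderate_variances(s_sq, d)
    se = np.sqrt(eb.s_tilde_sq * (1.0 / na + 1.0 / nb))
    tmod = log2_fc / se
    df_total = eb.d0 + d
    p = 2.0 * stats.t.sf(np.abs(tmod), df=df_total if np.isfinite(df_total) else 1e12)
    q = bh_adjust(p)
    if sd_based:
        fc_pass = np.abs(log2_fc) >= fc_threshold * np.sqrt(eb.s_tilde_sq)
    else:
        fc_pass = np.abs(log2_fc) >= np.log2(fc_threshold)
    out = pd.DataFrame(
        {
            "probe_id": expr.columns,
            "log2_fc": log2_fc,
            "t_moderated": tmod,
            "p": p,
            "q_bh": q,
            "significant": fc_pass & (q < fdr),
        }
    )
    out.attrs["ebayes"] = eb
    out.attrs["contrast"] = contrast.label
    return out


# ---------------------------------------------------------------- Eq.-style proportion test


def prop_test(
    calls: DetectionCalls,
    samples: pd.DataFrame,
    contrast: StageContrast,
    fdr: float = 0.05,
    include_disease: bool = True,
    include_quality: bool = True,
) -> pd.DataFrame:
    """Logistic activation/repression test on the variable track.

    Returns one row per testable probe with beta_stage (log-odds toward
    group_b), odds_ratio, Wald p, BH q, and direction. Probes expressed in
    all or in no samples within the contrast are excluded (returned in
    ``result.attrs['excluded']``): their intercept separates completely.
    """
    from .qtlmap import bh_adjust

    samp = samples.set_index("sample_id").loc[calls.sample_ids]
    if include_quality and "quality" not in samp.columns:
        raise ConfigError("samples table lacks the 'quality' covariate")
    in_a = samp["stage"].isin(contrast.group_a).to_numpy()
    in_b = samp["stage"].isin(contrast.group_b).to_numpy()
    use = in_a | in_b
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ConfigError(f"contrast {contrast.label}: empty group")
    y_all = calls.expressed[use]
    grp = in_b[use].astype(float)
    cols = [np.ones(use.sum()), grp]
    if include_disease:
        cols.append((samp.loc[use, "disease"] == "case").to_numpy(dtype=float))
    if include_quality:
        cols.append(samp.loc[use, "quality"].to_numpy(dtype=float))
    X = np.column_stack(cols)
    rows, excluded = [], []
    for j, probe in enumerate(calls.probe_ids):
        y = y_all[:, j].astype(float)
        if y.min() == y.max():
            excluded.append(probe)
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            beta, se = fit.params[1], fit.bse[1]
            if not np.isfinite(se) or se > 1e3:
                raise ValueError("unstable fit")
            pval = 2.0 * stats.norm.sf(abs(beta / se))
        except Exception:
            excluded.append(probe)
            continue
        rows.append((probe, beta, np.exp(beta), se, pval))
    out = pd.DataFrame(
        rows, columns=["probe_id", "beta_stage", "odds_ratio", "se", "p"]
    )
    out["q_bh"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["direction"] = np.where(out["beta_stage"] > 0, "activated", "repressed")
    out.attrs["excluded"] = excluded
    out.attrs["contrast"] = contrast.label
    return out


# ---------------------------------------------------------------- enrichment


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def enrich_hypergeometric(
    gene_list, gene_sets: dict[str, set[str]], background
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``gene_list`` in each set,
    intersected with the background universe; BH across sets."""
    from .qtlmap import bh_adjust

    background = set(background)
    if not background:
        raise ConfigError("empty background universe")
    gene_list = set(gene_list)
    if not gene_list <= background:
        raise ConfigError("gene_list must be a subset of the background")
    m_univ, k_list = len(background), len(gene_list)
    rows = []
    for name, genes in gene_sets.items():
        inset = genes & background
        n_set = len(inset)
        overlap = len(inset & gene_list)
        p = stats.hypergeom.sf(overlap - 1, m_univ, n_set, k_list)
        rows.append((name, n_set, overlap, p))
    out = pd.DataFrame(rows, columns=["gene_set", "N", "n", "p"])
    out["q_bh"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out.sort_values("p", kind="stable").reset_index(drop=True)
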