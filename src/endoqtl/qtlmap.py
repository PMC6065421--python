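"""Genome-wide eQTL (linear) and eBTL (logistic) scans with cis/trans
classification, sentinel selection, conditional analysis, genotype x stage
interaction tests, and multiple-testing helpers.

Definitions used throughout: a probe-variant pair is 'cis' when both sit on
the same chromosome and the SNP lies within +/-cis_window bp of the probe
start (boundary inclusive); 'trans' when they sit on different chromosomes;
same-chromosome pairs beyond the window are 'other' and belong to neither
result set. Effects are per copy of A1; distance = SNP position - probe
start (signed, same-chromosome pairs only).

Missing dosages are mean-imputed inside the vectorised scans (the input is
expected to be post-QC, <= 5% missing per variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, UntestableError
from .expression import DetectionCalls

STAGE_LEVELS_MERGED = ("M", "P", "ES", "MS", "LS")
STAGE_LEVELS_7 = ("M", "EP", "MP", "LP", "ES", "MS", "LS")


@dataclass
class ScanConfig:
    cis_window: int = 250_000
    covariates: tuple[str, ...] = ("disease", "stage")
    fdr: float = 0.05
    bonferroni_alpha: float = 0.05
    maf_floor: float = 0.05
    stage_levels: str = "merged"  # 'merged' (5-level) or 'full' (7-level)
    screen_p: float | None = None  # eBTL score-test screen; None = exact everywhere

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise ConfigError("cis_window must be > 0")
        if self.stage_levels not in ("merged", "full"):
            raise ConfigError("stage_levels must be 'merged' or 'full'")


# ---------------------------------------------------------------- multiple testing


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1, order-preserving)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_threshold(alpha: float, m: int) -> float:
    if m < 1:
        raise ConfigError("number of tests must be >= 1")
    return alpha / m


def bh_threshold(p, fdr: float = 0.05) -> float:
    """Largest p-value declared significant by BH at the given FDR (0 if none)."""
    p = np.sort(np.asarray(p, dtype=float))
    m = len(p)
    crit = np.arange(1, m + 1) / m * fdr
    passing = np.flatnonzero(p <= crit)
    return float(p[passing[-1]]) if len(passing) else 0.0


# ---------------------------------------------------------------- design helpers


def classify_cis_trans(probe_row, variant_row, cis_window: int = 250_000):
    """Class + signed distance for one probe-variant pair."""
    p_chrom, v_chrom = str(probe_row["chromosome"]), str(variant_row["chrom"])
    if not p_chrom or not v_chrom:
        raise ConfigError("chromosome labels required for cis/trans classification")
    if p_chrom != v_chrom:
        return "trans", None
    distance = int(variant_row["pos"]) - int(probe_row["probe_start"])
    klass = "cis" if abs(distance) <= cis_window else "other"
    return klass, distance


def covariate_matrix(samples: pd.DataFrame, cfg: ScanConfig) -> tuple[np.ndarray, list[str]]:
    """Intercept + requested covariates; stage enters as treatment-coded
    dummies over the merged 5-level vocabulary by default."""
    n = len(samples)
    cols, names = [np.ones(n)], ["intercept"]
    if "disease" in cfg.covariates:
        cols.append((samples["disease"] == "case").to_numpy(dtype=float))
        names.append("disease")
    if "stage" in cfg.covariates:
        levels = STAGE_LEVELS_MERGED if cfg.stage_levels == "merged" else STAGE_LEVELS_7
        observed = [s for s in levels if s in set(samples["stage"])]
        for s in observed[1:]:  # first observed level is the reference
            cols.append((samples["stage"] == s).to_numpy(dtype=float))
            names.append(f"stage_{s}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfigError("covariate design is rank deficient")
    return X, names


def _impute_mean(d: np.ndarray) -> np.ndarray:
    if not np.isnan(d).any():
        return d
    col_mean = np.nanmean(d, axis=0)
    out = d.copy()
    idx = np.where(np.isnan(out))
    out[idx] = col_mean[idx[1]]
    return out


def _residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return M - Q @ (Q.T @ M)


# ---------------------------------------------------------------- result containers


@dataclass
class ScanResult:
    """Dense per-pair scan statistics with lazy record extraction.

    ``effect``/``se``/``p`` are (n_probes, n_variants) arrays; entries are NaN
    where a pair was skipped (rank-deficient design) or, for a screened eBTL
    scan, where only the score p is available (p is then the score-test p).
    """

    probe_ids: list[str]
    probes: pd.DataFrame  # indexed by probe_id: chromosome, probe_start, gene_symbol
    variants: pd.DataFrame  # indexed by variant_id: chrom, pos, a1
    effect: np.ndarray
    se: np.ndarray
    p: np.ndarray
    kind: str  # 'linear' or 'logistic'
    cis_window: int
    n_samples: int
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n_tests(self) -> int:
        return int(np.isfinite(self.p).sum())

    def _class_arrays(self):
        p_chrom = self.probes["chromosome"].astype(str).to_numpy()
        v_chrom = self.variants["chrom"].astype(str).to_numpy()
        same = p_chrom[:, None] == v_chrom[None, :]
        dist = self.variants["pos"].to_numpy()[None, :] - self.probes[
            "probe_start"
        ].to_numpy()[:, None]
        cis = same & (np.abs(dist) <= self.cis_window)
        return same, cis, dist

    def frame(self, max_p: float | None = None, classes=("cis", "trans")) -> pd.DataFrame:
        """Records table (one row per pair) filtered by class and p-value."""
        same, cis, dist = self._class_arrays()
        keep = np.zeros_like(same)
        if "cis" in classes:
            keep |= cis
        if "trans" in classes:
            keep |= ~same
        if "other" in classes:
            keep |= same & ~cis
        mask = keep & np.isfinite(self.p)
        if max_p is not None:
            mask &= self.p <= max_p
        pi, vi = np.nonzero(mask)
        klass = np.where(~same[pi, vi], "trans", np.where(cis[pi, vi], "cis", "other"))
        out = pd.DataFrame(
            {
                "probe_id": np.asarray(self.probe_ids, dtype=object)[pi],
                "gene": self.probes["gene_symbol"].to_numpy()[pi],
                "chrom_probe": self.probes["chromosome"].astype(str).to_numpy()[pi],
                "variant_id": np.asarray(self.variants.index, dtype=object)[vi],
                "chrom_snp": self.variants["chrom"].astype(str).to_numpy()[vi],
                "position_snp": self.variants["pos"].to_numpy()[vi],
                "a1": self.variants["a1"].to_numpy()[vi],
                "effect": self.effect[pi, vi],
                "se": self.se[pi, vi],
                "p": self.p[pi, vi],
                "klass": klass,
                "distance": np.where(same[pi, vi], dist[pi, vi], np.nan),
            }
        )
        if self.kind == "logistic":
            out["odds_ratio"] = np.exp(out["effect"])
        return out.sort_values("p", kind="stable").reset_index(drop=True)

    def class_pvalues(self, klass: str) -> np.ndarray:
        """All finite p-values of one class (for FDR/Bonferroni accounting)."""
        same, cis, _ = self._class_arrays()
        sel = {"cis": cis, "trans": ~same, "other": same & ~cis}[klass]
        vals = self.p[sel]
        return vals[np.isfinite(vals)]


# ---------------------------------------------------------------- linear scan


def _align(expr_index, g, samples):
    ids = list(expr_index)
    if set(ids) - set(g.sample_ids):
        raise ConfigError("expression samples missing from genotypes")
    if set(ids) - set(samples["sample_id"]):
        raise ConfigError("expression samples missing from metadata")
    gg = g.subset_samples(ids)
    samp = samples.set_index("sample_id").loc[ids].reset_index()
    return gg, samp


def eqtl_scan(
    expr: pd.DataFrame,
    g,
    samples: pd.DataFrame,
    cfg: ScanConfig | None = None,
    probes: pd.DataFrame | None = None,
) -> ScanResult:
    """Additive-dosage linear scan of every probe against every variant.

    ``expr``: samples x probes normalised log2 matrix (quantitative track).
    ``probes``: annotation indexed by probe_id (gene_symbol, chromosome,
    probe_start) used for cis/trans classification. Per pair: y ~ dosage +
    covariates, Wald t p-value. Implemented by residualising expression and
    dosage on the covariates (Frisch-Waugh), which reproduces the full-model
    t-test exactly.
    """
    cfg = cfg or ScanConfig()
    g, samp = _align(expr.index, g, samples)
    keep = g.maf() >= cfg.maf_floor
    g = g.subset_variants(keep)
    C, cov_names = covariate_matrix(samp, cfg)
    n, k = C.shape
    dof = n - k - 1
    if dof <= 0:
        raise ConfigError("not enough samples for the covariate model")
    Q, _ = np.linalg.qr(C)
    Y = _residualize(expr.to_numpy(dtype=float), Q)
    G = _residualize(_impute_mean(g.dosage), Q)
    ssg = (G**2).sum(axis=0)
    ssy = (Y**2).sum(axis=0)
    degenerate = ssg < 1e-10  # genotype collinear with covariates: pair skipped
    ssg_safe = np.where(degenerate, np.nan, ssg)
    beta = (Y.T @ G) / ssg_safe[None, :]
    rss = np.maximum(ssy[:, None] - beta**2 * ssg_safe[None, :], 0.0)
    se = np.sqrt(rss / dof / ssg_safe[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=dof)
    return ScanResult(
        probe_ids=list(expr.columns),
        probes=_probe_meta(expr.columns, probes),
        variants=g.variants[["chrom", "pos", "a1"]].copy(),
        effect=beta,
        se=se,
        p=p,
        kind="linear",
        cis_window=cfg.cis_window,
        n_samples=n,
        covariate_names=cov_names,
    )


def _probe_meta(probe_ids, probes: pd.DataFrame | None) -> pd.DataFrame:
    """Align the probe annotation to the scanned probes; without annotation,
    fall back to placeholders (every pair then classifies as cis/other on a
    single dummy chromosome — callers wanting cis/trans must pass probes)."""
    if probes is not None:
        return probes.loc[list(probe_ids)][["gene_symbol", "chromosome", "probe_start"]]
    return pd.DataFrame(
        {
            "gene_symbol": ["" for _ in probe_ids],
            "chromosome": ["" for _ in probe_ids],
            "probe_start": [1 for _ in probe_ids],
        },
        index=list(probe_ids),
    )


# ---------------------------------------------------------------- logistic scan


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _batch_logistic(y: np.ndarray, C: np.ndarray, G: np.ndarray, maxit: int = 30, tol: float = 1e-8):
    """IRLS for y ~ C + g_v, vectorised over variants.

    Returns (beta_g, se_g, converged) arrays of length n_variants.
    """
    n, k0 = C.shape
    V = G.shape[1]
    k = k0 + 1
    beta = np.zeros((V, k))
    ridge = 1e-8 * np.eye(k)
    converged = np.zeros(V, dtype=bool)
    XtWX = np.zeros((V, k, k))
    for _ in range(maxit):
        eta = C @ beta[:, :k0].T + G * beta[:, k0]
        mu = _sigmoid(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        XtWX[:, :k0, :k0] = np.einsum("nv,nk,nl->vkl", w, C, C, optimize=True)
        cross = np.einsum("nv,nk->vk", w * G, C, optimize=True)
        XtWX[:, :k0, k0] = cross
        XtWX[:, k0, :k0] = cross
        XtWX[:, k0, k0] = (w * G * G).sum(axis=0)
        r = y[:, None] - mu
        score = np.empty((V, k))
        score[:, :k0] = r.T @ C
        score[:, k0] = (G * r).sum(axis=0)
        delta = np.linalg.solve(XtWX + ridge[None], score[..., None])[..., 0]
        beta += delta
        step = np.abs(delta).max(axis=1)
        converged = step < tol
        if converged.all():
            break
    cov = np.linalg.inv(XtWX + ridge[None])
    se_g = np.sqrt(np.maximum(cov[:, k0, k0], 0.0))
    return beta[:, k0], se_g, converged


def firth_logistic(X: np.ndarray, y: np.ndarray, maxit: int = 100, tol: float = 1e-8):
    """Firth-penalised logistic regression (Jeffreys-prior score correction).

    Yields finite estimates under complete separation. Returns (beta, se,
    converged).
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(maxit):
        mu = _sigmoid(X @ beta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        XtWX = (X * w[:, None]).T @ X
        try:
            inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            inv = np.linalg.inv(XtWX + 1e-8 * np.eye(k))
        h = np.einsum("ij,jk,ik->i", X * w[:, None], inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        delta = inv @ score
        if np.abs(delta).max() > 5.0:  # damp wild steps
            delta *= 5.0 / np.abs(delta).max()
        beta = beta + delta
        if np.abs(delta).max() < tol:
            mu = _sigmoid(X @ beta)
            w = np.maximum(mu * (1.0 - mu), 1e-12)
            inv = np.linalg.inv((X * w[:, None]).T @ X + 1e-12 * np.eye(k))
            return beta, np.sqrt(np.diag(inv)), True
    return beta, np.sqrt(np.diag(inv)), False


def logistic_score_scan(y: np.ndarray, C: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Rao score-test p-values for adding each variant to the null logistic
    model y ~ C. Fully vectorised; used to screen large eBTL scans."""
    import warnings

    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, C, family=sm.families.Binomial()).fit(maxiter=100)
    mu = fit.fittedvalues
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    U = G.T @ (y - mu)
    Cw = C * w[:, None]
    M = C.T @ Cw
    B = Cw.T @ G  # (k0, V)
    S = np.linalg.solve(M, B)
    V_info = (w[:, None] * G * G).sum(axis=0) - (B * S).sum(axis=0)
    V_info = np.maximum(V_info, 1e-12)
    return stats.chi2.sf(U**2 / V_info, df=1)


def ebtl_scan(
    calls: DetectionCalls,
    g,
    samples: pd.DataFrame,
    cfg: ScanConfig | None = None,
    probes: pd.DataFrame | None = None,
) -> ScanResult:
    """Logistic scan of expressed/not-expressed status against every variant.

    Per pair: expressed ~ dosage + covariates, Wald p on the dosage log-odds;
    a Firth-penalised refit replaces any non-converged/separated fit. Probes
    expressed in all or no samples must be excluded upstream (ConfigError
    otherwise). With ``cfg.screen_p`` set, pairs are first screened by a
    vectorised score test (valid per-pair p-values); only pairs passing the
    screen get the exact Wald/Firth refit - effect/se stay NaN elsewhere.
    """
    cfg = cfg or ScanConfig()
    expressed = calls.frame()
    g, samp = _align(expressed.index, g, samples)
    keep = g.maf() >= cfg.maf_floor
    g = g.subset_variants(keep)
    C, cov_names = covariate_matrix(samp, cfg)
    G = _impute_mean(g.dosage)
    Y = expressed.to_numpy(dtype=float)
    n, V = G.shape
    P = Y.shape[1]
    means = Y.mean(axis=0)
    if ((means == 0) | (means == 1)).any():
        raise ConfigError(
            "probes expressed in all or no samples must be excluded before ebtl_scan"
        )
    effect = np.full((P, V), np.nan)
    se = np.full((P, V), np.nan)
    pmat = np.full((P, V), np.nan)
    for j in range(P):
        y = Y[:, j]
        if cfg.screen_p is not None:
            p_score = logistic_score_scan(y, C, G)
            pmat[j] = p_score
            idx = np.flatnonzero(p_score <= cfg.screen_p)
            if idx.size == 0:
                continue
            Gsub = G[:, idx]
        else:
            idx = np.arange(V)
            Gsub = G
        b, s, conv = _batch_logistic(y, C, Gsub)
        bad = ~conv | (np.abs(b) > 8.0) | (s > 50.0) | ~np.isfinite(s)
        for t in np.flatnonzero(bad):
            X = np.column_stack([C, Gsub[:, t]])
            bf, sf_, _ = firth_logistic(X, y)
            b[t], s[t] = bf[-1], sf_[-1]
        effect[j, idx] = b
        se[j, idx] = s
        pmat[j, idx] = 2.0 * stats.norm.sf(np.abs(b / np.where(s > 0, s, np.nan)))
    return ScanResult(
        probe_ids=list(expressed.columns),
        probes=_probe_meta(expressed.columns, probes),
        variants=g.variants[["chrom", "pos", "a1"]].copy(),
        effect=effect,
        se=se,
        p=pmat,
        kind="logistic",
        cis_window=cfg.cis_window,
        n_samples=n,
        covariate_names=cov_names,
    )


# ---------------------------------------------------------------- sentinels & conditional


def select_sentinels(assoc: pd.DataFrame) -> pd.DataFrame:
    """Per probe and class, the minimum-p record; ties broken by larger
    |effect|, then lexicographic variant id."""
    if assoc.empty:
        raise ConfigError("cannot select sentinels from an empty table")
    ordered = assoc.assign(_abs_eff=assoc["effect"].abs()).sort_values(
        ["p", "_abs_eff", "variant_id"],
        ascending=[True, False, True],
        kind="stable",
    )
    out = ordered.groupby(["probe_id", "klass"], sort=False).head(1)
    return out.drop(columns="_abs_eff").reset_index(drop=True)


@dataclass
class ConditionalResult:
    probe_id: str
    signals: pd.DataFrame  # variant_id, effect, se, p_conditional (selection order)
    skipped_collinear: list[str] = field(default_factory=list)

    @property
    def n_independent(self) -> int:
        return len(self.signals)


def conditional_scan(
    probe_id: str,
    y: np.ndarray,
    region_g,
    samples: pd.DataFrame,
    cfg: ScanConfig,
    threshold: float,
    r2_guard: float = 0.99,
) -> ConditionalResult:
    """Forward stepwise selection of independent signals in a region.

    Starting from the covariate-only model, repeatedly add the minimum-p
    variant while its conditional p < ``threshold``; candidates with
    r^2 > ``r2_guard`` to an already-selected signal are skipped. Reported
    effects/SEs/p come from the final joint model.
    """
    samp = samples.reset_index(drop=True)
    C, _ = covariate_matrix(samp, cfg)
    G = _impute_mean(region_g.dosage)
    ids = list(region_g.variants.index)
    y = np.asarray(y, dtype=float)
    n = len(y)
    selected: list[int] = []
    skipped: list[str] = []
    while True:
        covs = np.column_stack([C] + [G[:, j] for j in selected]) if selected else C
        dof = n - covs.shape[1] - 1
        if dof <= 0:
            break
        Q, _ = np.linalg.qr(covs)
        yr = _residualize(y[:, None], Q)[:, 0]
        Gr = _residualize(G, Q)
        ssg = (Gr**2).sum(axis=0)
        ssg0 = (G - G.mean(0)).var(axis=0) * n
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = Gr.T @ yr / ssg
            rss = (yr**2).sum() - beta**2 * ssg
            tstat = beta / np.sqrt(rss / dof / ssg)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df=dof)
        for j in selected:
            pvals[j] = np.inf
        # collinearity guard: candidate nearly explained by current signals
        if selected:
            collinear = ssg < (1.0 - r2_guard) * np.maximum(ssg0, 1e-300)
            for j in np.flatnonzero(collinear):
                if j not in selected and pvals[j] < threshold:
                    skipped.append(ids[j])
                pvals[j] = np.inf
        else:
            pvals[ssg < 1e-10] = np.inf
        best = int(np.argmin(pvals))
        if not np.isfinite(pvals[best]) or pvals[best] >= threshold:
            break
        selected.append(best)
    if selected:
        X = np.column_stack([C] + [G[:, j] for j in selected])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = n - X.shape[1]
        sigma2 = (resid**2).sum() / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        k0 = C.shape[1]
        eff = beta[k0:]
        ses = np.sqrt(np.diag(cov)[k0:])
        pj = 2.0 * stats.t.sf(np.abs(eff / ses), df=dof)
        signals = pd.DataFrame(
            {
                "variant_id": [ids[j] for j in selected],
                "effect": eff,
                "se": ses,
                "p_conditional": pj,
            }
        )
    else:
        signals = pd.DataFrame(columns=["variant_id", "effect", "se", "p_conditional"])
    return ConditionalResult(probe_id=probe_id, signals=signals, skipped_collinear=skipped)


# ---------------------------------------------------------------- interaction


@dataclass
class InteractionResult:
    lrt_stat: float | None
    df: int | None
    p: float | None
    testable: bool
    reason: str = ""


def interaction_test(
    y: np.ndarray,
    dosage: np.ndarray,
    samples: pd.DataFrame,
    min_per_stage: int = 2,
) -> InteractionResult:
    """Likelihood-ratio test of genotype x stage interaction on expression.

    Compares y ~ stage + g (+ disease) against y ~ stage * g (+ disease);
    Gaussian LRT n*ln(RSS0/RSS1) on (n_stages - 1) df. Untestable when any
    stage level has fewer than ``min_per_stage`` samples or lacks genotype
    variation (both genotype groups must be represented within every stage).
    """
    samp = samples.reset_index(drop=True)
    stages = [s for s in samp["stage"].unique()]
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    dosage = np.where(np.isnan(dosage), np.nanmean(dosage), dosage)
    for s in stages:
        m = (samp["stage"] == s).to_numpy()
        if m.sum() < min_per_stage:
            return InteractionResult(None, None, None, False, f"stage {s}: <{min_per_stage} samples")
        if len(np.unique(dosage[m])) < 2:
            return InteractionResult(None, None, None, False, f"stage {s}: no genotype variation")
    n = len(y)
    stage_d = pd.get_dummies(samp["stage"], drop_first=True).to_numpy(dtype=float)
    base = [np.ones(n), stage_d, dosage[:, None]]
    if "disease" in samp.columns:
        base.append((samp["disease"] == "case").to_numpy(dtype=float)[:, None])
    X0 = np.column_stack([c if c.ndim == 2 else c[:, None] for c in base])
    X1 = np.column_stack([X0, stage_d * dosage[:, None]])
    rss0 = _ols_rss(X0, y)
    rss1 = _ols_rss(X1, y)
    if rss1 <= 0:
        raise UntestableError("saturated interaction model (zero residual)")
    stat = n * np.log(rss0 / rss1)
    df = stage_d.shape[1]
    return InteractionResult(float(stat), int(df), float(stats.chi2.sf(stat, df)), True)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)
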