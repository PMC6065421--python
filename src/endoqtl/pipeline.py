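"""End-to-end pipeline: simulate -> qc -> normalize -> partition -> de/prop
-> eqtl/ebtl -> conditional -> interaction -> overlap -> smr -> report.

Every stage reads its inputs from, and writes its outputs to, the run
directory, so any stage subset can be re-run from existing files. Each stage
also writes a ``<stage>.json`` summary (test counts, thresholds actually
applied, discovery counts); ``run_summary.json`` aggregates them. All
randomness flows from the single top-level seed via fixed per-stage offsets,
and no output embeds a timestamp, so identical config + seed reproduce every
file byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cyclestage, expression, genotypes, integrate, qtlmap, synthdata
from .errors import ConfigError, DependencyError, UntestableError

log = logging.getLogger("endoqtl")

STAGES = (
    "simulate",
    "qc",
    "normalize",
    "partition",
    "de",
    "prop",
    "eqtl",
    "ebtl",
    "conditional",
    "interaction",
    "overlap",
    "smr",
    "report",
)


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    # simulation (the bundled fixture scale)
    n_samples: int = 200
    n_probes: int = 2000
    n_variants: int = 20_000
    n_chromosomes: int = 5
    ld_block_size: int = 20
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    gwas_n: int = 5000
    gwas_b_xy: float = 0.2
    # thresholds (defaults are the study's stated settings)
    detection_threshold: float = 0.05
    high_fraction: float = 0.90
    cis_window: int = 250_000
    fdr: float = 0.05
    bonferroni_alpha: float = 0.05
    qc_max_missing: float = 0.05
    qc_min_maf: float = 0.05
    qc_hwe_min_p: float = 1e-6
    maf_floor: float = 0.05
    fc_threshold: float = 1.5
    ld_r2_min: float = 0.7
    ebtl_screen_p: float | None = 1e-3
    heidi_p_eqtl_max: float = 1.57e-3
    heidi_max_snps: int = 20
    heidi_min_snps: int = 3
    stage_merge: dict = field(default_factory=lambda: dict(cyclestage.STAGE_MERGE_DEFAULT))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        errors = [f"unknown config key: {k}" for k in data if k not in known]
        cfg = None
        try:
            cfg = cls(**{k: v for k, v in data.items() if k in known})
        except TypeError as exc:
            errors.append(str(exc))
        if cfg is not None:
            errors.extend(cfg._validate())
        if errors:
            raise ConfigError("; ".join(errors))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        if "maf_range" in data:
            data["maf_range"] = tuple(data["maf_range"])
        return cls.from_dict(data)

    def _validate(self) -> list[str]:
        errs = []
        for name, lo, hi in (
            ("detection_threshold", 0.0, 1.0),
            ("high_fraction", 0.0, 1.0),
            ("fdr", 0.0, 1.0),
            ("bonferroni_alpha", 0.0, 1.0),
            ("qc_max_missing", 0.0, 1.0),
            ("qc_min_maf", 0.0, 0.5),
            ("qc_hwe_min_p", 0.0, 1.0),
            ("ld_r2_min", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                errs.append(f"{name}={v} outside [{lo}, {hi}]")
        if self.cis_window <= 0:
            errs.append("cis_window must be > 0")
        if self.n_samples < 2 or self.n_probes < 1 or self.n_variants < 1:
            errs.append("simulation dimensions must be positive (n_samples >= 2)")
        return errs

    def scan_config(self) -> qtlmap.ScanConfig:
        return qtlmap.ScanConfig(
            cis_window=self.cis_window,
            fdr=self.fdr,
            bonferroni_alpha=self.bonferroni_alpha,
            maf_floor=self.maf_floor,
        )


# ---------------------------------------------------------------- helpers


def _out(cfg: RunConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p

def _need(cfg: RunConfig, stage: str, *names: str) -> list[Path]:
    paths = [_out(cfg) / n for n in names]
    missing = [p.name for p in paths if not p.exists()]
    if missing:
        raise DependencyError(
            f"stage '{stage}' needs {missing}; run its upstream stage first"
        )
    return paths

def _write_json(cfg: RunConfig, name: str, payload: dict) -> None:
    with open(_out(cfg) / f"{name}.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

def _read_json(cfg: RunConfig, name: str) -> dict:
    with open(_out(cfg) / f"{name}.json") as fh:
        return json.load(fh)

def _tsv(df: pd.DataFrame, cfg: RunConfig, name: str) -> None:
    df.to_csv(_out(cfg) / name, sep="\t", index=False)

def _load_inputs(cfg: RunConfig):
    g = genotypes.read_vcf(_out(cfg) / "genotypes_qc.vcf")
    samples = pd.read_csv(_out(cfg) / "samples_quality.tsv", sep="\t", dtype={"sample_id": str})
    probes = pd.read_csv(_out(cfg) / "probes.tsv", sep="\t").set_index("probe_id")
    return g, samples, probes

def _load_tracks(cfg: RunConfig):
    part = pd.read_csv(_out(cfg) / "partition.tsv", sep="\t")
    quant = list(part.loc[part["track"] == "quantitative", "probe_id"])
    varb = list(part.loc[part["track"] == "variable", "probe_id"])
    return quant, varb

def _load_calls(cfg: RunConfig) -> expression.DetectionCalls:
    ds = expression.read_expression(
        _out(cfg) / "intensity.tsv", _out(cfg) / "detection.tsv", _out(cfg) / "probes.tsv"
    )
    return expression.call_detection(ds, cfg.detection_threshold)


# ---------------------------------------------------------------- stages


def stage_simulate(cfg: RunConfig) -> dict:
    sim = synthdata.SimConfig(
        n_samples=cfg.n_samples,
        n_variants=cfg.n_variants,
        n_chromosomes=cfg.n_chromosomes,
        ld_block_size=cfg.ld_block_size,
        ld_rho=cfg.ld_rho,
        maf_range=cfg.maf_range,
        seed=cfg.seed,
    )
    g = synthdata.simulate_genotypes(sim)
    samples = synthdata.simulate_samples(sim)
    truth, probes = synthdata.make_truth(g, cfg.n_probes, seed=cfg.seed + 11)
    ds = synthdata.simulate_expression(g, samples, truth, probes, seed=cfg.seed + 12)
    genotypes.write_vcf(g, _out(cfg) / "genotypes.vcf")
    g.variants.reset_index().to_csv(_out(cfg) / "variants_meta.tsv", sep="\t", index=False)
    _tsv(samples, cfg, "samples.tsv")
    _tsv(truth, cfg, "truth.tsv")
    expression.write_expression(
        ds, _out(cfg) / "intensity.tsv", _out(cfg) / "detection.tsv", _out(cfg) / "probes.tsv"
    )
    # GWAS summary under pleiotropy for a cis effect at a common variant
    # (a low-MAF instrument would leave the GWAS signal below genome-wide
    # significance at the simulated cohort size)
    cis = truth[(truth["qtl_type"] == "cis") & (truth["beta_mean"] != 0.0)].copy()
    if len(cis):
        maf = g.maf()
        vidx = {v: j for j, v in enumerate(g.variants.index)}
        cis["causal_maf"] = [maf[vidx[v]] for v in cis["causal_snp"]]
        gwas_probe = cis.sort_values("causal_maf", ascending=False).iloc[0]["probe_id"]
    else:
        gwas_probe = ""
    if gwas_probe:
        rec = truth.set_index("probe_id").loc[gwas_probe]
        gwas = synthdata.simulate_gwas_summary(
            g,
            "pleiotropy",
            b_xy_true=cfg.gwas_b_xy,
            n_gwas=cfg.gwas_n,
            seed=cfg.seed + 13,
            causal_variant=rec["causal_snp"],
            b_zx=rec["beta_mean"],
        )
        integrate.write_gwas_ma(gwas, _out(cfg) / "gwas.ma")
    summary = {
        "seed": cfg.seed,
        "n_samples": cfg.n_samples,
        "n_probes": cfg.n_probes,
        "n_variants": cfg.n_variants,
        "gwas_probe": gwas_probe,
    }
    _write_json(cfg, "simulate", summary)
    return summary


def stage_qc(cfg: RunConfig) -> dict:
    _need(cfg, "qc", "genotypes.vcf")
    g = genotypes.read_vcf(_out(cfg) / "genotypes.vcf")
    meta_path = _out(cfg) / "variants_meta.tsv"
    if meta_path.exists():  # carry simulation metadata through QC
        meta = pd.read_csv(meta_path, sep="\t", dtype={"chrom": str}).set_index("variant_id")
        for col in ("af", "block", "ld_rho"):
            g.variants[col] = meta[col]
    gq, report = genotypes.qc_pipeline(
        g, cfg.qc_max_missing, cfg.qc_min_maf, cfg.qc_hwe_min_p
    )
    genotypes.write_vcf(gq, _out(cfg) / "genotypes_qc.vcf")
    report.to_frame().to_csv(_out(cfg) / "qc_report.tsv", sep="\t", index=False)
    summary = {
        "n_input": report.n_input,
        "removed_missingness": report.n_removed_missingness,
        "removed_maf": report.n_removed_maf,
        "removed_hwe": report.n_removed_hwe,
        "n_retained": report.n_retained,
        "thresholds": report.thresholds,
    }
    _write_json(cfg, "qc", summary)
    return summary


def stage_normalize(cfg: RunConfig) -> dict:
    _need(cfg, "normalize", "intensity.tsv", "detection.tsv", "probes.tsv")
    ds = expression.read_expression(
        _out(cfg) / "intensity.tsv", _out(cfg) / "detection.tsv", _out(cfg) / "probes.tsv"
    )
    norm = expression.quantile_normalize_log2(ds)
    norm.intensity_frame().rename_axis("sample_id").to_csv(
        _out(cfg) / "expr_norm.tsv", sep="\t"
    )
    summary = {"n_samples": ds.n_samples, "n_probes": ds.n_probes}
    _write_json(cfg, "normalize", summary)
    return summary


def stage_partition(cfg: RunConfig) -> dict:
    _need(cfg, "partition", "intensity.tsv", "detection.tsv", "probes.tsv", "samples.tsv")
    calls = _load_calls(cfg)
    part = expression.partition_probes(calls, cfg.high_fraction)
    rows = (
        [(p, "quantitative") for p in part.quantitative]
        + [(p, "variable") for p in part.variable]
        + [(p, "excluded") for p in part.excluded]
    )
    _tsv(pd.DataFrame(rows, columns=["probe_id", "track"]), cfg, "partition.tsv")
    samples = expression.read_samples(_out(cfg) / "samples.tsv")
    samples = expression.attach_quality(samples, calls)
    _tsv(samples, cfg, "samples_quality.tsv")
    summary = {
        "detection_threshold": calls.threshold,
        "high_fraction": cfg.high_fraction,
        "n_quantitative": len(part.quantitative),
        "n_variable": len(part.variable),
        "n_excluded": len(part.excluded),
        "mean_sample_quality": float(np.round(samples["quality"].mean(), 6)),
    }
    _write_json(cfg, "partition", summary)
    return summary


def _merged_samples(cfg: RunConfig) -> pd.DataFrame:
    samples = pd.read_csv(_out(cfg) / "samples_quality.tsv", sep="\t", dtype={"sample_id": str})
    return cyclestage.combine_stages(samples, cfg.stage_merge)


def stage_de(cfg: RunConfig) -> dict:
    _need(cfg, "de", "expr_norm.tsv", "partition.tsv", "samples_quality.tsv")
    expr = pd.read_csv(_out(cfg) / "expr_norm.tsv", sep="\t", index_col=0)
    quant, _ = _load_tracks(cfg)
    samples = _merged_samples(cfg)
    counts = {}
    for a, b in cyclestage.SUCCESSIVE_CONTRASTS:
        contrast = cyclestage.StageContrast((a,), (b,))
        res = cyclestage.de_test(
            expr[quant], samples, contrast, cfg.fc_threshold, cfg.fdr
        )
        _tsv(res, cfg, f"de_{a}_vs_{b}.tsv")
        counts[contrast.label] = int(res["significant"].sum())
    summary = {"fdr": cfg.fdr, "fc_threshold": cfg.fc_threshold, "n_significant": counts}
    _write_json(cfg, "de", summary)
    return summary


def stage_prop(cfg: RunConfig) -> dict:
    _need(cfg, "prop", "partition.tsv", "samples_quality.tsv")
    calls = _load_calls(cfg)
    _, varb = _load_tracks(cfg)
    calls = calls.subset_probes(varb)
    samples = _merged_samples(cfg)
    counts = {}
    for a, b in cyclestage.SUCCESSIVE_CONTRASTS:
        contrast = cyclestage.StageContrast((a,), (b,))
        res = cyclestage.prop_test(calls, samples, contrast, cfg.fdr)
        _tsv(res, cfg, f"prop_{a}_vs_{b}.tsv")
        sig = res[res["q_bh"] < cfg.fdr]
        counts[contrast.label] = {
            "activated": int((sig["direction"] == "activated").sum()),
            "repressed": int((sig["direction"] == "repressed").sum()),
            "excluded": len(res.attrs["excluded"]),
        }
    summary = {"fdr": cfg.fdr, "n_significant": counts}
    _write_json(cfg, "prop", summary)
    return summary


def _scan_summary(result: qtlmap.ScanResult, cfg: RunConfig) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Per-class FDR/Bonferroni accounting plus significant records/sentinels."""
    info: dict = {"n_samples": result.n_samples}
    frames = []
    for klass in ("cis", "trans"):
        pvals = result.class_pvalues(klass)
        m = len(pvals)
        if m == 0:
            info[klass] = {"n_tests": 0}
            continue
        bonf = qtlmap.bonferroni_threshold(cfg.bonferroni_alpha, m)
        p_fdr = qtlmap.bh_threshold(pvals, cfg.fdr)
        cut = max(p_fdr, bonf)
        recs = result.frame(max_p=cut if cut > 0 else bonf, classes=(klass,))
        recs = recs[recs["p"] <= max(p_fdr, bonf)]
        n_fdr = int((pvals <= p_fdr).sum()) if p_fdr > 0 else 0
        n_bonf = int((pvals < bonf).sum())
        sig = recs[recs["p"] <= p_fdr] if p_fdr > 0 else recs.iloc[0:0]
        info[klass] = {
            "n_tests": m,
            "bonferroni_threshold": bonf,
            "fdr_p_cutoff": p_fdr,
            "n_pass_fdr": n_fdr,
            "n_pass_bonferroni": n_bonf,
            "probes_pass_fdr": int(sig["probe_id"].nunique()),
            "genes_pass_fdr": int(sig["gene"].nunique()),
            "probes_pass_bonferroni": int(recs.loc[recs["p"] < bonf, "probe_id"].nunique()),
        }
        frames.append(sig)
    sig_all = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["probe_id", "klass", "p", "effect", "variant_id"])
    )
    sentinels = (
        qtlmap.select_sentinels(sig_all) if len(sig_all) else sig_all
    )
    return info, sig_all, sentinels


def stage_eqtl(cfg: RunConfig) -> dict:
    _need(cfg, "eqtl", "expr_norm.tsv", "partition.tsv", "genotypes_qc.vcf", "probes.tsv")
    g, samples, probes = _load_inputs(cfg)
    expr = pd.read_csv(_out(cfg) / "expr_norm.tsv", sep="\t", index_col=0)
    quant, _ = _load_tracks(cfg)
    samples = cyclestage.combine_stages(samples, cfg.stage_merge)
    result = qtlmap.eqtl_scan(expr[quant], g, samples, cfg.scan_config(), probes=probes)
    info, sig, sentinels = _scan_summary(result, cfg)
    _tsv(sig, cfg, "eqtl_significant.tsv")
    _tsv(sentinels, cfg, "eqtl_sentinels.tsv")
    _write_json(cfg, "eqtl", info)
    return info


def stage_ebtl(cfg: RunConfig) -> dict:
    _need(cfg, "ebtl", "partition.tsv", "genotypes_qc.vcf", "samples_quality.tsv")
    g, samples, probes = _load_inputs(cfg)
    calls = _load_calls(cfg)
    _, varb = _load_tracks(cfg)
    calls = calls.subset_probes(varb)
    samples = cyclestage.combine_stages(samples, cfg.stage_merge)
    scan_cfg = cfg.scan_config()
    scan_cfg.screen_p = cfg.ebtl_screen_p
    result = qtlmap.ebtl_scan(calls, g, samples, scan_cfg, probes=probes)
    info, sig, sentinels = _scan_summary(result, cfg)
    info["screen_p"] = cfg.ebtl_screen_p
    _tsv(sig, cfg, "ebtl_significant.tsv")
    _tsv(sentinels, cfg, "ebtl_sentinels.tsv")
    _write_json(cfg, "ebtl", info)
    return info


def stage_conditional(cfg: RunConfig) -> dict:
    _need(cfg, "conditional", "eqtl_sentinels.tsv", "expr_norm.tsv", "genotypes_qc.vcf")
    g, samples, probes = _load_inputs(cfg)
    expr = pd.read_csv(_out(cfg) / "expr_norm.tsv", sep="\t", index_col=0)
    samples = cyclestage.combine_stages(samples, cfg.stage_merge)
    sentinels = pd.read_csv(_out(cfg) / "eqtl_sentinels.tsv", sep="\t")
    eqtl_info = _read_json(cfg, "eqtl")
    threshold = eqtl_info.get("cis", {}).get("fdr_p_cutoff", 0.0) or eqtl_info.get(
        "cis", {}
    ).get("bonferroni_threshold", 0.0)
    cis_sent = sentinels[sentinels["klass"] == "cis"] if len(sentinels) else sentinels
    rows = []
    scan_cfg = cfg.scan_config()
    for _, s in cis_sent.iterrows():
        probe = s["probe_id"]
        chrom = str(probes.at[probe, "chromosome"])
        start = int(probes.at[probe, "probe_start"])
        var = g.variants
        in_region = (var["chrom"].astype(str) == chrom) & (
            (var["pos"] - start).abs() <= cfg.cis_window
        )
        if in_region.sum() == 0:
            continue
        region = g.subset_variants(in_region.to_numpy())
        region = region.subset_samples(list(expr.index))
        samp = samples.set_index("sample_id").loc[expr.index].reset_index()
        res = qtlmap.conditional_scan(
            probe, expr[probe].to_numpy(), region, samp, scan_cfg, threshold
        )
        for order, (_, sig) in enumerate(res.signals.iterrows(), 1):
            rows.append(
                (probe, order, sig["variant_id"], sig["effect"], sig["se"], sig["p_conditional"])
            )
    signals = pd.DataFrame(
        rows, columns=["probe_id", "signal_rank", "variant_id", "effect", "se", "p_conditional"]
    )
    _tsv(signals, cfg, "conditional_signals.tsv")
    summary = {
        "threshold": threshold,
        "n_probes_scanned": int(cis_sent["probe_id"].nunique()) if len(cis_sent) else 0,
        "n_independent_signals": len(signals),
        "n_secondary_signals": int((signals["signal_rank"] > 1).sum()) if len(signals) else 0,
    }
    _write_json(cfg, "conditional", summary)
    return summary


def stage_interaction(cfg: RunConfig) -> dict:
    _need(cfg, "interaction", "eqtl_sentinels.tsv", "expr_norm.tsv", "genotypes_qc.vcf")
    g, samples, probes = _load_inputs(cfg)
    expr = pd.read_csv(_out(cfg) / "expr_norm.tsv", sep="\t", index_col=0)
    samples = cyclestage.combine_stages(samples, cfg.stage_merge)
    de_sig: set[str] = set()
    for a, b in cyclestage.SUCCESSIVE_CONTRASTS:
        path = _out(cfg) / f"de_{a}_vs_{b}.tsv"
        if path.exists():
            de = pd.read_csv(path, sep="\t")
            de_sig |= set(de.loc[de["significant"], "probe_id"])
    sentinels = pd.read_csv(_out(cfg) / "eqtl_sentinels.tsv", sep="\t")
    eqtl_info = _read_json(cfg, "eqtl")
    bonf = eqtl_info.get("cis", {}).get("bonferroni_threshold", 0.0)
    cand = sentinels[(sentinels["klass"] == "cis") & (sentinels["p"] < bonf)]
    cand = cand[cand["probe_id"].isin(de_sig)] if de_sig else cand.iloc[0:0]
    samp = samples.set_index("sample_id").loc[expr.index].reset_index()
    rows = []
    for _, s in cand.iterrows():
        res = qtlmap.interaction_test(
            expr[s["probe_id"]].to_numpy(),
            g.subset_samples(list(expr.index)).column(s["variant_id"]),
            samp,
        )
        rows.append(
            (
                s["probe_id"], s["variant_id"],
                res.lrt_stat, res.df, res.p, res.testable, res.reason,
            )
        )
    out = pd.DataFrame(
        rows, columns=["probe_id", "variant_id", "lrt_stat", "df", "p", "testable", "reason"]
    )
    _tsv(out, cfg, "interaction.tsv")
    tested = out[out["testable"] == True]  # noqa: E712
    summary = {
        "n_candidates": len(out),
        "n_testable": len(tested),
        "n_significant_bonferroni": int(
            (tested["p"] < cfg.bonferroni_alpha / max(len(tested), 1)).sum()
        )
        if len(tested)
        else 0,
    }
    _write_json(cfg, "interaction", summary)
    return summary


def stage_overlap(cfg: RunConfig) -> dict:
    _need(cfg, "overlap", "eqtl_significant.tsv", "partition.tsv", "genotypes_qc.vcf")
    g, _, probes = _load_inputs(cfg)
    quant, _ = _load_tracks(cfg)
    eqtl = pd.read_csv(_out(cfg) / "eqtl_significant.tsv", sep="\t")
    universe = set(probes.loc[quant, "gene_symbol"])
    eqtl_genes = set(eqtl.loc[eqtl["klass"] == "cis", "gene"]) & universe
    de_genes: set[str] = set()
    for a, b in cyclestage.SUCCESSIVE_CONTRASTS:
        path = _out(cfg) / f"de_{a}_vs_{b}.tsv"
        if path.exists():
            de = pd.read_csv(path, sep="\t")
            de_genes |= set(
                probes.loc[de.loc[de["significant"], "probe_id"], "gene_symbol"]
            )
    de_genes &= universe
    summary: dict = {}
    try:
        chi2, p, obs, exp = integrate.overlap_chisq(eqtl_genes, de_genes, universe)
        summary["de_eqtl_overlap"] = {
            "chi2": chi2, "p": p, "observed": obs, "expected": exp,
            "n_eqtl_genes": len(eqtl_genes), "n_de_genes": len(de_genes),
            "n_universe": len(universe),
        }
    except ConfigError as exc:
        summary["de_eqtl_overlap"] = {"untestable": str(exc)}
    gwas_path = _out(cfg) / "gwas.ma"
    if gwas_path.exists():
        gwas = integrate.read_gwas_ma(gwas_path)
        catalogue = list(gwas.loc[gwas["p"] < 5e-8, "SNP"])
        sentinels = pd.read_csv(_out(cfg) / "eqtl_sentinels.tsv", sep="\t")
        esnps = list(sentinels.loc[sentinels["klass"] == "cis", "variant_id"]) if len(sentinels) else []
        pairs = integrate.overlap_by_ld(esnps, catalogue, g, cfg.ld_r2_min)
        _tsv(pairs, cfg, "gwas_ld_overlap.tsv")
        summary["gwas_ld_overlap"] = {
            "n_esnps": len(esnps),
            "n_catalogue_snps": len(catalogue),
            "n_matched_esnps": int(pairs["esnp"].nunique()) if len(pairs) else 0,
            "r2_min": cfg.ld_r2_min,
        }
    _write_json(cfg, "overlap", summary)
    return summary


def stage_smr(cfg: RunConfig) -> dict:
    _need(cfg, "smr", "eqtl_sentinels.tsv", "expr_norm.tsv", "genotypes_qc.vcf", "gwas.ma")
    g, samples, probes = _load_inputs(cfg)
    expr = pd.read_csv(_out(cfg) / "expr_norm.tsv", sep="\t", index_col=0)
    samples = cyclestage.combine_stages(samples, cfg.stage_merge)
    gwas = integrate.read_gwas_ma(_out(cfg) / "gwas.ma")
    gwas = integrate.harmonize_gwas(g.variants, gwas)
    sentinels = pd.read_csv(_out(cfg) / "eqtl_sentinels.tsv", sep="\t")
    eqtl_info = _read_json(cfg, "eqtl")
    bonf = eqtl_info.get("cis", {}).get("bonferroni_threshold", 0.0)
    cand = sentinels[(sentinels["klass"] == "cis") & (sentinels["p"] < bonf)]
    n_probes = max(int(cand["probe_id"].nunique()), 1)
    scan_cfg = cfg.scan_config()
    settings = integrate.HeidiSettings(
        p_eqtl_max=cfg.heidi_p_eqtl_max,
        max_snps=cfg.heidi_max_snps,
        min_snps=cfg.heidi_min_snps,
    )
    rows = []
    samp = samples.set_index("sample_id").loc[expr.index].reset_index()
    for probe in cand["probe_id"].unique():
        chrom = str(probes.at[probe, "chromosome"])
        start = int(probes.at[probe, "probe_start"])
        var = g.variants
        in_region = (var["chrom"].astype(str) == chrom) & (
            (var["pos"] - start).abs() <= cfg.cis_window
        )
        if in_region.sum() < 1:
            continue
        region_g = g.subset_variants(in_region.to_numpy()).subset_samples(list(expr.index))
        scan = qtlmap.eqtl_scan(
            expr[[probe]], region_g, samp, scan_cfg, probes=probes
        )
        region = scan.frame(classes=("cis", "trans", "other")).rename(
            columns={"effect": "effect", "se": "se", "p": "p"}
        )[["variant_id", "effect", "se", "p"]]
        try:
            res = integrate.run_smr(
                probe, region, gwas, region_g, n_probes_tested=n_probes,
                heidi_settings=settings,
            )
        except (UntestableError, ConfigError):
            continue
        rows.append(res)
    import dataclasses

    out = pd.DataFrame([asdict(r) for r in rows]) if rows else pd.DataFrame(
        columns=[f.name for f in dataclasses.fields(integrate.SmrResult)]
    )
    _tsv(out, cfg, "smr.tsv")
    summary = {
        "smr_threshold": integrate.smr_threshold(n_probes),
        "n_probes_tested": len(rows),
        "n_pass_smr": int((out["p_smr"] < integrate.smr_threshold(n_probes)).sum()) if len(out) else 0,
        "n_pass_both": int(out["passes"].sum()) if len(out) else 0,
        "genes_pass_both": sorted(
            probes.loc[out.loc[out["passes"] == True, "probe_id"], "gene_symbol"]  # noqa: E712
        )
        if len(out)
        else [],
    }
    _write_json(cfg, "smr", summary)
    return summary


def stage_report(cfg: RunConfig) -> dict:
    summary = collect_summary(cfg)
    text = generate_report(summary)
    with open(_out(cfg) / "report.txt", "w") as fh:
        fh.write(text)
    return summary


# ---------------------------------------------------------------- driver


def collect_summary(cfg: RunConfig) -> dict:
    # out_dir is environmental, not part of the analysis settings: keeping it
    # out of the summary makes same-seed runs byte-identical wherever written
    out = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
            if k != "out_dir"
        }
    }
    for stage in STAGES[:-1]:
        path = _out(cfg) / f"{stage}.json"
        if path.exists():
            out[stage] = _read_json(cfg, stage)
    return out


def run_pipeline(cfg: RunConfig, stages=None) -> dict:
    """Execute the requested stages in dependency order; returns the run
    summary (also written to run_summary.json)."""
    requested = list(STAGES) if stages is None else list(stages)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    funcs = {
        "simulate": stage_simulate,
        "qc": stage_qc,
        "normalize": stage_normalize,
        "partition": stage_partition,
        "de": stage_de,
        "prop": stage_prop,
        "eqtl": stage_eqtl,
        "ebtl": stage_ebtl,
        "conditional": stage_conditional,
        "interaction": stage_interaction,
        "overlap": stage_overlap,
        "smr": stage_smr,
        "report": stage_report,
    }
    for stage in STAGES:
        if stage in requested:
            log.info("stage=%s seed=%d out_dir=%s", stage, cfg.seed, cfg.out_dir)
            result = funcs[stage](cfg)
            log.info("stage=%s done: %s", stage, json.dumps(result, sort_keys=True, default=str)[:300])
    summary = collect_summary(cfg)
    with open(_out(cfg) / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def generate_report(summary: dict) -> str:
    """Human-readable accounting of discoveries per class and stage."""
    lines = ["endoqtl run report", "=" * 60]
    for scan in ("eqtl", "ebtl"):
        info = summary.get(scan, {})
        lines.append(f"\n[{scan}]")
        if not info:
            lines.append("  (stage not run)")
            continue
        for klass in ("cis", "trans"):
            k = info.get(klass, {})
            m = k.get("n_tests", 0)
            lines.append(f"  {klass}: tests={m}")
            if m:
                lines.append(
                    f"    Bonferroni threshold = {k['bonferroni_threshold']:.3e}"
                    f" -> {k['n_pass_bonferroni']} pass"
                    f" ({k.get('probes_pass_bonferroni', 0)} probes)"
                )
                lines.append(
                    f"    FDR p-cutoff = {k['fdr_p_cutoff']:.3e}"
                    f" -> {k['n_pass_fdr']} pass ({k.get('probes_pass_fdr', 0)} probes,"
                    f" {k.get('genes_pass_fdr', 0)} genes)"
                )
    cond = summary.get("conditional", {})
    lines.append("\n[conditional]")
    lines.append(
        f"  independent signals: {cond.get('n_independent_signals', 0)}"
        f" (secondary: {cond.get('n_secondary_signals', 0)})"
        if cond
        else "  (stage not run)"
    )
    smr = summary.get("smr", {})
    lines.append("\n[smr]")
    if smr:
        lines.append(
            f"  probes tested: {smr.get('n_probes_tested', 0)};"
            f" SMR threshold = {smr.get('smr_threshold', float('nan')):.3e};"
            f" pass SMR: {smr.get('n_pass_smr', 0)};"
            f" pass SMR+HEIDI: {smr.get('n_pass_both', 0)}"
        )
        if smr.get("genes_pass_both"):
            lines.append("  genes passing both: " + ", ".join(smr["genes_pass_both"]))
    else:
        lines.append("  (stage not run)")
    lines.append("")
    return "\n".join(lines)
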