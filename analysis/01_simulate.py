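"""Generate the synthetic study: 200 women across the menstrual cycle,
20,000 SNPs in LD blocks, 2,000 array probes with detection p-values, known
cis/trans mean-level and silencing effects, and a pleiotropy-scenario GWAS.

Writes genotypes.vcf, intensity/detection/probes/samples TSVs, the truth
table, and gwas.ma under results/run/.
"""

import importlib

conf = importlib.import_module("00_config")

from endoqtl.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    cfg = conf.config()
    summary = run_pipeline(cfg, stages=["simulate"])["simulate"]
    print(
        f"simulated {summary['n_samples']} samples x {summary['n_probes']} probes"
        f" x {summary['n_variants']} variants (seed {summary['seed']})"
    )
    print(f"GWAS summary statistics written for probe {summary['gwas_probe']}")


if __name__ == "__main__":
    main()
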