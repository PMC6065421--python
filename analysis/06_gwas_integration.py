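"""Integrate the eQTL results with the simulated GWAS: chi-square overlap
of cis-eGenes with DE genes, LD (r^2 > 0.7) matching of sentinel eSNPs to
genome-wide-significant GWAS SNPs, and SMR + HEIDI causal-gene inference.
Ends with the run report (results/run/report.txt)."""

import importlib

conf = importlib.import_module("00_config")

from endoqtl.pipeline import generate_report, run_pipeline  # noqa: E402


def main() -> None:
    summary = run_pipeline(conf.config(), stages=["overlap", "smr", "report"])
    ov = summary["overlap"].get("de_eqtl_overlap", {})
    if "chi2" in ov:
        print(
            f"cis-eGene/DE overlap: observed {ov['observed']} vs expected"
            f" {ov['expected']:.1f} (chi2 = {ov['chi2']:.2f}, p = {ov['p']:.2f})"
        )
    smr = summary["smr"]
    print(
        f"SMR: {smr['n_probes_tested']} probes tested at threshold"
        f" {smr['smr_threshold']:.2e}; {smr['n_pass_both']} pass SMR + HEIDI"
        + (f" ({', '.join(smr['genes_pass_both'])})" if smr["genes_pass_both"] else "")
    )
    print("\n" + generate_report(summary))


if __name__ == "__main__":
    main()
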