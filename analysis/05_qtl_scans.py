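"""Genome-wide scans: linear eQTLs on the quantitative track, logistic
eBTLs on the variable track (score-screened), sentinel selection, stepwise
conditional analysis of cis sentinels, and genotype x stage interaction
tests on DE cis-eGenes."""

import importlib

conf = importlib.import_module("00_config")

from endoqtl.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    summary = run_pipeline(
        conf.config(), stages=["eqtl", "ebtl", "conditional", "interaction"]
    )
    for scan in ("eqtl", "ebtl"):
        for klass in ("cis", "trans"):
            k = summary[scan][klass]
            print(
                f"{scan} {klass}: {k['n_tests']} tests; {k['n_pass_fdr']} pass FDR"
                f" ({k['probes_pass_fdr']} probes); {k['n_pass_bonferroni']} pass"
                f" Bonferroni ({k['bonferroni_threshold']:.2e})"
            )
    cond = summary["conditional"]
    print(
        f"conditional: {cond['n_independent_signals']} independent signals across"
        f" {cond['n_probes_scanned']} probes ({cond['n_secondary_signals']} secondary)"
    )
    inter = summary["interaction"]
    print(
        f"interaction: {inter['n_testable']}/{inter['n_candidates']} testable,"
        f" {inter['n_significant_bonferroni']} significant"
    )


if __name__ == "__main__":
    main()
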