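"""Apply the genotype QC chain (missingness > 5%, MAF < 0.05, HWE p < 1e-6)
and report the variant accounting."""

import importlib

conf = importlib.import_module("00_config")

from endoqtl.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    qc = run_pipeline(conf.config(), stages=["qc"])["qc"]
    print(
        f"QC: {qc['n_input']} variants in; removed "
        f"{qc['removed_missingness']} (missingness), {qc['removed_maf']} (MAF), "
        f"{qc['removed_hwe']} (HWE); {qc['n_retained']} retained"
    )


if __name__ == "__main__":
    main()
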