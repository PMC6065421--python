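"""Cycle-stage analyses across successive contrasts (M vs P, P vs ES,
ES vs MS, MS vs LS): moderated-t differential expression on the quantitative
track and logistic activation/repression on the variable track."""

import importlib

conf = importlib.import_module("00_config")

from endoqtl.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    summary = run_pipeline(conf.config(), stages=["de", "prop"])
    print("differential expression (significant probes per contrast):")
    for label, n in summary["de"]["n_significant"].items():
        print(f"  {label}: {n}")
    print("activation/repression (FDR < 0.05):")
    for label, d in summary["prop"]["n_significant"].items():
        print(f"  {label}: {d['activated']} activated, {d['repressed']} repressed")


if __name__ == "__main__":
    main()
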