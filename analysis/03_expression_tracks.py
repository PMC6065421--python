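"""Normalise intensities (quantile adjustment across individuals, then
log2), call detection at p <= 0.05, split probes into the quantitative
(>= 90% of samples) and variable tracks, and compute the per-sample quality
covariate."""

import importlib

conf = importlib.import_module("00_config")

from endoqtl.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    summary = run_pipeline(conf.config(), stages=["normalize", "partition"])
    part = summary["partition"]
    print(
        f"tracks: {part['n_quantitative']} quantitative, {part['n_variable']} variable,"
        f" {part['n_excluded']} never detected"
    )
    print(
        f"mean fraction of probes detected per sample: {part['mean_sample_quality']:.3f}"
    )


if __name__ == "__main__":
    main()
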