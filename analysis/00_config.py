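"""Shared run configuration for the numbered analysis scripts.

Every script operates on the same run directory (results/run) with one seed,
so the chain 01 -> 06 reproduces a complete synthetic study end to end.
"""

from endoqtl.pipeline import RunConfig

SEED = 2024


def config() -> RunConfig:
    return RunConfig(out_dir="results/run", seed=SEED)
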