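"""Shared run configuration for the numbered analysis drivers.

All drivers operate on the same layout: synthetic data under
``results/data`` and stage outputs under ``results/run``.
"""

from pathlib import Path

from polwave.pipeline import RunConfig

ROOT = Path(__file__).resolve().parent.parent


def make_config(seed: int = 1) -> RunConfig:
    return RunConfig(
        data_dir=str(ROOT / "results" / "data"),
        out_dir=str(ROOT / "results" / "run"),
        seed=seed,
    )
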