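"""Shared configuration for the numbered analysis drivers.

All drivers use one seed so intermediate artifacts regenerate
deterministically; outputs accumulate under results/.
"""

from pathlib import Path

from c4spectra.pipeline import RunConfig

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def run_config() -> RunConfig:
    return RunConfig(seed=SEED)
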