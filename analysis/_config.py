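"""Shared configuration for the numbered analysis drivers.

All drivers operate on one run directory (results/analysis_run) with one
seed, so later stages reuse the outputs of earlier ones and the whole
sequence is reproducible end to end.  Run the scripts in order, or run
any one of them — each recomputes the (deterministic) upstream stages it
needs in memory.
"""

import sys
from pathlib import Path

from tridacna_sdm.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def analysis_config(seed: int | None = None) -> RunConfig:
    if seed is None:
        seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
    return RunConfig(out_dir=str(RESULTS / "analysis_run"), seed=seed)
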