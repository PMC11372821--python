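"""Project habitat suitability now and under the four future scenarios.

Continuous suitability maps are thresholded at each model's maxTSS value
("prediction existence"); current/future binary pairs yield per-cell
loss/stable/gain/unsuitable categories and cell-area-weighted range
changes per level and scenario.

Writes the binary and change rasters plus range_change.csv.
"""

import logging
import warnings

from _config import analysis_config

from tridacna_sdm.pipeline import (
    new_context,
    stage_fit,
    stage_niche,
    stage_prep,
    stage_project,
    stage_simulate,
)

logging.basicConfig(level=logging.INFO, format="%(message)s")
warnings.filterwarnings("ignore")

cfg = analysis_config()
ctx = new_context(cfg)
for stage in (stage_simulate, stage_prep, stage_niche, stage_fit, stage_project):
    ctx = stage(ctx)
print(ctx["range_change_table"].to_string(index=False))
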