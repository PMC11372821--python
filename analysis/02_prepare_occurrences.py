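"""Clean, thin and label the occurrence records; balance with
pseudo-absences.

Duplicates, incomplete rows, out-of-extent and non-marine points are
dropped; at most one presence is kept per 5 arc-minute cell; each record
is labelled EIOS (west of the boundary) or WPI (east); and every
modelling level (species, EIOS, WPI) gets an equal number of
pseudo-absences drawn from sea cells outside the presences'
environmental envelope.

Writes occurrences_thinned.csv and response_<level>.csv.
"""

import logging

from _config import analysis_config

from tridacna_sdm.pipeline import new_context, stage_prep, stage_simulate

logging.basicConfig(level=logging.INFO, format="%(message)s")

cfg = analysis_config()
ctx = stage_prep(stage_simulate(new_context(cfg)))
occ = ctx["presences"]
counts = occ["population"].value_counts()
print(f"presences after cleaning/thinning: {len(occ)} "
      f"(EIOS {counts.get('EIOS', 0)}, WPI {counts.get('WPI', 0)})")
for level, table in ctx["tables"].items():
    print(f"{level}: {len(table)} rows, balanced "
          f"{int((table['response'] == 1).sum())}/{int((table['response'] == 0).sum())}")
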