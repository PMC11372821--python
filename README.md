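# tridacna-sdm

Habitat-suitability analysis for the giant clam *Tridacna maxima* in the
Indo-Pacific (90–140° E, 11° S–15° N), built as a tested, reusable
pipeline. The package covers the full workflow a conservation
biogeographer would run for this species:

1. **Occurrence preparation** — clean raw point records, thin to one
   presence per 5 arc-minute grid cell, split records into the East
   Indian Ocean–South China Sea (EIOS) and West Pacific–Indonesian (WPI)
   populations at a boundary line, and balance presences with an equal
   number of pseudo-absences drawn from environments where the species
   was not observed.
2. **Niche comparison** — standardized PCA of nine environmental
   predictors; each population's realized niche becomes a 4-D
   kernel-density *hypervolume*, and the pairwise difference decomposes
   as β_total = β_shift + β_contraction/expansion ∈ [0, 1]
   (replacement vs. net volume difference).
3. **Ensemble distribution models** — ten candidate algorithms (GLM,
   GAM, MARS, CTA, RF, GBM, ANN, FDA, MAXENT, SRE) scored by 5-fold
   cross-validation with 10 replicates on TSS (sensitivity +
   specificity − 1, maximized over thresholds) and rank-based AUC;
   learners passing TSS > 0.7 and AUC > 0.8 form an equally weighted
   ensemble, interpreted through permutation importance and response
   curves.
4. **Projection** — ensemble suitability maps for the present and for
   2050s/2100s under RCP 2.6 and RCP 8.5 (only current velocity,
   salinity, mean temperature and temperature range change); maps are
   binarized at the maxTSS threshold and compared as
   loss/stable/gain/unsuitable categories with cell-area-weighted range
   change.
5. **MPA gap analysis** — overlay with marine-protected-area polygons:
   protected km² and percent protection per scenario, plus Priority
   Conservation Areas (suitable now, unsuitable later, unprotected) and
   Conservation Areas Pending Optimization (same trajectory, inside an
   MPA).

Because the original occurrence and environmental data are large
external downloads, the package ships a first-class synthetic-data
module that reproduces the statistical structure the analysis assumes
(spatially autocorrelated predictor fields, two populations with
different temperature/salinity optima, presence sampling proportional to
true suitability, scenario perturbations of the dynamic layers only,
rectangular MPAs at a target coverage). Every stage is therefore
testable end to end with a known ground truth.

## Worked example

```python
from tridacna_sdm.pipeline import RunConfig, run

ctx = run(RunConfig(out_dir="runs/demo", seed=1))
print(ctx["niche_cmp"].beta_total)          # 0.372
print(ctx["gap_report"])
```

The demo run (seed 1, 400 presences on a 25° × 17° window) prints one
log line per stage decision and ends with:

```
niche: beta_total=0.372 (shift 0.221, rich 0.151)
fit[species]: included ['GLM', 'GAM', 'MARS', 'CTA', 'RF', 'GBM', 'ANN',
              'FDA', 'MAXENT']; excluded ['SRE']
gaps[current]: 2508909 km2 predicted, 17.03% protected
```

Reading: the two synthetic populations' niches differ moderately
(β_total 0.37, mostly replacement), the envelope model SRE fails the
TSS/AUC gates exactly as the weaker algorithms do on the real data, and
the synthetic MPA network protects about 17% of currently suitable
habitat — close to the ~16% coverage the generator was asked for, as
expected when protection is placed independently of suitability.

The same stages are available as numbered drivers under `analysis/`
(`01_simulate_inputs.py` … `07_gap_analysis.py`), each printing what it
found and writing its tables under `results/`, and as a CLI
(`tridacna-sdm demo`, `run-all`, or one subcommand per stage).

## Layout

```
src/tridacna_sdm/   grid.py        grids, cell areas, raster I/O
                    simulate.py    synthetic predictors/occurrences/MPAs
                    occurrences.py cleaning, thinning, pseudo-absences
                    predictors.py  extraction, collinearity, PCA
                    hypervolume.py niche hypervolumes and beta decomposition
                    ensemble.py    learners, TSS/AUC, CV, gating, ensembles
                    projection.py  maps, binarization, change, range change
                    gaps.py        MPA rasterization, protection, PCA/POCA
                    pipeline.py    stage orchestration and run manifests
                    cli.py         click front-end
analysis/           numbered narrative drivers over the same stages
tests/              pytest suite (unit, property and acceptance tests)
docs/methods.md     model and estimator documentation
```
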