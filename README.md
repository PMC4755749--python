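# kinarch

Geometric analysis of meiosis-I chromosome architecture in oocytes, driven
by a seeded synthetic spindle-cohort generator.

The package classifies, from 3D kinetochore spot tables (µm):

- **sister-pair configurations** — indistinguishable / overlapping /
  distinct / separated, with merged sub-resolution detections recorded at
  0 µm and "split" defined as distinct ∪ separated;
- **kinetochore–microtubule attachment modes** on cold-stable k-fibers —
  amphitelic / merotelic / lateral / unattached (merotelic requires end-on
  fibers to opposite poles; lateral-merotelic folds into lateral), plus
  fiber-topology types A (parallel), B (distant origins), C (branched
  trunk);
- **bivalent rotation** relative to the spindle axis — in-axis /
  half-inverted / fully-inverted / ambiguous;
- **bivalent twist** — the angle between the two sister-pair axes
  (scorable only when both pairs are split);
- **cohesion state** — intact / weak gap / disintegrated, with full
  46-chromosome accounting, univalent identification (proximal/distal)
  and univalent biorientation scoring;
- **predicted segregation outcomes** per (orientation, centromeric
  cohesion) — normal disjunction, lagging, univalent + chromatids, or
  reverse segregation.

The `simulate` module generates cohorts of oocytes (23 bivalent slots,
bipolar spindle ~12 µm) whose spot, chromatin and fiber geometry *entails*
the sampled ground-truth labels; localization noise and anisotropic
optical merging are applied on top, so a noisy cohort exercises the full
detect → pair → classify path and recovers every configured rate within
binomial sampling error. Packaged profiles: `young_baseline`,
`from30to35_baseline`, `over35_baseline`. A minimal volumetric renderer
and local-maxima spot detector (`volume` module) support the optional
image-level route. The `stats` module provides frequency tables, Fisher's
exact test (two-sided, hypergeometric enumeration), pooled/Welch t tests,
age-trend regression and anaphase-timing summaries.

## CLI

```bash
kinarch simulate --profile young_baseline --seed 1 --out out/cohort
kinarch classify --in out/cohort --out out/cohort
kinarch stats    --in out/cohort --out out/summary
kinarch run      --profile young_baseline --seed 1 --out out/full   # end-to-end
kinarch detect   volume.npy --out spots.csv                          # volumes
```

Every subcommand accepts `--seed` and `--config` (YAML/JSON
`PipelineConfig`). Exit codes: 0 success, 2 validation error,
3 infeasible-profile error. All tables are CSV with snake_case,
unit-suffixed columns (`x_um`, `angle_deg`); outputs are re-readable by
the package's own readers.

## Layout

```
src/kinarch/core.py      domain types, distance/angle, sister-pair assignment
src/kinarch/classify.py  all classification procedures + outcome table
src/kinarch/simulate.py  cohort generator, profiles, time-lapse simulator
src/kinarch/volume.py    volume rendering + spot detection
src/kinarch/stats.py     frequency/exact/t/trend/timing statistics
src/kinarch/pipeline.py  table -> model reconstruction, cohort classification
src/kinarch/io.py        table schemas, config, end-to-end runner
src/kinarch/cli.py       command-line interface
```
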