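# dendrotrend

Growth-decline analysis for tree-ring stands: from ring-width series, tree
metadata and monthly station climate to divergent growth-trajectory groups,
crown-damage thresholds for decline, and the crown-damage dependence of the
climate sensitivity of growth.

The package is aimed at dendroecologists studying within-stand vitality
decline — the situation where heavily crown-damaged trees coexist with
healthy ones (typical of old *Nothofagus pumilio* stands near the xeric
forest-steppe margin of northern Patagonia, the system this pipeline was
designed around) and stand-mean chronologies obscure divergent individual
trajectories.

## What it computes

* **Basal area increment** per tree, reconstructed backwards from diameter
  at breast height: BAI_t = π(r_t² − r_{t−1}²) with the outermost radius
  anchored at DBH/2.
* **Cross-dating validation** (P2YrsL-normalized series against a
  leave-one-out master; pass at r > 0.32 and t > 3.5) and **chronologies**
  by Tukey's biweight robust mean, with detrending by a 32-yr 50 %-cutoff
  smoothing spline or by the series mean, and signal strength via Rbar and
  EPS = n·rbar/(n·rbar + 1 − rbar).
* **Growth-trajectory groups**: PCA of the years × trees BAI matrix
  (correlation scale) over the common period; each tree is assigned to the
  component its series correlates with most; Welch / Mann-Whitney trait
  comparisons between groups.
* **Trends**: tie-corrected Mann-Kendall Tau per tree and per chronology;
  OLS of Tau on tree traits; the crown-damage threshold where the fitted
  trend crosses zero; loess turning years.
* **Climate**: per-month z-score departures against a reference period,
  equal-weight regional means, the moisture index P − T (strongly negative
  = hot and dry), and the 19-month southern-hemisphere season window
  (previous season's October, year −2, through current April).
* **Climate sensitivity**: 1000-fold bootstrapped Pearson correlations per
  monthly slot; per-tree seasonal (DJF/JFM) sensitivities; a penalized
  B-spline GAM of sensitivity against crown damage, reported as deviance
  explained with an exact F-test of the smooth.
* **Synthetic stands** with known ground truth (group labels, per-tree
  sensitivities, damage model) for end-to-end parameter-recovery testing.

Full model descriptions, parameter defaults and numerical conventions are
in [`docs/methods.md`](docs/methods.md).

## Worked example

Simulate the default stand (23 trees, a 17-tree stable group and a 6-tree
declining group that diverges in 1934) and run the full pipeline:

```python
from pathlib import Path
from dendrotrend import (StandParams, simulate_climate, simulate_stand,
                         write_rwl, RunConfig, run_pipeline)
from dendrotrend.ringio import write_climate
from dendrotrend.cli import _write_metadata

run = Path("example-run"); run.mkdir(exist_ok=True)
params = StandParams(seed=1)
stations = simulate_climate(range(params.first_year - 2, params.end_year + 1),
                            params)
cores, records, truth = simulate_stand(params, stations)
write_rwl(cores, run / "rings.rwl")
write_climate(stations, run / "climate.csv")
_write_metadata(records, run / "trees.csv")

config = RunConfig(rings_path=str(run / "rings.rwl"),
                   metadata_path=str(run / "trees.csv"),
                   climate_path=str(run / "climate.csv"),
                   seed=1)
report = run_pipeline(config, run / "out")
```

Summarizing the report dictionary prints:

```
site chronology: Rbar 0.349, EPS 0.915 (adequate: True)
PC1 57% / PC2 24% of BAI variance; groups: PC1: 17 trees, PC2: 6 trees
BAI trend 1941-2021  PC1   tau +0.417  p 3.59e-08
BAI trend 1941-2021  PC2   tau -0.237  p 0.00176
BAI trend 1941-2021  site  tau +0.089  p 0.242
trend turns negative above 58 % crown damage (fit p 4.2e-10, r2 0.85)
DJF-temperature sensitivity vs damage: deviance explained 0.82, p 5.1e-07
```

Reading the output: the stand-level chronology carries an adequate common
signal (EPS above the 0.85 convention). The first two PCA axes split the
stand 17 / 6, exactly recovering the generator's groups; the majority group
keeps a significant positive BAI trend over 1941–2021 while the declining
minority trends downward, and the stand mean sits near zero — the mean
hides the divergence. Per-tree trends flip sign where crown damage exceeds
~58 %, and crown damage explains 82 % of the deviance in the trees'
DJF-temperature sensitivity of growth (more damaged trees are more strongly
heat-limited).

The same run directory (`run/out/`) holds the per-stage tables:
`tree_traits.csv`, `bai.csv`, chronologies, `group_assignment.csv`,
`tree_trends.csv`, `climate_departures.csv`, `monthly_correlations.csv`,
`tree_seasonal_sensitivity.csv` and a versioned `report.json`.

The same works from the shell:

```bash
dendrotrend simulate --seed 1 --outdir example-run
dendrotrend run --config config.json --outdir example-run/out
```

with `config.json` holding the three input paths (subcommands `chronology`,
`modes`, `trends`, `climate`, `sensitivity` print single report sections).

## Analyzing real data

Point `RunConfig` at your own inputs: a Tucson `.rwl` (or long CSV) of ring
widths, a tree metadata CSV (`tree_id, dbh_mm, height_m, crown_damage_pct,
neighbors`), and a monthly climate CSV (`station_id, variable, year, month,
value`). Analysis periods (PCA span, trend span, climate span, reference
period), detrending method, bootstrap size and all thresholds are
`RunConfig` fields, loadable from YAML or JSON.
`dendrotrend.reproduce_replication(data_dir)` wraps this for a directory
holding a deposited stand's replication tables in those schemas.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch:
it generates the default synthetic stand from the given seed, executes every
pipeline stage (cross-dating through the damage GAMs, 1000-fold bootstrap),
prints the headline statistics and writes the result JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
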