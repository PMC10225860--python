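# siicov

Coverage metrics for biodiversity observation data on an equal-area grid:
how well do available species records document where species actually occur,
and how much does adding camera-trap (CT) data improve that coverage over
conventional occurrence records alone?

Global occurrence aggregates are enormous but idiosyncratic — a cell may hold
thousands of records yet only a handful of distinct sampling days, strongly
biased toward accessible places. Camera traps, by contrast, sample one
location continuously for weeks to months and record every passing species.
`siicov` quantifies this complementarity for macroecologists and biodiversity
indicator builders with four metric families, all computed on a 110 × 110 km
equal-area grid:

* **Sampling days** — unique calendar days per grid cell and year with data
  collection: distinct record dates for occurrence data, distinct
  active-deployment days for CT data; the two distributions are compared with
  a Welch (unequal-variance) two-sample *t*-test,

  *t* = (x̄₁ − x̄₂) / √(s₁²/n₁ + s₂²/n₂), with Welch–Satterthwaite d.f.

* **Taxonomic coverage** — per cell, the percentage of species expected there
  (from expert range maps coarsened to the grid) with at least one
  observation, and the percentage-point gain when CT data are added.
* **Species Information Index (SII)** — for species *s* in year *t*,

  SII(s, t) = O(s, t) / E(s),

  where E is the number of grid cells in the species' expected range and O
  the number of those cells with at least one observation that year. Annual
  values are averaged over a multi-year window (years without observations
  count as 0). The **national SII** averages species-level window means over
  all species expected in a country, each evaluated on the portion of its
  range inside the border.
* **Coverage boost** — the percent difference in mean SII between the
  occurrence-only baseline and the union of occurrence plus CT data, per
  species and per country, with "newly covered" units (baseline exactly 0)
  counted separately rather than averaged as infinite gains.

A seeded synthetic-data generator produces occurrence and CT inputs with the
two streams' contrasting statistical structure and exact ground truth, so the
whole pipeline is testable without any external download.

## Worked example

Simulate a small world (20 × 20 cells, 16 species, 2018–2022), run the full
indicator pipeline, and summarize complementarity:

```sh
siicov simulate --seed 42 --outdir demo_inputs --n-cols 20 --n-rows 20 \
    --n-mammals 8 --n-birds 8 --year-start 2018 --year-end 2022
siicov run --config demo_inputs/run_config.yaml --outdir demo_run
siicov summarize --rundir demo_run
```

The run prints its conservation ledgers (every input row kept or counted into
a dropped category):

```
occurrences: n_input=4982, ... n_kept=4982
camtrap: n_deployments_input=60, n_detections_input=479, ... n_detections_kept=479
```

and the summary table:

```
 class  n_species  n_species_boosted  n_species_gain_ge_min ...
  bird          8                  7                      3
mammal          8                  6                      4
```

meaning 7 of 8 bird and 6 of 8 mammal species gained *some* SII from CT data,
and 3 and 4 of them gained at least 0.01 (an extra 1 % of their range
covered). `demo_run/sii_species.csv` holds the per-species values, e.g.

```
species,class,n_expected_cells,mean_sii_occ,mean_sii_combined,boost_percent
Avianus species001,bird,16,0.675,0.7,3.7037037037036904
```

— this species is expected in 16 cells; occurrence records alone covered a
mean 67.5 % of them per year over the window, 70 % with CT data added, a
+3.7 % boost. The manifest records the Welch day-count comparison: here
occurrence cell-years had a mean of 2.8 unique sampling days against 72.6
active CT days (*t* = −16.1, d.f. = 71.0, *p* < 0.001) — the
continuous-versus-idiosyncratic contrast the indicator is designed to expose.

For real data, point the YAML config at Darwin-Core-style occurrence CSVs,
deployment/detection CSVs (Camtrap-DP column names accepted), a synonym table
(`variant,accepted,class`), pre-coarsened range cells (`species,cell_id`) or
GeoJSON range polygons via `siicov.grid`, and optionally a
`country_code,cell_id` membership table for national aggregation.

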