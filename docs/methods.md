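# Methods

## The indicator

For one species in one calendar year the Species Information Index (SII) is
the proportion of the species' expected range — expert range polygons
coarsened to an equal-area grid — whose cells contain at least one
observation that year: SII = O/E with 0 ≤ O ≤ E. A value of 0.5 means half
the expected range carried data; values near 1 are not expected even for
well-documented taxa, since that would require complete annual range
coverage. Window means average the annual values over every calendar year in
a configurable window (default 2010–2022 inclusive). The national SII is the
unweighted mean of species window means across all species expected in a
country, each species evaluated only on the cells of its range inside the
national border. The coverage boost of a second data source is the percent
difference between the baseline mean SII and the mean SII of the union of
both sources.

Key conventions, each genuinely open and decided here:

* **Zero years count.** A year with no observations contributes SII = 0 to
  the window mean rather than being skipped. The indicator asks how well the
  data document occurrence each year; skipping empty years would inflate the
  mean exactly where data are worst. A corollary: averaging per-species
  window means across species equals averaging per-year cross-species means
  (asserted on random fixtures), so the order of aggregation is immaterial.
* **The denominator is the expert range.** Observations outside a species'
  expected cells never enter O; they are surfaced as a diagnostic count
  (possible range-map omissions) rather than silently expanding E.
* **Window endpoints are configuration.** The default window is all calendar
  years 2010..2022 inclusive (13 years); both endpoints are run-config
  values.
* **Zero-baseline boosts.** When the baseline mean SII is exactly 0 and the
  combined value positive, the percent difference is undefined; such units
  are tagged "newly covered", counted in summaries, and excluded from mean
  boosts. This preserves the distinction between a large relative gain and
  an infinite one.
* **Species with an empty expected cell set** are excluded from the
  indicator with an error/flag, never scored 0.

## Grid and geometry

The grid is square cells of identical projected area (default 110 000 m
sides) in a registered equal-area CRS. Because no equal-area projection is
canonical for this analysis, the package fixes one: Lambert cylindrical
equal-area on the WGS84 authalic sphere (R = 6 371 007.180918 m) with
standard parallel 30°, the spherical analogue of the common EPSG:6933
parameterization. Forward and inverse maps are closed-form, and area is
preserved exactly on the sphere, so all cells have area `cell_size²` by
construction. The CRS id, origin and dimensions are recorded in every
output manifest, making cell ids (row-major, `id = row·n_cols + col`)
reproducible. Non-equal-area CRS ids are rejected at construction.

Cell membership is half-open, `[x0, x0+w) × [y0, y0+w)`, so the grid is an
exact partition: every in-extent point belongs to exactly one cell, with
shared-edge points resolving to the upper/right neighbour.

Range polygons are coarsened by the *positive-area overlap* rule: a cell is
in the expected range iff the projected polygon overlaps its square with
area above a small numerical floor (1 m², i.e. ~10⁻¹⁰ of a cell — large
enough to absorb floating-point slivers from projection round-trips, far
below any real overlap). Any-overlap is the most inclusive deterministic
rule, consistent with coarsening's purpose of absorbing range-map error;
centroid or majority rules would need separate justification and can be
implemented on top of the exported cell tables. Invalid geometries are
repaired (`make_valid`) before coarsening; unrepairable ones fail naming the
species. Country clipping intersects range and country polygons in projected
space and coarsens the intersection, so a border-straddling range
contributes cells to every country it overlaps.

Ocean/coastal cells are not masked; expected sets come entirely from the
supplied ranges.

## Harmonization and ingest

Scientific names from both streams pass through a synonym table
(`variant → accepted`, many-to-one, with a mammal/bird class per accepted
name). Matching is exact after normalization — trim, collapse whitespace,
"Genus epithet" casing, trinomials truncated to the binomial; no fuzzy
matching, no live taxonomic-backbone queries. Unresolved names are dropped
*and counted*, never silently: every reader returns a conservation ledger in
which kept plus dropped rows equal input rows, and the pipeline manifest
preserves all ledgers.

Dates are ISO 8601; year-only and year-month values support annual presence
but are excluded from unique-day counting (day counts need day resolution;
this can only undercount). Records are assigned to calendar years as
written, with no timezone arithmetic. Camera-trap detections must fall
inside their deployment's inclusive [start, end] interval and reference an
existing deployment; violations are dropped with counts, duplicate
deployment ids are a hard error.

Both streams reduce to the same currency — deduplicated
(species, cell, year) triples per source — because every downstream metric
is location-year scale; the image-versus-sequence distinction in camera-trap
exports therefore collapses at ingest. Merging sources is a set union,
which makes every combined metric ≥ its single-source counterparts
(monotonicity) and ≤ their sum (subadditivity); both are asserted as
properties in the suite.

## Sampling-day comparison

Occurrence effort is proxied by distinct record dates per cell-year (true
effort is not reported by aggregators; days without records are invisible,
so this is a lower bound). Camera-trap effort is the union of active
deployment day-intervals per cell-year, endpoints inclusive, split by
calendar year, overlaps not double-counted. The two cell-year distributions
are compared with the Welch unequal-variance two-sample t-test (the two
sources have very different spreads, making the pooled-variance form
inappropriate); the statistic and Welch–Satterthwaite degrees of freedom are
computed from the closed forms, with `scipy.stats.ttest_ind(equal_var=False)`
serving as an independent cross-check in the tests. Descriptive shares use
configurable cut points (default ≤ 30 and > 100 days per cell-year).

## Synthetic worlds

The generator emulates the structural difference between the streams, not
any particular fauna:

* **Ranges** are connected blobs grown by seeded stochastic accretion from a
  random start cell, with sizes drawn uniformly between configurable bounds
  (default 4–60 cells on a 40 × 40 grid, 30 species split evenly between
  mammals and birds over six years).
* **Occurrence sampling** is a Poisson-thinned Bernoulli process: visit days
  per cell-year ~ Poisson(λ·bias), each visit day recording each locally
  expected species with probability `p_occ` (defaults λ = 3, p_occ = 0.5).
  The bias field is a smooth exponential gradient across the grid
  (amplitude 1.5 on the log scale), a minimal accessibility proxy for the
  documented geographic bias of occurrence data. The closed form
  P(cell-year observed) = 1 − exp(−λ·bias·p_occ) anchors the stochastic
  tests.
* **Camera traps** are deployments placed uniformly among cells intersecting
  at least one range, active for a uniform 30–150 consecutive days from a
  uniform start day, detecting each locally expected species each active day
  with probability `p_det` = 0.05. A fixed survey design (pinned cells,
  start date and duration) can be imposed for calibration: with fixed
  duration d the per-deployment detection probability is exactly
  1 − (1 − p_det)^d.
* 10 % of emitted names use a synonym variant, exercising harmonization; all
  randomness flows from one root seed through named child streams
  (`ranges`, `occurrence`, `camtrap`), so each stage is independently
  bit-reproducible.

With these defaults the median camera-trap cell-year carries well over three
times as many unique sampling days as the median occurrence cell-year,
reproducing the qualitative continuous-versus-idiosyncratic contrast the
metrics are designed to expose.

What the generator does **not** emulate: animal movement and detection
heterogeneity, spatially correlated occupancy within ranges, false-positive
identifications, effort reporting gaps, embargoes. Passing tests therefore
demonstrate the correctness of the accounting — that the pipeline computes
exactly the defined metrics on any input with these schemas — not that the
defaults are a calibrated model of any real corpus.

## Verification strategy and problem sizes

The guarantees are enforced at three levels, all seeded and deterministic:

* **Exact oracle equivalence**: on 100 independently seeded worlds (12 × 12
  cells, 8 species, 3 years — small enough for a fast default suite, within
  the generator's supported envelope), every metric from the full
  CSV-ingest pipeline equals a plain-Python set-and-loop recount from the
  raw simulated tables, exactly (floating-point equality, since both routes
  perform the same exact integer ratios).
* **Constructive and stochastic recovery**: with certain detection and a
  planned survey, annual SII is exactly |range ∩ surveyed|/|range|; over 500
  replicate detection draws, mean SII matches the closed forms above within
  3 Monte-Carlo standard errors.
* **Properties**: union monotonicity on 1000 random presence pairs, Welch
  closed-form agreement to 1e−9, grid partition on 10 000 random points
  against an independent floor-division oracle, and byte-identical repeated
  end-to-end runs.

## Limitations

* Coordinates are treated as exact points; no coordinate-uncertainty
  buffering.
* The day-count proxy undercounts occurrence effort by construction.
* National aggregation requires a supplied country-membership table (or
  polygon clipping via the geometry module); no administrative-boundary
  database ships with the package.
* No occupancy/detection-probability modelling, density estimation, or
  capture–recapture — the indicator measures data coverage, not abundance
  or occupancy.
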