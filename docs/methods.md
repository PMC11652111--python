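# Methods

This note records the models, conventions and design choices behind
`elevdiv`, in the order the pipeline runs.

## Cleaning

Occurrence records are standardised and filtered in a fixed order: synonym
mapping first (a local raw→accepted table; mapping never touches mountain
or elevation), then removal of records lacking an elevation, then records
outside the mountain's declared span (excluded by default,
`keep_out_of_span` retains them), then duplicate collapse. A duplicate is
an identical (accepted name, mountain, elevation rounded to 1 m) triple;
the first occurrence is kept. Names absent from the taxonomy backbone are
kept verbatim by default and dropped only on request, so synthetic data
needs no backbone. Cleaning is idempotent, and the report satisfies the
exact identity `kept = input − no_elevation − out_of_span − duplicates −
unresolved_dropped`. Plot-survey and specimen records are weighted
identically; the elevation is the only spatial datum used (no coordinate
cleaning).

## Belts

Each mountain's span `[min, max]` is tiled with `ceil(span/width)` belts of
`width` metres (default 100 m, the convention in elevational-gradient
studies). Belts are half-open `[lo, lo+width)` with the summit belt
truncated at `max` and closed, so a record at an exact multiple of the
width is counted once. The grid is anchored at the mountain's declared
minimum elevation (not sea level); `anchor` overrides this, since sources
differ on where belts should start. Belt labels for plotting and regression
are interval midpoints.

Occupancy rules: `record` (a species occupies exactly the belts holding at
least one record — the default, faithful to specimen evidence) and
`range_through` (every belt intersecting the species' min–max record
interval — the interpolation convention). Range-through occupancy is always
a superset of record occupancy, and both modes are echoed in every output.

## Faith's PD and phylogenetic endemism

PD of a taxon set is the sum of branch lengths of the minimal spanning
subtree, anchored at the root by default (the dominant convention in
community-phylogenetics software); `include_root=False` excludes the MRCA's
root path, making single-tip PD zero. Zero-length branches are allowed and
contribute 0.

PE down-weights each branch by its range: `PE(belt) = Σ_b L(b)/r(b)` over
branches `b` with a descendant present in the belt, where `r(b)` counts the
belts occupying the branch. The range unit is *belts within the mountain*
(grid-cell ranges are not available in a one-gradient analysis). Because
each branch's length is split exactly across its occupying belts, Σ_belts
PE equals PD of the pooled flora — asserted to 1e-9 relative tolerance in
the tests and typically exact to ~1e-15. Empty belts get PE 0 with a
warning.

Trees are any rooted Newick with branch lengths; polytomies are fine,
missing lengths or duplicate tips are load errors. Tree and belt matrix are
pruned to their shared taxa before any phylogenetic statistic, and the
drops are reported.

## β-diversity

For adjacent non-empty belts (empty belts are skipped, not scored as
zero-similarity), with `a`/`b` the species unique to each belt and `c` the
shared count: Jaccard `β_j = c/(a+b+c)` and Cody `β_c = (a+b)/2`
(equivalently `(|A|+|B|−2c)/2`). Printed formulations of these indices
sometimes define `a`, `b` as *total* community richness, which breaks
`β_j(A,A)=1`; both literal variants (`literal_totals`, `over_c`) are
implemented and selectable, the standard forms are the defaults, and every
output row records the convention used.

## NRI null model

MPD is the mean patristic distance over unordered pairs. NRI standardises
it against randomly assembled communities of the same size:
`NRI = −(MPD_obs − mean MPD_null)/sd MPD_null`, sample (n−1) sd,
`rank_p = (1 + #{null ≤ obs})/(n_reps + 1)`. Positive NRI = clustering.

Two null schemes are offered because the literature describes the same
randomization both ways: `pool_draw` (default; communities drawn uniformly
without replacement from the pool) and `taxa_label_shuffle` (tip labels of
the pool subtree permuted). For presence-only MPD the two induce the same
distribution. The pool is all species recorded on the mountain — the
analysis is per-mountain, never the cross-mountain union. Default 1000
replicates. A degenerate null (sd ≤ 1e-12 relative — e.g. community =
pool) yields NaN with an explicit flag, never a silent zero. Belts with
fewer than two species are reported as not evaluable. Per-belt seeds derive
deterministically from the run seed; absent a seed, one is drawn from
entropy and logged.

## Trend models

Counts (richness) are fitted with log-link Poisson GLMs by IRLS
(statsmodels), with dispersion estimated from the Pearson χ² statistic and
folded into t-tests on the slope — the quasi-Poisson model. "R²" is not
uniquely defined for GLMs; the deviance pseudo-R²
`1 − D_resid/D_null` is reported, with the squared Pearson correlation of
fitted vs observed carried alongside. A constant response returns slope 0,
pseudo-R² 0 directly (IRLS is degenerate there). NRI~elevation and
NRI~richness use Gaussian OLS — NRI is real-valued, not a count — and the
family is recorded per fit; the elevation fit classifies each mountain as
clustering-increasing/decreasing/flat at α = 0.05.

A mountain's diversity peak is the midpoint of its richest belt (ties →
lowest belt; invariant to adding a constant to richness). Peak determinants
are four *separate* single-predictor fits (relative elevation = span of the
gradient in m, longitude, annual mean temperature, annual precipitation),
requiring ≥ 4 mountains; quasi-Poisson by default (peaks are positive
reals; the non-integer warning is expected and suppressed there), Gaussian
selectable, no multiple-testing correction — the four p-values are shown
side by side. Cross-mountain means of species/genus/family counts are
rounded half-up to integers.

## Synthetic data

The generator emulates a mid-sized subtropical mountain at herbarium
sampling intensity. Defaults: 200 species, 0–2000 m span, ~12 records per
species (Poisson; real mountains of this kind run roughly 5–17 records per
species), 10% duplicate injection, 5% missing elevations, 5% non-native
fraction with coupling 0.8, lognormal range widths (median 25% of the span,
log-sd 0.6). Trees are pure-birth (Yule, rate 1): extinction would add
nothing the computed statistics consume. All randomness in a run flows from
one seed through `SeedSequence` child streams, and the seed is echoed in
every emitted file.

Scenarios shape range placement:

- `neutral`: midpoints uniform, clipped to the span — clipping alone gives
  a mid-domain richness hump;
- `filter_low` / `filter_high`: one randomly chosen clade holding 20–50% of
  tips confined to the bottom/top third — habitat filtering, which should
  and does surface as positive NRI in those belts;
- `mid_peak`: midpoints Beta(2.5, 2.5) on the span;
- `monotonic_decrease`: nested attrition — 80% of species reach the base
  with upper limits thinning as Beta(1, 2.5) on the span, 20% are narrow
  lowland specialists. A pure midpoint-density model cannot put the
  expected richness peak in the bottom belt (range geometry always
  depresses the domain edge), so the scenario is built from range limits
  instead; the peak lands in the lowest belt in ≥ 95% of replicates.

Duplicates are injected as exact copies of base records; missing elevations
by blanking. The truth record stores, per species, the intended range and
the belt occupancy implied by the records that survive blanking — the
information cleaning can actually recover — so the end-to-end recovery test
(`range_through`, zero sampling noise) must reproduce it exactly at any
duplicate/missing rate. Non-native species are a random subset whose ranges
are redrawn: with coupling → 1 their midpoints follow belts in proportion
to native richness, with coupling 0 they are uniform. Note that even
uncoupled subsets correlate weakly positively with native richness at the
belt level (both profiles share the bounded span's hump geometry); the
tested property is that coupling *raises* the correlation.

What the generator does not emulate: spatial (lat/long) structure, climate
fields, detection bias varying with elevation, taxonomic error beyond a
synonym table, and abundance. Passing tests therefore demonstrate
correctness of the computations and sensitivity to the encoded assembly
signals, not robustness to every artefact of real herbarium data.

## Numerical choices

- Degenerate NRI nulls detected at sd ≤ 1e-12×max(1, |mean|): identical
  null communities can differ by float summation order (~1e-16).
- PE/PD conservation asserted at 1e-9 relative; observed ~1e-15.
- Duplicate rounding: half-up to integer metres.
- Monte-Carlo NRI validation uses the delta-method MC standard error with
  the exact null's skewness and kurtosis — small discrete nulls are far
  from normal, and the naive `sqrt((1+NRI²/2)/R)` understates the SE.
- Problem sizes in the validation suite: 50 synthetic mountains for PE
  conservation; 22 tree/community cases at 10,000 null replicates against
  exact enumeration; 1000 random set pairs for β brute force; 200 Poisson
  simulations at n = 50 for CI coverage; 100 replicates × 200 species ×
  200 null replicates for scenario separation.

## Known limitations

- Name resolution is exact-match through the synonym table; no fuzzy
  matching.
- No phylogenetic β-diversity, NTI/MNTD, abundance weighting, or
  occupancy-constrained (independent-swap) nulls.
- Cross-mountain peak determinants with ~8 mountains have little power;
  the four separate fits are a screen, not a model comparison.
- Megatree construction and GIS extraction of areas/climate are out of
  scope: trees and tables are inputs.
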