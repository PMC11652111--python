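# elevdiv

Taxonomic and phylogenetic plant diversity along mountain elevational
gradients.

Mountains concentrate much of the world's plant diversity, and how that
diversity is distributed over elevation — monotonically declining from the
base, or hump-shaped with a mid-elevation peak — matters directly for where
conservation effort goes. `elevdiv` is a reusable pipeline for the standard
analysis applied to such systems: it takes raw occurrence records (herbarium
specimens, plot surveys, literature records), a dated phylogeny, and
optional belt-area / climate tables, and computes for each mountain:

- **cleaning**: records without usable elevations removed, exact duplicates
  (same accepted name, mountain, elevation to 1 m) collapsed, names resolved
  through a local synonym table — no online name services;
- **belt binning**: the gradient partitioned into fixed-width elevational
  belts (default 100 m, half-open `[lo, hi)`, summit belt closed), each belt
  treated as one community; occupancy either by direct records or
  range-through interpolation;
- **α-diversity per belt**: species richness *SR*, Faith's phylogenetic
  diversity *PD* (total branch length of the root-anchored subtree spanning
  the belt's species), and phylogenetic endemism
  *PE = Σ_b L(b)/r(b)* where *r(b)* is the number of belts occupied by
  branch *b* — so Σ_belts PE = PD of the whole flora, exactly;
- **β-diversity between adjacent belts**: Jaccard similarity
  *β_j = c/(a+b+c)* and Cody turnover *β_c = (a+b)/2* (with *a*, *b* the
  belt-unique species counts and *c* the shared count; literal textbook
  variants selectable);
- **phylogenetic structure**: the net relatedness index
  *NRI = −(MPD_obs − mean MPD_null)/sd MPD_null* per belt, with a
  1000-replicate randomization null drawn from the mountain's species pool
  (`pool_draw`, or tip-label shuffling); NRI > 0 is phylogenetic clustering,
  NRI < 0 overdispersion;
- **trend models**: quasi-Poisson GLMs (log link, Pearson-dispersion
  t-tests) for richness~area, OLS for NRI~elevation and NRI~richness,
  Pearson correlation of native vs non-native belt richness, and
  single-predictor fits of each mountain's diversity-peak elevation on
  relative elevation, longitude, temperature and precipitation.

A first-class synthetic-data module generates complete mountains — Yule
phylogenies, elevational ranges under five assembly scenarios (neutral
mid-domain, low/high-elevation habitat filtering of a clade, mid-peak,
monotonic decrease), occurrence files with realistic cleaning hazards
(duplicates, missing elevations), belt-area profiles and a coupled
non-native subset — so the whole pipeline is testable without any data
download.

## Worked example

Run a synthetic mountain with a clade confined to the top third of a
0–2000 m gradient (habitat filtering) and look at the top belts:

```python
from elevdiv import RunConfig, ScenarioConfig, run_mountain

cfg = RunConfig(
    mountain_id="demo", out_dir="demo_run", seed=42, n_reps=1000,
    synthetic=ScenarioConfig(mountain_id="demo", n_species=120,
                             scenario="filter_high", seed=42),
)
run = run_mountain(cfg)
print(run.alpha.tail(3).to_string(index=False))
print(run.nri.tail(3)[["midpoint", "n_taxa", "nri", "rank_p"]].to_string(index=False))
```

prints

```
mountain_id  belt_lo  belt_hi  midpoint  SR        PD       PE
       demo   1700.0   1800.0    1750.0  37 57.635605 9.153816
       demo   1800.0   1900.0    1850.0  31 47.779707 7.152113
       demo   1900.0   2000.0    1950.0  26 45.833455 6.479455

 midpoint  n_taxa      nri   rank_p
   1750.0      37 3.456482 0.007992
   1850.0      31 2.614872 0.019980
   1950.0      26 2.158009 0.031968
```

The top belts hold 26–37 species whose NRI of 2.2–3.5 (null rank p < 0.05)
flags strong phylogenetic clustering — exactly the signature the confined
clade should leave: the summit flora is dominated by close relatives. The
trend table from the same run fits richness against belt area
(`SR ~ area_km2, slope 0.0069, pseudo-R² 0.47, p 0.001`) and NRI against
elevation (`slope 0.0014, R² 0.42, p 0.002`, classified
`clustering_increasing`).

Every run writes its surfaces as CSV/JSON (belt matrix, α-diversity,
adjacent-belt β, NRI profile, trend fits, taxonomic summary) plus a
`manifest.json` recording the seed, a config hash and every decision flag
(occupancy rule, β conventions, null scheme, …). Identical config + seed
reproduces every output byte for byte.

The same pipeline is available from the shell:

```bash
elevdiv simulate --seed 42 --n-species 120 --scenario filter_high --out inputs/
elevdiv run-all --config run.yaml
elevdiv cross-mountain --config m1.yaml ... --attributes attrs.csv --out cross/
```

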