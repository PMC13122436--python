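# otolife

Life-history reconstruction and selective-mortality analysis for migratory
salmon, from otolith and eye-lens chemistry.

Juvenile Chinook salmon leave their natal river either as newly emerged fry
("early migrants") or months later as smolts ("late migrants"). Most of the
fish that die along the migratory corridor are never observed — but their
otoliths travel with the survivors. Because strontium isotope ratios
(⁸⁷Sr/⁸⁶Sr) differ between the natal river, the tidal Delta, and the ocean,
and are recorded chronologically in the otolith, a transect from the core
reconstructs the size at which each surviving fish left its natal river and
left freshwater. Comparing those reconstructed size distributions between
fish sampled sequentially — entering the Delta, leaving it, and returning
to spawn years later — measures where and how strongly mortality selects
on size. `otolife` implements that full chain for researchers in fisheries
and movement ecology, exercised end-to-end on a synthetic cohort generator
so no field data are required.

The core quantities:

* **Exit sizes** — the natal-exit radius is the first downward crossing of
  the natal-river minimum water ratio (0.7085), the freshwater-exit radius
  the first upward crossing of the estuary-boundary mean (0.70785), both by
  linear interpolation along the transect, with normalised-SrV and
  total-radius fallbacks for fish whose profiles never cross. Radii become
  fork lengths through the broken-stick regression
  FL = 0.021259·OR + 31.08748 (OR < 256 μm), 0.165660·OR − 5.8799
  (OR ≥ 256 μm).
* **Phenotype cutoff** — Hartigan's dip test establishes that pooled
  natal-exit sizes are bimodal; a two-component normal mixture N(μ₁,σ₁²),
  N(μ₂,σ₂²) is fitted by EM and the early/late cutoff is the density
  crossing w₁φ₁(x) = w₂φ₂(x) between the means.
* **Selection differentials** — i = (z̄* − z̄)/s between each sampling
  point and its survivors, standardised by the initial sample's SD.
* **Cohort replacement rate** — natural-origin returns per natural-origin
  spawner, CRR(B) = Σₐ E_nat(B+a)·fₐ(B+a) / E_nat(B) over ages 2–4, after
  expanding hatchery-assigned counts by 1/(1 − marking rate) for the marked
  fish carcass surveys skip.

## Worked example

The analysis is organised as numbered drivers under `analysis/`, each a thin
script over the library (`src/otolife/`), writing tidy tables under
`results/`:

```
python analysis/01_simulate_cohorts.py        # 8 cohorts, 32 000 fish
python analysis/02_reconstruct_life_histories.py
python analysis/03_provenance.py
python analysis/04_phenotype_cutoff.py
python analysis/05_selection_differentials.py
python analysis/06_cohort_replacement.py
```

Step 04 prints, for the default seed:

```
dip test on 1374 pooled natal-exit sizes: D = 0.042, p = 0.000999 (bimodal)
early/late cutoff: 49.4 mm FL (334 μm otolith radius)

percent early migrants by region (all-years rows):
     region  natal_mean_mm  pct_early  pct_early_legacy
delta_entry           47.9       69.5              69.7
  delta_bay           42.6       95.2              95.4
 delta_exit           57.8       45.7              47.0
   spawning           66.0       21.9              22.4
```

The dip test rejects unimodality (two migration pulses), the fitted cutoff
lands near the generator's true density crossing (50.0 mm), and the early
fraction falls monotonically from ~70% of Delta-entry juveniles to ~22% of
returning adults — progressive loss of early migrants, the signature of
size-selective mortality. Step 05 quantifies it per segment
(SD-standardised differentials, segment means Delta 0.69, Ocean 0.52,
All 1.25 under the default survival settings), and step 06 estimates
hatchery fractions, natural escapement and replacement rates
(CRR 0.48–1.51 across brood years in the example run).

`run_pipeline` in `otolife.pipeline` performs the same chain in one call
for programmatic use.

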