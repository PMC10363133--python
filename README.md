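# planktonts

Analysis toolkit for multi-year, multi-trophic plankton observatory time
series — the kind collected at coastal monitoring stations where surface
water, CTD profiles, amplicon libraries, microscopy counts and net hauls
accumulate over many years at irregular cadence (twice-weekly to monthly).
It targets the Baltic Sea proper setting (brackish, strongly seasonal,
spring dinoflagellate bloom, summer cyanobacteria) but every constant is
configurable.

The package covers the full chain from raw observations to food-web
summaries:

- **Climatology** — observations are pooled across years onto a 1–365
  julian-day axis (leap days folded onto day 60), same-day values averaged
  first, then a centred circular 15-day rolling mean with a moving
  standard deviation: the multi-year average annual cycle of each variable.
  Seasons follow the HELCOM convention (winter Jan–Feb, spring Mar–May,
  summer Jun–Sep, autumn Oct–Dec).
- **Hydrography** — potential density anomaly σθ from the EOS-80
  (UNESCO 1983) one-atmosphere polynomial; mixed-layer depth as the
  shallowest depth where Δσθ > 0.125 kg m⁻³ relative to the surface,
  located by linear interpolation; the combined nutrient availability
  index ∛([NO₃⁻+NO₂⁻]·[PO₄³⁻]·[SiO₄⁴⁻]).
- **Carbon stocks** — bacterioplankton cells × 20 fg C cell⁻¹,
  mesozooplankton wet weight × 5 %, phytoplankton biovolume × per-group
  factors (pg C µm⁻³), assembled into a seasonal budget over
  *complete-case* samplings (dates observed at every trophic level) for
  four compartments: bacterioplankton, phytoplankton, the mixotrophic
  ciliate class Litostomatea (reported as its own pool), and large
  mesozooplankton.
- **Community dynamics** — 16S copy-number normalization
  aᵢ = (cᵢ/kᵢ)/Σⱼ(cⱼ/kⱼ), cyanobacteria exclusion from the amplicon table
  (they are carried in the phytoplankton microscopy fraction), group
  aggregation with an audit of the "< 2 % rule" for catch-all groups, and
  Bray–Curtis time-lag similarity: for every sample pair,
  BC = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ), similarity 1−BC, binned by months of lag —
  annual peaks expose seasonally recurring community states.
- **Co-occurrence** — pairwise-complete Spearman ρ with t-approximation
  p-values for all biotic/abiotic variable pairs, and predator–prey link
  extraction (mesozooplankton groups + Litostomatea vs phyto- and
  bacterioplankton groups, relative biomasses, p < 0.05, no
  multiple-testing correction).
- **Synthetic campaigns** — a first-class generator emulating the study
  conditions (sinusoidal abiotic seasonality, Dirichlet compositional
  communities, two-layer stratified CTD casts, irregular sampling) that
  always emits its ground truth, so every estimator can be validated by
  parameter recovery without any external data.

## Worked example

```python
import planktonts as pts

campaign = pts.simulate_campaign(seed=1)           # 8-year synthetic campaign
report = pts.run_pipeline(pts.PipelineConfig(seed=1, out_dir="run"))
print(report["budget"].round(3))
```

Running `python examples/04_carbon_budget.py` prints (seed 1):

```
complete-case samplings: 88 (mesozooplankton is the monthly limiting level)

season             pool  carbon_mg_m3  fraction  n
spring bacterioplankton        40.776     0.160 22
spring    phytoplankton       150.773     0.590 22
summer bacterioplankton        83.457     0.368 31
summer  mesozooplankton         8.835     0.039 31
...
```

Phytoplankton dominates the spring carbon pool (59 %) while
bacterioplankton peaks in both absolute and relative terms in summer —
the seasonal structure the generator encodes and the budget recovers.
`examples/05_lag_similarity.py` shows the annual recurrence signal
(lag-12 mean similarity 0.885 vs lag-6 0.791 for the bacterioplankton
community), and `examples/03_mixed_layer_depth.py` recovers per-cast MLD
with RMSE 0.24 m on a 0.5 m depth grid. Each example script is a short,
narrated entry point to one capability.

A thin CLI mirrors the stages:

```bash
plankton simulate --out data --seed 1
plankton climatology --in data/abiotic/temperature.csv --window 15 --out clim.csv
plankton mld --in data/ctd --threshold 0.125 --out mld.csv
plankton run --seed 1 --out run
```

## Layout

- `src/planktonts/` — library (`timeseries`, `hydrography`, `carbon`,
  `community`, `cooccurrence`, `synthetic`, `pipeline`, `cli`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, parameter choices, numerical conventions,
  limitations
- `tests/` — unit, property and acceptance suites
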