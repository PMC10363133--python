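# Methods

This note documents the models and conventions behind `planktonts`: what
each stage computes, the defaults and why, what the synthetic generator
does and does not emulate, and the numerical choices that matter when
results are compared across implementations.

## Climatology on the julian-day axis

Observatory sampling is irregular (days to a month between cruises), so
the annual cycle is estimated by pooling all years onto a common
julian-day axis rather than by fitting a curve.

- **Leap days.** Feb 29 maps to day 60 and every later date in a leap
  year shifts back one day, keeping a fixed 365-day axis. The Feb 29 /
  Mar 1 collision is absorbed by the collapsing step. The alternative (a
  366-day axis) leaves day 366 populated by at most a quarter of years.
- **Same-day collapsing.** Observations sharing a julian day across
  years are arithmetically averaged *before* the rolling window, so a day
  that happened to be sampled in many years does not dominate its
  neighbourhood. Consequently the rolling statistics weight collapsed
  days, not raw observations.
- **Window.** "Covering 15 julian days" is implemented as a centred
  window of ±7 days — the standard moving-average convention. The window
  wraps circularly modulo 365 so the curve is continuous across the
  New Year; this makes the climatology exactly equivariant under circular
  shifts of the data, a property the tests exploit.
- **Moving SD.** Sample SD (n−1 denominator) over the collapsed values in
  the window; reported missing when fewer than two days contribute.
  Missing values propagate; nothing is imputed or gap-filled.
- A useful closed form: a daily-sampled cosine of period 365 passes
  through the 15-day window attenuated by the Dirichlet-kernel factor
  sin(15π/365)/(15·sin(π/365)) ≈ 0.9973, which the tests verify to 1e-9.

## Hydrography

- **Equation of state.** σθ uses the EOS-80 (UNESCO 1983) one-atmosphere
  density polynomial, with measured temperature treated as potential
  temperature. For casts of ≤ 40 m the adiabatic correction and the
  pressure dependence of σθ are far below the 0.125 kg m⁻³ MLD threshold,
  and EOS-80 has published check values (ρ(35, 5, 0) = 1027.67547 kg m⁻³
  and friends) that make the implementation independently verifiable.
  EOS-80's formal validity at brackish salinities (S ≈ 7) is accepted
  as-is; the threshold criterion only uses density *differences*.
- **Mixed-layer depth.** Reference density is the shallowest measured
  level (no extrapolation to 0 m). The Δσθ > 0.125 kg m⁻³ crossing is
  located by linear interpolation between the bracketing levels, making
  the estimate grid-resolution independent to first order. When the
  threshold is never exceeded the deepest measured depth is reported with
  `crossed=False` — deep winter MLDs are data, not failures, and extreme
  shallow values are likewise retained.
- **Nutrient availability.** ∛(NO₃⁻+NO₂⁻ × PO₄³⁻ × SiO₄⁴⁻), in µM: a
  geometric-mean-type index that is symmetric, homogeneous of degree one,
  and zero whenever one nutrient is depleted. Ammonium deliberately does
  not enter. Slightly negative concentrations (below-detection rounding)
  should be clamped to zero upstream; the function rejects negatives.

## Carbon stocks and the seasonal budget

- Bacterioplankton: cells mL⁻¹ × 20 fg C cell⁻¹ → mg C m⁻³
  (1×10⁶ cells mL⁻¹ ≡ 20 mg C m⁻³).
- Large mesozooplankton: carbon = 5 % of wet weight.
- Phytoplankton: biovolume (µm³ mL⁻¹) × per-group volumetric factor
  (pg C µm⁻³). Published class-specific conversion tables are a *user
  input*; the shipped defaults (0.11–0.22 pg C µm⁻³ by group) sit in the
  range of plasma-volume-based factors and exist to make the synthetic
  pipeline self-contained, not to substitute for a real conversion table.
- **Complete-case rule.** The budget uses only calendar days on which all
  trophic levels were sampled — with monthly net hauls this makes
  mesozooplankton the limiting level. Pool values are arithmetic means
  over those samplings within each HELCOM season, pooling years (medians
  are a defensible alternative; means were chosen and are stated here).
- **Litostomatea** (in practice the mixotrophic ciliate *Mesodinium
  rubrum*) is counted in the phytoplankton microscopy table but reported
  as its own budget pool and treated as a predator in the co-occurrence
  analysis.
- The depth mismatch between bottle samples (2 m) and net hauls (0–30 m)
  is ignored in the budget, as is conventional; an optional per-sample
  era label allows stratifying the budget by instrument/method period.

## Community dynamics

- **Copy-number normalization.** Amplicon counts are divided by the
  taxon's 16S copies-per-genome before closure; taxa without a reference
  value fall back to the dataset median with a logged warning (dropping
  them would silently distort compositions).
- **Cyanobacteria placement.** Cyanobacterial taxa are deleted from the
  amplicon table and carried only in the phytoplankton microscopy
  fraction; the pipeline validator enforces that no taxon appears in both
  tables.
- **Bray–Curtis inputs.** Relative abundances for bacterioplankton (after
  normalization) and relative *biomass* for the microscopy levels —
  phytoplankton biovolumes are converted to carbon per taxon before
  closure, since shares of biovolume and shares of carbon differ by the
  per-group factors. Genus level throughout; no square-root or Hellinger
  transformation.
- **Lag binning.** A pair of samples Δ days apart falls in lag-month m
  when (m−1)·30.44 < Δ ≤ m·30.44, so bin 1 holds all pairs within one
  average Gregorian month. Self-pairs (Δ = 0) do not exist since one
  sample per date enters the table. Calendar-month binning is the main
  alternative; fixed-width bins were chosen because they make the first
  bin's meaning exact.

## Co-occurrence

- Spearman ρ is the Pearson correlation of mid-ranks (average ranks on
  ties); p-values use the two-sided t-approximation
  t = ρ√((n−2)/(1−ρ²)), df = n−2, which is the default in standard
  statistical tooling and accurate for the n ≥ 30 typical here. |ρ| = 1
  maps to p = 0. Fewer than 3 complete pairs is an error; zero rank
  variance yields an undefined (missing) ρ.
- Matrices are pairwise-complete at individual-sampling resolution (no
  seasonal averaging), and per-pair sample counts are reported so sparse
  overlaps are visible. Predator–prey links keep edges with p < α
  (default 0.05) with *no* multiple-testing correction, matching the
  plain display convention of exploratory co-occurrence analyses; the
  type-I error of this rule is calibrated by simulation in the tests
  (5 % of null edges retained, within binomial error). Correlations are
  computed on individual samplings for both the matrix and the links; a
  seasonal-average mode would be a one-line change but mixes two very
  different effective sample sizes.

## The synthetic campaign generator

The generator emulates an offshore Baltic Proper station sampled 2011-ish
to 2018-ish and exists so that every downstream estimator has a ground
truth to recover.

- **Seasonality.** Every scalar follows one or two cosine harmonics
  x(d) = mean + a₁cos(2π(d−p₁)/365) + a₂cos(4π(d−p₂)/365) plus additive
  Gaussian noise, truncated at zero for concentrations. Defaults land on
  the station's observed levels: temperature 4 → 18 °C (peak day 205),
  nitrate 2.5 → 0.2 µM, phosphate 0.8 → 0.1 µM, silicate 16 → 8 µM,
  Chl a with a spring maximum near 4.5 µg L⁻¹ and winter floor near
  0.3 µg L⁻¹, DOC ~360 µM with a mid-summer pulse to 410 µM (the second
  harmonic), cDOM 0.25 → 0.33 m⁻¹. Ammonium is flat with noise, as
  observed. The single/double-harmonic family is the simplest form that
  reproduces the stated winter/summer levels; it cannot produce sharp
  blooms or skewed pulses.
- **Sampling dates.** Per-season exponential inter-arrival times with
  mean cadence (winter 14 d, spring/summer 7 d, autumn 10 d), rounded and
  clipped to ≥ 1 day: irregular like the real schedule, without calendar
  bookkeeping. Mesozooplankton is subsampled to the first campaign date
  of each calendar month (net hauls were monthly).
- **Communities.** Group shares are unnormalized seasonal cosine weights
  renormalized to sum to one at each date — seasonal percentages quoted
  per group in field studies are season averages that need not sum to
  100, so they are treated as weights. Realized compositions are
  Dirichlet draws centred on the seasonal shares (precision 200 by
  default; `None` = degenerate/noise-free). Fixed within-group splits
  define 7–11 pseudo-genera per level with plausible Baltic names. Total
  biomass follows its own seasonal curve (bacterioplankton 20 → 90,
  phytoplankton ~25 winter → ~240 spring peak, mesozooplankton 1 → 10
  mg C m⁻³), floored at a small positive value (0.5 mg C m⁻³) so
  compositions stay defined when noise would cross zero.
- **Observables.** Bacterioplankton is emitted as amplicon counts with
  the copy-number bias built in (reads ∝ share × copies/genome, library
  size 1e5) plus a cell-count series consistent with the 20 fg rule;
  phytoplankton as biovolume consistent with the per-group carbon
  factors; mesozooplankton as wet weight consistent with the 5 % rule.
  Recovery through the corresponding conversions is therefore exact at
  zero noise — by construction, and that is the point.
- **CTD casts.** Two layers on a 0–40 m grid (0.5 m step): seasonal
  surface temperature/salinity above a seasonally varying cline (winter
  ~23 m, summer ~10 m), cold slightly saltier water below, with small
  per-level noise. The salinity step guarantees a Δσθ jump above the
  0.125 kg m⁻³ threshold year-round, and the configured cline depth is
  stored as the per-cast true MLD.
- **What it does not emulate:** advection and mixing physics, sharp bloom
  asymmetry, sequencing-depth variation and zero inflation, taxonomic
  misassignment, era effects between instruments, and any trend or regime
  shift. Passing recovery tests therefore demonstrates estimator
  correctness under the stated model, not robustness to everything real
  data can do.

### Ground truth and the recovery convention

`Campaign.true_seasonal_pool_means()` / `true_seasonal_group_shares()`
evaluate the noise-free generator curves either uniformly over the
365-day year or at a supplied set of sampling dates. Recovery tests use
the *sampled-dates* truth: with monthly complete cases, winter holds only
two samplings per year, and where a seasonal curve varies strongly within
a season the uniform-day mean and the sampled mean legitimately differ —
that is sampling design, not estimator error, and the tests are built to
separate the two.

## Problem sizes and determinism

The test and acceptance workloads use an 8-year campaign (~350 sampling
dates, ~60 000 Bray–Curtis pairs), 100 casts for MLD recovery, 1000
random instances for the brute-force oracle comparisons and 500 null
replicates (10 000 edges) for the type-I calibration — sizes at which all
Monte-Carlo margins in the assertions are multiples of the relevant
standard errors. All randomness flows from a single seed through
independent named substreams (dates, abiotic, profiles, communities), so
a campaign is bit-identical under a fixed seed and the full pipeline is
byte-identical on rerun; output files embed a provenance header with the
package version, seed and a hash of the scientific configuration (output
paths excluded from the hash).

## Known limitations

- EOS-80 rather than TEOS-10; fine at 40 m, not for deep or precise work.
- Budget uncertainty is not propagated beyond per-season means; no
  bootstrap.
- Lag bins use fixed 30.44-day months; curves from calendar-month tools
  can differ by one bin near the year boundaries.
- The Spearman p-value is asymptotic; for n < ~15 an exact/permutation
  test would be preferable (the engine reports n so users can judge).
- The generator's Dirichlet noise is exchangeable across taxa within a
  date; real compositional noise is overdispersed and autocorrelated.
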