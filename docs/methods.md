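# Methods

This note documents the statistical procedures implemented in `mldchl`, the
assumptions behind them, the knobs that matter, and what the synthetic
testbed does and does not establish about real data.

## The scientific setting

In stratified, oligotrophic basins the surface chlorophyll-a concentration
(CHL, a proxy for phytoplankton biomass) depends on nutrients entrained
from below when the surface mixed layer deepens. The package quantifies the
co-variability of mixed layer depth (MLD, metres, from a hydrodynamic
model, gap-free) and CHL (mg/m³, from satellite ocean colour, gappy) at
seasonal and interannual scales, over latitude-band sub-regions of a basin
confined to deep water by an isobath mask.

## Data model and compositing

Daily fields live on a common lat/lon grid (`DailyGrid`; MLD is bilinearly
interpolated onto the CHL grid when needed). Missing values are NaN.
Quality control removes individual CHL pixels exceeding 10 mg/m³ (strict
`>`; a value of exactly 10 is kept). CHL is then log10-transformed — CHL is
approximately lognormal, so statistics are computed in log space and a mean
of log values back-transforms to a geometric mean.

Composites are per-pixel means over contiguous, non-overlapping 4-day
blocks; the block calendar matters and three anchorings are provided:

* **record-anchored** (`make_composites`): blocks from an arbitrary anchor
  date; the generic primitive.
* **year-anchored** (`yearly_anchored_composites`): blocks restart every
  January 1, so block-of-year indices align across years. This is the
  calendar used for climatological annual cycles: a record-anchored
  calendar drifts by one day per year (365 mod 4), so composite-of-year
  groups would never align and a "climatology" would degenerate into the
  raw record.
* **season-anchored** (`season_anchored_composites`): blocks restart at
  each season's first day. An October–December season always yields
  exactly 23 composites (92/4), and eleven such seasons 253 — the sample
  size the winter anomaly analysis is gated on.

A trailing partial block is always dropped; a composite is missing iff no
day contributed, and the contributing-day count is carried alongside.
No single 4-day calendar reproduces a 96-composites-per-year climatology
(365/4 ≈ 91; month-anchored gives ~84); `monthly_anchored_composites` is
provided for comparison and the package forces neither convention.

## Annual cycle and co-variability

Per region, 4-day climatological maps are averaged pixel-wise across years
(year-anchored calendar), then spatially averaged; the CHL cycle is
back-transformed to mg/m³. Co-variability statistics on the two cycles:

* relative change ΔX_rel(t) = (X_{t+1} − X_t)/X_t · 100 (%);
* sign agreement: the percentage of consecutive-composite pairs where
  sign(ΔMLD_rel) = sign(ΔCHL_rel). Exactly zero changes count as
  non-agreement by default (configurable); ties essentially never occur on
  continuous data;
* conditional mean responses: mean ΔMLD and ΔCHL over co-increasing pairs
  and, separately, over co-decreasing pairs; an empty class is reported as
  undefined, never as zero;
* OLS regression CHL = a·MLD + b per season (winter = October–March,
  summer = April–September), with R² and the slope F-test
  (F = R²/(1−R²)·(n−2) on (1, n−2) dof); a zero-variance MLD season is a
  singular fit, and a constant CHL season returns slope 0, R² 0 exactly.

## Standardised anomalies

Anomalies remove the seasonal cycle and unify units:

    X_anom(t) = (X(t) − mean_month(t)) / std_month(t)

with mean and std per pixel per calendar month over the baseline years
(sample std, ddof=1, configurable; the choice is documented because with
~10 baseline years ddof changes std by ~5%). A composite belongs to the
month of its window start date. Cells with std = 0 or fewer than 2 samples
give undefined anomalies (masked, never ±inf).

Monthly standardisation is deliberately simple, and it is *approximate*:
the deterministic seasonal cycle varies within a month, and that
within-month residue survives in the anomalies of both variables. On the
synthetic testbed this attenuates the measured MLD–CHL anomaly correlation
below its analytic value (0.92 measured vs 0.99 analytic in the frozen
Monte-Carlo band test) and — because the residue is shared between the two
variables — places a floor under the correlation at zero coupling.
Parameter-recovery tests therefore use the generator's own standardisation
(`true_standardised_anomalies`, known climatology and noise std), under
which the lag-0 correlation is monotone in the coupling coefficient by
construction; the monthly-climatology route is validated separately against
its Monte-Carlo band.

### Correlation maps

Per-pixel Pearson r between the MLD and CHL anomaly composites, pairwise-
complete (each pixel uses its own overlapping non-missing pairs). Two-sided
significance from

    t = r·sqrt(n−2)/sqrt(1−r²),  p = 2·(1 − F_t(|t|, n−2)).

Pixels with n below a minimum-pairs gate are masked: the canonical gate is
n ≥ 100 of the N = 253 winter composites (≥ 40% coverage); shorter demo
records scale the gate by the same ratio. No field-significance or
false-discovery correction is applied across pixels — the maps are
descriptive, as is standard in this literature.

### Regional series, lagged and per-season correlations

Regional anomaly series are spatial means over region pixels, with
composites dropped when regional coverage falls below 10%. Lagged
correlations (CHL lagged behind MLD by 0..10 composite steps = 0–40 days)
are pairwise-complete with the same t-based p. Per-season correlations are
computed over each OND and JFM window separately (n = 23 / 22 when
complete), flagged significant at p < 0.05.

## Extreme events

Extremes are detected on regionally averaged daily series (MLD: plain
spatial mean; CHL: geometric mean of present pixels), against a day-of-year
percentile climatology in the style of the marine-heatwave literature:

1. pool all daily samples within an 11-day window (±5 days) of each
   day-of-year across all years;
2. take the pool mean and its 90th (or 10th) percentile, linear
   interpolation between order statistics;
3. smooth both along the day-of-year axis with a centred 30-day circular
   moving mean.

Feb 29 occupies a 366th slot: its samples join the pools around the
Feb/Mar boundary and its own threshold is the mean of the Feb 28 and Mar 1
values. An event is a maximal run of consecutive days beyond the threshold
lasting ≥ 4 days (MLD) or ≥ 3 days (CHL). By default runs separated by
even one sub-threshold day stay separate; an optional `join_gap` parameter
merges runs separated by at most that many days before the duration filter,
for comparison with marine-heatwave schemes that bridge ≤ 2-day
interruptions.

Calibration: on stationary iid data the fraction of days above the
90th-percentile threshold is ~10% before the duration filter (measured
10.1% on 30 synthetic years). Injected 3-sigma events of qualifying
duration are recovered with boundaries within ±1 day in ≥95% of seeded
runs; the residual failures are adjacent natural exceedance days extending
an event boundary by two days, which is detector-faithful behaviour.

The **CHL response** to MLD extremes is the percentage of all extreme-MLD
days on which the daily regional CHL standardised anomaly exceeds +0.5
(deep events) or falls below −0.5 (shallow events); the boundary is strict
`>` by default with an inclusive `≥` switch, and days with missing CHL
count in the denominator. **Compound events** are sign-matched temporal
overlaps (deep & high, shallow & low) of MLD and CHL events; each
overlapping pair contributes its intersection interval. Event-mean maps
average the daily anomaly fields over an event's days, missing-aware.

## Light

K_d(PAR) is derived from satellite K_d(490) by the clear-water relation
K_d(PAR) = 4.6051·K_d(490)/(6.07·K_d(490)+3.2) for K_d(490) ≤ 0.115 m⁻¹
(boundary inclusive). For turbid pixels no coefficients are built in: they
are masked unless the caller supplies (a, b, c) for a·K/(b·K+c) from a
source of their choosing — guessing a published turbid-water fit silently
would be worse than an explicit gap. The euphotic depth is the 1% light
level Z_e = ln(100)/K_d(PAR) ≈ 4.605/K_d(PAR); Z_e·K_d(PAR) = ln(100) is
preserved to 1e-12 through the round trip. Z_e − MLD maps are signed so
that positive means the lit layer is deeper than the mixed layer.

## The synthetic generator

The generator is first-class, tested code: it defines the study conditions
under which everything else is validated. Per pixel,

    MLD(t) = m(lat) + a(lat)·cos(2π(doy − phase)/365.25) + e_m(t)
    z(t)   = e_m(t)/σ_m
    log10 CHL(t) = log10 base(lat) + A_c·cos(…) + β·z(t − lag) + e_c(t)

with e_m, e_c independent AR(1) processes (shared coefficient 0.3,
innovation stds 6 m and 0.08 log10 units, stationary initialisation), then
Bernoulli cloud-masking of CHL with month/latitude-band probabilities.
Defaults: a 10–28°N domain at 0.1° cells (echoing a basin-scale north–south
gradient without claiming any geography), winter-maximum MLD 40 m (south)
to 90 m (north) peaking at day-of-year 25, summer minima 12–15 m, CHL base
0.45 (south) to 0.12 (north) mg/m³ with 0.18 log10 units of winter-high
seasonality, coupling β = 0.5 at lag 0, 25% base missingness. Demo and
test configurations use coarser cells (0.5–2°) and shorter records purely
to keep problem sizes proportionate; the structure is identical.

The contemporaneous correlation between z and the CHL log-anomaly is
β/sqrt(β² + σ_c²) with σ_c the stationary log-noise std — the analytic
anchor for the Monte-Carlo band tests. Injected extremes shift the noise
term by amplitude × stationary std inside a date window and spatial
footprint, and (for MLD) propagate into CHL through the coupling, so
compound-event detection can be checked against a ground-truth ledger.
A winter noise-suppression factor (< 1 multiplies the CHL innovation std
in October–March) creates records whose winter regression R² exceeds the
summer one, the qualitative regime the seasonal analysis expects.

What the generator does *not* emulate — and hence what green tests do not
show about real data: spatially correlated cloud shapes (missingness is
independent Bernoulli per pixel-day), advection and eddies (no spatial
correlation in the noise at all), asymmetric seasonal cycles, retrieval
error structure in K_d(490) (a fixed monotone power law of CHL stands in),
and any feedback from CHL to MLD.

## Numerical choices

* Log base 10 throughout for CHL (ocean-colour convention).
* Sample std (ddof=1) for monthly climatologies; percentiles by linear
  interpolation between order statistics.
* NetCDF I/O uses the NetCDF3 classic format via xarray's scipy engine;
  CF time encoding, `_FillValue` → NaN.
* Bilinear regridding rejects any target node outside the source hull
  rather than extrapolating.
* The 30-day smoothing window (even length) is centred with offsets
  −15..+14.
* Pipeline determinism: every product is a pure function of
  (config, seed); SHA-256 checksums of all outputs are recorded in a run
  manifest, and repeated runs must reproduce them bit-for-bit.
* Problem sizes in the shipped tests and demo (0.5–2° cells, 3–10 years,
  50-seed Monte-Carlo loops) were chosen so the whole suite exercises
  every statistic at meaningful sample sizes while remaining quick to run
  end-to-end.

## Known limitations

* Monthly standardisation leaves within-month seasonal residue in the
  anomalies (quantified above); a day-of-year climatology would remove it
  but is not what this analysis tradition uses for composite anomalies.
* Sub-region boundary latitudes are configuration, not science: the
  defaults split the domain into five equal bands named by the standard
  basin nomenclature (NRS, NCRS, SCRS-N, SCRS-S, SRS) and must be
  overridden for real-data work.
* Extremes are detected on regional means by default; per-pixel detection
  would need a different climatology cache and is out of scope.
* The turbid-water K_d(PAR) branch requires user coefficients.
* No trend handling anywhere: baselines are stationary climatologies.
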