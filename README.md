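# mldchl — mixed layer depth vs. surface chlorophyll co-variability

`mldchl` is an analysis pipeline for a classic question in biological
oceanography: in a stratified, oligotrophic basin, how much of the surface
chlorophyll-a signal (CHL, satellite ocean colour, mg/m³) is explained by
vertical mixing, proxied by the mixed layer depth (MLD, hydrodynamic model,
m)? Deeper winter mixed layers entrain nutrients into the lit surface
layer and fuel phytoplankton blooms; the package quantifies that coupling
at seasonal and interannual scales and flags the episodes where it is
strongest.

It is aimed at researchers with gridded daily CHL and MLD fields (CF-style
NetCDF) who want a tested, reproducible implementation of this analysis
chain — and a synthetic-data generator with known ground truth to validate
every stage without downloading archives.

## What it computes

Given daily CHL (gappy) and MLD (gap-free) on a shared grid, a bathymetry
grid and latitude-band sub-regions confined to deep water by an isobath
mask (default 250 m):

1. **Compositing & QC** — CHL pixels > 10 mg/m³ removed, log10 transform,
   per-pixel means over 4-day windows (year-anchored for climatologies,
   season-anchored for the winter analysis: an Oct–Dec season is exactly
   23 composites).
2. **Annual cycle co-variability** — regional climatological cycles;
   relative changes ΔX_rel = (X_{t+1}−X_t)/X_t·100; the percentage of
   composites whose MLD and CHL changes share a sign; conditional mean
   responses; per-season OLS `CHL = a·MLD + b` with R² and an F-test.
3. **Standardised anomalies** — X_anom = (X − mean_month)/std_month per
   pixel; per-pixel Pearson correlation maps with pairwise-complete
   samples, p = 2(1 − F_t(|t|, n−2)) for t = r√(n−2)/√(1−r²), and a
   minimum-pair coverage gate (n ≥ 100 of 253 winter composites);
   regional anomaly series (10% coverage gate), lagged correlations to
   10 composite steps, and per-OND/JFM-season correlations.
4. **Extremes & compound events** — day-of-year percentile climatologies
   (11-day pooling window, 30-day circular smoothing); deep/shallow MLD
   events (90th/10th percentile, ≥ 4 consecutive days) and high/low CHL
   events (≥ 3 days) on regional daily series; the percentage of extreme-
   MLD days with |CHL anomaly| > 0.5; sign-matched temporal overlaps as
   compound events, and event-mean anomaly maps.
5. **Light** — K_d(PAR) from K_d(490), euphotic depth Z_e = ln(100)/K_d(PAR),
   and seasonal Z_e − MLD maps (where mixing outruns the lit layer).

The synthetic generator (`mldchl.synthetic`) produces all inputs with a
known winter-deep/summer-shallow MLD cycle, lognormal CHL coupled to the
standardised MLD anomaly through a coefficient β, AR(1) noise,
satellite-like missingness and injectable multi-day extremes with a
ground-truth ledger. See `docs/methods.md` for the model and assumptions.

## Worked example

The numbered drivers under `analysis/` run the whole study on a generated
demo basin (14–26°N, 0.5° cells, six winters, four injected extremes):

```sh
cd analysis
python 01_simulate.py && python 03_seasonal_cycle.py
```

prints (abridged):

```
2009 days on a 24x16 grid
MLD range 1.0-111.9 m; CHL gaps 27.9% of pixel-days
4 ground-truth extremes -> results/demo_injections.csv
SRS     co-vary  67.8%  cycle r=0.95 (n=91)
        winter: R^2=0.67 slope=0.0106 (p=4.9e-12)
NRS     co-vary  70.0%  cycle r=0.93 (n=91)
        winter: R^2=0.58 slope=0.0019 (p=1.5e-09)
```

Reading this: in the demo's southern region the MLD and CHL climatological
cycles change in the same direction in 67.8% of 4-day steps and correlate
at r = 0.95 over the 91 composites of the mean year; in winter, MLD
explains 67% of the CHL cycle's variance with a positive slope
(0.0106 mg/m³ per metre of deepening). Driver 04 then shows lag-0 anomaly
correlations peaking at lag 0 in every region, and driver 05 recovers both
injected compound events:

```
NCRS     2 deep /  3 shallow MLD,  4 high /  6 low CHL,  2 compounds
injected deep-high event 2005-12-05: recovered
injected shallow-low event 2007-02-08: recovered
```

All tables land in `results/`. The same pipeline is scriptable end-to-end
(`mldchl run-all --config <yaml> --seed 7`) or stage-by-stage (`mldchl
synth | composite | extremes | compound | light`); a run writes a manifest
with SHA-256 checksums, and a repeated run with the same seed reproduces
them bit-for-bit.

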