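# whalemorph

Comparative morphometrics of blue whale populations from drone
photogrammetry, with the oceanographic seasonality of their foraging
grounds — implemented as a tested analysis pipeline over synthetic data
with known ground truth.

Blue whale populations feeding in Monterey Bay (Eastern North Pacific
population), the South Taranaki Bight (New Zealand) and the Corcovado
Gulf (Chile) differ in migratory strategy and prey behavior. Two
questions drive the analysis this package implements:

1. **Do the populations differ morphologically?** Unoccupied-aircraft
   (UAS) images are digitized into total length (TL), skull measures
   (rostrum–blowhole RB, jaw length JL, eye-to-eye EE), tail and fluke
   measures (Tail, fluke span Fs, fluke width Fw), and perpendicular
   body widths at 5% increments of TL. Body condition is the **body
   area index** — dorsal surface area over the 20–90% body range,
   standardized by TL²:

   BAI = 100 · SA(0.2·TL → 0.9·TL) / (0.7·TL)²,

   a scale-invariant, unitless metric. Because photogrammetric
   measurements carry platform-specific error, each platform is
   calibrated from images of known-sized objects under the model
   *measured = true·(1+b) + ε*, ε ~ N(0, σ²), and every whale
   measurement becomes a posterior (mean, variance) rather than a point
   estimate. Populations are compared by a **Monte Carlo ANOVA**: in
   each of 10⁶ replicates every whale's value is drawn from
   N(posterior mean, posterior variance) and a one-way ANOVA is fit;
   group coefficients and pairwise differences are averaged over
   replicates and a 95% highest posterior density interval (HPDI) over
   the replicate distribution decides significance (interval excludes
   0). Scaling of each part with body size is assessed by OLS of
   log(part) on log(TL) — slope 1 is isometry — after a Dixon's Q
   outlier screen.

2. **How seasonal is each foraging ground?** Daily forcing (an
   upwelling transport index, an SST-difference upwelling index, or
   box-averaged zonal wind stress) is accumulated within each *season
   year* (January-start in the Northern Hemisphere, July-start in the
   Southern), averaged into a 10-year climatological cumulative curve,
   and summarized by **accumulation windows**: the 50% window spans the
   25%→75% crossings of the annual total (the 80% window: 10%→90%).
   Short windows mean concentrated, strongly seasonal forcing.
   Productivity is summarized by a monthly chlorophyll-a climatology
   and a salinity–chlorophyll Pearson correlation (freshwater
   influence).

The package is aimed at quantitative ecologists working with
photogrammetric morphometrics or upwelling phenology who want these
procedures as tested, reusable functions rather than one-off scripts.

## Layout

```
src/whalemorph/
  photogrammetry.py   pixels -> meters, BAI, TL-standardization, quality filters
  uncertainty.py      per-platform Bayesian error model, posterior prediction
  inference.py        Monte Carlo ANOVA, HPDI, allometry, Dixon's Q
  ocean.py            season years, cumulative climatology, windows, correlations
  synth.py            ground-truth generators (whales, UAS error, forcing)
  pipeline.py         end-to-end orchestration + run manifests
analysis/             numbered narrative drivers (01 simulate ... 04 ocean)
tests/                pytest suite including end-to-end acceptance checks
scripts/acceptance.py recomputes the headline quantities from scratch
```

## Worked example

Generate the synthetic study (63 whales in three populations with a
known body-condition gap, one UAS platform with a 2% bias and 5 cm
scatter, 200 calibration objects), then run the comparison:

```
python analysis/01_simulate_data.py
python analysis/02_morphometrics.py
```

prints, among other lines,

```
platform P4S: bias b = +0.0199 (sd 0.0009), scatter sigma = 0.045 m (edge mass 1.65e-10)
Chile: n = 15, mean TL = 22.34 m
ENP: n = 31, mean TL = 22.68 m
NZ: n = 17, mean TL = 22.13 m
```

— the calibration recovered the simulated 2% platform bias, and the
corrected mean total lengths sit near the generative ~22 m. Then

```
python analysis/03_population_comparison.py
```

prints the Table-1-shaped contrast table; e.g. the body-condition row

```
measurement      pair  difference  hpdi_low  hpdi_high significant
        BAI    ENP-NZ      -0.963    -1.014     -0.912           *
```

reads: the ENP group's body area index averaged 0.96 below New
Zealand's (95% HPDI −1.01 to −0.91, excluding 0, hence starred) — the
pipeline recovers the simulated NZ-higher body-condition gap from
biased, noisy pixel measurements. Finally

```
python analysis/04_ocean_seasonality.py
```

```
  MontereyBay  50% window:   72.2 days (day 145.2 -> 217.4)
  STB          50% window:  173.9 days (day 96.3 -> 270.3)
  Corcovado    50% window:  176.7 days (day 94.9 -> 271.6)
seasonality ranking (shortest 50% window first): MontereyBay < STB < Corcovado
Corcovado SSS vs Chl-a: Pearson r = -0.70 (p = 2.44e-218)
```

— the strongly seasonal region (concentration κ = 3) gets a short 50%
accumulation window, the weakly seasonal regions get windows near the
182.5-day constant-forcing limit, and the simulated freshwater–
productivity coupling appears as a negative salinity–chlorophyll
correlation.

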