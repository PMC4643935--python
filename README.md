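# meadowtherm

Stream-temperature analysis for high-elevation meadow streams under
livestock grazing and climate warming.

Cold headwater streams of the southern Sierra Nevada are the last habitat
of the California golden trout (*Oncorhynchus mykiss aguabonita*). Cattle
strip the willow (*Salix spp.*) cover that shades these channels, and the
exposed water warms as it travels through grazed reaches. `meadowtherm`
implements the full analysis chain used to quantify that effect and to ask
what it means under climate warming:

1. **Logger QC** — whole-day removal of out-of-water records, restriction
   to the eight warmest weeks of the year (ISO weeks 24–31);
2. **Thermal metrics** — per probe, the daily minimum/mean/maximum
   (DminT/DavgT/DmaxT); their centred 7-day moving *medians*
   (WminT/WavgT/WmaxT), robust to single aberrant days; and the season
   maxima MWavgT and MWmaxT, the standard proxies for chronic and acute
   thermal exposure;
3. **Autocorrelation-aware comparisons** — Moran's *I* (inverse-distance
   weights, randomization null E[*I*] = −1/(n−1)) as a residual
   diagnostic; per-reach OLS of MWmaxT on downstream distance; and linear
   mixed models `metric ~ meadow + (1 | month) [+ (1 | probe)]` with
   Satterthwaite degrees of freedom for the among-meadow contrasts at
   week/month/year aggregation scales;
4. **Climate projection** — a mixed model `DmaxT ~ WavgT + (1 | date)` per
   meadow; air-warming scenarios (0 / 1 / 3.7 / 5.6 °C) scaled to water by
   a conservative 0.5 ratio and pushed through the fitted line, with
   50/95/99 % normal prediction bands read as 2-, 20- and 100-year
   recurrence temperatures.

No logger data were ever deposited for this system, so the package ships a
first-class synthetic generator (`meadowtherm.synthetic`) that emulates
the study design: three meadows (two rested, one split by a livestock
exclosure), 13–30 probes per reach sampled every 30 min, a diel sinusoid
whose amplitude depends on solar exposure (sunny ≥ 98 %), a downstream
warming gradient (+0.41 °C/100 m) where cattle graze and cooling
(−0.25 °C/100 m) through the exclosure, AR(1) logger noise with
exponentially distance-decaying cross-probe correlation, regional weekly
weather, and out-of-water artifacts.

## Worked example

Run the numbered analysis scripts from the repository root:

```bash
python analysis/01_simulate.py   # probe network + logger files + willows
python analysis/02_qc.py         # out-of-water removal, summer window
python analysis/03_metrics.py    # daily / weekly / season-maxima tables
python analysis/04_compare.py    # vegetation, gradients, meadow contrasts
python analysis/05_project.py    # warming-scenario projection table
```

`03_metrics.py` prints the per-reach summary of the weekly metrics
(mean ± sd over probe-days):

```
  BigWhitney:ungrazed  WavgT  10.7 +- 1.6  WmaxT  16.6 +- 2.5
  Mulkey:grazed        WavgT  13.4 +- 1.7  WmaxT  19.5 +- 3.0
  Mulkey:ungrazed      WavgT  13.0 +- 1.5  WmaxT  18.3 +- 2.7
  Ramshaw:ungrazed     WavgT  11.7 +- 1.5  WmaxT  16.2 +- 2.4
```

— the partially grazed meadow is the warm one despite its intermediate
elevation. `04_compare.py` prints the downstream gradients of the season
maximum:

```
  Mulkey:grazed        +0.58 +- 0.12 (t = 4.86, p = 0.000)*
  Mulkey:ungrazed      -0.25 +- 0.11 (t = -2.39, p = 0.036)*
```

water warms along the grazed section and cools again inside the
exclosure, while the rested meadows stay essentially flat. `05_project.py`
fits the max-vs-avg response (slope 1.74 °C/°C in the grazed meadow,
steeper than in either rested meadow — warming is amplified where cattle
graze) and prints the scenario table, e.g. for the pessimistic scenario
(+3.7 °C air, +1.8 °C water):

```
scenario     meadow       WavgT  shift  DmaxT     50% (2 yr)    95% (20 yr)
pessimistic  Mulkey        13.2   15.0   22.1    [21.5:22.7]    [20.3:23.9]
```

i.e. an expected daily maximum of 22.1 °C, with 23.9 °C expected once
every twenty years in the warmest parts of the river. All tables land in
`results/` as CSV.

The same pipeline is scriptable through a single CLI
(`meadowtherm simulate|qc|metrics|compare|project|run --config cfg.yaml
--out results --seed 1`).

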