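# mullet-telemetry

Seasonal coastal residency, space use, and regional connectivity analysis
for acoustic-telemetry detections of two sympatric grey mullet species
(thicklip *Chelon labrosus* and thinlip *C. ramada*) in a shallow tidal
sea, built as a tested, reusable pipeline with a ground-truthed synthetic
detection simulator in place of archived field data.

Passive acoustic telemetry logs every decoded transmitter ping as a
(tag, receiver station, timestamp) record. Before any ecology can be read
off such data, false records must go: detections logged before a tag was
deployed, exact duplicates, records closer together than the tag's minimum
transmission delay, lone detections with no companion at the same station
within 24 h, and everything from fish that died with the tag still
transmitting. On the filtered data the package computes, per fish and
year:

* **arrival / departure** — first and last detection in the focal region;
* **residence duration** — inclusive day count between them;
* **residency index** `RI = N detection days / residence duration ∈ (0, 1]`;
* **local residency index** `RI_stat = N days at a station / N days in the
  array` (a station's share of a fish-year's detection days);
* **station counts** and **minimum convex polygons** over the stations
  used, optionally clipped to remove overlap with land (areas in km²);
* **cross-region movement events** (outbound / inbound relative to the
  focal sea) aggregated into weighted origin–destination edges, plus
  weekly and monthly distinct-fish presence summaries;
* **Kruskal–Wallis rank-sum tests** (tie-corrected, χ² reference with
  k−1 df) and **Dunn post-hoc comparisons with Bonferroni adjustment**
  for species and year contrasts.

Timing, duration, and RI statistics use only *return years* (years after
tagging) and fish-years detected > 5 days; minimum convex polygons
additionally require ≥ 3 stations; receivers damaged or deployed < 90
days are excluded from occurrence and per-station summaries.

The synthetic generator (`mullet_telemetry.simulate`) emulates the study
design — 90 focal-sea stations plus offshore blocks and one freshwater
receiver, two species differing in arrival timing (day-of-year medians
158 vs 135), mobility, site fidelity and freshwater affinity, a
two-point logistic detection-range model (p = 0.5 at 149 m, 0.05 at
610 m), uniform 60–120 s transmission delays, mortality, and labelled
noise (echo duplicates, sub-delay ghosts, isolated false positives) — so
every filtering and recovery claim is verified against known truth.
See `docs/methods.md` for the full model description and conventions.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data, writing tables under `results/`:

```bash
python analysis/01_simulate.py --seed 1   # detections, deployments, stations, truth
python analysis/02_filter.py              # filter cascade + audit report
python analysis/03_residency.py           # arrival/departure/duration/RI
python analysis/04_space_use.py           # station counts, MCPs, RI_stat medians
python analysis/05_connectivity.py        # movement events, presence summaries
python analysis/06_stats.py               # Kruskal-Wallis / Dunn comparisons
```

With seed 1 the filter stage prints

```
filter cascade: 532531 -> 487445 records (45086 removed)
  predeployment        examined    532531  removed      13
  duplicates           examined    532518  removed      50
  min_delay            examined    532468  removed      50
  singletons_24h       examined    532418  removed      37
  mortality            examined    532381  removed   44936
  cross-station simultaneities retained: 4516
ghost/false-positive keys surviving the cascade: 0 of 100
```

— all 150 injected noise records fall to the rule that targets them (the
50 false positives split between the pre-deployment and singleton rules),
the 4,516 simultaneous receptions by overlapping receivers are retained
as physically valid, and the mortality rule drops the nine dead fish.
The residency stage then reports, for return-year fish-years detected
more than 5 days:

```
  thicklip  arrival_doy    median  160.00  IQR 145.50-183.50
  thinlip   arrival_doy    median  134.00  IQR 133.00-137.00
  thicklip  ri             median    0.37  IQR 0.35-0.42
  thinlip   ri             median    0.55  IQR 0.52-0.61
```

recovering the configured 23-day arrival contrast (160 − 134 = 26 at this
small n = 11 + 4) and the configured residency-index ordering, which the
stats stage confirms (`ri by species: H = 8.25, df = 1, p = 0.0041`)
while departure timing and duration show no species difference — the
same qualitative pattern the analysis is designed to resolve.

The one-call equivalent lives in `mullet_telemetry.pipeline`:

```python
import mullet_telemetry as mt
from mullet_telemetry import pipeline

cfg = mt.PipelineConfig(simulation=mt.SimulationConfig(seed=1),
                        seed=1, output_dir="results/run1")
bundle = pipeline.run(cfg)      # 9 artefacts + manifest, byte-reproducible
print(pipeline.report(bundle))  # per-array and per-species summary blocks
```

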