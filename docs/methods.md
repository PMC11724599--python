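# Methods

`mullet_telemetry` implements an acoustic-telemetry analysis of seasonal
coastal residency for two sympatric grey mullet species (thicklip,
*Chelon labrosus*, and thinlip, *C. ramada*) in a shallow tidal sea
monitored by a large receiver grid, together with a ground-truthed
synthetic detection generator that stands in for archived field data.
This note documents the models, the conventions behind every threshold,
and what the synthetic experiments do and do not demonstrate.

## Data model

Three delimited-text tables drive everything:

* **detections** — one row per decoded transmission: `tag_id`,
  `station_id`, UTC `timestamp` (second resolution). The triple is the
  identity used for duplicate detection.
* **tag deployments** — fish/tag metadata, including the tag's minimum and
  maximum transmission delay (seconds) and the release instant.
* **station deployments** — receiver position (projected planar metres),
  array name, one of three closed region labels (`wadden_sea`,
  `north_sea`, `fresh_water`), an active interval, and a damage flag. A
  station may appear once per deployment interval.

Timestamps are UTC throughout and a "detection day" is the UTC calendar
date. No timezone is inherent to the problem; UTC avoids daylight-saving
ambiguity at the cost of at most a one-hour shift at day boundaries.
Coordinates must arrive already projected; any equal-area local projection
is a caller responsibility (the generator emits metres natively, so no CRS
machinery is included). Land masks are well-known-text polygons.

## False-detection filtering

Five rules run in a fixed order; each reports examined/removed counts and
the counts reconcile exactly with input minus output:

1. **Pre-deployment** — drop records timestamped strictly before the
   matching tag's release ("prior to" is read strictly, so a record at
   exactly the release instant is retained).
2. **Duplicates** — keep exactly one of identical
   (tag, station, timestamp) records. Identical (tag, timestamp) records
   at *different* stations are physically valid (overlapping receiver
   ranges) and are retained but counted as cross-station simultaneities.
3. **Minimum delay** — per (tag, station), scanning chronologically, a
   record is dropped when its gap to the previously *retained* record is
   positive and shorter than the tag's minimum transmission delay. The
   later record of a violating pair falls; a run of spurious records
   cannot shield itself because comparison is always against the last
   survivor. Duplicates must run first so a gap of zero never consumes
   this scan.
4. **24-hour singletons** — a record with no companion at the same
   (tag, station) within ±24 h is unreliable and dropped. Evaluation is
   simultaneous on the rule's input: two records 25 h apart, with nothing
   else, are *both* dropped. A window (rather than calendar-day) reading
   avoids midnight artefacts; a companion at exactly 24 h rescues.
   Detections at *other* stations do not rescue a lone record — the rule
   is station-local by definition.
5. **Mortality** — all records of fish listed in a mortality table are
   dropped (default), or only records after the death time when one is
   given. Mortality identification is input-driven; a convenience
   heuristic flags fish with ≥ 14 consecutive single-station detection
   days (the signature of a tag transmitting from a fixed position), but
   it is advisory and not part of the cascade.

The cascade is idempotent, never adds records, and — by construction of
the noise model below — removes injected noise exactly, while the only
true records lost are genuine 24-hour singletons.

Station reliability is a separate, per-analysis exclusion: receivers that
were damaged or deployed < 90 days (half a standard 6-month deployment;
strictly less, so 90 days is retained) are excluded from occurrence and
per-station summaries but not from arrival/departure timing. A calendar
year can likewise be excluded from statistical tests while remaining in
data summaries (mirroring a final study year with a single detected fish).

## Residency metrics

Per fish and calendar year in the focal region:

* **arrival / departure** — first and last detection instants;
* **residence duration** — inclusive day count,
  `(date(departure) − date(arrival)) + 1`. The inclusive convention
  bounds the residency index at 1 (an exclusive difference would let a
  fish detected every day exceed 1) and changes ~90–100-day durations
  negligibly;
* **RI** = distinct detection dates / duration, in (0, 1];
* **RI_stat** per station = days detected at that station / days detected
  in the whole array. Per fish-year, Σ RI_stat ≥ 1, with equality exactly
  when no date has detections at more than one station;
* **station count** — distinct stations with ≥ 1 retained detection.

Timing, duration, and RI statistics use only *return years* (calendar
years after tagging, so arrival is not confounded by capture date) and
fish-years with duration strictly greater than 5 days (screening out
partial residence seen only while entering or leaving the array). All
fish-years feed occurrence summaries. Day-of-year is 1-based (Jan 1 = 1);
printed DOY/date pairs in the source tables are internally inconsistent by
one day in some rows, and this package standardises on the DOY values.

## Space use

The minimum convex polygon per fish-year is the convex hull of the
*stations used* (≥ 1 retained detection), not of raw positions; the 100%
hull is taken (no percentile peeling). Eligibility requires duration
> 5 days and ≥ 3 stations; collinear station sets yield area 0 with a
degenerate flag and are excluded from species comparisons. Areas are
planar (shoelace) in km²; an optional land mask is subtracted by polygon
difference. MCPs over receiver positions are a deliberately coarse,
array-design-dependent proxy — they assume full use of the hull interior.

## Connectivity

A movement event is an adjacent pair of detections of one fish whose
stations lie in different regions: origin is the last detection in the
previous region, destination the first in the new one. No speed,
displacement, or elapsed-time gate is applied — none is defined for this
kind of summary. Direction is classified relative to the focal region
(outbound / inbound / external). Events aggregate into weighted
origin–destination edges whose weights sum to the event count; because it
is ambiguous whether a "recorded movement" counts station-to-station or
station-to-region transitions, both aggregations are exposed. Presence
summaries count distinct fish per region and ISO-8601 week or calendar
month; a fish visiting two regions in one period counts once in each, and
monthly counts can be normalised per species within each month.

## Rank-based comparisons

Group comparisons use the tie-corrected Kruskal–Wallis statistic

    H = [12/(N(N+1)) Σᵢ Rᵢ²/nᵢ − 3(N+1)] / C,
    C = 1 − Σₜ(t³−t)/(N³−N),

against the χ² distribution with k−1 degrees of freedom at all sample
sizes (the standard practice behind "(χ², df, p)" reporting; no exact
small-sample tables). When every pooled value is tied, C vanishes and H
is defined as 0 ("no evidence against the null") rather than undefined.
Dunn's post hoc z uses mean ranks with the tie-corrected variance and
two-sided normal p-values (sidedness is not dictated by the analysis;
two-sided is the conservative default), Bonferroni-adjusted by k(k−1)/2.
The post hoc runs only after a significant omnibus test with more than
two groups. Implementation is from the closed forms above; tests
cross-check H and p against `scipy.stats.kruskal` and a hand-worked
nine-value fixture for Dunn.

## Synthetic generator

The generator is first-class, tested code. It emulates the study design:

* **Array** — 90 stations (within the study's 81–100 band) on a jittered
  grid over ~55 × 25 km, including three sub-kilometre "harbour pairs"
  whose detection ranges overlap (producing genuine cross-station
  simultaneities and multi-station days); ~5% damaged and ~5%
  short-deployed stations exercise the exclusion rule; 21 offshore
  stations in three blocks 90–250 km away; exactly one freshwater
  receiver behind the sluice barrier.
* **Range model** — per-transmission detection probability is a logistic
  in distance fixed by two anchors: p = 0.5 at the midpoint range
  (149 m, the study's high-power midpoint) and p = 0.05 at the maximum
  range (610 m), zero beyond it (maximum range read as where detections
  cease). The two anchors fully determine the curve; at distance 0 it
  gives p ≈ 0.72 per transmission, which with hundreds of transmissions
  per day saturates daily detection near a station.
* **Movement** — a daily centre-of-activity model. Within the residence
  window a fish stays near its anchor station (within 140 m, i.e. inside
  detection range) with per-day probability `station_fidelity`, else
  roams with a Gaussian step (`mobility_step_m`), re-anchoring when the
  roam lands within maximum range of a station. Detectability near a
  station is confined to a daily window (default 4 h) as a crude
  stand-in for tidal accessibility, keeping per-day detection counts at
  a realistic scale. Outside the window the fish is offshore and passes
  an offshore receiver with a small per-day probability (0.01); thinlip
  fish additionally make freshwater forays (p = 0.02 per residence day).
* **Timing** — arrival/departure days-of-year are truncated-normal draws
  per species and year. Medians follow the printed study medians
  (arrival 158 vs 135, departure 259 vs 233) and spreads derive from the
  printed IQRs (spread = IQR/1.349), giving the thicklip a much wider
  arrival window (sd ≈ 30 d) than the thinlip (sd ≈ 5 d).
* **Tags** — transmission gaps uniform in [60, 120] s by default (tag
  spec sheets are configuration, never hard-coded), timestamps floored
  to the second; flooring preserves the minimum-delay guarantee because
  ⌊t+g⌋ − ⌊t⌋ ≥ ⌊g⌋.
* **Demography** — 60% of fish are tagged in year 1 and the rest in
  year 2; a fish present one season returns the next with per-species
  probability (0.16 / 0.50, matching the study's return-year sample
  structure of 12 + 6 at its tagged 106 + 16); 7.4% of fish die during
  their first season (9 of 122 in the study), after which the tag emits
  from a fixed position for 60 days — the signature the mortality
  heuristic looks for.
* **Noise** — exact echo duplicates of true records, sub-delay ghosts
  placed 1…(min_delay−1) s after a true record at the same station, and
  isolated false positives guaranteed to have no companion within 24 h
  at their (tag, station). Each synthetic record carries exactly one
  truth label. Placement rules make filter recovery exact, so the
  recovery tests are sharp rather than statistical.

Identical configurations (including the seed) give bit-identical outputs.

### Deliberate departures from field realism

The two species are parameter sets, not code paths. Several quantities
are *not* calibrated to the study and are documented as synthetic
choices: station fidelities (0.30 / 0.50) produce residency indices
around 0.3–0.5 rather than the study's 0.040 / 0.186. Reproducing
RI ≈ 0.04 would require a daily detection probability so low that
first-detection arrival estimates would lag true arrival by weeks,
breaking the package's own contract that median arrival bias stays
within a few days at default detectability; the preserved, tested
property is the *ordering* (thinlip RI > thicklip RI), which is what the
species comparison consumes. Likewise there is no tidal forcing, no
depth, no behaviourally realistic turning kernel, and movement below the
daily scale is not modelled (the analysis consumes detection days, so
sub-daily realism buys nothing). Passing tests therefore show that the
analysis chain is correct and recovers known contrasts under this
generative model — not that the model reproduces every marginal of the
field data.

## Experiment and test problem sizes

Problem sizes are chosen to keep each synthetic experiment sharp at desk
scale: filter-vs-oracle equivalence on 200 random collision-heavy tables
of up to 2,000 records; noise recovery over 50 seeded runs of 30 labelled
noise records each; residency algebra on a 500-fish cohort; hull geometry
on 1,000 random point sets against a monotone-chain + shoelace oracle
(10⁻⁹ relative) and land clipping against 10⁶-sample ray-casting
Monte-Carlo estimates (within 1%, ~3 sampling σ of margin); null
calibration of the Kruskal–Wallis p-value over 5,000 replicates (three
groups of 10; Kolmogorov distance < 0.05); arrival-difference recovery at
200 fish per species over three study years (all tagged in year 1, so
every fish contributes return years; the configured 23-day contrast is
recovered within ±5 days); and RI-ordering power over 200 replicates at
the return-year sample sizes 12 + 6 (≥ 80% of replicates must order the
species correctly with KW p < 0.05).

## Known limitations

* Residence is a single first-to-last window per year; no gap-based
  splitting into multiple residence events, and no state-space or
  hidden-Markov residency model.
* MCP is the only space-use estimator (no kernel densities or Brownian
  bridges) and inherits the array's geometry.
* The false-detection filters are rule-based; no probabilistic
  (speed/distance plausibility) scoring, and no receiver clock-drift
  correction.
* The singleton rule is station-local; detections at neighbouring
  stations do not rescue a lone record. This is one defensible reading
  of "single detections at one receiver station within 24 h"; the
  alternative (array-wide rescue) would retain slightly more records.
* Whether the duplicate rule should also collapse cross-station
  simultaneities is ambiguous; they are retained and reported so either
  convention can be audited.
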