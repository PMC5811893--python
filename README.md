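# radarwatch

Analysis pipeline for bird-borne radar-detector (XGPS) tracks: detect marine
vessels from the radar emissions a flying seabird's logger picks up, classify
each bird–vessel encounter, match it to declared VMS vessel positions, and
summarize interaction patterns — including detections with *no* declared
vessel, the signature of unreported fishing.

It is written for movement ecologists and fishery-interaction researchers
working with combined GPS + X-band radar-detector loggers on wide-ranging
seabirds (the motivating system is wandering albatrosses foraging from a
sub-Antarctic colony among long-line fishing vessels), and it ships a full
synthetic study generator so every stage is testable without field data.

## The method

The logger integrates 9.41 GHz radar bursts into a power-indicator voltage
and counts, every 100 ms, how often that voltage exceeds four references
(1.65, 0.825, 0.412, 0.206 V), giving per-interval comparator counts
C3 ≤ C2 ≤ C1 ≤ C0. The radar-level power index is

    index = √(8·C3 + 4·C2 + 2·C1 + C0)

and a GPS fix with index > 0 is a radar detection. The pipeline then:

1. **segments** detections into contact events (gaps ≤ 15 min),
2. **classifies** each event from track kinematics —
   *fly past* (1–5 detections, straight route), *follow* (sustained linear
   flight behind a steaming vessel), *attend* (sit/fly alternation at a
   fishing vessel),
3. **matches** detections to hourly VMS positions (linear interpolation,
   nearest vessel within 6 km; otherwise *undeclared*),
4. **summarizes**: per-trip contact fractions, a per-behavior table
   (mean/range duration, frequency, % of time in contact), sex comparisons
   (Yates-corrected χ², one-way ANOVA), and GeoJSON/KML track export.

## Worked example

Run the whole chain on a synthetic deployment (43 birds, 7 vessels, 72-h
trips) and print the behavior table:

```sh
radarwatch run-all --seed 5 --out demo/
```

```
Behavior      Mean (h)         Range (h)  Freq (%)  Contact (%)
---------------------------------------------------------------
FLY_PAST          0.10         0.00-0.20      17.2          0.1
FOLLOW            1.90         0.10-7.33       8.6          0.5
ATTEND            2.83        0.00-18.93      74.2          6.7
{"pct_loggers_with_contact": 93.0233}
```

Reading it: attendance dominates — 74 % of classified encounter events, and
6.7 % of all trip time is spent in radar contact while attending vessels;
fly-pasts are frequent but contribute almost no contact time; 93 % of the
simulated loggers recorded at least one vessel contact. `demo/` now holds
per-bird trip CSVs (logger dialect), `vms.csv`, ground-truth episodes
(`truth.csv`), classified `events.csv`, per-detection `matched.csv` with the
distance–intensity table, `report.json`, and `tracks.geojson` for map
inspection.

The same stages are available as a library:

```python
from radarwatch import SimConfig, simulate_study, detect_and_classify

study = simulate_study(SimConfig(seed=5))
events = detect_and_classify(study.trips[0])
```

and as separate CLI stages (`simulate`, `detect`, `classify`, `match`,
`summarize`) for real logger/VMS CSV files.

## Layout

```
src/radarwatch/
  geo.py        geodesic primitives, track kinematics, interpolation
  radar.py      comparator counting, power index, logger CSV dialects
  simulate.py   synthetic vessels, bird trips, VMS, radar reception
  encounter.py  contact segmentation and behavior classification
  vms.py        VMS matching, distance-intensity table, attribution
  report.py     trip/population summaries, statistics, GeoJSON/KML
  evaluate.py   scoring against simulator ground truth
  pipeline.py   run-all chain with deterministic outputs
  cli.py        command-line interface
docs/methods.md   model descriptions, parameter rationale, limitations
```
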