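# Methods

`radarwatch` analyses tracks from bird-borne GPS loggers that carry an X-band
(9.41 GHz) radar detector — devices deployed on wide-ranging seabirds such as
wandering albatrosses to reveal when and where the birds interact with marine
vessels, including vessels that report no position (the illegal-fishing
signature). This note records the models, parameter choices, numerical
decisions, and the limits of what the synthetic validation shows.

## Detector model

The logger converts radar bursts into a power-indicator voltage (0–3.3 V).
Rather than digitising it, the firmware compares the signal every
`sample_period` (default 0.1 s) against four reference voltages, each half
the previous: 1.65, 0.825, 0.412, 0.206 V. A sample strictly above a
reference increments that comparator's counter, so the counts nest
(c3 ≤ c2 ≤ c1 ≤ c0). The per-interval radar-level power index is

    index = √(8·C3 + 4·C2 + 2·C1 + C0),

a quantised integral of received power over the logging interval (60, 120 or
300 s). A fix is a *detection* when its index is positive (C0 ≥ 1). We apply
no debouncing at this layer; run-level filtering belongs to the encounter
segmentation. Cumulative comparator semantics (a strong sample increments all
four counters) are the only reading under which the 8:4:2:1 weights behave as
a power integral; exclusive bands would make the weights incoherent. The
sampling cadence is configurable because deployed firmware revisions may
differ; 0.1 s is the default.

## Encounter segmentation and classification

Detections are segmented into contact events wherever consecutive detections
are no more than `max_gap` apart (default 15 min — three times the coarsest
5-min logging interval: long enough to bridge reception dropout, short enough
not to merge distinct encounters). Each event is classified from track
kinematics over the event window:

1. **Fly past** — 1–5 detections, straightness ≥ 0.90, sitting fraction
   < 0.10: the bird passes a vessel without deviating.
2. **Follow** — straightness ≥ 0.80, sitting fraction < 0.20, mean speed at
   or above the flight threshold: sustained linear flight tracking a
   steaming vessel.
3. **Attend** — everything else: the area-restricted-search signature of a
   bird alternating sitting on the water with short flights at a (typically
   fishing) vessel. Events with neither sit/fly alternation nor a bounding
   radius ≤ 10 km are still attendance, flagged low-confidence.

Rules apply in order, so an event satisfying both 1 and 2 is a fly past (the
fly-past definition subsumes very short follows). The flight/sit speed
threshold is 10 km/h: drift on water is < 5 km/h, flight is typically
> 30 km/h, and 10 km/h bisects the strongly bimodal speed distribution. The
straightness cutoffs operationalise the qualitative field notions of "no
significant change in route" and "linear movement"; all thresholds live in
`EncounterConfig` and are never hard-coded elsewhere. Windows with fewer than
three fixes are padded by one neighbouring fix on each side so that the
kinematics of single-detection events are defined rather than fabricated.

## VMS matching

VMS (vessel monitoring system) reports arrive hourly; detections every
1–5 min. For each detection, every vessel whose pings bracket the detection
time within 90 min (one missed ping tolerated, never extrapolated) is
linearly interpolated to the detection time; the nearest vessel within the
match radius is assigned, ties broken by lexicographic vessel id. The default
radius is 6 km: reception tops out near 5.5 km and the extra 0.5 km absorbs
interpolation error of hourly pings (≤ 0.1 km for a straight steaming course
at ≤ 22 km/h; larger for tortuous fishing tracks, which is measured on the
simulation rather than assumed). Detections with no vessel inside the radius
are *undeclared* — the quantity of interest for unreported fishing. An event
is attributed to the modal matched vessel among its detections when that
vessel accounts for at least half of the matched ones.

## Geodesy

All distances are haversine great-circle kilometres on a sphere of mean
radius 6371.0088 km. Every distance that matters here (≤ 6 km matching,
trip ranges of 10²–10³ km) tolerates the < 0.5 % sphere-vs-ellipsoid error,
and the closed forms (meridian arc, antipodal distance) make the primitive
directly testable. Speeds are assigned to the end fix of each segment; the
heading of a zero-length segment is NaN, not fabricated. Interpolation
unwraps longitudes first, so antimeridian crossings interpolate the short
way.

## Synthetic study generator

No field data ship with the package, so every downstream stage is validated
against a simulator whose defaults emulate the study conditions the pipeline
is designed for: a colony at 46.4°S 51.8°E, 43 birds, GPS fixes every 2 min,
72-h trips, 7 licensed long-liners reporting hourly VMS, and trip-level
contact statistics in the range reported for this system (mean contact
fraction a few percent of trip time, most loggers recording at least one
vessel contact).

**Vessels** alternate FISHING bouts (2–5 km/h, heading s.d. 40°/step,
4–30 h) with STEAMING bouts (15–22 km/h, one near-straight course per bout,
2–16 h), each confined to a home ground 150–550 km from the colony; homes
are spread in azimuth so operating areas never overlap and vessel
attribution has an unambiguous answer.

**Birds** move by a mode-switching correlated random walk — fast, nearly
straight transit (65 ± 8 km/h); slow tortuous area-restricted search with
sit/fly alternation; drifting sits (0.3–1.5 km/h) — interleaved with
scripted vessel encounters drawn from a configured mix of the three
behaviors. Episode durations are log-uniform within the ranges observed for
each behavior (follow 0.20–15.50 h, attend 0.06–24.90 h), capped at the
target vessel's remaining steaming/fishing bout so the signature stays
coherent; fly-past duration follows from the pass geometry (a straight run
at 80–95 km/h, 2.2–3.5 km abeam of a fishing vessel), consistent with the
0.01–0.03 h scale reported for that behavior. A drawn class is sticky: if no
vessel can host it yet, the bird forages and retries, so the realized mix
tracks the configured one. Follows and attends are approached via a staging
point 18 km astern of the vessel's upcoming course, with any slack waited
out on the water; the final, detectable approach leg is therefore aligned
with the episode and does not corrupt the event's straightness.

Two construction rules keep the ground-truth labels clean: natural foraging
is only sited, and only continues, outside the 30-km vessel attraction
radius; and transit legs skirt all radar-emitting vessels at 15 km except
the episode's own target. Both have behavioral readings (birds that engage
do so deliberately; the attraction radius is the distance from which this
species is known to divert toward vessels), but their purpose in the
generator is to prevent unlabeled vessel contact from contaminating recovery
tests. Every scripted episode emits an `EncounterTruth` record.

**Radar reception.** The noise-free median peak voltage follows
v(d) = 0.206 V · (5.5 km / d)^γ, clipped to [0, 3.3 V]. The exponent
γ = ln(1.65/0.206)/ln(11) ≈ 0.867 is fixed by the two calibration points the
reception structure implies — the lowest comparator threshold is crossed at
5.5 km (the outermost observed detections) and the highest near 0.5 km
(strong signals only at close range). A free-space exponent of 2 cannot pass
through both points; the compressive exponent is consistent with a Schottky
peak detector driven beyond its square-law region. On top of the median
curve: lognormal shadowing (σ = 0.3 log-volts) and a per-interval dropout of
0.005 emulating antenna-orientation loss. The dropout is deliberately small:
the design requirement that a vessel within 2 km is detected in ≥ 99 % of
intervals caps the admissible dropout at ~0.005 once shadowing is accounted
for. Within an integration interval the voltage is modulated by a
deterministic rotating-beam envelope (Gaussian azimuthal mainlobe, σ = 20°,
rotation period 2.37 s, incommensurate with the 0.1-s sampling), which makes
the comparator counts a smooth, strictly monotone function of the peak
voltage — with a constant within-interval voltage the counts would be a step
function of distance and the distance–intensity table could not decrease
strictly across bins.

**Determinism.** One master seed; every vessel, bird, radar-noise stream and
truncation decision uses an independent named substream
(`SeedSequence(seed, spawn_key=...)`), so outputs are identical across runs
and platforms, and the end-to-end pipeline writes byte-identical CSV/JSON
under a fixed seed.

**Validation scales.** The label-recovery and calibration checks run on a
160-bird, 6-vessel, 72-h deployment with a balanced episode mix (≥ 200
scripted episodes per class, ≥ 10⁴ detection intervals), which completes in
well under a minute; the reporting checks run on the default 43-bird
configuration.

## Reporting

Per-trip contact time is the union of event intervals (two vessels attended
simultaneously must not double count). Incomplete trips (truncated by logger
failure; default incidence 0.16) are summarized but excluded from
population means of per-trip contact fractions. In the behavior table,
frequencies are percentages of classified events (they sum to 100), and
per-class time-in-contact is the class's contact time as a percentage of
total trip time — the rows therefore sum to the overall contact fraction,
not to 100.

The sex comparison uses the Yates-corrected chi-square on the attended-vs-not
2×2 table, with the correction floored: a table whose |O − E| < 0.5 scores
exactly 0 (scipy's implementation shifts rather than floors, so it is used as
a cross-check only where the two agree). The per-bird metric comparison is a
one-way ANOVA delegated to `scipy.stats.f_oneway`. p-values are reported for
convenience; the statistics are the stable surface.

## What the synthetic validation does and does not show

The simulator realizes the three encounter signatures cleanly, with
separation the field data may not offer: real birds mix behaviors within an
encounter, follow vessels they later attend, and forage naturally near
vessels. Perfect or near-perfect recovery on synthetic episodes therefore
demonstrates that the pipeline's rules are mutually consistent and correctly
implemented — not that the classifier would reach the same accuracy on field
data. Wind, diel rhythm, sea state, antenna shadowing by the bird's body,
and fishery spatial effort structure are all unmodeled. The reception model
is a scalar proxy; no antenna gain pattern or RF propagation physics is
simulated.

## Known limitations

* Behavior classes are mutually exclusive per event; a follow that decays
  into attendance is classified by its aggregate features.
* Hourly VMS interpolation of a tortuous fishing track can err by ~1–2 km;
  the 6-km match radius absorbs this, but a vessel manoeuvring hard near the
  radius boundary could be missed.
* The undeclared-vessel flag is only as good as the VMS feed: a declared
  vessel with a broken transponder is indistinguishable from an illegal one.
* Trips are simulated at fixed cadence with no GPS gaps; the pipeline
  accepts irregular fixes, but recovery statistics were not measured under
  heavy gap structure.
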