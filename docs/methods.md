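# Methods

This note documents the models and procedures implemented in `kitetrails`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the validation does and does not demonstrate.

## Coordinate frame and velocity features

All analysis happens in a bird-specific Cartesian frame: a **spherical
Lambert azimuthal equal-area projection** tangent at the nest (the
chronologically first fix, since tags are fitted to chicks in the nest),
rescaled to kilometres using the authalic Earth radius 6371.0072 km. The
equal-area property is what matters — home-range areas measured by the
planar shoelace formula in this frame agree with spherical areas to well
under 0.5 % out to several hundred kilometres (the test suite checks both
the area distortion of a geodesic quadrilateral ~200 km out and the
geodesic re-measurement of actual isopleth polygons). A spherical rather
than ellipsoidal figure costs <0.1 % at these scales; the projection
routines are isolated in `geometry.py` so an ellipsoidal backend could be
substituted without touching any caller.

Each fix then gets polar coordinates: r (km from nest) and θ (degrees
counter-clockwise from east, in (−180°, 180°]; θ at the exact origin is 0
by convention — it can never influence classification because r = 0 lies
deep inside the nest buffer). Velocities are **backward differences as
recorded**, with no interpolation:

* v_r[n] = (r_n − r_{n−1}) / (t_n − t_{n−1}), km/h;
* v_θ[n] = wrap(θ_n − θ_{n−1}) / (t_n − t_{n−1}), deg/h, where wrap maps
  into (−180°, 180°] so a crossing of the ±180° branch cut never reads as a
  near-360° turn.

A bird's first fix has undefined velocities and is never an excursion.
Multi-day gaps (winter) are left alone: a large Δt simply produces tiny
velocities, and any genuinely new location after a gap is caught, if at
all, by the novelty rule. Duplicate timestamps are resolved at ingestion
(first occurrence kept), so Δt > 0 always.

## Excursion classification

Three heuristics, applied per fix, with rule provenance recorded:

1. **Nest buffer (veto).** r ≤ 30 km → never an excursion. Prevents
   ordinary movement around the natal site from being read as travel.
2. **Velocity rule.** r > 30 km and |v_r| > 5 km/h and |v_θ| < 45 °/h.
   Magnitudes are used on both velocities: "high radial speed" includes the
   fast inbound leg of a round trip (strongly negative v_r), and "low
   angular velocity" describes magnitude. The literal signed behaviour
   (outbound only) is available via `use_absolute_v_r=False`.
3. **Novelty rule.** r > 30 km and the fix is more than 3 km from *every*
   strictly earlier fix of the same bird (the nest itself counts as the
   first previous fix; earlier fixes count regardless of their own label).
   Implemented with a uniform spatial hash (cell side = the novelty
   distance, 3×3 neighbourhood search) and verified identical to the
   brute-force all-pairs computation on thousands of random trajectories.

Rules 2 and 3 combine by OR (each is a sufficient condition); when both
fire, provenance goes to the velocity rule.

**Gap relabelling.** With at most six fixes a day, the interior of a long
journey can look locally sedentary. Every maximal run of ≤ 3 settlement
labels flanked on both sides by excursion fixes becomes excursion with
rule `gapfill`. One pass over maximal runs reaches the fixed point:
relabelling merges adjacent excursion runs and cannot create a new short
flanked run (asserted by an idempotence property test). After this pass,
excursion fixes inside the 30 km buffer can exist, but only with `gapfill`
provenance.

All thresholds live in `ClassifierConfig` (defaults 30 km, 5 km/h,
45 °/h, 3 km, 3 fixes) and classification is a deterministic function of
trajectory and config. Raising the v_r or novelty thresholds, or lowering
the v_θ ceiling, can only shrink the pre-gapfill excursion set
(monotonicity property test).

## Kernel home ranges

The utilisation distribution is a **product kernel estimate**: an
independent Gaussian kernel per axis with one shared bandwidth h,
evaluated on a `grid_cells × grid_cells` (default 90×90) grid covering the
point bounding box plus a 3h margin (beyond three bandwidths the excluded
tail mass is negligible), then normalised to unit mass. The grid
evaluation factorises into two (grid × n) kernel matrices and one matrix
product, so even multi-year trajectories cost milliseconds.

**Bandwidth semantics.** The `smoothing` default of 0.04 is a *fraction of
the point set's bounding-box diagonal*, converted to km with a 0.5 km
floor. A scale-free bandwidth keeps ranges tight but unfragmented whether
a bird roamed 10 km or 500 km; an absolute `bandwidth_km` override is
provided, and the floor covers degenerate (near-point) inputs. Both the
grid size and the smoothing fraction are exposed because reasonable
alternative readings exist; the defaults are documented interpretations,
not measured constants.

**Isopleth extraction.** Cells are ranked by density; the threshold d* is
the largest density such that cells with density ≥ d* hold cumulative mass
≥ the level (0.90 by default). Tied densities are included together, so
the contained mass always reaches at least the level (deterministic and
conservative). The boundary is traced marginally below d* by marching
squares with bilinear interpolation on the zero-padded grid (padding
guarantees closed rings); rings are assembled into polygons with even-odd
nesting so ring-shaped ranges get holes. Areas are planar km² in the
equal-area frame. Verified against closed forms: the 90 % region of a
circular-Gaussian UD is a disc of radius h·√(2 ln 10) (matched within a
few percent at the default grid), contained mass ≥ level on arbitrary
inputs, mass conservation to 1e-9, and <3 % area change when the grid is
doubled.

**With vs without excursions.** `compare_ranges` computes the isopleth on
all fixes and on settlement-only fixes under the same `KernelConfig`
(bandwidth re-derived per point set, since it is scale-free by definition)
and reports the area ratio and symmetric difference. **Weekly ranges** are
cumulative: each week's range uses every settlement fix observed up to and
including that week, so previously settled areas persist as "known home
ranges" — the knowledge model a weekly reporting pipeline actually has.
Weeks adding no fixes carry the previous range object forward.

## Weekly behaviour classification

Weeks are Monday-anchored calendar windows (configurable anchor). Weekly
distance is the great-circle chain over steps whose *later* endpoint falls
in the window — a lower bound on true path length, which is all that a few
fixes per day can support. Miles use 1 km = 0.621371 mi.

The pattern cascade (first match wins) runs against the known ranges from
the *previous* week:

1. no fixes → `no_data`;
2. no excursion fixes and ≥ 80 % of fixes within the known ranges →
   `within_home_range`;
3. excursion fixes present and first and last fix in the same known
   polygon → `round_trip`;
4. first and last fix in different known polygons →
   `travel_between_home_ranges`;
5. a trailing block of ≥ 5 fixes outside all known polygons, sitting in a
   ≤ 5 km-radius disc for ≥ 3 days → `new_home_range` (every sufficiently
   long suffix of the trailing outside run is tested, because the run
   usually begins with the travel that got the bird there);
6. otherwise → `exploring_outside`.

Membership in a known range uses a 5 km tolerance around the isopleth
polygons: the contour is an estimate, and a roost just outside the 90 %
line is not evidence of exploration. The 80 % / 5 fixes / 5 km / 3 days
thresholds are operational choices for sparse duty-cycled data, exposed in
`BehaviorConfig`; they are not field-measured constants. Note that
travelling to a *previously unknown* area can never classify as
`travel_between_home_ranges` — the destination range does not exist yet —
and resolves to `new_home_range` once the bird settles; this matches how
the categories are used in reporting.

Each pattern renders to one fixed template sentence (pure function of the
week summary; byte-identical on identical input).

## The simulator and the validation benchmark

`synthetic.simulate` generates what the analysis consumes: a bird that
occupies settlement areas in sequence and undertakes scripted travel
events, observed through the tag's duty cycle.

* **Duty cycle.** Per-season fixes per day (summer 6, spring/autumn 4,
  winter 0–1 with P(transmit) = 0.3), at evenly spaced slots across a
  season-dependent daylight window with ±25 % slot jitter. Scheduled
  rather than uniform-random times reflect how solar PTT tags are
  programmed — and matter: with i.i.d. random times, fixes minutes apart
  combined with kilometre-scale position scatter would imply impossible
  within-settlement speeds that no real tag series shows.
* **Settlement movement.** The offset from the settlement centre follows a
  mean-reverting Ornstein–Uhlenbeck process with stationary s.d. 2 km and
  correlation time 24 h: positions hours apart are close (site fidelity —
  shared roosts, regular feeding places), while day-to-day scatter fills
  the area. Independent per-fix scatter was rejected because it implies a
  rate of "never-visited" locations and apparent short-interval speeds
  that contradict observed settlement behaviour and would make any
  fix-level classifier look spuriously bad.
* **Travel events.** Constant-speed (default 25 km/h) near-straight legs
  with small heading jitter (5°); a transfer ends at the next settlement,
  a round trip goes out, stays overnight at the target, and returns. The
  ground-truth label is excursion exactly for fixes generated between an
  event's departure and its final arrival. GPS noise (30 m) is added to
  every fix; the first fix is exactly at the nest; one integer seed
  determines everything.

**Benchmark scenario** (`benchmark_config`): six months (April–September),
natal settlement at the nest, a second settlement 80 km east, one transfer
(a Tuesday morning), one overnight round trip from each settlement (~90 km
and ~86 km one-way — the scale of documented prospecting journeys), cruise
25 km/h, a flat four fixes per day (~732 fixes). Scripted weekly truth:
the first week of any occupancy (including the natal week and the
transfer-to-new-area week) is `new_home_range`, round-trip weeks are
`round_trip`, all other observed weeks `within_home_range`.

Across 20 seeds the classifier recovers ground truth with pooled precision
and recall ≈ 0.80–0.94, the settlement-only home range is ~3× tighter than
the all-fixes range (mean area ratio ≈ 0.29), and weekly-pattern accuracy
is ≈ 0.98. Two structural effects bound what precision/recall can reach
here, and would equally affect real data:

* the first fix transmitted *after* an arrival carries the journey in its
  backward difference and is flagged as travel although the truth calls it
  settlement (about one fix per event);
* travel within 30 km of the nest is vetoed by construction, so the first
  hour of any journey from the natal area is unlabellable at fix level.

## What the simulation does not show

The generator makes no attempt at behavioural realism beyond the structure
the classifier sees: no foraging model, thermals, roost dynamics, habitat,
weather or mortality; daylight is a flat seasonal window, not a solar
model; travel is piecewise-straight. Passing the benchmark therefore shows
that the pipeline recovers the *kind* of structure it targets from
realistically sparse, noisy sampling — not that real kites meet the
generator's assumptions. The published 24-bird summary table is used the
other way around: its per-bird counts are inputs whose printed percentages
and totals the summary arithmetic must reproduce exactly (they do,
including the half-up rounding its percentages were printed with).

## Numerical and edge-case conventions

* Timestamps are UTC; naive input is assumed UTC and flagged in the parse
  report. Exact duplicate rows are dropped; duplicate timestamps within a
  bird keep the first occurrence.
* Ingestion rejects (and counts) unparseable rows rather than coercing.
* All-identical points are a valid KDE input (bandwidth floor applies);
  a single-cell UD degenerates to that cell's rectangle.
* Isopleth levels must lie strictly in (0, 1).
* The settlement-only home range requires ≥ 2 settlement fixes; fewer is
  an error suggesting threshold review rather than a silent fallback.
* GeoJSON output follows RFC 7946 (exterior rings counter-clockwise,
  WGS84 lon/lat after inverse projection); labelled-fix CSVs round-trip
  coordinates at full precision via `repr`.
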