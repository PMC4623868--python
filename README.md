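# kitetrails

Excursion detection, kernel home ranges and weekly movement summaries for
sparse raptor satellite-tag data.

Solar-powered GPS tags on dispersing raptors (the motivating system is
reintroduced red kites, *Milvus milvus*, tracked from northern Scotland)
transmit only a handful of fixes per day — up to six in summer, four in
spring/autumn, almost none in winter. During post-natal dispersal these
birds alternate between *temporary settlement areas* (used intensively for
weeks or months) and *excursions*: swift, relatively straight journeys away
from or between settlement areas. Conventional home-range estimators mix
the two behaviours; conservation reporting needs them separated, automatically
and in near-real time.

`kitetrails` implements that separation and everything downstream of it:

* **Excursion classification.** Fixes are projected to a nest-centred
  equal-area plane (spherical Lambert azimuthal projection, km) and to
  polar coordinates (r, θ). Backward differences give a radial velocity
  v_r = (r_n − r_{n−1})/(t_n − t_{n−1}) (km/h) and an angular velocity
  v_θ = Δθ/Δt (deg/h, Δθ wrapped into (−180°, 180°]). A fix is part of an
  excursion when it is more than 30 km from the nest **and** either
  (a) |v_r| > 5 km/h with |v_θ| < 45 °/h (fast, straight, radial travel), or
  (b) it lies more than 3 km from every previous fix of the same bird
  (novel ground). Runs of at most three settlement fixes flanked by
  excursion fixes are relabelled as part of the same excursion, bridging the
  sparse sampling. Each excursion fix records the rule that fired.
* **Kernel home ranges.** The utilisation distribution is a product kernel
  estimate (independent Gaussian per axis, shared bandwidth) on a 90×90
  grid; the home range is the 90 % isopleth — the highest-density region
  holding 90 % of UD mass — traced by marching squares and measured in km²
  directly in the equal-area plane. Ranges are computed on all fixes and on
  settlement-only fixes, and compared.
* **Weekly behaviour.** Calendar weeks are classified into the patterns
  used in public-facing dispersal reporting — within home range, new home
  range, travel between known home ranges, round trip, exploring outside,
  no data — against the cumulative "known" ranges from previous weeks, and
  rendered as deterministic template sentences with weekly mileage.
* **A ground-truthed simulator.** Because such telemetry is rarely
  redistributable, a dispersal simulator (settlement areas + scripted travel
  events + the tag's seasonal duty cycle + GPS noise) generates trajectories
  with per-fix truth labels, so every algorithm here is validated by
  simulation recovery rather than by eye.

## Worked example

```python
from kitetrails import MovementModel, synthetic

traj, truth = synthetic.simulate(synthetic.benchmark_config(), seed=3)
res = MovementModel(traj).fit()
print(res.summary())
```

```
                         Movement analysis
====================================================================
Bird id:            synthetic
Period:             2021-04-01 .. 2021-09-30
Fixes:              732
Excursion fixes:    15 (2.0 %)
  by velocity rule:  5
  by novelty rule:   5
  by gapfill rule:   5
--------------------------------------------------------------------
Home range (90% isopleth), all fixes:         1722.6 km2 in 2 part(s)
Home range (90% isopleth), settlement only:    528.4 km2 in 2 part(s)
Area ratio (settlement / all):   0.307
--------------------------------------------------------------------
Weeks by movement pattern:
  within_home_range           23
  new_home_range              2
  round_trip                  2
Total distance:     1569 km (975 miles)
====================================================================
```

The simulated bird spent six months across two settlement areas 80 km
apart, with one transfer between them and one overnight round trip from
each. The classifier flags 15 of 732 fixes as excursion travel; excluding
them shrinks the 90 % home range to a third of its all-fixes area
(ratio 0.307) because the kernel no longer has to cover the journeys.
Week-level narration picks out the interesting weeks:

```python
for w, text in zip(res.weeks, res.week_texts()):
    if w.pattern != "within_home_range":
        print(w.start.date(), text)
```

```
2021-03-29 This week, synthetic flew around 14 miles and was exploring its newly established home range.
2021-05-10 This week, synthetic flew around 140 miles and made a journey outside its home range and back.
2021-06-21 This week, synthetic flew around 73 miles and was exploring its newly established home range.
2021-08-09 This week, synthetic flew around 134 miles and made a journey outside its home range and back.
```

Scored against the simulator's ground truth
(`synthetic.evaluate(res.labels, truth.labels)`), this run has excursion
precision 0.800 and recall 0.923.

The same pipeline runs from the shell on any fix CSV
(`bird_id,timestamp,lat,lon`):

```sh
kitetrails simulate --seed 7 --out fixes.csv --truth truth.csv
kitetrails detect   --fixes fixes.csv --out labeled.csv --summary table.csv
kitetrails homerange --labeled labeled.csv --exclude-excursions \
                     --geojson ranges.geojson --summary areas.csv
kitetrails weekly   --labeled labeled.csv --out weeks.csv --text blog.txt
kitetrails evaluate --pred labeled.csv --truth truth.csv --out metrics.json
```

Every command writes a `.manifest.json` (resolved parameters, input/output
SHA-256 digests, package version, seed) next to its primary output.

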