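# mvftrack

Movement-verified filtering (MVF) of high-resolution (≥ 1 Hz) GPS
tracks for collar-borne wildlife biologgers, using tri-axial
acceleration as an independent witness of movement.

## The problem

GPS fixes recorded at 1 Hz resolve fine-scale animal movement — but
only when the animal is actually travelling. While an animal rests,
positional *jitter* (fixes fluctuating around a true stationary
location) masquerades as movement, and because most terrestrial
animals rest most of the time, naive summing of fix-to-fix distances
grossly overestimates distance travelled. `mvftrack` implements a
decision-tree protocol that verifies movement per second by requiring
*both* the GPS and an independent motion sensor to agree, and flags
everything else as non-travelling:

1. **Outlier screen (Z).** Missing fixes are completed by linear
   interpolation (giving the raw-fix track, RF) and a centre-aligned
   rolling median over `median_window` = 60 s is applied to latitude
   and longitude (the median-filtered track, MeFF). Seconds where the
   Haversine distance RF→MeFF exceeds `z_dist` = 100 m are extreme
   outliers and fail outright.
2. **Joint magnitude thresholds (X, Y).** VeDBA — the vectorial
   dynamic body acceleration, ‖a − g‖ with the gravity estimate g
   taken as a 2 s rolling mean per axis, smoothed over 2 s — must
   reach `x_vedba` = 0.11 g, *and* GPS speed — Haversine distance
   between every 5th retained fix divided by its time span, smoothed
   over 5 s — must reach `y_speed` = 0.35 m s⁻¹. High speed with low
   VeDBA is the signature of locational error; high VeDBA with low
   speed is stationary (non-travelling) behaviour. Either failure
   keeps MVF = 0.
3. **Duration threshold (T).** Both thresholds must hold for at least
   `t_min` = 5 consecutive seconds; qualifying runs separated by ≤ 2 s
   are merged.

Each second gets MVF ∈ {0, 1} plus a reason code
(`moving`, `both_below`, `speed_only`, `vedba_only`, `too_short`,
`outlier_z`, `missing`). Downstream summaries (distance, speed,
straightness, hourly budgets, confusion rates against an ethogram,
per-bout speed~VeDBA regression) can then be computed before and
after filtering.

A seeded synthetic-data generator (`mvftrack.synthetic`) produces
ground-truthed GPS + 40 Hz accelerometer records with two-state
(moving/resting) structure, state-calibrated VeDBA (0.198 ± 0.058 g
moving, 0.039 ± 0.012 g resting), state-dependent jitter, dropout and
rare large outliers, so the whole pipeline is testable at desk scale.

## Worked example

```sh
mvftrack simulate --out-dir demo --seed 1 --duration 7200
mvftrack filter   --gps demo/gps.csv --accel demo/accel.csv --out demo/track.csv
mvftrack evaluate --track demo/track.csv --ethogram demo/ethogram.csv --out demo/confusion.csv
mvftrack metrics  --track demo/track.csv --out-prefix demo/run
```

which prints (to standard error):

```
simulating 7200 s scenario (seed 1)
wrote fixtures to demo
reading demo/gps.csv and demo/accel.csv
7200 s aligned; 2128 s verified moving (29.6%)
accuracy 99.31%  TPR 97.70%  FPR 0.00%
wrote demo/run_bouts.csv and demo/run_hourly.csv
```

Of the two simulated hours, 2128 s pass all screens as verified
travel; scored against the generator's ground truth (converted to an
ethogram CSV of `moving`/`non-moving` labels) the protocol recovers
the true state on 99.3 % of seconds and never labels a resting second
as travel. The movement summaries make the point of the method
directly: on the same record,

```
unfiltered 49914 m  filtered 7540 m  inflation 562%
```

— summing raw fix-to-fix distances over all seconds claims ~50 km
travelled, while restricting to MVF-verified seconds gives ~7.5 km;
the rest is resting-state jitter.

The same operations are available as a library
(`read_gps`, `read_accel`, `run_pipeline`, `segment_bouts`,
`path_metrics`, `evaluate_confusion`, `simulate_scenario`, …); every
threshold lives in `MvfConfig`, which round-trips through a flat
`key = value` config file and is overridable per CLI flag
(`--x-vedba`, `--y-speed`, `--t-min`, `--z-dist`, …).

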