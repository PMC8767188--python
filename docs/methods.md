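# Methods

This note documents the models and conventions behind `mvftrack`: what
each stage computes, the defaults and why, what the synthetic
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Signal derivations

**VeDBA.** The static (gravitational) component of each accelerometer
axis is estimated with a centre-aligned rolling mean over
`static_window` (default 2 s); the dynamic component is the residual,
and VeDBA is its Euclidean norm, post-smoothed with a centre-aligned
rolling mean over `vedba_smooth` (default 2 s) so that the
acceleration and deceleration halves of a stride cycle share a
window. The static window equals the smoothing window by default: the
two scales serve the same purpose (separating sub-stride structure
from posture), and a single 2 s scale is appropriate for a large
cursorial carnivore with stride frequencies of ~1–3 Hz. VeDBA is
rotation-invariant by construction (the norm of the dynamic vector),
which the tests verify directly; collar roll therefore affects
pitch/roll estimates but not VeDBA.

**Posture.** With the collar convention x = surge, y = sway,
z = heave (+z up), pitch = atan2(−x̄, √(ȳ² + z̄²)) and
roll = atan2(ȳ, z̄) from the static vector. A zero-norm static vector
(free fall, or corrupt data) yields missing angles.

**GPS speed.** Distances use the Haversine formula on a sphere of
radius 6 371 000 m (the mean Earth radius; configurable — the choice
moves distances by < 0.3 %). At 1 Hz, fix-to-fix distances are
dominated by coordinate-precision and jitter error (the fifth decimal
place of a coordinate spans ≈ 1.1 m), so speed is computed over a
*stepping range*: every `stepping_range`-th (default 5th) non-missing
fix is retained, the distance between consecutive retained fixes is
divided by the elapsed time, and that speed is assigned uniformly to
every second of the interval (a step function — the data give no
information about within-interval variation) before a 5 s
centre-aligned rolling mean. Missing fixes are skipped, not
interpolated, so intervals spanning gaps simply cover more seconds.
Seconds outside any interval (before the first or after the last
retained fix) carry no speed and are treated as missing by the
classifier.

**Outlier screen.** Missing fixes are first completed by linear
interpolation in latitude/longitude against time (leading/trailing
gaps copy the nearest fix), giving RF; a centre-aligned rolling
median over `median_window` (default 60 s) applied per coordinate
gives MeFF. The per-second RF→MeFF Haversine distance exceeding
`z_dist` (default 100 m, deliberately lenient) marks an extreme
outlier. The median window must be long enough that a batch of
consecutive anomalies cannot capture the median; 60 s tolerates
batches up to ~30 s. The screen runs on the raw track in a single
pass — flagged seconds are *not* removed before speed or MeFF
computation; they simply fail the protocol. Consequences: (i) the
stepping intervals adjacent to an outlier retain inflated speeds;
(ii) within ~half a window of the record ends the median is
one-sided, so genuinely fast straight travel can be flagged in the
first/last ~30 s of a record. Both are accepted as edge behaviour of
the single-pass design.

## Classification

Per second, in precedence order: missing (no position, no usable
speed, or no usable VeDBA) → `outlier_z` → behavioural evaluation.
Thresholds are pass-inclusive (VeDBA ≥ X, speed ≥ Y): the protocol
defines the *fail* conditions with strict inequalities, leaving
equality unassigned — a measure-zero choice resolved in favour of
passing. Runs of candidate seconds shorter than `t_min` become
`too_short`; qualifying runs label every second `moving`, including
the first `t_min − 1`. After the duration screen, MVF = 1 runs
separated by ≤ `merge_gap` (default 2 s) are merged, the gap seconds
relabelled `moving` regardless of their prior reason (the gaps are at
most 2 s, typically a missing fix or threshold flicker inside genuine
travel). Because merging happens after the duration screen, a merged
bout always contains at least one run of length ≥ `t_min`; two
sub-threshold runs can never bridge into a bout. Raising X or Y can
only shrink, and lowering T only grow, the set of MVF = 1 seconds
(verified as a property test).

## Movement summaries

Distance for a state selection sums Haversine steps between
successive non-missing fixes within each maximal run of selected
seconds; runs are never bridged, so filtered (moving-only) distance
can never exceed the unfiltered total. "Non-moving" excludes missing
and outlier seconds — those are reported separately, as in the
reason-code breakdown, which normalises the four behavioural reasons
to sum to one. Hourly grouping bins each step by the clock hour of
its starting second, so hourly distances sum exactly to the total.

Tortuosity is reported as the straightness index — net displacement
over cumulative path length, in [0, 1] — computed per bout. Confusion
rates against an ethogram are pooled per-second counts by default
(TPR/FNR and FPR/TNR are exact complements by construction);
`average_rates` offers the per-individual averaging alternative,
which generally gives slightly different pooled accuracy. The
speed~VeDBA relationship is an ordinary least-squares fit of per-bout
mean smoothed speed on per-bout mean smoothed VeDBA over moving
bouts.

## The synthetic generator

The generator emulates a rest-dominated carnivore deployment:

| parameter | default | rationale |
|---|---|---|
| duration | 86 400 s | one day |
| moving fraction | 0.1937 | rest-dominated activity budget |
| mean moving bout | 300 s | minutes-scale travel bouts; resting mean derived (≈ 1249 s) so the budget holds in expectation |
| moving speed | 0.9 ± 0.3 m s⁻¹ (bout level), ±0.15 within bout | sustained walking |
| heading persistence | 0.85 | correlated random walk, turn s.d. (1−p)·π rad |
| VeDBA targets | 0.198 ± 0.058 g moving, 0.039 ± 0.012 g resting | state-wise calibration |
| speed–VeDBA correlation | 0.9 | VeDBA is a (noisy) linear proxy for speed at bout level |
| GPS jitter σ | 5 m resting, 2 m moving | jitter disproportionately high at rest |
| fix dropout | 8 % resting, 3 % moving | ~90–97 % fix success |
| outliers | p = 5·10⁻⁴, 500 m uniform bearing | rare gross errors |
| accelerometer | 40 Hz, stride 2 Hz, sensor noise 0.005 g | collar logger regime |

Bout lengths are exponential (memoryless — no bout-duration model is
imposed). Per bout, a smoothed-VeDBA target is drawn from the state's
normal (truncated at 0); for moving bouts the draw correlates with
the bout's mean speed. The stride sinusoid's amplitude is solved
numerically per bout: a unit-amplitude signal of the bout's length is
pushed through the same static-estimation/smoothing pipeline the
analysis uses, and the amplitude scales the target by the resulting
mean (VeDBA is linear in amplitude, so the solve is exact up to
cross-bout window leakage). Gravity holds steady while moving and
drifts as a slow posture random walk (0.3°/s) at rest. Metres are
mapped to degrees with a local flat-earth projection at the scenario
origin — valid at the ≤ km scales generated. GPS observation adds
isotropic Gaussian noise, state-dependent dropout, and outlier
displacement. All draws come from one seeded generator in a fixed
order, so outputs are byte-identical per seed.

**What passing tests do and do not show.** The generator reproduces
the *statistical contrast* the protocol exploits (state-separated
VeDBA, jitter at rest, genuine displacement while moving); it does
not model habitat-driven error correlation, fix-latency misalignment
between GPS and accelerometer clocks, DOP structure, gait changes, or
collar-roll corruption of the axis convention. High desk-scale
accuracy (≈ 97–99 % per-second agreement, false-positive rate ≪ 1 %)
therefore demonstrates the pipeline's correctness under its own
assumptions, not expected field accuracy — though the ordering (very
high specificity, slightly lower sensitivity at bout boundaries)
matches what ground-truthed field calibration reports.

**Known limitation — the speed~VeDBA r².** Under the default
scenario, per-bout OLS r² is low (~0.0–0.3; ~0.3–0.5 with outliers
disabled) even though the generator couples speed and VeDBA at
ρ = 0.9. Three structural causes: rare 500 m outliers inside moving
bouts leave ~100 m s⁻¹ leverage points in neighbouring stepping
intervals (the Z screen flags only the displaced second); the
walking-only speed distribution (0.9 ± 0.3 m s⁻¹) offers a small
dynamic range relative to 2 m moving jitter, whereas field records
spanning walking-to-running speeds support much higher r²; and MVF
selection truncates low-VeDBA bouts (range restriction). The
regression tests therefore assert recovery of the positive coupling,
not a particular r² level.

## Numerical conventions

- Rolling windows are centre-aligned and shrink at the edges
  (preserving record length); even windows take the extra sample on
  the left of centre, and an even median window returns the midpoint
  of the two central order statistics.
- Timestamps are aligned by integer-second flooring; sub-second GPS
  latency is ignored (the 1 Hz subsampling would absorb it anyway —
  this is a known source of boundary misclassification in real data).
- Accelerometer seconds holding fewer than 50 % of the nominal sample
  count (strict) yield missing VeDBA for that second.
- Missing positional fields serialise as the literal `NA`;
  coordinates are written to six decimal places (below the ~1.1 m
  physical resolution of the fifth place), VeDBA to 10⁻⁵ g.
- Degenerate inputs fail loudly: empty series, all-missing tracks,
  zero-variance regressors and zero-norm static vectors raise or
  return flagged-missing values rather than silently propagating.
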