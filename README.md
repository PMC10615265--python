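# fincount

Impedance-based fish counting: detect fish passing between a pair of wall
electrodes from the measured electrical impedance, model the tank's electric
field to understand *where* the measurement is sensitive, and evaluate the
detector on seeded synthetic benchmarks.

## The idea

A freshwater fish conducts electricity roughly twenty times better than the
surrounding low-conductivity water. Driving a small alternating current
between two strip electrodes on opposite tank walls and monitoring the
complex impedance therefore shows a fish as a transient **decay** of the
measured resistance (and reactance) while it swims through the sensitive
region between the electrodes. Counting fish reduces to detecting these
decays against baseline drift and electrical interference.

The package has four parts:

- **`fincount.detector`** — a four-state online detector. A 200-sample
  rolling buffer tracks the baseline; the *noise amplitude* is the maximum
  positive deviation from the buffer median (positive excursions are by
  construction noise, never fish), and a sample fires a detection when it
  drops below `median − threshold_ratio · 2 · max(noise_amplitude,
  noise_floor)`. A stability criterion (bounded swing and bounded
  least-squares slope) gates threshold updates: during unstable periods the
  thresholds stay frozen at the last stable values, so interference cannot
  inflate them. Four operating modes use the resistance channel, the
  reactance channel, or their OR/AND fusion. An exactly equivalent vectorized
  replay makes parameter sweeps cheap.
- **`fincount.field`** — a cell-centered finite-difference solver for
  `div(σ grad V) = 0` in the tank, with Dirichlet strip electrodes and
  insulating walls. It yields the resistance, the current density and the
  impedance-sensitivity field `S = |J|²/I²`, plus a fish model (conductive
  ellipsoid) and a depolarization-corrected linearized estimate of the
  fish-induced resistance change.
- **`fincount.synth`** — seeded synthetic benchmarks: smooth spline
  trajectories of two ground-truth classes (wall-to-wall *passes* and
  near-wall *dwells*), rendered into impedance streams through a precomputed
  field surrogate plus baseline drift, Gaussian noise and positive spikes.
- **`fincount.tracks` / `fincount.evaluate`** — trajectory tools (LOWESS
  smoothing, headings, pass/dwell labelling, two-camera triangulation via
  reference-plane homographies) and the evaluation pipeline (sensitivity =
  TP/(TP+FN), specificity = TN/(TN+FP), detector-setting sweeps, distance
  stratification, spatial median maps).

## Worked example

Generate the nominal benchmark (40 passes + 40 dwells, 20 mm electrodes,
0.05 S/m water, seed 1), sweep the detector, and score it:

```python
from fincount import ScenarioConfig, make_benchmark, sweep

benchmark = make_benchmark(ScenarioConfig(seed=1))
table = sweep(benchmark, modes=("re", "or"), ratios=(3.0, 3.5, 4.0))
print(table.to_string(index=False))
```

```
mode  threshold_ratio  TP  FN  TN  FP  sensitivity  specificity
  re              3.0  37   3  40   0        0.925          1.0
  re              3.5  37   3  40   0        0.925          1.0
  re              4.0  36   4  40   0        0.900          1.0
  or              3.0  37   3  40   0        0.925          1.0
  or              3.5  37   3  40   0        0.925          1.0
  or              4.0  37   3  40   0        0.925          1.0
```

Every dwell is rejected (specificity 100 %) and at least 90 % of passes are
detected at each setting; the few misses are the passes that stay farthest
from the electrodes, where the resistance dip sinks below the noise. The
fish-free tank resistance behind these streams is 246.0 Ω on the 10 mm
surrogate grid (231.3 Ω when re-solved at 5 mm).

The same field model explains the electrode-design trade-off. Sensitivity
profiles along the electrode-to-electrode midline, for increasing electrode
width/spacing ratio (5 mm grid):

```python
import numpy as np
from fincount import TankGeometry, midline_profiles

profs = midline_profiles((20/240, 0.125, 0.5, 1.0), TankGeometry(), h=0.005)
for ratio, (y, db) in profs.items():
    print(f"width/spacing {ratio:.3f}: span {np.ptp(db):.2f} dB")
```

```
width/spacing 0.083: span 18.79 dB
width/spacing 0.125: span 14.98 dB
width/spacing 0.500: span 3.65 dB
width/spacing 1.000: span 0.61 dB
```

Narrow electrodes are ~19 dB more sensitive next to the electrode than at
mid-tank (they miss distant fish); plate-like electrodes (ratio 1) are
uniform to within 0.61 dB but produce correspondingly smaller dips.

### Command line

```
fincount simulate --config run.yaml --out bench/      # write a benchmark
fincount detect bench/pass_000_stream.csv --out events.csv
fincount evaluate bench/ --modes re,or --ratios 3,3.5,4 --out sweep.csv
fincount field --out field/                           # R, S-map, profiles
```

Every command echoes its full numeric configuration into a
`run_metadata.json` next to its outputs; identical config + seed reproduce
identical files byte for byte.

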