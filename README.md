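# fourroom

Analysis pipeline for hippocampal place-cell recordings in a four-room maze
whose connectivity can be changed by locking saloon-type doors, together
with a ground-truth synthetic-data generator so that every analysis stage
can be validated by parameter recovery.

## The scientific problem

Place cells in dorsal CA1 fire at specific locations and are thought to
implement a cognitive map.  Whether that map explicitly encodes
*connectivity* — which transitions between subspaces are currently possible
— is a distinct question from whether it encodes location.  The experimental
design this package analyzes probes it directly: four geometrically
identical 60 × 60 cm boxes arranged 2 × 2, joined by 16 × 16 cm pushable
door units that can be locked in one or both directions.  A recording day
is a sequence of five sessions, `O1 O2 C1 C2 O3`: two all-open baselines, two
test sessions (one door locked both ways, "Closed-Door", or every door
locked in one direction, "One-Way"), and a re-opened control.  Each session
contains 12 bell-cued trials in which the animal runs to a rewarded box and
then forages in it.

The pipeline measures, on the behavioral side, whether the animal *knows*
the connectivity (door-push rates on locked vs open door sides, bell
responses, optimal first door pushes, correct first foraging), and on the
neural side whether place cells *encode* it:

- **Rate maps** are spike/dwell bivariate histograms on 2 cm bins, smoothed
  with a Gaussian kernel (σ = 2.5 bins, 9 × 9 support) before division;
  bins occupied < 0.05 s are empty and samples slower than 5 cm/s are
  removed.  Spatial tuning is the Skaggs information rate
  `SI = Σᵢ pᵢ λᵢ log₂(λᵢ/λ)` (bits/s), tested against 100 circular
  spike-train time shifts.
- **Place cells** are units with rate > 0.1 Hz in ≥ 2 sessions and, in their
  highest-rate session, rate in (0.1, 5) Hz, SI > 0.5 bits/s above the 95th
  shuffle percentile, and waveform width > 300 μs.
- **Remapping** is assessed by Pearson map correlations (whole maze, per
  box, 25 cm doorway regions) against random-cell shuffles, and by the Fuhs
  rate-remapping metric `Σ|f₁−f₂| / Σ(|f₁|+|f₂|)` on zero-meaned maps.
- **Place fields** are connected regions above 20% of the map maximum with
  ≥ 9 bins and peak > 1 Hz; the **bridge index** `1 − |a−b|/(a+b)` measures
  how evenly a door-adjacent field splits across the door line (0 =
  one-sided, 1 = even).
- **Decoding** is memoryless Bayesian: spike counts in τ = 300 ms windows
  under a Poisson, cell-independent likelihood with a uniform prior, argmax
  over position bins, summarized as a 16 × 16 quadrant confusion matrix
  (chance 1/16).
- **Custom statistics**: chi-square test of expected proportions, a
  sequential Holm-Bonferroni correction, and cluster-quality metrics
  (isolation distance, L-ratio) on Mahalanobis distances.

The synthetic generator produces full five-session sequences — trajectory
(50 Hz), bell and door-push events, and inhomogeneous-Poisson spike trains
from planted Gaussian field maps with controllable per-box repetition,
connectivity-triggered remapping, drift and door-push learning — with all
ground truth recorded.

## Worked example

```bash
fourroom simulate --out demo_data --seed 7 --n-cells 16 --session-minutes 8
fourroom analyze  --data demo_data --out demo_results --seed 7
fourroom report   --results demo_results
```

The report (`demo_results/report.md`) printed by this run:

```
- Optimal first door pushes: 96.3% (chance 50%)
- Correct first foraging: 100.0% (chance 33%, excluding the initial box)

## Door pushes per side per minute
| session   |    control |     locked |     open |
|:----------|-----------:|-----------:|---------:|
| C1        | nan        |   0.180672 | 0.361344 |
| C2        | nan        |   0        | 0.363857 |
| O1        |   0.239684 | nan        | 0.199736 |
| O2        |   0.121266 | nan        | 0.242532 |
| O3        |   0.122269 | nan        | 0.244539 |

## Quadrant decoding (chance = 1/16)
- O1->O2: diagonal 0.484, windows 1649
- O2->C1: diagonal 0.485, windows 1660
```

Reading it: the simulated agent pushes locked door sides about half as
often as open ones in the test sessions (it is learning the lock state),
its first door push after a bell is almost always on a shortest path to
the goal, and a Poisson decoder trained on one session decodes box
quadrants in the next at ~8 × chance — the population carries a stable,
global positional code.  The `demo_results/` directory also holds the tidy
per-visit, per-cell and per-field CSV tables each number came from.

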