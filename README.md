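# flysleep

A toolkit for analyzing the behavior and physiology of the *Drosophila*
sleep circuit: the loop in which sleep-promoting dorsal fan-shaped body
(dFB) neurons inhibit helicon cells, helicon cells excite R2 ring
neurons of the ellipsoid body, and R2 activity generates the sleep
pressure that switches the dFB on — a relaxation oscillator rather than
a continuous feedback controller.

The package is aimed at researchers who run single-fly sleep assays
(beam-crossing activity monitors or video tracking), closed-loop
optogenetic stimulation rigs, and whole-cell recordings from
central-complex neurons, and who want the standard computations of that
workflow as tested, reusable code:

- **`flysleep.synth`** — synthetic-data generators for every input the
  pipeline consumes, with ground truth attached: a two-state wake/sleep
  renewal process with diel modulation in a 65-mm tube; rendered
  grayscale video of a fly-sized blob; per-minute midline-crossing
  counts (Drosophila Activity Monitor style); and membrane-potential
  traces with Poisson spikes at UP/DOWN-state rates and EPSP trains
  modulated by photostimulation.
- **`flysleep.tracker`** — the real-time movement detector: background
  subtraction against an exponential-moving-average background, cluster
  thresholding, largest-cluster intensity-weighted centroid, and the
  2.5-mm displacement filter ("if no movement was detected, the fly is
  assumed to have remained at its last known location").
- **`flysleep.stim`** — deterministic open- and closed-loop stimulation
  controllers (blocks of 3 pulses at 20 Hz, triggered after 3 min of
  inactivity, repeated every 30 s until the next movement) plus
  light-dose accounting in 15-min bins.
- **`flysleep.sleep`** — sleep scoring (inactivity ≥ 5 min), hourly time
  courses, bout statistics by day/night phase, deprivation-rebound
  accounting against a baseline-matched 24-h window, and the
  visual-arousal assay (percentage of sleeping flies awakened).
- **`flysleep.ephys`** — spike and EPSP detection, hysteretic UP/DOWN
  state segmentation at the 1-Hz firing-rate criterion, stimulus–bout
  association, state-conditioned movement rates, and EPSP rate
  modulation by photostimulation.
- **`flysleep.homeostat`** — the relaxation-oscillator model of the
  sleep homeostat, validated against the RC neon-flasher closed form
  `T = R·C·ln((Vs − V_ext)/(Vs − V_ign))`.

## Worked example

Score sleep and quantify stimulus statistics on synthetic data:

```python
import numpy as np
from flysleep import (
    BehaviorParams, simulate_behavior, beam_counts, score_sleep,
    StimConfig, run_closed_loop, stimulus_bout_association,
)

# one fly, 24 h, wake bouts of mean 10 min alternating with sleep bouts
# of mean 20 min
traj = simulate_behavior(BehaviorParams(), 86400.0, seed=1)
bouts = score_sleep(beam_counts(traj))
print(f"{len(bouts)} sleep bouts, {sum(b.duration_min for b in bouts):.0f} min total")

# closed-loop controller on a fly that rests from 0 s and moves at 600 s
log = run_closed_loop([600.0], StimConfig(), 600.0)
print(f"{len(log.block_onsets)} blocks, {len(log)} pulses")

# association of 94 visual stimuli with locomotor bouts, 68 followed
# within 1 s
stim = np.arange(94) * 30.0
table = stimulus_bout_association(stim, np.sort(stim[:68] + 0.4))
print(f"association probability {table.probability:.4f}")
```

Output:

```
41 sleep bouts, 1121 min total
14 blocks, 42 pulses
association probability 0.7234
```

The 42 pulses are the 14 blocks of 3 pulses the controller schedules at
180, 210, …, 570 s of the 10-min rest; the association probability is
the fraction of stimuli followed by a bout onset within the 1-s window.

A command-line interface mirrors the pipeline stages; for example:

```sh
flysleep simulate dam --duration 86400 --n-flies 8 --seed 1 --out monitor.tsv
flysleep sleep score --in monitor.tsv --out bouts.csv
flysleep homeostat run --duration 200 --out trajectory.csv
```

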