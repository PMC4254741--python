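# axobot

Closed-loop simulation of an automated femtosecond-laser axotomy platform
for *C. elegans* touch neurons.

The package couples a **virtual microscope rig** (worm phantoms with known
ground truth, bright-field and fluorescence rendering with defocus blur and
sensor noise, coarse-stage/piezo motion with backlash hysteresis, a
geometric ablation model) with the **four-step image-analysis pipeline**
used to target 300 nm axons automatically:

1. **Worm localization** (`axobot.worm_locator`) — background subtraction,
   Otsu thresholding inside the trapping-area ROI, a 300-pixel particle
   filter, centroid extraction with edge rejection.
2. **Soma detection** (`axobot.soma_finder`) — coarse 2.5 µm z-steps with an
   8×-mean intensity cutoff and a 2–6 µm circular-feature gate; at most ten
   iterations before the worm is flushed.
3. **Neuron verification** (`axobot.neuron_verifier`) — piezo fine-focus via
   the LoG-filtered variance-of-intensity metric (`axobot.focus_metrics`),
   then a straight-edge search in two 150×200 px flanking ROIs to
   distinguish ALM from AVM and find the head direction.
4. **Axon targeting** (`axobot.axon_targeter`) — 50 µm anterior translation,
   mean-intensity axon fine-focus, and a proportional control loop
   (Kp = 0.9) driving the piezo y-axis until the sub-pixel axon centre lies
   within ~1 px of the ablation spot, then a 300-pulse / 4 nJ cut.

`axobot.automation_controller` orchestrates the per-worm cycle (symbolic
valve program: stage → inject → cyclic trap → axotomize → eject/flush) and
runs whole populations with per-step attrition bookkeeping.
`axobot.stats_reporting` reproduces the attrition arithmetic and the
two-sided Fisher exact reconnection comparison. All step durations are
*simulated* draws; the package makes no wall-clock throughput claims.

## CLI

```sh
axobot simulate --n-worms 5 --seed 1 --out out/sim      # TIFF stacks + truth JSON
axobot run --n 350 --seed 1 --out out/run               # population + attrition summary
axobot analyze --records out/run/records.jsonl \
       --reconnection 58 111 46 101                      # attrition + Fisher test
axobot calibrate                                         # z-offset calibration scan
axobot fixtures --out out/fx                             # tiny deterministic fixture
```

Configuration is YAML (`--config cfg.yaml`); unknown keys are rejected and
every output embeds the seed and a config hash. `axobot run` defaults to the
fast bookkeeping mode (step outcomes decided by each phantom's ground-truth
degenerate flags, exact for attrition statistics); set `imaging: full` in
the config to run the four detection steps closed-loop against rendered
frames.

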