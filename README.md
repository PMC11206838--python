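# balancefb

Reactive-balance analysis with delayed center-of-mass (CoM) feedback.

Standing balance perturbed by a combined backward support-surface
translation and toe-up rotation drives the CoM forward, then backward.
This package reconstructs lower-leg muscle envelopes (LG, MG, SOL, TA)
as the sum of two half-wave-rectified pathways fed by delayed CoM
displacement, velocity and acceleration — a balance-correcting pathway
and an antagonistic ("prime") pathway quantifying co-activation drive —
plus a stiction term on the initial CoM acceleration that is gated off
once the ankle has rotated 0.5°. Feedback gains are estimated per
subject, muscle and perturbation level by bounded multi-start
minimisation of a squared-error cost with a quadratic penalty (1e-4) on
the prime gains. Around the model sit the supporting analyses: EMG
envelope conditioning (10–450 Hz band-pass, rectification, 40 Hz
low-pass, per-subject max scaling), time-binned reactive activity
(0–150 / 150–250 / 250–400 ms, kinematic bins shifted 100 ms earlier),
co-contraction indices (mean of the pointwise minimum of two scaled
envelopes), and inverse-variance-weighted mixed-model group comparisons
with Bonferroni–Holm correction.

Because no clinical recordings ship with the package, a synthetic
module generates the whole dataset from known ground-truth gains:
smooth perturbation profiles, CoM trajectories with exactly one
forward-to-backward reversal, early monotone ankle dorsiflexion, and
EMG produced by forward evaluation of the same feedback equations the
fitter estimates. Parameter recovery and oracle equivalence form the
acceptance surface.

## Layout

| module | contents |
| --- | --- |
| `balancefb.dataio` | trial time-series files (TSV), YAML dataset manifest |
| `balancefb.synthetic` | perturbation profiles, CoM/ankle trajectories, EMG from known gains, cohort generation |
| `balancefb.preprocess` | EMG filter chain, scaling, derivatives (incl. Savitzky–Golay acceleration), analysis grid, trial averaging |
| `balancefb.timebins` | reactive EMG and kinematic time-bin averages |
| `balancefb.cci` | co-contraction index battery |
| `balancefb.model` | feedback reconstruction, stiction gating, gain fitting, goodness of fit, simple-vs-extended cost improvement |
| `balancefb.stats` | inverse-variance weights, weighted random-intercept mixed model (profiled REML), Holm step-down, post-hoc contrasts |
| `balancefb.pipeline`, `balancefb.cli`, `balancefb.config` | orchestration and the `balancefb` command |

## CLI

```sh
# synthetic cohort: trial files + manifest + ground-truth sidecar
balancefb simulate --out data/ --seed 7 --n-per-group 20

# preprocessing, time bins, CCI, both model variants -> cohort table
balancefb analyze --manifest data/manifest.yaml --out results/

# weighted mixed models + Holm correction per outcome family
balancefb stats --table results/cohort_table.tsv --out results/stats/

# summary panels
balancefb report --table results/cohort_table.tsv --out results/report/
```

All commands accept `--config config.yaml` overriding the defaults in
`balancefb.config.DEFAULT_CONFIG` (filter edges, bin edges, model delay
and bounds, statistical families, ...). Outputs embed the config hash
and seed; the full pipeline is a pure function of (config, seed).

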