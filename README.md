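# fpmat

Single-cell analysis of fluorescent-protein (FP) chromophore maturation:
per-cell inference of maturation rates from two-channel fluorescence
trajectories, stochastic simulation of maturation under a fluctuating
("global extrinsic noise") rate constant, and the noise statistics that
connect a reaction's timescale to the cell-to-cell variability it inherits
from the intracellular environment.

## The problem

A newly translated FP only becomes fluorescent after its chromophore
matures — approximately a first-order reaction with rate constant $k_3$ and
maturation time $\ln 2 / k_3$.  In a two-channel assay, protein production
and maturation are decoupled: a constitutively expressed reporter tracks how
much of the induced target FP exists ($F_c$, scaled into target-FP units by
a ratio $R$), while the target FP's own fluorescence $F_i$ tracks how much
of it has matured.  After induction at $t=0$:

$$
\frac{dm}{dt} = k_1 - \alpha m,\qquad
\frac{d(F_c R)}{dt} = k_2 m,\qquad
I = F_c R - F_i,\qquad
\frac{dF_i}{dt} = k_3 I ,
$$

with mRNA level $m$, unmatured pool $I$, and mRNA turnover $\alpha$ fixed at
0.03/min.  The system has closed-form solutions in which $F_c$ depends only
on $k = k_1 k_2$ and $F_i$ on $(k, k_3)$, so $k_3$ is identifiable cell by
cell from a single induction movie — no translation inhibitors needed.

Because maturation rates span an order of magnitude across common FPs
(~10–140 min), the reaction is a natural probe of how fast environmental
fluctuations propagate downstream: a slow reaction averages a fluctuating
rate constant over a long window and should therefore be *quieter* across
cells than a fast one.  The package quantifies exactly that, on synthetic
data whose generator is itself part of the tested surface.

## What's in the box

- `fpmat.kinetics` — closed-form model curves, background subtraction,
  scaling-ratio calibration, and the two-stage per-cell fit (closed-form
  $k$, 1-D search for $k_3$) with an $R^2 \ge 0.98$ quality gate.
- `fpmat.simulate` — Gillespie simulation of a pool of molecules whose rate
  constant is a white-noise time series (Gaussian amplitudes on a short-lag
  grid); each step uses the dwell-window time-averaged rate.  An exact
  per-molecule hazard-inversion scheme serves as the reference dynamics.
  Sweep drivers over maturation time, noise amplitude and copy number.
- `fpmat.noise` — CV, MAD outlier filtering, bias-corrected bootstrap CIs,
  the dual-reporter intrinsic/extrinsic decomposition, Pearson tests.
- `fpmat.synthetic` — seeded generators for induction trajectories,
  scaling-ratio experiments and two-colour snapshots.
- `fpmat.pipeline` — end-to-end recipes used by the numbered drivers in
  `analysis/`.

## Worked example

```sh
python analysis/01_generate_data.py   # synthetic panel, scaling expt, snapshots
python analysis/02_fit_maturation.py  # calibrate R, fit every cell
python analysis/03_noise_vs_rate.py   # CV vs maturation time + Pearson test
python analysis/04_simulation_sweeps.py
python analysis/05_two_color_noise.py
```

`02_fit_maturation.py` calibrates the scaling ratio from the steady-state
experiment (`R = 0.4999` on the shipped seed, truth 0.5) and fits 902 cells
across 14 conditions; every cell passes the R² gate and a handful are
MAD-flagged.  `03_noise_vs_rate.py` then prints the per-condition summary,
ending with

```
noise vs maturation time: Pearson r = -0.86, t = -5.72, df = 12, p = 9.6e-05
=> slower-maturing reporters carry less cell-to-cell noise (rate-dependent filtering recovered)
```

i.e. the CV of maturation time falls from ~0.37 for a 10-min reporter to
~0.11 for a 140-min reporter, exactly the rate-dependent noise structure the
generator built in.  `04_simulation_sweeps.py` reproduces the same signature
from the mechanistic side — 100 cells × 2,000 molecules per condition, rate
noise σ = 0.5·mean — with the CV of the half-maturation time falling from
0.092 (10 min) towards the molecule-level floor of 0.032 as the reaction
slows, rising with the noise amplitude, and recorded descriptively across
copy numbers.

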