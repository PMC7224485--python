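# Methods

## Kinetic model and its closed form

Induction at $t=0$ drives constant mRNA production $k_1$ with first-order
turnover $\alpha$; translation at rate $k_2$ feeds an unmatured pool that
matures with first-order rate constant $k_3$.  Measured are the
constitutive-channel signal $F_c$ (total target protein divided by the
scaling ratio $R$) and the matured-FP signal $F_i$.  Writing
$P = R\,F_c$ and $k = k_1 k_2$:

$$P(t) = \frac{k}{\alpha}t - \frac{k}{\alpha^2}\left(1-e^{-\alpha t}\right),$$

$$F_i(t) = \frac{k}{\alpha}t
  - \left(\frac{k}{\alpha k_3}+\frac{k}{\alpha^2}\right)\left(1-e^{-k_3 t}\right)
  + \frac{k\,k_3}{\alpha^2}\,\frac{e^{-\alpha t}-e^{-k_3 t}}{k_3-\alpha}.$$

Protein degradation and dilution are omitted (short movies, non-dividing
cells); $\alpha$ is fixed at 0.03/min rather than fitted, since the two
channels identify only $k$ and $k_3$.  The removable singularity at
$k_3=\alpha$ is evaluated through `expm1`:
$(e^{-\alpha t}-e^{-k_3 t})/(k_3-\alpha) =
e^{-\alpha t}\,(1-e^{-\Delta t})/\Delta$ with $\Delta=k_3-\alpha$, which is
accurate for arbitrarily small $|\Delta|$ and switches to the exact limit
$t\,e^{-\alpha t}$ only at $\Delta=0$.  The curves satisfy
$m(0)=P(0)=F_i(0)=0$ and $0 \le F_i \le P$; both are enforced against
round-off by clipping at the $10^{-16}$ level.  Tests verify the closed form
against adaptive numerical integration (LSODA, rtol $10^{-11}$) to better
than $10^{-8}$ relative across $k_3 \in [10^{-3}, 0.5]$/min including
$k_3 = \alpha(1\pm10^{-7})$.

## Per-cell fitting

Two stages exploit the model's structure:

1. $P(t) = k\,g(t)$ is linear in $k$, so $\hat k$ is a closed-form weighted
   least-squares projection of $R F_c$ onto
   $g(t) = t/\alpha - (1-e^{-\alpha t})/\alpha^2$.
2. With $k$ fixed at $\hat k$, $F_i(t) = k\,h(t;k_3)$ leaves a 1-D problem:
   the weighted sum of squared $F_i$ residuals is scanned over 80 log-spaced
   values of $k_3$ in $[10^{-4}, 2]$/min (maturation times 0.35 min–115 h)
   and polished by bounded scalar minimisation between the best grid point's
   neighbours; grid ties resolve to the smaller $k_3$.  An estimate pinned
   at a search bound is reported as `no_convergence` and fails QC.

**Weighting.**  Measurement noise on fluorescence readouts is predominantly
multiplicative, and the generator models it that way.  Both stages therefore
minimise *fractional* residuals (inverse-squared-signal weights, floored at
0.1% of each channel's maximum to keep early near-zero frames finite);
plain unweighted least squares is available as `weighting="absolute"`.  The
difference is material: at a 10-min maturation time with 2% noise the
per-cell maturation-time error is ~1.2% SD under relative weighting versus
~6.3% under absolute, because unweighted fits are dominated by the late
high-signal frames that carry little $k_3$ information.  An optional joint
$(k, k_3)$ Levenberg–Marquardt refinement over both channels is provided but
changes noise-free results only at round-off level.

**Quality control.**  $R^2$ values are the conventional unweighted ones.
The $R^2 \ge 0.98$ gate is applied to the inducible channel, which is the
channel that determines $k_3$; the constitutive channel's $R^2$ is reported
but not gating.  Among QC-passing cells, maturation times are screened with
the MAD rule: flag cells with $|x-\mathrm{median}|/(1.4826\,\mathrm{MAD}) >
3$.  A zero MAD (majority-identical values) flags nothing.  Note the
filter's false-positive rate on clean data is by construction that of a
3-sigma rule (~0.3% per cell for roughly normal spreads), so occasional
legitimate flags in large panels are expected behaviour, not errors.
Flagged and failed cells stay in the output table; nothing is dropped
silently.

**Scaling ratio.**  $R$ is calibrated from a separate experiment with a
pre-induction background phase and a post-transcription-shutoff steady
state: per cell, the ratio of background-subtracted steady-state channel
increments; aggregated as the median over cells, excluding (and counting)
cells whose constitutive increment is non-positive.

## Stochastic simulation of maturation under a fluctuating rate

Each in-silico cell owns an independent rate-constant time series: i.i.d.
Gaussian amplitudes $\mathcal N(\bar k, \sigma^2)$ on a uniform grid of lag
$\delta$, clamped below at $10^{-6}$/min (the clamped fraction is logged in
sweep outputs).  Defaults follow the study conditions: 2,000 molecules in
each of 100 cells; $\delta = \bar k$'s maturation time / 100 so the grid is
much finer than the reaction timescale; the per-cell readout is the
half-maturation time (the $\lceil n/2\rceil$-th smallest maturation event).

Two schemes convert a rate path into event times:

- **`averaged` (sequential, dwell-window time-averaged).**  With $n$ unmatured
  molecules at time $t$, the next dwell $\tau$ uses the rate averaged over
  its own window: by default the two are made *self-consistent*, i.e.
  $\tau$ solves $n\int_t^{t+\tau} k(s)\,ds = -\ln u$, equivalently
  $\tau = -\ln u / (n\bar k_{[t,t+\tau)})$ where $\bar k$ is the average
  over the realised window.  This is the fixed point of the
  dwell-defines-window / window-average-defines-dwell circle, found by
  piecewise-linear inversion of the cumulative hazard.
- **`exact` (per-molecule hazard inversion).**  Each molecule solves
  $\int_0^{T} k(s)\,ds = E$, $E \sim \mathrm{Exp}(1)$.  For constant rates
  both schemes reduce to textbook Gillespie dynamics, and the half-time
  obeys the exponential order-statistic law
  $\mathbb E[T_{1/2}] = \bar k^{-1}\sum_{i=n/2+1}^{n} i^{-1}$ with CV
  $\approx 0.032$ at $n=2000$ — the intrinsic, molecule-level noise floor
  used as an oracle in the tests.

A literal one-pass averaging variant (`averaging="one_pass"`: provisional
dwell from the instantaneous rate defines the window, the averaged rate then
sets the final dwell) is retained for sensitivity analysis but is not the
default: committing a dwell computed from a microscopic window is unstable
when that window happens to sit in a near-floor grid cell — the committed
dwell is then $\sim -\ln u/(n\cdot10^{-6})$ minutes — which fattens the
right tail of the half-time distribution enough to mask the rate-dependent
trend entirely.  The self-consistent form keeps the time-averaging
interpretation (each step literally uses its own window average) without
that artefact.

**Sweeps** hold every non-swept setting fixed, including the grid lag,
which is resolved once from the base configuration (0.2 min for the default
20-min base); per-condition seeds derive from the base seed and condition
index.  Under white noise the cell-to-cell CV behaves like
$\sqrt{\mathrm{CV}_{\mathrm{int}}^2 + \sigma_{\mathrm{rel}}^2\,\delta/T}$:
it decreases with maturation time $T$ (the filtering signature), increases
with $\sigma$, and — in this self-consistent dynamics — *decreases* with
copy number, since only the intrinsic floor depends on $n$.  The direction
of the copy-number effect is therefore recorded descriptively, not
asserted: a copy-number-driven *increase* of extrinsic susceptibility would
require the per-step averaging window ($\propto 1/(nk)$) to control the
inherited noise, which is the one-pass regime the default deliberately
avoids.

## Noise statistics

- **CV** uses the sample ($n-1$) standard deviation over the mean.
- **Bias-corrected bootstrap** (B = 2000, 95%): $z_0 =
  \Phi^{-1}(\#\{\theta^* < \hat\theta\}/B)$ with half-weight on ties, bounds
  at percentiles $\Phi(2z_0 \mp z_{0.975})$; resamples where the statistic
  is undefined are redrawn and counted.  Plain BC, not BCa, is used.  Its
  small-sample behaviour is a known limitation: for the CV of $n=30$
  lognormal samples the empirical coverage of the nominal 95% interval is
  ~88% (misses concentrated above the interval), comparable to BCa (~87%)
  and better than the plain percentile interval (~84%) under identical
  conditions — an inherent underdispersion of resampled spread statistics
  at small $n$, not an implementation artefact.
- **Dual-reporter decomposition**:
  $\eta_{int}^2 = \langle(c_1-c_2)^2\rangle / (2\langle c_1\rangle\langle
  c_2\rangle)$, $\eta_{ext}^2 = (\langle c_1 c_2\rangle - \langle
  c_1\rangle\langle c_2\rangle)/(\langle c_1\rangle\langle c_2\rangle)$,
  $\eta_{tot}^2 = \eta_{int}^2+\eta_{ext}^2$ exactly.  Channels are
  mean-normalised by default so unequal gains (e.g. nucleus vs cytoplasm of
  one reporter) do not masquerade as intrinsic noise; a negative sampling
  estimate of $\eta_{ext}^2$ is kept as a signed square with
  $\eta_{ext}=0$ and a flag.
- **Pearson test**: $t = r\sqrt{(n-2)/(1-r^2)}$, two-sided $p$ from the $t$
  distribution; verified against worked small-sample values (e.g.
  $|t| = 0.54$ at $r=-0.3542$, df 2) and scipy as an independent oracle.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study geometry — 6-min frames over 6 h
post-induction, 14 conditions log-spaced over maturation times 10–140 min,
16–130 cells per condition (50 in the recovery suites), two-colour
snapshots of 245 cells — with lognormal cell-to-cell variability in $k$
(CV 0.3) and maturation time (CV 0.2 by default; the noise-vs-rate recipe
uses $0.45\sqrt{10/T}$, the time-averaging square-root law anchored at the
fast end of the measured range), multiplicative lognormal measurement noise
(2% default; the magnitude is a free choice, exposed in config), and
additive background offsets.  Per-cell substreams are keyed by cell index,
so growing a dataset never reshuffles existing cells.

It does **not** emulate: segmentation/tracking errors, photobleaching,
protein degradation, cell division, mis-specified kinetics (every synthetic
cell follows the fitted model exactly), or camera noise floors.  Passing
recovery tests therefore demonstrate estimator correctness and precision
under the stated noise model, not robustness to model misspecification.

## Problem sizes and numerical defaults

Test and acceptance workloads use: 100 ODE-oracle parameter sets; 14 × 50
cells for recovery; 1,000–2,000 cells × 2,000 molecules for the
constant-rate oracle and scheme comparison; 100 cells × 2,000 molecules per
sweep condition with 3 seeds for the rate sweep (trend assessed on the
per-condition CVs averaged over the seeds); 500 simulations × B=2000 for
bootstrap coverage.  Key defaults: $\alpha=0.03$/min; $R^2$ gate 0.98; MAD
cutoff 3 with scale 1.4826; $k_3$ bounds $[10^{-4},2]$/min; rate floor
$10^{-6}$/min; grid lag = base maturation time / 100; bootstrap B = 2000.

## Known limitations

- $\alpha$ is assumed, not measured; a misestimated $\alpha$ biases $k$ but
  affects $k_3$ only weakly (it enters $F_i$ through the same basis).
- The white-noise environment has no autocorrelation at the grid scale; an
  exponentially correlated series generator would be the natural extension
  for sensitivity analysis.
- The copy-number susceptibility question (above) is scheme-dependent and
  is reported, not resolved.
- BC bootstrap intervals undercover for spread statistics at small $n$
  (quantified above).
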