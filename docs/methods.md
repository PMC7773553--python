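# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the known limitations.

## Survival model

Lifespan T in one environment × genotype cell follows Weibull(λ, k)
(scale in days, shape dimensionless; mean λ·Γ(1+1/k)). Trial-to-trial
variability enters as log-normal perturbations of both parameters per
batch b: λ_b = λ·exp(σ_λ u_b), k_b = k·exp(σ_k v_b) with u, v ~ N(0, 1)
(non-centered parameterization). The likelihood of a right-censored animal
is the survival function S(t) = exp(−(t/λ_b)^k); this marginalizes the
truncated-Weibull imputation a data-augmentation sampler would perform.
When deaths are scored at daily transfer points, `day_resolution=1.0`
replaces the point density with the interval probability
S(d−1) − S(d); without it the recorded (rounded-up) day biases the scale
by about +0.5 day, i.e. ≈3 % of a 18-day mean — measurable against the
generator's ground truth.

Priors are flat but bounded for propriety: λ ∈ (0, 10³] days,
k ∈ (0, 50], σ_λ, σ_k ∈ (0, 2]. At the sample sizes used (≥150 animals
per cell) the bounds are never active.

Sampling uses an affine-invariant ensemble (emcee) with a
differential-evolution move mixture (DEMove 0.8 / DESnookerMove 0.2) —
the default stretch move mixes poorly in the funnel between the batch-SD
hyperparameters and the batch effects. Hierarchical groups get twice the
configured iterations. Walkers are grouped into 8 pseudo-chains and
convergence is declared at split-chain R̂ < 1.05 on every parameter.
With only 3 batches the posteriors of σ_λ, σ_k are diffuse and
heavy-tailed; their R̂ converges slowly and can sit at 1.05–1.15 at the
default chain length for the smallest groups, while the top-level scale
and shape (the decodable quantities) converge much faster. The per-
parameter R̂ values are always written to the posterior summary.

Derived posteriors are computed per draw: mean lifespan λ·Γ(1+1/k) from
the top-level parameters; the dynamic range across foods as the per-draw
max−min of the mean-lifespan draws. The overlap between two posteriors is
min(p, 1−p) with p the fraction of randomly paired draws where the first
exceeds the second; ties count one half, so a distribution compared with
itself scores exactly 0.5. Kaplan–Meier curves (ties: deaths before
censorings) come from lifelines.

## Expression model

Recorded fluorescence F of a reporter in channel c at imaging time τ is
F = f·(C₁ᶜ + C₂ᶜ·τ), with the drift coefficients estimated by Bayesian
linear regression of bead-standard fluorescence on time (flat prior on
(C₁, C₂, log σ²) → normal-inverse-χ² posterior, sampled exactly).
Normalization divides by the posterior-mean factor; drift uncertainty is
small relative to the biological layers, and full propagation can be
emulated by re-normalizing per posterior draw. Bead brightness is
normalized to 1 at zero drift so the regression returns the factor
directly.

Normalized 3-cell expression y (tph-1@NSM, tph-1@ADF, daf-7@ASI) in one
condition follows a two-layer hierarchy:

    m_b ~ N(μ, Σ_batch),   y_i ~ N(m_{b(i)}, Σ_pop).

The Gibbs sampler uses conjugate updates (multivariate normal for m_b and
μ; inverse-Wishart for both covariances, df = d+2, scale = 10⁻³ ×
diag(sample variance) — proportional to the data scale, which makes the
posterior exactly equivariant under a global rescaling of fluorescence
units). After each centered sweep, μ is re-drawn holding the batch
*offsets* fixed (an interweaved, non-centered step); this removes the slow
random walk between μ and the batch means and brings the mean parameters
to R̂ ≈ 1.00 within a few hundred sweeps. Covariance entries are weakly
identified with 3 batches and heavy-tailed; convergence is therefore
reported separately for the means (`max_rhat_mu`). A single-batch group
fixes Σ_batch = 0 with a logged warning.

The decoding response model for a condition is N(μ̂, Σ̂_batch + Σ̂_pop)
(posterior means; the layers add in quadrature), plus a ridge of
10⁻⁸ × trace for full rank.

## Decoding

Responses are decoded to the stimulus with maximal likelihood under the
per-stimulus densities; exact ties are broken uniformly at random with a
seeded generator, which keeps chance-level performance at exactly 1/K in
expectation. The confusion matrix row-normalizes decoded counts per true
stimulus, and decoding power is the unweighted diagonal mean (a weighted
variant is available). Posterior uncertainty of the power is obtained by
rebuilding the response models from individual posterior draws and, by
default, decoding fresh responses simulated from that draw's models
(decoding the fixed observed set is the alternative). Lifespan decoding
uses uncensored records only. A leave-one-out variant recomputes the
power with each stimulus removed.

## Network model

The joint activity state of (ADF, ASI, NSM) = (x, y, z) lives on the
8 corners of a cube, ordered 1 = (0,0,0), 2 = (1,0,0), 3 = (0,1,0),
4 = (1,1,0), 5 = (0,0,1), 6 = (1,0,1), 7 = (0,1,1), 8 = (1,1,1). Only
single-neuron flips are allowed. Every ON switch has the reference rate
kon (fixed at 1; exposed for sensitivity checks). The OFF switch of
neuron β from state s has rate w_ββ · Π_{α active, α≠β} w_αβ, so entries
above 1 accelerate switch-off (negative regulation) and entries below 1
are positive regulation; 1 means no edge. The stationary distribution
solves the balance equations with the normalization row substituted; the
residual must be below 10⁻¹⁰, and the solver is validated against direct
long-time integration of the Master equation (agreement ≤ 10⁻⁸ on 100
random matrices) and against the decoupled closed form
Q_n = kon/(kon + w_nn) when all cross terms are 1.

Knockouts delete all edges *arising from* the cells that express the gene
and keep incoming edges (the promoter, hence the readout, is still
present): daf-7⁻ resets row y (t₄,t₅,t₆); tph-1⁻ resets rows x and z;
the double mutant resets all nine, making its marginals exactly 1/2.
Observed ratios pair each mutant batch with the same-batch wild-type
control; the per-pair ratio of batch mean expression is summarized by its
across-pair mean R and SD σ. The cost
H(w) = Σ (R̄−R)²/σ² (9 terms) is minimized in log-w space by multi-restart
greedy stochastic descent (Gaussian steps σ = 0.1, 20 restarts from
log-uniform starts in [−log 10, log 10], box |log w| ≤ log 100, sign
constraints enforced by reflection), followed by a bounded deterministic
Powell refinement of the 3 best restarts — the fixed-step descent alone
demonstrably stalls at H ≈ 0.05–0.13 on noiseless data where the true
minimum is 0. The accepted-cost sequence of the stochastic phase is
non-increasing by construction. The 512-model enumeration packs all
models × restarts into one vectorized descent (a single batched 8×8 solve
per iteration) and polishes only the winning model.

### Identifiability

The knockout design constrains the nine edges unevenly. The double
mutant's ratios pin the wild-type marginals; the tph-1⁻ network retains
only row y, so t₄,t₅,t₆ face 3 clean constraints and are recovered
reliably. The remaining six edges share the six wild-type/daf-7⁻
constraints, and pairs of edges that the knockouts delete or keep
*together* — t₂ (ADF→ASI) with t₈ (NSM→ASI), and t₃ (ADF→NSM) with t₇
(NSM→ADF) — trade off along nearly cost-flat directions. Consequences,
measured on synthetic ratio data (replicate noise CV 0.1):

* magnitudes along the flat directions are not recoverable even from
  noiseless ratios (signs are, at the exact optimum);
* with 24 paired replicates, the best-fit sign model matches a random
  dense truth (|log w| ∈ [log 1.5, log 5]) on ≥8/9 edges in ≈75–85 % of
  datasets, with errors concentrated on t₂,t₃,t₇,t₈; the rate reaches
  ≈94 % only at ≈400 pairs. Because the model has as many parameters as
  ratio observations, the global minimum interpolates the noise, and a
  *better* optimizer recovers signs slightly *worse* at small pair
  counts.

Analyses that need robust sign calls should therefore read consensus
signs across conditions (as the rewiring analysis does) rather than
single-condition fits, or aggregate across the 512-model scan.

Edge classification: sign from the fitted w (neutral at exactly 1),
strength strong when max(w, 1/w) ≥ θ with θ = 2 by default (the threshold
is a reporting convention, configurable). Aggregation schemes: best fit;
geometric mean weighted by exp(−H/2); unweighted geometric mean of models
with normalized likelihood exp(−(H−H_min)/2) ≥ 0.95.

The rewiring permutation test encodes the per-condition edge signs in a
table with one column per (food, temperature). The statistic counts edges
whose per-temperature consensus (majority across food columns, ties
neutral) has opposite nonzero signs at the lowest and highest temperature
and moves monotonically through intermediate ones — a strict sign flip, so
neutral-to-sign drifts do not count. Shuffles permute the columns
uniformly; p̂ is the fraction with statistic ≥ max(1, min(observed,
min_edges)) (the floor of 1 keeps a flip-free table from matching
trivially). The shuffle loop is vectorized and 10⁵ shuffles of an
18-column table take a few seconds.

## Synthetic data

The generators emulate the *structure* of the worm study, not its
empirical distributions:

* **Lifespans** — Weibull scale falls from ≈24 d at 15 °C to ≈12 d at
  25 °C and declines with food (multipliers 1.2 → 0.78 across the 6 food
  levels); knockouts flatten the food response (exponent 0.5 single,
  0.15 double); shape 2; batch log-SDs 0.05; right-censoring at the end
  of an every-2-days observation schedule; deaths recorded as whole days.
* **Expression** — wild-type means around (120, 180, 250) a.u. for
  (NSM, ADF, ASI), rising with food for the tph-1 reporters and falling
  for daf-7, with the modulation amplitude growing with temperature;
  mutant means are the wild-type means times the Master-equation ratios
  of the condition's ground-truth network, so the expression and network
  layers are mutually consistent. Noise: batch CV 8 %, population CV
  20 %, inter-cell correlation 0.3 (equicorrelation, hence PSD by
  construction). Drift: factor 1.2 − 0.01·τ applied to both channels;
  beads report the factor with 0.5 % noise at ≥3 timepoints per batch
  range.
* **Default grid** — 6 foods × 3 temperatures × 4 genotypes, 3 batches of
  50 animals per cell: large enough for recovery tests, small enough for
  continuous integration. The network-inference study uses 6 batches,
  because an SD estimated from 3 pairs is too unstable to weight the
  cost. The ground-truth network flips its three ASI-converging edges
  (t₂, t₅, t₈) between the cold and warm end of the temperature range and
  keeps the six other edges fixed.
* **Ratio observations** — multiplicative log-normal replicate noise with
  unit mean and configurable CV; 24 paired replicates in the recovery
  calibration (the scale of a high-throughput imaging campaign).

What passing tests do **not** show about real data: real lifespan hazards
are not exactly Weibull, real expression is right-skewed rather than
Gaussian on the linear scale, LED drift need not be linear over long
campaigns, and real batch effects are not log-normal. The recovery
results certify the estimators under the assumed structure, not the
structure itself.

## Reproducibility and problem sizes

A single global seed is fanned out to named per-stage substreams
(`stage_seed`), so stages can be rerun independently and two runs with the
same configuration produce identical artifacts. The acceptance script
uses, per quantity: 512-model enumeration at reduced optimizer settings;
100 random matrices for the ODE oracle; 50 replicate datasets for sign
recovery; 500 animals with ≈20 % censoring for the survival recovery;
10⁴ responses per stimulus for the chance-level check; 10⁵ draws for the
overlap calibration; and the full 18-condition study with 10⁵ shuffles
for the rewiring analysis.
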