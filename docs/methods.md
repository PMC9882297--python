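# Methods

`locusdyn` analyses the joint stochastic motion and transcriptional output of
a pair of chromosomal loci — an enhancer region and a distal reporter
promoter — recorded as time series of 3-D positions (nm) and nascent
transcription intensity (a.u.) at a uniform frame interval, across a panel of
genomic separations *s* (kb). Because the package is developed against
synthetic data, every analysis stage is paired with a generator whose ground
truth it must recover; this note documents the models, the defaults and why,
the numerical choices, and what passing tests do and do not establish about
real data.

## Physical model

**Single-locus motion.** A locus embedded in a polymer subdiffuses:
M1(t) = ⟨(r(t₀+t) − r(t₀))²⟩ = Γ t^β. In the generalized Rouse framework the
dynamic exponent is tied to the packing (fractal) dimension *d* of the fiber
by β = 2/(2+d): an ideal chain (d = 2) gives β = 1/2, a crumpled globule
(d = 3) gives β = 2/5.

**Two-locus motion.** The separation vector R = r_A − r_B has
M2(t) = ⟨(R(t₀+t) − R(t₀))²⟩, which grows as 2Γt^β while the loci move
independently and saturates at 2⟨R²⟩. The crossover defines the relaxation
time τ = (⟨R²⟩/Γ)^{1/β} — the time the pair needs to diffuse across its own
typical separation. For the ideal chain (β = 1/2) the full crossover has the
closed form

    M2(t) = 2Γ√t (1 − e^{−τ/(πt)}) + 2J erfc(√(τ/(πt))),   τ = (J/Γ)²,

with J = ⟨R²⟩ the plateau half-value. Note that the two-locus diffusivity Γ
in M2 = 2Γ√t numerically equals the single-locus M1 coefficient, since
M2 = 2·M1 for independently moving loci.

**Scaling with genomic separation.** With ⟨R²⟩ ~ s^{2/d} and Γ(s) ~ s^α,
the relation Γτ^β ~ s^{2/d} gives τ ~ s^γ with γ = (2/d − α)/β. Classical
limits: ideal chain γ = 2; crumpled globule γ = 5/3; Zimm (hydrodynamic
coupling, τ ~ R³) γ = 3/d = 1 at d = 3. The anomalous regime the package is
built to quantify combines 1/d ≈ 0.31, α ≈ 0.27 and β ≈ 0.52, which plug in
to γ ≈ 0.67 — a far weaker dependence of encounter times on genomic distance
than any of the classical models. The two-locus autocorrelation
C2(t) = ⟨R(t₀)·R(t₀+t)⟩ = ⟨R²⟩ − M2(t)/2 decays as t^λ with λ = 2(1−d)/(2+d)
for t ≫ τ, and rescaling lags by s^{−γ} collapses the normalized C2 curves
across separations onto one master curve.

**Velocity cross-correlations.** Coarse-graining velocities on an interval
δ, v^(δ)(t) = (x(t+δ) − x(t))/δ, the normalized cross-correlation intercept
between the two loci follows from the increment identity
Cvv(0) = [2M1(δ) − M2(δ)]/(2δ²) and Cv(0) = M1(δ)/δ², hence
ratio = 1 − M2(δ)/(2M1(δ)), a function of δ/τ only. For the Rouse closed form
this evaluates to e^{−τ/(πδ)} − √(τ/δ)·erfc(√(τ/(πδ))); we re-derived this
expression symbolically from the identity above and verify it against
Brownian-dynamics simulation in the tests. For the stretched-exponential
family (below) the same identity gives 1 − (τ/δ)^β(1 − e^{−(δ/τ)^β}). Both
are monotone in δ/τ with limits 0 (δ ≪ τ) and 1 (δ ≫ τ); the approach to 1
is slow, ~√(τ/δ).

## Synthetic-data generators

**Rouse chain** (`simulate_rouse_chain`). Overdamped Brownian dynamics of an
ideal bead-spring chain: per axis, dx_i = −(1/t_b)(L x)_i dt + √(2D) dW with
L the chain graph Laplacian, b the RMS bond length, t_b the bond relaxation
time and D = b²/(3 t_b). Chains start from the exact Gaussian equilibrium
ensemble (iid bond vectors, per-axis sd b/√3). Defaults: b = 200 nm/bond,
10 kb/bead (so ⟨R⟩ ≈ 0.7 µm at 149 kb, matching the observed scale),
t_b = 1 s, dt = t_b/10. Euler–Maruyama is stable for dt < t_b/2; the config
enforces dt ≤ t_b/10, at which the stationary variance of the fastest modes
is still inflated by ~λdt/2 (up to a few percent on equilibrium ⟨R²⟩ — the
OU dumbbell test uses dt = t_b/100 where the bias is ~1%). Divergence (from
a deliberately large dt) raises an explicit error rather than emitting NaNs.
Useful exact references: ⟨R²⟩ = m b² for beads m apart; M1 = 2b²√(t/(π t_b));
τ_m = (m b²/Γ)² = π m² t_b/4. For tagged pairs whose τ_m approaches the
slowest internal chain time N² t_b/π², finite-chain effects depress τ, so
simulation configs keep N well above the largest tagged separation and the
recording longer than the largest τ_m.

**Gaussian-process surrogate** (`simulate_surrogate_pair`). The anomalous
regime has no closed-form microscopic model, so the surrogate samples R(t)
directly as a stationary Gaussian process per axis with autocovariance
C(t) = (⟨R²⟩(s)/3)·exp[−(t/τ(s))^β] — a stretched exponential, chosen as the
single-τ family that reproduces both required asymptotics (M2 → 2Γt^β and
→ 2⟨R²⟩). Sampling is by exact Cholesky factorization on the frame grid
(trajectories are ≤ ~200 frames, so no approximation is needed); a
non-positive-definite covariance raises with a diagnostic. Per-locus
positions are synthesized as r_A = U + R/2, r_B = U − R/2 with an
independent common-mode process U whose increment variance is
Γt^β − M2(t)/4, making the single-locus MSD exactly Γt^β and the velocity
intercept identity hold by construction. Defaults are the measured
conditions: β = 0.52, 1/d = 0.31, α = 0.27, 64 frames at Δt = 28 s (~30
min), separations {58, 149, 190, 330, 595} kb, with prefactors set so
⟨R⟩(149 kb) ≈ 700 nm and τ(149 kb) ≈ 200 s (all relaxation times then lie
inside the 30-min window).

**State kinetics** (`overlay_state_process`). Three topological states:
open/silent O_off, paired/silent P_off, paired/transcribing P_on. Pairing is
reaction-limited *given* proximity: O_off → P_off fires with rate
1.5×10⁻³ s⁻¹ only while R < 500 nm, encoding search limited by diffusion
into proximity. While paired, R is re-drawn from an OU tether (stationary
mean distance 375 nm — the observed 350–400 nm paired range, independent of
s — relaxation 60 s) while the locus midpoint continues the open-state
motion. P_off ↔ P_on is a telegraph with on = off = ln2/600 s⁻¹ (10-min
median transcriptional lifetime, ~50% conditional on-fraction); unpairing
(P_off → O_off only) at 1/720 s⁻¹ encodes the ~12-min focal-contact
lifetime. Direct O_off ↔ P_on transitions never occur.

**Measurement model** (`apply_measurement`). Isotropic Gaussian localization
noise (default 30 nm per axis per locus — a typical spot-localization
precision; the value for the source experiments is not published),
independent frame dropout (default 10%), and an intensity channel: Gaussian
background 100 ± 20 a.u. everywhere except P_on frames, which draw from
300 ± 40 a.u. (active mean 10 background-sd above background).

## Estimation

**MSDs and correlations.** Time average over all overlapping origins
(maximal-overlap estimator) per trajectory, then ensemble average weighted
by pair counts; missing frames are excluded pairwise. Uncertainties are a
bootstrap over trajectories (nuclei); the replicate curves are retained.
With `use_xy_only` the 3-D MSD is estimated as 3/2 × the planar MSD under
isotropy (off by default). C2 is computed both directly and as
⟨R²⟩_pairs − M2/2 over the same origin pairs; the two agree to machine
precision on gap-free data and both are stored. No localization-noise offset
is subtracted by default.

**Bayesian M2 fits** (`fit_rouse_m2`). Two model families: the ideal-chain
closed form (β fixed at 1/2 by default; a free-β variant exists for
sensitivity analysis) and the stretched-exponential family
M2 = 2J(1 − e^{−(t/τ)^β}), which matches the surrogate's generating process
and serves as a general empirical crossover model. The likelihood is a
multivariate Gaussian on log M2 over a log-spaced subset of ~12 lags with
the covariance estimated from the bootstrap replicates (plus a 0.1% ridge):
MSD values at different lags share trajectories and are strongly
correlated, and an independent-lags likelihood yields drastically
overconfident posteriors (~30% coverage of nominally 95% intervals in our
calibration runs; the covariance-aware likelihood restores 90–100%).
Priors are log-uniform over 6 decades centered on moment-based guesses
(Γ from the first lag, J from half the curve maximum). Sampling: emcee, 24
walkers × 1500 steps, 500 burn-in, fixed seed; an acceptance fraction
outside (0.1, 0.9) flags non-convergence. τ is derived per posterior draw,
so the τ = (J/Γ)² identity holds draw-wise; reported intervals are 16–84%
and 2.5–97.5% quantiles.

**State inference** (`fit_hmm`, `decode_states`). Three-state HMM on
(distance, intensity). Distance emissions are Maxwell-type radial densities
(the magnitude of an isotropic 3-D Gaussian), p(r) ∝ r²σ⁻³e^{−r²/2σ²}, with
a state scale σ; intensity emissions are Gaussian with the background
component shared by O_off and P_off. O_off ↔ P_on entries of the transition
matrix are structurally zero. Masked frames contribute unit emission
likelihood (marginalized). Fitting is Baum–Welch over all trajectories
jointly, initialization by an intensity split (frames > background mean + 5
background sd are unambiguously transcribing, hence paired; their distances
anchor the paired scale) with distance-tercile fallback, 5 restarts keeping
the best likelihood, convergence at relative log-likelihood change < 1e-8
or 500 iterations. The two paired distance scales are tied (paired geometry
is transcription-independent) and, by default, held fixed at the
intensity-anchored estimate during EM: the emission model assumes frames
are independent given the state, which polymer distance series are not, and
an unconstrained EM exploits that misspecification by widening the hidden
P_off state to absorb temporally correlated low-distance excursions of the
open state (likelihood rises, decoding accuracy falls). Anchoring the
paired scale on the unambiguous transcribing frames removes that failure
mode; `paired_scale="free"` restores plain EM. Decoding returns both
forward–backward posteriors and the Viterbi path; downstream kinetics use
Viterbi. Label switching is resolved by the open-scale > paired-scale
ordering at initialization; a violated ordering after fitting is flagged,
never silently relabeled.

**Dwell-time statistics.** Maximal state runs become dwells (run length ×
Δt); runs touching a trajectory boundary or a masked gap are censored
rather than stitched — an unseen state change cannot be excluded. Survival
curves use the Kaplan–Meier product-limit estimator (lifelines), with
deaths processed before censorings at tied times and the median defined as
the earliest t with S(t) ≤ 0.5; confidence bands are lifelines'
exponential-Greenwood intervals, built on the Greenwood variance. Lifetimes
are also estimated by censoring-aware exponential maximum likelihood
(rate = events / total exposure; CI from the Fisher information of the log
rate). Pairing probability P(s) is frame-weighted (not
trajectory-weighted), with bootstrap errors over nuclei; the conditional
on-fraction is restricted to paired frames and reported missing where a
separation has none.

**Power-law fits.** Weighted least squares of log₁₀y on log₁₀x with
relative errors mapped to log-space; exponent SE from the weighted
covariance (residual-based for unweighted fits, so an exact power law
reports SE 0).

**Data collapse** (`collapse_gamma`). Curves rescaled to
(t·s^{−γ}, C2/⟨R²⟩), interpolated onto a common log-lag grid restricted to
the overlap region; score = mean pointwise variance across curves; γ grid 0
to 3 step 0.05 with local refinement at step 0.005 (γ values that destroy
the overlap score as +∞; only a fully non-overlapping family errors out).
The γ uncertainty is a leave-one-curve-out jackknife. Recovery of an exact
collapse is limited by interpolation bias of order the coarse grid step.

**Pipeline.** simulate → infer → kinetics → dynamics → report, one YAML
config, one global seed from which per-stage substreams are derived
(SeedSequence), delimited-text tables plus a config snapshot per run;
stages re-run from intermediate tables. Dynamics are computed on frames
decoded O_off (excised paired frames become pairwise-excluded gaps),
matching the analysis convention for the anomalous-scaling measurement; the
velocity interval δ (default 300 s) is snapped to the nearest multiple of
the frame interval (308 s at Δt = 28 s). On surrogate-type data the
pipeline fits the stretched family and predicts velocity intercepts with
the matching stretched-form master curve; on Rouse-type data it uses the
ideal-chain closed form.

## Problem sizes

Defaults were chosen so a full synthetic study runs on a laptop-class
single core: 64-frame recordings, 100–200 trajectories per separation, five
separations; Rouse runs use ~100 chains of 96–256 beads with recordings a
few times the largest tagged-pair relaxation time (the {8,16,32,64}-bead
panel uses a longer, coarser-sampled recording for the two largest
separations so every τ lies inside its observation window). The acceptance
script regenerates everything it reports at these scales.

## What the synthetic tests do and do not show

The generators reproduce the statistical structure the estimators rely on —
subdiffusive Gaussian motion with a plateaued separation process, state
kinetics with proximity-gated pairing, localization noise, dropouts, an
intensity channel — and every headline quantity is recovered from them with
known ground truth. They do **not** emulate: non-Gaussian displacement
statistics or heterogeneity between nuclei; drift, chromatic or
motion-correction residuals (corrected positions are an input by design);
intensity bleaching or background drift; time-varying kinetics across the
nuclear cycle; or a microscopic mechanism for the anomalous exponents (the
surrogate imposes them). Passing tests therefore establish estimator
correctness and calibration under the stated model, not the biological
conclusions themselves.

## Known limitations

* The HMM's iid-emission assumption is violated by construction (polymer
  distances are autocorrelated); the anchored paired scale is a pragmatic
  guard, and decoding accuracy degrades at small separations where open and
  paired distance distributions overlap most (~75% at 58 kb vs ~93% at
  595 kb on defaults; ~89% pooled).
* Euler–Maruyama discretization inflates fast-mode variances by ~λdt/2 at
  the default dt = t_b/10 (few percent on statics); halve dt where that
  matters.
* Kaplan–Meier medians are reported without an interpolation convention
  beyond S(t) ≤ 0.5; with Δt = 28 s frames, medians are quantized to the
  frame grid.
* The stretched-exponential surrogate is one of many covariance families
  with the required asymptotics; quantities sensitive to the detailed
  crossover shape (e.g. the velocity intercept at δ ≈ τ) are
  family-dependent at the few-percent level.
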