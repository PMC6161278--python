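# Methods

## Electro-diffusion model

All ionic fluxes follow the constant-field (Goldman–Hodgkin–Katz) formalism
restricted to monovalent ions. The reversal potential of a membrane
permeable to K⁺, Na⁺ and Cl⁻ is

    E_rev = (RT/F) ln[(P_K[K]o + P_Na[Na]o + P_Cl[Cl]i) /
                      (P_K[K]i + P_Na[Na]i + P_Cl[Cl]o)]

and per-ion current densities follow the GHK flux equation, with the
removable singularity at V = 0 evaluated by a first-order series (switch at
|zFV/RT| < 10⁻⁶). Outward current is positive. Divalent ions are rejected by
construction: Ca²⁺/Mg²⁺ (1.8 mM each in the recording solutions) and the
7.2 mM Cl⁻ they contribute are excluded from GHK bookkeeping, matching the
nominal monovalent-salt accounting of the bath recipes; pH-titration
Na⁺/K⁺ is likewise ignored (unquantified). Gluconate⁻ and
N-methyl-D-glucamine⁺ are treated as strictly impermeant, which is the
purpose of those substitution ions.

Temperature defaults to 293.15 K (the 20 ± 2 °C recording condition);
R and F are CODATA values, giving RT/F = 25.2617 mV.

**Internal concentrations.** Oocyte internal activities were not measured;
the defaults [K]i = 110, [Na]i = 10, [Cl]i = 33 mM are typical Xenopus
oocyte values. They are explicit inputs, echoed in every report: the
permeability-ratio solver is exercised as a round trip (forward model →
inversion) precisely because absolute reversal potentials depend on this
assumption.

## Permeability-ratio inversion

Given ≥ 2 bath conditions with measured reversal potentials, the solver
minimizes Σ w_c (E_model − E_meas)² over log-ratios (positivity by
construction), with w_c = n_c/SD_c² when dispersions are provided, else 1.
Three starts spanning ratios 10⁻³–10¹ guard against boundary minima;
tolerances are set to machine level (ftol = xtol = gtol = 10⁻¹⁵) so noiseless
round trips are exact to ~10⁻¹⁰. The linearized covariance of the log-ratios
s²(JᵀJ)⁻¹ is reported; truly impermeant ions drive their log-ratio to the
lower bound (ratio ≈ 10⁻¹³), correctly indistinguishable from zero. Which
conditions enter the fit, the internal composition, and the weighting are
all caller-supplied rather than assumed.

## Gating and kinetics

Steady-state activation is the modified Boltzmann curve with a
voltage-independent floor Pmin; the exponent sign is such that
hyperpolarization opens the channel (P → Pmax as V → −∞). After a voltage
step the open probability relaxes as dP/dt = (P∞ − P)/τ, i.e.
mono-exponentially; τ is the e-fold time constant of the printed exponential
form I(t) = A·e^(−t/τ) + I∞ (the source material also calls this quantity a
"half-activation time", but the printed formula is unambiguous and the
e-fold reading is used). The coefficient A is the amplitude of the decaying
term, so the literal t = 0 value is A + I∞ — the only reading that makes
the formula self-consistent.

Reference gating values used as generative defaults: zδ = 0.016,
V0.5 = −62 mV, Pmin = 0.43, Pmax = 1, τ = 0.59 s. (A floor of 0.46 is also
quoted in the source's discussion; the results-section value 0.43 is taken
as canonical for all fixtures.)

## Estimators

Both fitters use `scipy.optimize.least_squares` with analytic Jacobians,
machine-level tolerances, data-driven initialization (Pmax ← max Po,
Pmin ← min Po, V0.5 ← voltage nearest mid-range Po, zδ ← 0.01; I∞ ← tail
mean, A ← first sample minus I∞, τ ← e-fold crossing with a grid fallback)
and five seeded, jittered restarts before declaring non-convergence. τ is
optimized in log-space to enforce positivity. The analytic Jacobian matters:
with zδ ~ 0.016 the Boltzmann curve is nearly linear over the protocol range
and the four parameters are strongly correlated, so recovery to 10⁻³
requires driving the residual to machine precision.

95% confidence intervals default to the linearized covariance
s²(JᵀJ)⁻¹ with the t-quantile (how the original intervals were computed is
not stated; the method is always named in reports); a seeded residual
bootstrap (default 1000 replicates) is available and agrees with the
linearized intervals within a few tens of percent on well-conditioned data —
a documented diagnostic, not a guarantee. A fit whose zδ interval spans zero
is flagged non-identifiable; flat inputs yield flagged results rather than
exceptions so cohort pipelines keep running. Pmax is a free parameter by
default (fitting it guards against normalization artifacts); a flag pins it
at 1.

## Measurement conventions

Steady-state current is the mean of the last 10% of each step (200 ms of
2 s — the residual relaxation bias after > 3τ is < 1%; the original window
is unstated). Instantaneous current is a 10 ms window starting 5 ms after
onset. No leak subtraction is performed by default (raw currents are
reported, with water-injected cohorts as reference); chord-conductance Po
excludes points within ±5 mV of E_rev to avoid the singularity — at 20 mV
grid spacing at most one point is lost. Po can be computed from the
group-mean I–V (default, matching the figure-style presentation) or
per-oocyte then averaged (flag).

## Statistics

Student's t-test is the classical pooled-variance two-tailed test (Welch
optional). Dunnett's many-to-one procedure uses the statistic
t_i = (x̄_i − x̄_0)/√(MSE(1/n_i + 1/n_0)) with MSE pooled over all groups,
and obtains critical values from a seeded Monte-Carlo sample of the null
max|t_i| distribution (default 10⁵ draws) — simpler and directly testable
against both a 10⁶-draw oracle and the multivariate-t implementation in
scipy, which serves as an independent cross-check only. Per-voltage testing
replicates the figure presentation; no across-voltage multiplicity
correction is applied, so over nine voltages roughly one false positive per
two null contrasts is expected and observed.

## Simulator

Per sweep: I(t) = gain · a_oocyte · P(t) · I_GHK(V) + g_leak(V − E_leak) +
rectifier(V) + ε. Defaults, chosen once as realistic for oocyte batches:

| parameter | default | rationale |
|---|---|---|
| P_K (absolute) | 5×10⁻⁷ cm/s | with 0.2 cm² area gives ~−2 µA at −100 mV |
| membrane area | 0.2 cm² | effective oocyte surface incl. microvilli |
| g_leak, E_leak | 1 µS, −40 mV | −0.06 µA at −100 mV, the background level |
| noise SD | 0.02 µA | sample-level recording noise |
| amplitude CV | 0.3 | lognormal per-oocyte expression variability |
| co-ion threshold | 5 mM | both Na⁺ and K⁺ required externally |

The Na⁺+K⁺ co-presence requirement is encoded phenomenologically as a gain
switch (its mechanism is unresolved); the 9.6/9.6 mM substitution bath stays
above the threshold, so reduced current there arises from the GHK driving
term only. The endogenous outward rectifier (seen in high-K⁺ baths) is an
instantaneous conductance with Boltzmann activation above ~0 mV (V½ = +20 mV,
slope 15 mV) — no kinetics are modeled because none are characterized.
Gating starts each step from the holding-potential steady state; the ~3%
re-equilibration error after a 2 s inter-step interval is neglected. Noise
is i.i.d. Gaussian per sample; no capacitive transients are synthesized
(analysis windows exclude step onsets).

What the simulator does **not** emulate — and what passing tests therefore
do not show about real recordings: series-resistance and space-clamp error,
capacitive/transient artefacts, slow inactivation of outward current,
channel (stochastic gating) noise, rundown or time-dependent drift, and any
Ca²⁺ or other-alkali-cation permeation.

## Problem sizes and numerical choices

The demo study uses 4–6 oocytes per cohort and the standard nine-step
protocol at 1 kHz (2000 samples/sweep) — miniature but preserving every
contrast the analysis consumes; the whole study runs in under a second.
Monte-Carlo defaults: 10⁵ Dunnett null draws, 2000 calibration experiments,
200 kinetics-noise replicates. All RNG streams derive from explicit seeds
(cohort members keyed on (seed, oocyte index)); study outputs use fixed
float formatting so identical seeds reproduce tables byte-identically.

## Known limitations

End-to-end refitting of the four-parameter Boltzmann curve from noisy
chord-conductance Po is poorly identified when the true gating is as weak as
zδ ≈ 0.016: the GHK chord curvature and cohort noise dominate the ~1.4%
gating modulation, and the pipeline reports the fit with its
non-identifiability flag set. Exact recovery is demonstrated on noiseless
curves; confident recovery from realistic noisy cohorts would require far
larger n or a steeper channel (zδ ≳ 0.5 recovers cleanly). Reversal-potential
estimates from the 20 mV grid carry up to ~2 mV interpolation bias plus a
small leak-induced shift, which propagates into the demo study's recovered
permeability ratios (Na within ~15%, Cl biased upward); the solver itself is
exact given exact reversal potentials.
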