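# Methods

## Kinetic model

The body is treated as one well-mixed compartment with first-order uptake
and loss. After an i.v. bolus, blood concentration decays as
`C(t) = (dose/V)·e^(−k_e t)`; after an oral dose it follows the Bateman
curve `C(t) = (dose/(V/F))·k_a/(k_a−k_e)·(e^(−k_e t) − e^(−k_a t))`. Only
the ratio V/F is identifiable from oral data; an i.v. arm (F ≡ 1) pins V
and hence lets bioavailability be estimated from the dose-normalised AUC
ratio. Rate constants are stored in h⁻¹ everywhere; half-lives are reported
in minutes (`60·ln 2 / k`); the single h⁻¹→min⁻¹ conversion sits inside the
body-burden module. The removable singularity at k_a = k_e is handled by
the analytic limit `(dose/(V/F))·k·t·e^(−kt)`, switched on when
|k_a−k_e|/k_e < 1e−8.

**Flip-flop identifiability.** The oral curve is invariant under exchanging
k_a and k_e *provided* the amplitude is rescaled: the triples
(k_a, k_e, V/F) and (k_e, k_a, V/F·k_e/k_a) trace identical curves. The
shape alone therefore cannot say which rate is absorption. Fits report the
k_a > k_e branch — consistent with every group mean in the underlying study
— and flag when the optimiser landed on the mirror branch.

## Fitting

Each individual is fitted separately by damped (Levenberg–Marquardt) least
squares on residuals weighted by 1/C_obs, i.e. minimising
Σ (C_obs − C_pred)²/C_obs. Reciprocal-concentration weighting is near
maximum-likelihood when measurement error is proportional to the signal,
which is also the noise model of the synthetic generator — the two choices
are deliberately consistent. Observations recorded as 0 (below the
quantification limit) have no defined 1/C weight; they are excluded from
the objective and counted in the fit diagnostics.

Starting values are deterministic: k_e from the log-linear slope of the
last three positive observations, k_a by the method of residuals (curve
stripping), V/F from dose/(AUC_trapezoid·k_e). Standard errors come from
the Gauss–Newton approximation s²(JᵀJ)⁻¹ with s² = WRSS/(n−p), and 95 %
confidence intervals use the Student-t quantile at n−p degrees of freedom;
a parameter is flagged non-significant when its CI includes zero.
Non-convergent fits are returned with diagnostics, never dropped silently,
so group summaries remain reproducible.

Model order is checked with `AIC = n·ln(WRSS) + 2p` (the convention of
classical PK fitting software; only differences matter) against a
biexponential two-compartment comparator fitted under the same weighting —
for oral data with first-order input constrained to C(0) = 0. Both
compartmental AUC (dose/((V/F)·k_e), the default) and trapezoidal AUC are
available, since study reports rarely say which was used.

## Body-burden model

Two pools — gut contents and everything else ("internal") — advanced by
forward Euler with Δt = 1 min:

    D_gut  ← D_gut + I·Δt − k_a·Δt·D_gut·F
    D_int  ← D_int + k_a·Δt·D_gut·F − k_e·Δt·D_int

with both transfers evaluated at the pre-update state and
D_gut(0) = D_int(0) = 0. I(t) is piecewise-constant over feeding bouts. The
absorption term is identical in the two equations, so whatever leaves the
gut enters the body and mass balance
(ingested = gut + internal + eliminated) closes to accumulation round-off
for *any* F; with F < 1 absorption is merely slowed, no separate unabsorbed
pool arises from these update rules. Step sizes with k·Δt ≥ 1 (min⁻¹) are
refused as unstable. The recurrences are evaluated as linear IIR filters,
bit-identical to the explicit loop but vectorised.

An exact continuous-time solution (matrix exponential of the affine system,
composed across bout boundaries) serves as the independent oracle: at
Δt = 0.01 min the Euler trace agrees with it to within 0.05 % of the peak
on all four reference scenarios, and the error halves when Δt halves
(first-order convergence). At the working Δt = 1 min the discretisation
bias on the bolus peak is ≈ +0.5 % relative to the continuous maximum
(≈ 1189 vs ≈ 1183 mg kg⁻¹ bw); published spreadsheet implementations of
the same difference equations differ by a comparable margin depending on
their update ordering, which is why scenario peaks are compared at a 2 %
tolerance rather than exactly.

Default horizon is the last bout end + 24 h (≈ 6 elimination half-lives at
k_e = 0.25 h⁻¹), well past any peak. The four reference scenarios deliver
the rat oral LD₅₀ (1563 mg kg⁻¹ bw) as: a 1-min bolus; constant feeding
over 2 h; constant feeding over 4 h; and two 1-h bouts separated by a 4-h
pause. Exact bout rates (total/duration, e.g. 13.025 mg kg⁻¹ min⁻¹ for
2 h) are the default; a `literal_rates` switch reproduces the rounded rates
quoted in study summaries (13, 6.5), whose 0.2 % dose shortfall is
tolerated by the scenario validator (0.5 % reconciliation band). Worst-case
kinetics — highest group-mean k_a (2.2 h⁻¹, low-dose oral rats) with lowest
group-mean k_e (0.25 h⁻¹, oral rats) and F = 1 — maximise the predicted
peak and are the protective default for risk use.

## Synthetic data

Real individual-level data from the rat ADME study are unpublished, so the
generator emulates the design: five groups (i.v. 0.5; oral 0.5 and
100 mg kg⁻¹ bw under two radiolabel tags) of three males and three females,
sampled at 0.25–48 h. Individual parameters are lognormal with natural-scale
mean and SD moment-matched to the published group summaries. V/F is never
printed in such summaries; its mean is recovered from the compartmental
identity V/F = dose/(AUC·k_e) applied to group means, and its CV is taken
from the AUC CV (at a common dose the AUC spread is, to first order, the
V/F spread). Measurement noise is multiplicative lognormal with CV 10 % — a
typical radio-assay precision and the regime in which 1/C weighting is the
right choice — and values below a 5 ng ml⁻¹ LOQ are censored to zero, which
reproduces the observed behaviour that low-dose blood levels fall below
quantification within 24 h. Radiolabel position is an inert tag; sex enters
only through group assignment. The true between-animal distribution shape
is unknown — lognormal is an assumption; passing tests therefore show the
estimators work under proportional-noise, lognormal-variability conditions,
not that the real study's residual structure is captured (no assay drift,
no within-animal correlation, no body-mass covariate).

Tissue panels assume instant tissue–blood equilibrium (tissue = partition
coefficient × blood), matching the empirical blood–tissue correlation
(r ≥ 0.9) that justified collapsing the body to a single compartment.

## Numerical and design choices

- Fitting is unconstrained in the natural parameter space (CI-includes-zero
  significance only makes sense there); positivity violations would surface
  as non-significant or non-converged fits rather than being clamped.
- The bolus is one 1-minute bout at 1563 mg kg⁻¹ min⁻¹ — the literal
  "eaten during 1 min" reading — so the full dose sits in the gut after the
  first step.
- Euler transfer uses the pre-update gut amount; alternative orderings move
  the bolus peak by ≲ 0.5 %, inside the 2 % comparison band.
- Group summaries use the n−1 SD and skip empty groups with a warning; a
  single-fit group reports an undefined SD rather than zero.
- Test problem sizes (500-replicate coverage runs, 40/20-replicate AIC
  ranking majorities, Δt = 0.01 min oracle grids subsampled every 20 s) were
  chosen to make the statistical checks sharp at interactive runtimes.

## Known limitations

No metabolite kinetics, saturable processes, PBPK structure, toxicodynamics
or growth dilution; feeding scenarios use piecewise-constant intake only.
Pooled rate-constant means computed from *rounded published group means*
can differ in the last printed digit from values pooled over raw individual
estimates (e.g. oral k_e: 0.24 from the printed means vs 0.25 published);
the discrepancy is a rounding artefact of the available inputs, not of the
pooling.
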