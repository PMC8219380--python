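# Methods

## The kinetic proofreading model

A pMHC ligand L binds a TCR R at rate k_on (µM⁻¹s⁻¹) to form a complex
C₀. The complex must traverse N sequential biochemical steps, each at
rate k_p (s⁻¹), before reaching the signalling state C_N; the ligand can
dissociate at rate k_off (s⁻¹) from any step, resetting the chain. The
mass-action ODE system for (L, R, C₀…C_N) closes under the two
conservation laws L₀ = L + ΣC_i and R₀ = R + ΣC_i. Its steady state is

    C_tot = [L₀ + R₀ + k_off/k_on − √((L₀ + R₀ + k_off/k_on)² − 4·L₀·R₀)] / 2
    C_N   = (1 + k_off/k_p)^(−N) · C_tot .

One printed form of the terminal rate equation in circulating derivations
duplicates the C₀ equation; the unique terminal ODE consistent with the
steady state above is dC_N/dt = k_p·C_{N−1} − k_off·C_N (the final step
is fed by the chain and drained only by unbinding). The implementation
uses this form, and the test suite verifies the closed form against
direct ODE integration to < 10⁻⁸ relative error over 10³ random
parameter draws.

N is permitted to be non-integer in all analytic formulas (interpretable
as a mixture of chain lengths when an intermediate step survives ligand
unbinding); stochastic simulation requires integer N.

## From steady state to ligand potency

A T cell activates when C_N/R₀ exceeds a threshold λ. Writing x = L₀/R₀
and introducing conversion constants γ (model dose → experimental dose)
and δ (model affinity → experimental K_D), the dose that exactly reaches
threshold is, with B = (1 + k_off/k_p)^N,

    x = (λB/γ) · [1 − δ·K_D / (λB − 1)] ,   valid iff λB < 1.

Fitting uses the orthogonalised parameters λ̂ = λ/γ and δ̂ = δ/γ and the
log form

    ρ = log₁₀(λ̂) + N·log₁₀(1 + k_off/k_p)
        + log₁₀(1 − δ̂·K_D / (λ̂B − 1/γ)) ,

with k_off = k_on·K_D at a fixed k_on = 0.0447 µM⁻¹s⁻¹ (the average
TCR/pMHC on-rate at 37 °C; on-rates vary little between single-residue
peptide variants, so K_D differences are carried by k_off). The two
expressions are algebraically identical; a 10³-draw equivalence test
enforces this, which also pins down the typographically fragile final
log term.

**Reachability.** The threshold is attainable at *some* dose iff
λB < 1 — equivalently λ̂γ(1 + k_off/k_p)^N < 1. For λB < 1 the final log
argument is automatically positive, and for λB ≥ 1 no dose suffices
(C_N ≤ R₀/B even at saturation). The implementation flags such ligands
as "unreachable" rather than returning the spurious root that the
formula would produce; during fitting any parameter set rendering an
observed data point unreachable receives infinite distance.

## Hierarchical annealed Metropolis–Hastings fit

Multi-experiment potency tables are fitted with global (N, γ, δ̂) and
per-experiment (k_p, λ̂) parameters — 3 + 2I parameters for I
experiments. The distance is the summed squared log₁₀ residual
D(Θ) = ΣᵢΣⱼ (ρ(…; K_D,ij) − log₁₀ P_ij)².

Each chain starts at a prior draw (uniform in log₁₀ for all parameters
except N, which is uniform-linear on (0, 4); plate priors:
log₁₀k_p ∈ (−1, 1), log₁₀λ̂ ∈ (−4, 1), log₁₀γ ∈ (−6, −4),
log₁₀δ̂ ∈ (−7, −5); cell data uses log₁₀λ̂ ∈ (−6, −3)). Proposals shift
every coordinate independently by Unif(−0.005, 0.005) × prior width on
the fitting scale (±0.02 for N), reflecting at the bounds. Improvements
are always accepted; otherwise acceptance has probability
exp(−ΔD/ξ). ξ starts at 10 and drops along a fixed ladder
({1, 0.1, 0.01, 0.005, 0.001} at accepted distances
{50, 30, 20, 18, 17.5} for plate data, {100, 75, 50, 40, 35} for cell
data) until the chain reaches the termination distance (11.08 plate,
39.2 cell). Independent chains (1000 in the full protocol) map the
compatible parameter distribution; τ_KP = N/k_p is derived per chain and
experiment.

Numerical/design choices:

- **ξ-switch trigger.** Whether the ladder triggers on candidate or
  accepted distances is ambiguous in circulating descriptions; this
  implementation triggers on the accepted state's distance (the
  candidate's distance the moment it is accepted, or the initial state's).
- **Initialisation.** Prior draws with infinite distance (some data point
  unreachable) are redrawn: an all-infinite neighbourhood gives the
  walker no gradient to follow. Chains that are entirely inside an
  unreachable region would otherwise stall for the full step budget.
  Infinite-vs-infinite proposals are accepted (equal distance) so chains
  can still diffuse out of such regions mid-run.
- **Synthetic schedule.** The published ladders are tuned to the residual
  scale of the original datasets. For synthetic data of known noise
  σ_log the termination distance is set to n_points·σ_log²·1.2 (20%
  above the expected residual sum at truth) and the plate ladder —
  thresholds, ξ values and initial ξ — is rescaled proportionally.
- **Safeguard.** max_steps = 5·10⁶ per chain; chains hitting it are
  reported as failed and excluded from the ensemble, never silently
  dropped.
- **Pooled summaries.** N is summarised as ensemble median with min–max;
  pooled k_p and τ_KP use the mean over per-experiment medians with a
  95% percentile interval over all chain × experiment values (the
  pooling estimator is not canonical; alternatives are easy to compute
  from the ensemble table).
- **Engines.** The chain kernel is numba-compiled; a pure-Python
  reference implementation consumes the identical RNG stream and
  produces bit-identical trajectories (asserted in tests).

Identifiability follows the structure visible in the fitted curves: k_p
is pinned by the K_D value where potency saturates, N by the log–log
slope at large K_D, so panels must span saturation to near-loss of
response (the default synthetic panel spans 3–1500 µM).

## SPR affinity estimation

Free fit: Langmuir isotherm with KD, Bmax > 0, Levenberg–Marquardt,
initialised at KD₀ = median(T), Bmax₀ = 1.2·max(B). Constrained fit:
Bmax fixed from the standard curve; SSE minimised over log₁₀KD by
bounded 1-D search (bracket 10⁻⁶–10⁹ µM), which is well conditioned on
ridge-shaped SSE surfaces.

Standard curve: ordinary least squares of fitted Bmax on W6/32 plateau
Rmax, restricted to free fits with max[TCR]/KD ≥ 2.5 (below that the
fitted Bmax itself is untrustworthy). The intercept is left free (a
through-origin constraint is not assumed); interpolation outside the
retained Rmax range is refused, which keeps the intercept choice
low-impact. The W6/32 plateau is obtained from the empirical trace model
R = Rmax·t/(K_t + t) (K_t a nuisance). Reporting rule: constrained KD
strictly above 20 µM is reported, otherwise the free KD ("above" read
strictly; at exactly 20 µM the free fit is used). Double referencing
(reference-channel and flanking-buffer subtraction) is applied to
already-tabulated series; sensogram alignment is upstream of this
package.

## Potency and the power law

Dose–response curves are fitted on the linear % scale with the
four-parameter sigmoid R(x) = Emin + (Emax−Emin)/(1 + (EC50/x)^H), then
inverted analytically at the threshold X (15% for CD69, 10% for IL-2 —
config values, never inferred):
PX = EC50/((Emax−Emin)/(X−Emin) − 1)^(1/H). Curves never reaching X are
flagged below-threshold; PX beyond the highest tested dose is flagged
extrapolated. A literature mode interpolates tabulated points linearly
in (log₁₀ dose, response). The lmfit solution is polished with a tight
(`xtol = 10⁻¹⁵`) least-squares pass so noiseless round-trips through the
generator close to ≤ 10⁻⁹ relative.

The discrimination power is the OLS slope of log₁₀PX on log₁₀K_D (or
log₁₀k_off when k_on varies across ligands — an explicit per-table
choice). Before fitting, records with K_D < 1 µM are removed (potency
saturates in the engineered high-affinity regime and would flatten the
slope) along with all flagged records; every removal is written to an
audit log. Aggregation across experiments takes the arithmetic mean of
per-experiment slopes with a t-based 95% CI, dropping fits whose slope
p ≥ 0.05 (an explicit override retains sparse datasets). Hypothesis
tests against α = 1 are one-sample t-tests on log₁₀α.

## Stochastic phase maps

Sensitivity: a single agonist (L₀ = 1, k_off = 1 s⁻¹) must give
⟨C_N⟩ > λ = 0.1. Discrimination at power α: Δ_L = 10⁴ copies of a
Δ_A = Δ_L^(1/α)-fold weaker ligand must give ⟨C_N⟩ < λ (so that the dose
compensating the affinity loss under the power law just fails). The
deterministic constraints use the binding-dominated approximation
C_tot ≈ min(L₀, R₀); exact Gillespie simulation (250 realisations to
t = 100 s, R₀ = 30 000) provides the stochastic classification. The
per-molecule k_on is not canonical for these scenarios; it is set so
k_on·R₀ = 100·k_off,1, making single-agonist occupancy > 99% and
matching the deterministic approximation. Cells exactly at threshold do
not pass (strict inequalities).

The test suite runs the stochastic scenarios at scaled sizes
(R₀ = 300, Δ_L = 100, with Δ_A = Δ_L^(1/α) preserving the
dose-compensation logic) so a grid completes in seconds per cell; the
paper-scale values remain the configuration defaults. Agreement between
modes is asserted against the exact closed-form steady state of the same
scenario, restricted to cells whose ensemble mean is ≥ 3 SE from the
threshold — near the boundary Monte-Carlo noise makes the binary label
undefined by construction.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analysis assumes:
Langmuir SPR curves with additive Gaussian RU noise (σ = 2 RU default),
per-ligand immobilisation levels drawn log-uniformly over 800–2000 RU,
an active-pMHC fraction f_active (default 0.7) that decouples
immobilisation level from active density, antibody plateaus constructed
by inverting the standard curve (slope 2, intercept 0 by default, so the
noiseless pipeline closes exactly), KP potencies with lognormal noise
(σ_log = 0.1 default — chosen to make recovery tests informative;
recorded in truth.json, not asserted as an empirical value), and
sigmoid dose–response curves whose EC50 is the closed-form inverse of
the target potency. Potency noise is lognormal precisely because the
fit distance is a sum of squared log₁₀ residuals: the generator makes
the fit's implicit noise model explicit.

Not emulated: time-resolved association/dissociation kinetics (only
steady-state binding), TCR aggregation at high concentration, antibody
non-saturation beyond the empirical standard curve, biological
curve-shape variability (the Hill shape is shared within a dataset), and
any cellular mechanism beyond the KP potency map. Passing recovery tests
therefore demonstrates correctness of the estimators under the assumed
noise model, not robustness to real-data artefacts.

## Problem sizes used in the tests

Parameter recovery runs 12 experiments × 8 ligands with 50 chains
(the full 1000-chain protocol is a configuration default); the ODE and
algebraic oracles use 10³ draws; the SPR contrast uses 20 replicates at
K_D = 500 µM; Gillespie consistency uses 2000 realisations for the mean
check and a 3 × 3 (N, τ) grid at 250 realisations for the phase map.
These sizes were chosen so the whole suite runs in a couple of minutes
on one core while keeping Monte-Carlo error well below the asserted
effects.

## Known limitations

- The annealed MH scheme is a heuristic ensemble search, not a calibrated
  posterior sampler; ensemble spreads are compatibility intervals, not
  credible intervals.
- The fold-amplification interpretation of α assumes the power law holds
  across the extrapolated range.
- Literature-mode potency extraction inherits the digitisation error of
  reading single representative curves.
- KP extensions (feedbacks, limited signalling, antagonism, optimal
  affinity) are out of scope.
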