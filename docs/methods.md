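# Methods

This note records the models implemented, the numerical choices behind
them, the design decisions taken where conventions differ between tools,
and what the synthetic data do and do not establish.

## Trait-free birth–death likelihoods (`paleodiv.bd`)

All trait-free likelihoods operate on branching times of a rooted,
strictly bifurcating, ultrametric tree (ages in Ma; t = 0 is the present).
With sampling fraction f, the probability E(t) that a lineage alive at age
t leaves no sampled descendant solves the Riccati equation

    dE/dt = μ(t) − (λ(t) + μ(t)) E + λ(t) E²,   E(0) = 1 − f.

Because every tip carries the same initial condition, E is a single global
function of age, and the per-branch likelihood factors Ψ reduce to the
integral of 2λE − (λ+μ) weighted by the lineage-through-time count k(t).
The log-likelihood is

    n log f + Σ_{non-crown nodes} log λ(t_i) + ∫₀ᵀ k(t)[2λE − (λ+μ)] dt
      − 2 log(1 − E(T))   (crown-survival conditioning; toggleable),

solved jointly (E plus the accumulated integral) with an adaptive
stiff-capable integrator (LSODA, rtol 1e-9, atol 1e-11 by default;
tightened where tests compare engines at 1e-8). The spec-level per-branch
ODE formulation is mathematically identical; tests verify the engine
against a literal fine-grid per-branch RK4 oracle.

Rate forms are constant, exponential in time, and exponential in an
environmental proxy. Proxy curves are cubic smoothing splines over
(age, value) samples with caller-supplied degrees of freedom (default
min(n, 50); df ≥ n gives exact interpolation); queries clamp to the
sampled age range, and the df used is recorded in fit metadata because
published analyses rarely state their smoothing. Conditioning defaults to
crown survival (both crown lineages leave sampled descendants), the
convention of the R environment-dependent fitters this mirrors; it is a
recorded, toggleable setting since upstream papers usually leave it
implicit.

Fitting is bounded multi-start local optimization (Nelder–Mead polished by
L-BFGS-B; 3 starts; λ₀ ∈ [1e-6, 10], μ₀ ∈ [0, 10], α ∈ [−2, 2]); equal-AIC
ties resolve toward fewer parameters.

## Episodic models (`paleodiv.episodic`)

Piecewise-constant rates are parameterized per interval (present-to-past)
as net diversification r_i and turnover ε_i ∈ [0, 1), matching the
"Rate"/"Turn" columns of episodic model tables; λ_i = r_i/(1−ε_i).
Within an interval, y = 1 − E obeys the logistic equation
dy/dt = r y − λ y², so E and the branch factors have closed forms
(log Ψ = −rΔ + 2 log(y₁/y₀) per lineage-interval); the implementation is
the exact solution of the segmented ODE and is vectorized per interval.

Shift placement uses greedy sequential search on an age grid (default
0.1 Myr; grids exclude one step at each boundary, where shifts are
unidentifiable): each new shift is scanned conditional on the accepted
ones with a cheap optimizer budget, and the winning placement is
re-polished at full precision with jittered restarts. Shift times count as
free parameters (np = 2(s+1) + s), and the shift count is chosen by
sequential LRTs with 3 df per added shift (one time, one rate, one
turnover) at α = 0.05, with the AIC table reported alongside.

A caveat the tests document: because the LRT statistic is maximized over
grid placements, the nominal χ²(3) reference is anti-conservative on
constant-rate data (measured type-I error on pure-birth simulations is
roughly 20–25% rather than 5%). This is a property of the grid-search
protocol itself, not of the likelihood; genuine shifts of the magnitude
studied here (4-fold) are recovered essentially always, with the shift
time located to within the grid resolution.

## Diversity-dependent models (`paleodiv.dd`)

Five variants, with n the standing species count:
DDL λ(n) = λ₀(1 − n/K), μ = 0; DDL+E λ(n) = λ₀ − (λ₀−μ₀)n/K (equilibrium
diversity K), μ = μ₀; DDX+E λ(n) = λ₀n^{−x}; DD+EL
μ(n) = μ₀ + (λ₀−μ₀)n/K; DD+EX μ(n) = μ₀n^x. Speciation rates clamp at 0.
These functional forms are recorded in fit metadata because the variant
names alone do not pin them down.

The likelihood evolves, forward in time from the crown (k = 2 observed
lineages, no hidden species), the probability vector over the number m of
hidden coexisting species — extant species not ancestral to any sampled
tip. With n = k + m: hidden births enter at rate λ(n)(m + 2k) — the factor
2 on observed-lineage births is the same daughter-exchangeability
multiplicity that produces the 2λED term in branch-ODE frameworks — hidden
deaths at μ(n)m, and the diagonal carries the full event outflow n(λ+μ) so
that observed-lineage deaths leak probability. Observed branchings
multiply by λ(n); at the present, tips weigh f^k and hidden survivors
(1−f)^m. The truncation bound is max(2K, n_tips + 200) states (cap 2000),
auto-doubling when boundary mass exceeds 1e-8. Intervals are advanced with
sparse Krylov matrix exponentials (the generator is tridiagonal and
time-homogeneous between branchings); μ = 0 with f = 1 has a closed-form
fast path (no hidden lineages can exist).

Conditioning on crown survival is computed exactly by a 2-D master
equation over the pair of crown-subclade sizes, started at (1, 1), with
present-day weight (1 − (1−f)^{n_A})(1 − (1−f)^{n_B}); it reduces to 1
when μ = 0 and f = 1 and reproduces (1 − E(T))² in the constant-rate
limit. Missing species enter only as unsampled-at-present (i.i.d.
Bernoulli), never with assumed placement.

Fits use 3 starts with the initial carrying capacity at the clade's known
species count. Decoupled key-innovation and clade-wide shifting-rate
variants are out of scope.

## Mk habitat evolution (`paleodiv.mk`)

Habitats {forest, intermediate, open} (encoded 0/1/2) evolve under a 3×3
rate matrix with structure ER (1 free rate), SYM (3) or ARD (6). Pruning
likelihoods use per-branch propagators from one eigendecomposition of Q
per evaluation; the root prior is equal (1/3) by default with FitzJohn
weighting available — recorded in outputs because source analyses rarely
state the choice. Structure selection: ARD only if it beats both ER
(χ², 5 df) and SYM (3 df) at α = 0.05; else SYM if it beats ER (2 df);
else ER (parameter parsimony).

Marginal ancestral states combine the postorder partials with a preorder
"rest-of-tree" pass. Stochastic maps are drawn conditional on the ML Q
("empirical" mapping, as large-scale simmap studies do): node states are
sampled jointly from their conditional distribution (vectorized across
maps), then branch interiors are filled by uniformization bridges — jump
counts from the endpoint-conditioned Poisson mixture, the virtual-jump
chain sampled with precomputed R-matrix powers, jump times as uniform
order statistics, self-jumps discarded. The bridge sampler is validated
against rejection sampling in the tests. Summaries report mean transition
counts per ordered state pair and time-in-state proportions.

## Hidden-state SSE models (`paleodiv.sse`)

The combined state space is 3 examined habitats × d concealed states
(default d = 3, mirroring the examined count; d is a recorded knob since
source analyses do not state it). Speciation is tied across concealed
states and free across habitats (ETD), the reverse (CTD), or single (CR);
extinction is one shared rate by default (per-state μ exists but is off:
published fits report a single extinction value). Anagenetic transitions
follow one of six habitat structures — unconstrained 1- or 6-rate, and
constrained variants that forbid direct forest↔open moves (single rate,
four rates, specialist/generalist, openness-directional) — replicated in
each concealed block, plus one shared concealed-flip rate; concealed
parameterization mirrors the examined structure with a single rate (a
recorded default; the alternative of free concealed rates is not
identifiable at these data sizes).

Cladogenesis: dual inheritance gives both daughters the parent's habitat
(rate λ_s on the diagonal pair); single inheritance gives exactly one
daughter the parent's habitat while the other takes any habitat adjacent
under the structure (constrained structures only allow moves through the
intermediate state), with λ_s split equally across the ordered daughter
pairs so the tensor sums to λ_s for every parent state (asserted at spec
construction).

Per-branch ODEs on (E, D) over combined states are integrated with an
adaptive Dormand–Prince 4(5) stepper compiled with numba (rtol 1e-8 /
atol 1e-10 by default; 1e-7/1e-9 inside optimization); D is renormalized
at every node with the scale accumulated in log space. Tips set D = f on
the observed habitat for every concealed state and E = 1 − f. Root states
are weighted by conditional likelihoods (uniform available, recorded), and
the likelihood is conditioned on survival of both crown lineages by the
per-state λ_s(1 − E_s)² divisor. Node-level habitat probabilities come
from the adjoint (transposed-propagator) up-pass, marginalizing concealed
states; tests verify them against restricted-likelihood ratios (clamping
each node to each habitat). AICc uses n = number of tips (a recorded
choice; the AICc sample size is not standardized).

The 36-model space is {ETD, CTD, CR} × {dual, single} × 6 structures. The
simulate-and-refit validation draws trees + tip habitats under the fitted
ETD and CTD models (crown age tuned so reconstructed sizes match the
empirical tip count, enforced by resimulation), refits both, and selects
by raw log-likelihood, yielding a 2×2 confusion table.

## Spectral clade detection (`paleodiv.spectral`)

The tree is a weighted graph on all vertices with W_uv = 1/branch length
between adjacent vertices and L = D − W ("modified graph Laplacian"; the
construction is isolated behind one function so alternates such as the
inverse-patristic-distance complete graph can be swapped, and the variant
used is implied by that single constructor). The cluster count reads the
eigengap of the ascending spectrum as the ratio λ_{k+1}/λ_k (k ≥ 2):
k well-separated clades leave k near-zero eigenvalues followed by an
order-one one, and the ratio — unlike the absolute difference — is not
dominated by the magnitude growth of the upper spectrum of a weighted
tree graph. When no ratio among the leading eigenvalues exceeds 2 the
tree is called a single cluster. Tip assignment is k-means (deterministic
seed, 10 restarts) on the leading Laplacian eigenvectors; consistency
across a tree collection is the share of applications returning the modal
partition (mean ± sd).

On trees without strong separation the suggested count is unstable by
construction — the operation still returns a value plus the gap
magnitudes, and the orchestration layer accepts recorded clade lists
wherever detection is ambiguous.

## Model comparison (`paleodiv.selection`)

AIC = 2k − 2logL (asserted to 1e-9 on every fit result), AICc with the
usual small-sample correction, ΔAIC against the table minimum, Akaike
weights (fraction and percentage), and χ² LRTs for nested models with
small negative statistics clamped at 0 (beyond −1e-6 is an error).
Equal-AIC ties prefer fewer parameters.

## Simulators (`paleodiv.simulate`)

All simulators run the complete process forward in time by Gillespie
simulation — exact for constant, episodic (rates switch at shift ages),
diversity-dependent (rates re-evaluated at every event) and SSE models
(per-lineage habitat states, anagenetic flips, dual/single cladogenetic
inheritance). Smoothly time-varying rates use thinning against a bound
over a 0.25-Myr look-ahead window. The reconstructed tree is obtained by
i.i.d. Bernoulli tip sampling (per-state for SSE) and pruning; pruning
preserves ultrametricity. Conditioning (crown survival; a target
reconstructed tip count within a tolerance band, default ±10%) is enforced
by resimulation with a bounded attempt budget that reports the last
failure mode on exhaustion. Every simulator is bit-reproducible from its
seed.

The study-shaped fixture emulates the empirical data's shape: a ~94-tip,
20-Ma tree whose two nested focal clades are generated under the two
regimes the analyses should re-detect — a diversity-dependent clade
(DDL, λ₀ = 0.3, K = 70, crown 17.5 Ma, ~54 tips) and an episodic clade
with two downshifts (2 and 17 Ma, ~40 tips; recent/middle/old net rates
0.013/0.10/0.548 with turnovers 0.163/0.6/0.503, values in the range of
published episodic fits) — joined at a 20-Ma root, with habitats evolved
under an ARD Mk process biased toward forest ancestry and a monotone
temperature-like proxy over 0–25 Ma, all at sampling fraction 0.92. What
the fixture does *not* emulate: phylogenetic error (a single true tree,
no posterior sample beyond branch-length jitter), habitat-dependent
diversification (habitats evolve neutrally on the fixture tree, so SSE
fits on it test machinery, not signal), non-identifiable outgroups, and
empirical proxy noise. Tests passing on the fixture therefore demonstrate
correctness of the estimators under their own generating assumptions, not
the empirical conclusions.

## Problem sizes in the shipped experiments

The recovery experiments run at sizes chosen to give stable Monte-Carlo
verdicts on one CPU: diversity-dependence recovery uses 50 DDL trees at
the generating conditions (λ₀ = 0.3, K = 70, crown 17.5 Myr) simulated
and fitted at complete sampling, where the DDL likelihood is closed-form
(the general master-equation path is exercised by the oracle and
reduction tests); episodic shift recovery uses 15 replicates of ~200-tip
trees with a 4-fold drop at 5 Ma on a 0.25-Myr grid; the
habitat-dependent ordering experiment uses 20 replicates of ~90-tip trees
generated and fitted with d = 1 concealed states (ETD ties speciation
across concealed states, so additional concealed states add computation
but no information when ETD generates the data); the ETD/CTD
simulate-and-refit validation in the analysis scripts defaults to 10 + 10
replicates. Type-I-error style checks (Yule vs shifts, ER vs ARD) use
10–20 replicates.

## Known limitations

- Environment curves are functions of age only; rate functions other than
  constant/exponential are out of scope.
- The episodic LRT's χ² reference is anti-conservative under grid-search
  placement (see above).
- The DD conditioning truncates each crown subclade at 200 species; for
  clades far above that diversity the conditioning probability saturates.
- SSE fitting with all 36 models at d = 3 on ~100-tip trees is
  computationally heavy; the analysis driver defaults to d = 2 and a
  representative subset, with `--all` for the full space.
- Stochastic maps condition on the ML transition matrix; uncertainty in Q
  is not propagated.
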