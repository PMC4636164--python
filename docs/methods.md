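# Methods

## Models

Two nested deterministic ODE models of a bacterial population defending
itself against lytic phage with a regulated CRISPR-like system.

The **simple model** tracks free cells `P`, infected cells `Q` (both in
units of the carrying capacity `Φ_p`) and phage `V` (also in `Φ_p` units
here), with time in adsorption units `1/(α_q Φ_p)`.  Immunity returns
infected cells to the free pool at rate `G_{Q→P}`, infected-cell
autoimmunity (abortive infection) removes them at `G_{Q→φ}`, lysis at
`G_{Q→V}` releases `α_v` phage each, and free cells suffer autoimmunity
at `δ G_{P→φ}` where `δ ∈ [0, 1]` is the infection-state regulation
factor (0 = fully repressed when uninfected).  All rates are first-order
mass action; growth is logistic in the total cell density.

The **detailed model** generalizes the fixed immunity/autoimmunity rates
into products of per-spacer rate constants and dynamic per-cell spacer
quotas.  Quotas (in units of the phage protospacer complement `π_v`)
come in three classes per pool: active (phage-matching), inactive
(phage-matching but PAM-mutated, at phage mutation rate `μ_v` per
protospacer) and self-targeting (host-matching, sourced from the host
protospacer pool `β·π_v`).  Time is measured in spacer-acquisition units
`1/α_c`; phage in `α_v Φ_p` units.  The per-infected-cell quota
equations contain two per-capita mixing terms — infection inflow
dilution `A_V P V / Q` and immune-survivor inheritance
`G_{Q→P} Y_{QA} Q / P` — that are singular at empty pools; see
*Numerics*.

Both models are implemented verbatim from their nondimensional forms;
the dimensional→nondimensional maps (and their inverses) are pure
algebra in `params.py`.  One reading decision: the per-quota groups are
`G_{Q→P} = γ_{q→p} π_v / α_c` and `G_{Q→φ} = γ_{q→φ} π_v / α_c`
(dimensional per-spacer rates times the quota unit over the time unit),
and the mutation group is `M_V = μ_v / α_c` (0.3 at the reference
kinetics); both follow from requiring each term of the quota equations
to be dimensionless, and the conversion is overridable.

## Closed-form coexistence state

The coexistence fixed point of the simple model is reported two ways.
The closed form drops the `−P V` adsorption sink from the phage
equation, giving

    P_c = (G_V/α_v) · (1 + (G_{Q→φ}+G_{Q→P})/G_{Q→V})
    V_c = G_Q · [A_P(1−P_c) − δ G_{P→φ}] / (A_P P_c + G_{Q→φ} + G_{Q→V})
    Q_c = P_c V_c / G_Q

(the second factor of `P_c` is the *immune advantage*: hosts with
stronger infected-cell immunity or abortive infection equilibrate above
the phage-limited level `G_V/α_v`).  The exact root satisfies
`P_c,exact = G_V / (α_v G_{Q→V}/G_Q − 1)`; the closed form is its
leading term for `α_v G_{Q→V}/G_Q ≫ 1` and both are returned with their
relative discrepancy.  Downstream code (continuation, boundary tracing)
uses the exact root, refined by damped Newton from the closed-form seed
(residual tolerance 1e-12, 100 iterations; non-convergence flags the
record as closed-form only).  The thresholds `δ₁`, `δ₂` and the
coexistence-line intercepts `K₁`, `K₂` use the closed form, as their
derivations do; the `validity_ratio` field carries
`α_v G_{Q→V}/G_Q` so callers can judge them.

## Stability

Stability is always computed by two independent routes: Routh–Hurwitz
conditions (`a₁ > 0`, `a₃ > 0`, `a₁a₂ − a₃ > 0`) on the characteristic
polynomial of the analytic 3×3 Jacobian, and a numerical eigensolve.
Any Routh–Hurwitz quantity or leading real part within 1e-9 of zero is
*marginal*, as is any disagreement between the routes.

## Numerics

**Integrator.** The detailed model's nondimensional groups span O(1)
(`G_C`, `M_V`) to O(1e9) (`G_{Q→P}` at the reference per-spacer rate),
so the default integrator is LSODA with `rtol = 1e-8`, `atol = 1e-12`.
Negative excursions are clipped to zero in recorded output (and
counted); the state is not log-transformed because the extinction fixed
points at zero must remain exact.  The RHS cores are JIT-compiled with
numba when available; a pure-Python fallback produces identical values
(tested).

**Empty pools.** The per-cell quota of an empty pool is meaningless, so
when a pool's density falls below the extinction threshold (1e-10 in
carrying-capacity units) its entire quota block is frozen, and the
singular per-capita denominators are additionally floored at 1e-12.  An
alternative *total-content* mode integrates quota×population products,
which stay finite at extinction, and recovers quotas afterwards; the two
modes agree on occupied-pool trajectories (tested) and differ only in
the meaningless quota rows of empty pools.

**Steady states.** `find_steady_state` alternates integration with root
polishing.  Integration proceeds in chunks growing fourfold from 1/16384
of the nominal horizon (50 time units for the simple model, 100 for the
detailed one), throttled by observed cost: several regimes relax onto
weakly damped stiff spirals costing ~1e6 RHS evaluations per time unit,
where integrating to full equilibrium is impractical, so chunks shrink
when expensive and every `solve_ivp` call carries a hard evaluation cap.
After each chunk a Newton polish of the RHS root is attempted and
accepted only if it (i) stays near the trajectory, (ii) is nonnegative,
(iii) is a genuine root under *per-row* residual scaling — each residual
component divided by its own Jacobian row norm, so a slow equation
cannot hide behind a fast row's scale — and (iv) is not linearly
repelling, then confirmed by a short integration (about 50 fast
characteristic periods) from the root.  Without an accepted polish,
convergence requires trailing-window drift below 1e-6 over a chunk
spanning at least the nominal horizon; the window always includes the
final solver step so a single long step cannot fake flatness.  The
search never raises on slow convergence; it returns `converged=False`
when the evaluation budget (3e6) or time cap (1024 nominal horizons)
runs out.

**Boundary tracing** classifies grid nodes and refines each label
change between adjacent nodes by bisection to a relative parameter
tolerance of 1e-3.  For the simple model the classification is analytic
and keyed to the phage-free state `F*`: infeasible (`P_f ≤ 0`) means
host extinction, unstable means the phage invades and persists
(coexistence — as a stable point, or as a limit cycle where the
coexistence fixed point is an unstable spiral, which it is for most of
the large-burst regime), stable means phage evasion.  The
`F*`-stability flip is a transcritical exchange with `C*`, so this
boundary is exactly the coexistence-feasibility line.  The detailed
model classifies by relaxation from the default inoculum.  Folds along 1-D
branches are detected as branch-distance minima below 1e-2 rather than
by pseudo-arclength continuation — every boundary mapped here is a
simple crossing at the scales scanned.

## Regime classification

A converged detailed-model steady state is labeled: **III** if the host
is extinct (below 1e-10 for free and infected pools); else **I** if the
immune advantage `(G_{Q→P} Y_{QA}* + G_{Q→φ} Y_{QS}*)/G_{Q→V}` is below
`eps_adv = 1e-3` (the exact-zero condition of the no-advantage regime is
unattainable numerically); else **II** if the restriction share
`G_{Q→P} Y_{QA}*/G_{Q→V}` exceeds `eps_restrict = 1e-3`; else **IV**
(advantage carried by self-targeting spacers alone — pure abortive
infection).  Phage being driven below a reporting threshold is recorded
but does not enter the label.

When the phage (and infected pool) is extinct, the frozen infected-pool
quotas are artifacts of where the extinction transient happened to stop,
and using them would make labels depend on the integration path (e.g.
on warm-started sweeps).  The classifier therefore imputes the infected
cell's own kinetic balance — active `(1−μ_v)/G_C`, self-targeting
`β/G_C` (per the infected-pool deletion rate of the active variant) —
which is the quota level that drove the phage out and is
path-independent.

**Sweeps** relax every `(β, G_C)` cell from the default inoculum
(`P = 0.1`, `V = 0.01`, all else zero; the models' outcomes are
insensitive to the inoculum, which merely seeds both species).  Warm
starts carry over only the slow quota block from the neighbouring cell;
populations always restart from the inoculum, because the extinct state
is invariant and a warm-started zero population could never leave it.  A
failed warm-started cell is retried cold before being reported
unclassifiable.

## Model variants

* `no-abi` removes the autoimmune loss term from the infected-cell
  equation only; free-cell autoimmunity (and hence the extinction
  constraint) remains.
* `del-const` runs free-cell spacer deletion at the full rate `G_C`
  instead of `δ G_C` (constitutive deletion machinery); the phage-free
  self-targeting quota drops from `β/G_C` to `δβ/G_C`.
* `del-inverse` additionally silences infected-cell deletion entirely —
  regulation opposite to the rest of the CRISPR machinery.  No partial
  repression factor is modeled.

## Study conditions

The preset `benchmark-simple` fixes `α_p = 1/hr`, `Φ_p = 1e8 cells/ml`,
`α_q = 5e-9 ml/phage/hr`, `γ_v = 5/hr`, `α_v = 50` and defaults the
scan rates `γ_{q→p} = γ_{q→φ} = γ_{q→v} = γ_{p→φ} = 1/hr`; the choice
`γ_{p→φ} = α_p` (i.e. `G_{P→φ} = A_P`) puts the host-extinction line
exactly at `δ = 1`.  The preset `reference-detailed` fixes the reference
kinetics (`α_c = 1e-6/hr`, `π_v = 1000`, `μ_v = 3e-7` per protospacer,
`γ_{q→v} = 1/hr`, `γ_{q→p} = 1 (spacers/cell)⁻¹hr⁻¹`) and defaults the
swept parameters to `γ_c = α_c`, `γ_{q→φ} = γ_{q→p}`, `β = 1`; burst
size is not part of the kinetic table and defaults to 50.  All defaults
are flagged `varied` in the records and logged in run manifests.

Sweep grids default to `β ∈ [1e-2, 1e2]` (the upper end matching a
~100-fold host-to-phage protospacer excess, realistic for a bacterial
genome against a small phage) and `G_C ∈ [1, 1e8]` log-spaced — wide
enough that the advantage score crosses `eps_adv` (near `G_C ≈ 1e6` at
reference kinetics) inside the grid.  Randomized checks draw
log-uniformly: `δ ∈ [1e-4, 1]`, `β ∈ [1e-2, 1e2]`, `G_C ∈ [1e-1, 1e4]`,
`G_{Q→φ} ∈ [1e7, 1e10]`, spanning the regimes on both sides of the
activation constraint; draws within 5% of `δ_max` are excluded as
numerically undecidable at any finite horizon.  Constraint checks start
from a fresh population (zero spacer quotas): the `δ < δ_max` bound
governs accumulation from the acquisition flux, whereas a large seeded
self-targeting load can kill the host outright regardless of the bound
(a basin-of-attraction effect, deliberately out of scope of the
constraint).  Boundary-line checks use
`α_v = 2000` so the validity ratio exceeds 100, which the benchmark
burst size (50) cannot reach.

## What passing tests do and do not show

The models are their own study system — there is no external data — so
the tests establish internal correctness (equations, fixed points,
thresholds, stability, reductions agree with independent derivations and
with simulation) and the qualitative phenomenology (four-regime
topology, variant orderings, extinction boundaries).  They do not
calibrate the kinetic constants against any experimental culture, and
quota variables are population averages: strain-level spacer *sequence*
diversity, multi-genotype competition, and stochastic extinction at low
copy number are all outside the models' scope.

## Known limitations

* Steady-state search can report `converged=False` on genuinely
  oscillation-dominated parameter sets whose spirals damp slower than
  the evaluation budget allows; such cells are surfaced as
  `unclassifiable` rather than silently mislabeled.
* No Hopf-bifurcation or limit-cycle detection: every analysis targets
  steady states, which is where all tested parameterizations end up.
* No stochastic (Gillespie) counterpart; densities are continuous, and
  "extinction" means falling below 1e-10 of carrying capacity for the
  final stretch of a run.
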