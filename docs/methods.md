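# Methods

This note documents the model implemented in `t6duel`, the choices made
where the design was genuinely open, and what the synthetic study
conditions do and do not establish.

## Model

### Cells and arena

Cells are rigid spherocylinders (cylinder length `seg_length`, radius
`R_cell`, volume `π R² L + (4/3) π R³`) confined to the z = 0 plane — the
model targets surficial, monolayer competition, so three-dimensional
vectors are carried for compatibility but z-components are pinned to zero.
The arena is only an initial-placement disc (radius `arena_radius`); growth
is unconfined. Initial patches scatter a specified mixture of strategists
uniformly over the disc by rejection sampling until no two capsules
overlap, with per-cell volumes jittered as `V_0 + U[0, η_division)` so
division times desynchronize from the start (without this, every cell in a
noise-free patch divides on the same step).

Density is controlled the way the competition experiments vary it: a fixed
arena with varying cell counts. The default `arena_radius = 28 µm` makes
20 cells ≈ 2% area fill (dilute) and 400 cells ≈ 33% fill — dense enough
that most cells start within needle reach of a neighbour, while still
placeable by random sequential insertion.

### Growth, division, resources

Volumes grow exponentially, `dV/dt = k_grow V`, applied per step as the
exact factor `exp(k_grow·dt)` rather than an Euler increment, which removes
dt-order growth bias and makes single-cell trajectories machine-exact
against the closed form. A cell divides when it exceeds a threshold
`2V_0 + η` drawn once at its birth (`η ~ U[0, η_division)`); the two
half-volume daughters are placed end-to-end with their outer tips at the
parent's tips (the resulting mid-cell overlap is resolved mechanically),
axes perturbed by independent `U(−η_orientations, +η_orientations)` angles.
Division conserves volume exactly. Daughters inherit the parent's
translocation count — toxins already in the cytoplasm do not vanish at
division — but start with empty retaliation queues; both are modelling
choices where the biology is ambiguous.

The shared patch resource depletes at zeroth order, `dE/dt = −k_max ΣV`
over living non-lysing cells, and the simulation ends at `E = 0`. `E_0`
therefore fixes how much biovolume a patch can ever produce.

### T6SS combat

Needles are in-plane segments of length `L_needle` anchored on the firing
cell's outline. Random firers draw `Poisson(k_fire·dt)` needles per step at
points uniform in outline arc length, directed along the outward normal.
Retaliators answer each hit queued in the previous step with
`retaliation_multiplicity` needles from the recorded entry point, directed
along the exact reverse of the incoming needle (the aiming-knockout variant
fires the same number from random outline points instead). The one-step
retaliation latency avoids unbounded same-step duel recursion; dt is small
relative to every other timescale.

Hit detection is two-step: (i) a candidate passes if the minimum distance
between needle segment and target axis segment is below
`R − L_penetration`; (ii) the entry point is the nearest intersection of
the needle ray with the capsule surface (cylinder flank or polar caps),
and the needle stops at the first cell it enters — one victim per needle.
Non-clonemate hits not covered by the target's immunity set increment a
cumulative translocation count; at `N_hits` the cell irreversibly commits
to lysis, stops growing, firing and consuming, remains a mechanical
obstacle, and is removed after `1/k_lysis`. Retaliation is triggered by any
non-clonemate hit, toxic or not: the biological trigger is membrane
perturbation, not toxicity, so mutually immune attackers still provoke
counterattacks.

Costs reduce growth: `k_grow = k_max(1 − c_upfront − c·N_firings/dt)`,
clamped to [0, 1] total. Cost-saving strategists pay for realized firings
only; the no-cost-saving knockout pays the flat reference rate
`c·k_fire_ref` like a random firer of that rate.

### Mechanics

After growth, overlaps are relaxed by iterating a regularized least-squares
solve `(AᵀA + αM)p = −Aᵀd` over planar rigid-body increments (x, y, θ per
cell): A holds the contact-normal Jacobians at witness points (lever arms
couple torque), d the negative gaps, and M a diagonal drag matrix with drag
proportional to cell span (long cells move less). Contacts are re-found
each iteration (a single linearized solve cannot clear chained overlaps);
parallel-segment witness points are tie-broken at the midpoint of the
overlap interval, which keeps the operation symmetric and deterministic.
The loop stops when the deepest overlap is below `relax_tol` or after
`relax_max_iter` iterations; a singular solve escalates α tenfold and
retries. Relaxation draws no randomness.

### Invasion analysis

One competition yields per-genotype invasion fitness
`ω = ln(ΣV_end/ΣV_start)`; extinction maps to a −∞ sentinel that
propagates as "cannot invade" for invaders and "trivially invadable" for
residents. Local invasion compares the two fitnesses inside the mixed
patch; global invasion compares the rare invader's mixed-patch fitness
against the resident's fitness among its own kind, with a re-invasion
guard. Weighted forms cover partial mutual immunity between T6SS+ strains
(weight `p_s`; T6SS carriage is a prerequisite, so unarmed strains always
carry weight 0) and within-patch relatedness (weight `I`, the probability
of growing beside mutually immune clonemates). Self-pairings of strategies
that never fight their own kind — unarmed strains, retaliators, non-firing
cheaters — reduce to the unweighted entry, since neither strain fires in
such patches.

Pairwise invasibility plots average ω over replicate seeds before taking
index ratios; failed simulations mark entries missing rather than
fabricated. The ESS search accepts a grid rate only when mutants on *both*
sides cannot invade (boundary rates are reported as truncation artifacts,
not ESSes) and reports the incremental-invasion walks from both grid ends.
ESS localization is at grid resolution only; each matrix entry is a
stochastic simulation, so sub-grid root polishing would be noise-fitting.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `k_max` | 2.08 | h⁻¹ | 20-min doubling, fast-growing γ-proteobacteria |
| `V_0` | 1.57 | µm³ | newborn rod at R = 0.5 µm scale |
| `R_cell` | 0.5 | µm | typical rod radius |
| `dt` | 0.005 | h | k_max·dt ≈ 0.01, well under stability guard 0.1 |
| `L_needle` | 1.0 | µm | needle ≈ one cell width–length |
| `L_penetration` | 0.05 | µm | shallow-graze rejection tolerance |
| `N_hits` | 2 | — | multi-hit resilience; 1 and ∞ probed in experiments |
| `k_lysis` | 20 | h⁻¹ | 3-min lysis delay |
| `c_upfront`, `c` | 0.05, 0.001 | —, h | carriage and pro-rata firing costs; at k_fire = 50 h⁻¹ total cost is 10% of k_max |
| `η_division` | 0.5 | µm³ | ~30% of V_0; desynchronizes divisions |
| `η_orientations` | 0.1 | rad | slight division-axis imperfection |
| `α`, `drag_coeff` | 0.01, 1 | — | mild regularization; drag ∝ span |
| `relax_tol` | 0.05 | µm | residual overlap 10% of R; visually negligible, keeps the relaxation loop to a few iterations per step |
| `E_0` | 4000 | µm³ | uncontested patch saturates at ~2000 cells |

All overridable per run/config; experiments fix their own values.

## Study conditions and scale

The packaged experiments run at desk scale: competitions start from the
standard densities (10/50/100/200 cells per strain in the fixed arena) but
use resource quotas `E_0` of 1500–2000 µm³, so patches end at several
hundred to ~1500 cells after ~1 h of simulated growth rather than growing
to tens of thousands. This is a deliberate scale choice: the qualitative
contrasts probed — density dependence of random-firer advantage, strong
versus single retaliation, the N_hits = 1 collapse, the aiming advantage —
are front-loaded in the contact-rich early phase of a patch and are already
decisive at this scale, while each condition stays re-runnable in seconds
to tens of seconds.

## What the synthetic conditions do not show

The generator emulates idealized monolayer patches: uniform initial
scatter, a single shared homogeneous resource, one global parameter set per
strain, no nutrient gradients, no 3-D stacking, no substrate adhesion or
friction, no toxin-specific effector–immunity genetics beyond a
genotype-level immunity relation. Passing tests establish the model's
internal logic and its qualitative strategy rankings under these
conditions; they do not calibrate absolute rates, timescales or
proportions for any real community.

## Numerical notes and edge cases

* Identical (params, strategies, counts, seed) give bit-identical
  trajectories; replicates differ only by seed. The engine's batched
  Poisson scheduling draws in a fixed cell order.
* Exactly crossing axis segments (measure-zero) leave the contact normal
  ill-defined; a perpendicular of the first cell's axis is used.
* `N_hits = ∞` is representable directly (immune strains accumulate
  translocations but never lyse). `k_lysis → ∞` removes cells the same
  step the threshold is crossed (deadline comparison is closed).
* Total growth cost is clamped to [0, 1]: a cell bursting with firings
  stalls rather than shrinking.
* Lysing-but-not-yet-removed cells are excluded from final counts and
  biovolumes — they are committed dead.
* The t statistic and Cohen's d use the pooled-variance forms
  (dof = n₁+n₂−2, `d = (μ₁−μ₂)/√((SD₁²+SD₂²)/2)`) with sentinels for
  zero-variance samples; scipy provides only the t distribution's CDF.

## Known limitations

* The relaxation solves a regularized linearization per iteration; deep
  overlap chains (dense late-stage colonies) retain residuals up to
  `relax_tol`, and the iteration cap bounds work per step, deferring any
  remainder to the next step.
* Needle trajectories are straight, in-plane and instantaneous;
  out-of-plane misses can only be emulated by reducing hit probability
  geometrically.
* The adaptive-dynamics layer assumes rare-invader/common-resident
  separation of timescales and takes competition endpoints (patch
  depletion) as the fitness-relevant census.
* ESS localization is limited to the simulated rate grid; refine by
  re-gridding around a candidate.
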