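# t6duel

Agent-based simulation and evolutionary game theory of bacterial warfare
through the type VI secretion system (T6SS).

Many bacteria carry the T6SS, a contact-dependent molecular speargun that
injects toxic effectors into neighbouring cells. Species differ strikingly in
*how* they fire it: some (e.g. *Vibrio cholerae*) fire continuously from
random points on their surface, while *Pseudomonas aeruginosa* retaliates —
it fires back specifically from the sites where it was struck. `t6duel` is a
tool for asking when each firing strategy pays: it simulates communities of
rod-shaped cells competing on a resource-limited surface patch, and embeds
the competition outcomes in an adaptive-dynamics framework to decide which
strategies can invade, resist invasion, and sit at an evolutionarily stable
firing rate (ESS).

It is aimed at researchers in microbial ecology and evolution who want a
tested, seed-reproducible re-implementation of this class of model that runs
on a laptop.

## The model

Cells are rigid spherocylinders of radius `R` living in the plane. Each
carries a strategy:

* **U** (unarmed): no T6SS, no costs, killable.
* **R** (random firer): fires `N ~ Poisson(k_fire·dt)` needles per step from
  uniformly random surface points along the outward normal.
* **TFT / 2TFT** (retaliators): fire one / two counterattacks per incoming
  hit, from the recorded entry point along the reversed attack direction.
* **Rc** (cheater): carries the T6SS genes (pays carriage, may share
  immunity) but never fires.

Per timestep the engine applies: firing → two-step needle hit detection
(candidate test `d_min < R − L_penetration`, then nearest surface intercept
as entry point; needles stop at the first cell) → intoxication (clonemates
are mutually immune; at `N_hits` cumulative translocations a cell commits to
lysis and is removed after `1/k_lysis`) → growth (`dV/dt = k_grow V`,
integrated exactly) with T6SS costs

    k_grow = k_max · (1 − c_upfront − c · N_firings/dt),

noisy lengthwise division at `2V_0 + η`, zeroth-order resource depletion
`dE/dt = −k_max ΣV`, and mechanical relaxation to quasi-static equilibrium
by the regularized least-squares solve `(AᵀA + αM) p = −Aᵀd` over planar
rigid-body degrees of freedom. A run ends when the patch resource `E`
reaches zero.

The analysis layer turns competition endpoints into invasion fitness
`ω_X = ln(ΣV_X(t_end)/ΣV_X(t_start))` and classifies invasions at local
(within-patch) and global (metapopulation) competition scales, including
weighted extensions for partial mutual immunity (`p_s`), non-firing
cheaters, and within-patch relatedness (`I`). Pairwise invasibility plots
and a grid-based ESS search sit on top.

## Worked example

```python
from t6duel import SimParams, strategy_presets, competition, final_proportion

pre = strategy_presets()
R = pre["R"](0, k_fire=50.0)      # random firer, 50 firings cell^-1 h^-1
T2 = pre["2TFT"](1)               # strong retaliator

params = SimParams(E_0=2000.0)    # desk-scale resource quota
traj = competition(params, R, T2, counts=(200, 200), seed=1)
s = traj.summary
print(f"t_end = {s['t_end']:.2f} h, "
      f"final cells = {sum(s['final_counts'].values())}, "
      f"R proportion = {final_proportion(s, 0):.3f}, "
      f"deaths = {s['death_counts']}")
```

prints

```
t_end = 1.09 h, final cells = 746, R proportion = 0.304, deaths = {0: 201, 1: 222}
```

Starting from a 1:1 mixture of 200 random firers and 200 strong retaliators,
the patch depletes after ~1.1 h of simulated growth; the strong retaliator
ends with ~70% of the surviving cells despite having absorbed the first
strike of every duel — each absorbed hit was answered twice, so random
firers died faster than their victims. Swapping `2TFT` for `TFT` (one
counterattack per hit) reverses the outcome: the same competition then ends
with the random firer at ~94% of the patch.

A thin CLI wraps the same machinery:

```bash
t6duel simulate --config duel.yaml --seed 3 --out run/   # one competition
t6duel sweep Rv2TFT --seeds 0,1,2,3,4 --out sweep.csv    # preset sweeps
t6duel assay --config duel.yaml --n-events 100           # static hit assay
```

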