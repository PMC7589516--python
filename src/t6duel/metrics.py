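"""Competition outcome measures, the static hit assay and comparative stats.

The main fitness measure is the invasion fitness omega_X = ln(sum V_X(end) /
sum V_X(start)), the natural log of a genotype's final-to-initial biovolume
ratio over one patch competition.  Extinction maps to a -inf sentinel that
the invasion layer interprets as "cannot invade / always invaded".

The static hit assay freezes a mixed cell configuration and measures, per
strategy, the probability that a single firing event strikes any cell and
that it strikes a non-clonemate — the geometric aiming advantage of
retaliators, separated from all growth and cost dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from . import combat
from .world import PatchState, StrategySpec

__all__ = [
    "AssaySample",
    "final_proportion",
    "strategist_fitness",
    "static_hit_assay",
    "growth_rate_summary",
    "two_sample_t",
    "cohens_d",
    "segregation_index",
]

NEG_INF = float("-inf")


@dataclass
class AssaySample:
    """Per-event or per-cell measurements for one strategy/genotype."""

    values: np.ndarray
    label: str

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.size == 0:
            raise ValueError("AssaySample requires at least one value")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.n > 1 else 0.0


def final_proportion(summary: dict, genotype: int) -> float:
    """Final cell-count fraction of the genotype; 0 if extinct."""
    counts = summary["final_counts"]
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty patch: final proportion undefined")
    return counts.get(genotype, 0) / total


def strategist_fitness(summary: dict, genotype: int) -> float:
    """omega = ln(final biovolume / initial biovolume); -inf if extinct."""
    v0 = summary["initial_biovolume"].get(genotype, 0.0)
    if v0 <= 0:
        raise ValueError(f"genotype {genotype} absent at start")
    v1 = summary["final_biovolume"].get(genotype, 0.0)
    if v1 <= 0:
        return NEG_INF
    return math.log(v1 / v0)


def growth_rate_summary(patch: PatchState, genotype: int) -> AssaySample:
    """Current per-cell specific growth rates of living cells of a genotype."""
    mask = (patch.genotype == genotype) & ~patch.lysing
    if not mask.any():
        raise ValueError(f"no live cells of genotype {genotype}")
    name = patch.strategies[genotype].name
    return AssaySample(patch.k_grow[mask], label=name)


# ---------------------------------------------------------------------------
# static hit assay
# ---------------------------------------------------------------------------


def static_hit_assay(patch: PatchState, strategy_pair, n_events: int, seed):
    """Hit probabilities of single firing events in a frozen configuration.

    For each strategy in ``strategy_pair`` (StrategySpec or genotype id),
    ``n_events`` independent firing events are simulated with no growth,
    death or movement.  Random firers launch one needle from a random
    surface point of a random focal cell.  Aiming retaliators are first
    struck by a random incoming needle fired by a random cell of the other
    genotype (attacks that miss are redrawn), then fire one reversed
    counterattack from the recorded entry point.  Returns a dict mapping
    strategy name to ``{"absolute": AssaySample, "non_clonemate":
    AssaySample}`` of 0/1 outcomes.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    rng = np.random.default_rng(seed)
    results = {}
    genotypes = sorted(patch.strategies)
    for strat in strategy_pair:
        if not isinstance(strat, StrategySpec):
            strat = patch.strategies[int(strat)]
        geno = strat.genotype
        focal_idx = np.flatnonzero((patch.genotype == geno) & ~patch.lysing)
        if focal_idx.size == 0:
            raise ValueError(f"no live cells of genotype {geno} in the patch")
        other = [g for g in genotypes if g != geno]
        other_idx = np.flatnonzero(np.isin(patch.genotype, other) & ~patch.lysing)
        absolute = np.zeros(n_events)
        nonclone = np.zeros(n_events)
        for k in range(n_events):
            if strat.is_retaliator and strat.aiming:
                needle = _provoke_retaliation(patch, rng, focal_idx, other_idx)
            else:
                idx = int(rng.choice(focal_idx))
                needle = _single_random_needle(patch, rng, idx)
            hits = combat.detect_hits([needle], patch)
            if hits:
                absolute[k] = 1.0
                if not hits[0].clonemate:
                    nonclone[k] = 1.0
        results[strat.name] = {
            "absolute": AssaySample(absolute, label=strat.name),
            "non_clonemate": AssaySample(nonclone, label=strat.name),
        }
    return results


def _single_random_needle(patch, rng, idx) -> combat.Needle:
    u = rng.uniform()
    pts, nrm = combat.surface_points(
        patch.center[idx][None], patch.axis[idx][None],
        patch.seg_length[idx], patch.params.R_cell, u,
    )
    return combat.Needle(int(patch.ids[idx]), pts[0], nrm[0],
                         patch.params.L_needle, 0)


def _provoke_retaliation(patch, rng, focal_idx, other_idx, max_tries=10000):
    """Expose focal cells to random attacks; return the reversed counter-needle."""
    if other_idx.size == 0:
        raise ValueError("retaliation assay needs attacker cells of another genotype")
    focal_ids = set(int(i) for i in patch.ids[focal_idx])
    for _ in range(max_tries):
        aidx = int(rng.choice(other_idx))
        incoming = _single_random_needle(patch, rng, aidx)
        hits = combat.detect_hits([incoming], patch)
        if hits and int(hits[0].target_id) in focal_ids:
            rev = -incoming.direction
            rev = rev / np.linalg.norm(rev)
            return combat.Needle(int(hits[0].target_id),
                                 hits[0].entry_point.copy(), rev,
                                 patch.params.L_needle, 0)
    raise RuntimeError("no incoming attack struck a focal cell; patch too sparse")


# ---------------------------------------------------------------------------
# comparative statistics (pooled-variance t and Cohen's d)
# ---------------------------------------------------------------------------


def two_sample_t(sample1, sample2):
    """Two-sample two-sided pooled-variance t test.

    Returns (t, dof, p) with dof = n1 + n2 - 2 and sample1-minus-sample2
    sign convention.  Zero pooled variance with equal means gives t = 0;
    with unequal means, a signed infinity sentinel (p = 0).
    """
    x1 = np.asarray(getattr(sample1, "values", sample1), float)
    x2 = np.asarray(getattr(sample2, "values", sample2), float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need n >= 2")
    dof = n1 + n2 - 2
    m1, m2 = x1.mean(), x2.mean()
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / dof
    if sp2 == 0:
        if m1 == m2:
            return 0.0, dof, 1.0
        return math.copysign(math.inf, m1 - m2), dof, 0.0
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), dof)
    return float(t), dof, float(p)


def cohens_d(sample1, sample2) -> float:
    """d = (mu1 - mu2) / sqrt((SD1^2 + SD2^2) / 2), sample1 minus sample2."""
    x1 = np.asarray(getattr(sample1, "values", sample1), float)
    x2 = np.asarray(getattr(sample2, "values", sample2), float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("both samples need n >= 2")
    denom = math.sqrt((x1.var(ddof=1) + x2.var(ddof=1)) / 2)
    diff = x1.mean() - x2.mean()
    if denom == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return float(diff / denom)


# ---------------------------------------------------------------------------
# spatial mixing
# ---------------------------------------------------------------------------


def segregation_index(patch: PatchState, radius: float) -> float:
    """Mean same-genotype fraction among each cell's neighbors within radius.

    1.0 for fully segregated monoclonal blocks; approximately the focal
    genotype's own frequency for randomly mixed labels.  Cells with no
    neighbor inside the radius are skipped.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    live = np.flatnonzero(~patch.lysing)
    genos = np.unique(patch.genotype[live])
    if genos.size < 2:
        raise ValueError("segregation index needs at least 2 genotypes")
    pts = patch.center[live, :2]
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, r=radius)
    fracs = []
    for k, lst in enumerate(neighbors):
        others = [m for m in lst if m != k]
        if not others:
            continue
        same = sum(patch.genotype[live[m]] == patch.genotype[live[k]] for m in others)
        fracs.append(same / len(others))
    if not fracs:
        raise ValueError("no cell has neighbors within the radius")
    return float(np.mean(fracs))
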