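"""Adaptive-dynamics layer: invasion indices, pairwise invasibility, ESS.

Fitness entries are omega_X(X|Y) = ln(final/initial biovolume) of strategist
X in a patch competition against Y; a primed opponent (Y') marks a pairing
simulated under mutual immunity.  A rare novel strategist invades a
metapopulation of residents when its entry index exceeds 1, and replaces the
resident permanently when the re-invasion guard also holds.

Two competition scales are supported.  Local: the invader competes only
inside mixed patches, so the index is the ratio of within-patch fitnesses.
Global: the rare strategist's patches are mixed while common residents sit
in resident-only patches, so the entry index compares the invader's
mixed-patch fitness with the resident's fitness among its own kind.

The weighted extensions cover partial mutual immunity between T6SS+ strains
(probability p_s that two strains share effector-immunity pairs) and
within-patch relatedness (probability I of perfect strategist segregation,
in which case a strategist grows beside mutually immune clonemates).

Sign conventions follow the printed forms: entry indices test "> 1"; the
re-invasion guards I_inv,2 of the weighted forms test "<= 1" (invader keeps
the patch), while the plain global guard tests ">= 1".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .world import StrategySpec

__all__ = [
    "FitnessTable",
    "InvasionOutcome",
    "local_invasion_index",
    "global_invasion_check",
    "mutual_immunity_indices",
    "relatedness_indices",
    "cheater_triplet",
    "build_invasion_trace",
    "pairwise_invasion_plot",
    "PIPResult",
    "find_ess",
    "ESSResult",
]

NEG_INF = float("-inf")


class FitnessTable:
    """Replicate omega values keyed by (focal, opponent, primed).

    ``focal`` and ``opponent`` are strategist labels; ``primed=True`` marks
    the mutually immune version of the pairing.  ``mean`` of a pairing with
    an extinct replicate (-inf) is -inf: one lost patch among replicates
    still reads as extinction for the log-fitness average.
    """

    def __init__(self):
        self._entries: dict[tuple, list] = {}

    def add(self, focal: str, opponent: str, omega: float, primed: bool = False):
        self._entries.setdefault((focal, opponent, bool(primed)), []).append(float(omega))

    def replicates(self, focal, opponent, primed=False) -> list:
        key = (focal, opponent, bool(primed))
        if key not in self._entries:
            raise KeyError(f"no fitness entries for {key}")
        return list(self._entries[key])

    def mean(self, focal, opponent, primed=False) -> float:
        vals = self.replicates(focal, opponent, primed)
        if any(v == NEG_INF for v in vals):
            return NEG_INF
        return float(np.mean(vals))

    def se(self, focal, opponent, primed=False) -> float:
        vals = [v for v in self.replicates(focal, opponent, primed)]
        if len(vals) < 2 or any(v == NEG_INF for v in vals):
            return 0.0
        return float(np.std(vals, ddof=1) / math.sqrt(len(vals)))

    def n(self, focal, opponent, primed=False) -> int:
        return len(self.replicates(focal, opponent, primed))

    def keys(self):
        return list(self._entries)

    def to_records(self):
        return [
            {"focal": f, "partner": o, "primed": pr, "replicate": i, "omega": w}
            for (f, o, pr), vals in self._entries.items()
            for i, w in enumerate(vals)
        ]


def _ratio(num: float, den: float) -> float:
    """Index ratio with extinction sentinels.

    Invader extinct (-inf numerator) -> 0 (cannot invade); resident fitness
    <= 0 or extinct -> +inf (invader wins trivially).
    """
    if num == NEG_INF:
        return 0.0
    if den == NEG_INF or den <= 0.0:
        return math.inf
    return num / den


@dataclass
class InvasionOutcome:
    """Classified invasion verdict at one parameter point."""

    scale: str
    verdict: str
    I1: float
    I2: float | None = None
    params: dict = field(default_factory=dict)
    neutral_band: float = 0.0


def _verdict(I1, I2=None, guard_ge=True, band=0.0) -> str:
    """Map index values to a verdict.

    ``guard_ge=True`` reads the guard as "I2 >= 1 resists" (plain global
    form); ``False`` reads it as "I2 <= 1 resists" (weighted I_inv,2 forms).
    """
    if I1 > 1 + band:
        if I2 is None:
            return "invades_and_resists"
        ok = (I2 >= 1 - band) if guard_ge else (I2 <= 1 + band)
        return "invades_and_resists" if ok else "invades_only"
    if abs(I1 - 1) <= band:
        return "neutral_boundary"
    return "cannot_invade"


# ---------------------------------------------------------------------------
# plain indices (local and global)
# ---------------------------------------------------------------------------


def local_invasion_index(table: FitnessTable, invader: str, resident: str) -> float:
    """Within-patch index: omega_inv(inv|res) / omega_res(inv|res)."""
    return _ratio(table.mean(invader, resident), table.mean(resident, invader))


def global_invasion_check(table: FitnessTable, invader: str, resident: str,
                          band: float = 0.0):
    """Entry and guard indices of the plain global constraints.

    I1 = omega_inv(inv|res) / omega_res(res|res)   (entry, > 1)
    I2 = omega_inv(inv|inv) / omega_res(inv|res)   (guard, >= 1)
    """
    I1 = _ratio(table.mean(invader, resident), table.mean(resident, resident))
    I2 = _ratio(table.mean(invader, invader), table.mean(resident, invader))
    return I1, I2, _verdict(I1, I2, guard_ge=True, band=band)


# ---------------------------------------------------------------------------
# weighted indices: mutual immunity and relatedness
# ---------------------------------------------------------------------------


def _carries(s) -> bool:
    return s.carries_t6ss if isinstance(s, StrategySpec) else bool(s.get("carries_t6ss", True))


def _fights_self(s) -> bool:
    """Whether two distinct strains of this strategy actually fight each other.

    Constitutive firers do; retaliators and unarmed strains paired with their
    own strategy never fire, so their self-pairing needs no immunity weight.
    """
    if isinstance(s, StrategySpec):
        return s.carries_t6ss and s.k_fire > 0
    return bool(s.get("carries_t6ss", True)) and s.get("k_fire", 0) > 0


def _name(s) -> str:
    return s.name if isinstance(s, StrategySpec) else s["name"]


def _wmix(table, focal, opponent, p):
    """p-weighted mix of primed and unprimed fitness of focal vs opponent."""
    if p == 0:
        return table.mean(focal, opponent, primed=False)
    if p == 1:
        return table.mean(focal, opponent, primed=True)
    a = table.mean(focal, opponent, primed=True)
    b = table.mean(focal, opponent, primed=False)
    if a == NEG_INF or b == NEG_INF:
        return NEG_INF
    return p * a + (1 - p) * b


def mutual_immunity_indices(table: FitnessTable, p_s: float, pairing,
                            band: float = 0.0):
    """Global entry/guard indices under partial mutual immunity.

    ``pairing = (invader, resident)`` as StrategySpec (or dicts with name /
    carries_t6ss / k_fire).  T6SS carriage is a prerequisite for immunity:
    any pairing that includes a T6SS- strain uses weight 0 for that pairing.
    For an armed invader A against an unarmed resident U:

        I1 = w_A(A|U) / w_U(U|U)
        I2 = w_U(A|U) / [p_s w_A(A|A') + (1-p_s) w_A(A|A)]   (<= 1 resists)

    and against an armed resident Y:

        I1 = [p_s w_A(A|Y') + (1-p_s) w_A(A|Y)] / w_Y(Y|Y)
        I2 = [p_s w_Y'(A|Y') + (1-p_s) w_Y(A|Y)] /
             [p_s w_A(A|A') + (1-p_s) w_A(A|A)]              (<= 1 resists)

    Self-pairings of strategies that never fight their own kind (unarmed
    strains, retaliators, non-firing cheaters) carry no immunity weight.
    """
    if not 0 <= p_s <= 1:
        raise ValueError("p_s must lie in [0, 1]")
    inv, res = pairing
    p_pair = p_s if (_carries(inv) and _carries(res)) else 0.0
    p_inv_self = p_s if _fights_self(inv) and _carries(inv) else 0.0
    p_res_self = p_s if _fights_self(res) and _carries(res) else 0.0
    A, Y = _name(inv), _name(res)

    num1 = _wmix(table, A, Y, p_pair)
    den1 = _wmix(table, Y, Y, p_res_self)
    I1 = _ratio(num1, den1)

    num2 = _wmix(table, Y, A, p_pair)
    den2 = _wmix(table, A, A, p_inv_self)
    I2 = _ratio(num2, den2)
    return I1, I2, _verdict(I1, I2, guard_ge=False, band=band)


def relatedness_indices(table: FitnessTable, I_weight: float, pairing,
                        scale: str = "local", band: float = 0.0):
    """Invasion indices under within-patch relatedness weight I.

    With probability ``I_weight`` a strategist is perfectly segregated and
    grows beside mutually immune clonemates (the primed self entry); with
    probability 1 - I it competes in the mixed patch.  ``pairing =
    (invader, resident)``; residents that never fight their own strategy
    reduce omega_common to the plain self entry.

    scale='local' returns the single index

        [I w_A(A|A') + (1-I) w_A(A|Y)] / [I w_Y(Y|Y') + (1-I) w_Y(A|Y)]

    scale='global' returns (I1, I2, verdict) with

        I1 = [I w_A(A|A') + (1-I) w_A(A|Y)] / w_Y,common       (> 1)
        I2 = [I w_Y(Y|Y') + (1-I) w_Y(A|Y)] /
             [I w_A(A|A') + (1-I) w_A(A|A)]                    (<= 1 resists)
    """
    if not 0 <= I_weight <= 1:
        raise ValueError("I_weight must lie in [0, 1]")
    inv, res = pairing
    A, Y = _name(inv), _name(res)
    Iw = I_weight

    def blend(a, b, w):
        if w == 0:
            return b
        if w == 1:
            return a
        if a == NEG_INF or b == NEG_INF:
            return NEG_INF
        return w * a + (1 - w) * b

    A_selfp = (table.mean(A, A, primed=True) if _fights_self(inv)
               else table.mean(A, A, primed=False))
    Y_selfp = (table.mean(Y, Y, primed=True) if _fights_self(res)
               else table.mean(Y, Y, primed=False))

    num = blend(A_selfp, table.mean(A, Y), Iw)
    if scale == "local":
        den = blend(Y_selfp, table.mean(Y, A), Iw)
        return _ratio(num, den)
    if scale != "global":
        raise ValueError("scale must be 'local' or 'global'")
    # omega_Y,common per the segregation reduction
    den1 = blend(Y_selfp, table.mean(Y, Y, primed=False), Iw)
    I1 = _ratio(num, den1)
    num2 = blend(Y_selfp, table.mean(Y, A), Iw)
    den2 = blend(A_selfp, table.mean(A, A, primed=False), Iw)
    I2 = _ratio(num2, den2)
    return I1, I2, _verdict(I1, I2, guard_ge=False, band=band)


def cheater_triplet(table: FitnessTable, p_s: float, parent, partner, cheater,
                    band: float = 0.0) -> dict:
    """Six global invasion indices for a {T6SS+ parent, partner, cheater} trio.

    The cheater carries its parent's T6SS genes (pays carriage, may share
    immunity when p_s > 0) but never fires.  Returns a dict keyed by
    '<invader>_vs_<resident>' with (I1, I2, verdict) for the parent-partner
    pair plus the four cheater pairings.
    """
    out = {}
    # the original pair's two indices plus four cheater-centric ones; each
    # mutual_immunity_indices call yields the (entry, guard) couple
    pairings = [
        (parent, partner),
        (cheater, parent),
        (cheater, partner),
    ]
    for invader, resident in pairings:
        key = f"{_name(invader)}_vs_{_name(resident)}"
        out[key] = mutual_immunity_indices(table, p_s, (invader, resident), band=band)
    return out


# ---------------------------------------------------------------------------
# 1-D invasion traces and 2-D pairwise invasibility
# ---------------------------------------------------------------------------


def _midpoint_refine(x: np.ndarray) -> np.ndarray:
    mids = 0.5 * (x[:-1] + x[1:])
    out = np.empty(x.size + mids.size)
    out[0::2] = x
    out[1::2] = mids
    return out


def build_invasion_trace(k_grid, omega_sweep: dict, band: float = 0.0):
    """Classify invasion along a firing-rate grid, midpoints interpolated.

    ``omega_sweep`` maps the four entry names 'w_inv_mixed', 'w_res_mixed',
    'w_inv_self', 'w_res_self' to arrays over ``k_grid``.  One extra value
    is linearly interpolated between each pair of adjacent grid points, then
    every rate is classified under both the local and the global constraint.
    Returns a list of dicts with local/global InvasionOutcome per rate.
    """
    k = np.asarray(k_grid, float)
    if k.size < 2 or np.any(np.diff(k) <= 0):
        raise ValueError("k_grid must be sorted strictly increasing, >= 2 points")
    needed = {"w_inv_mixed", "w_res_mixed", "w_inv_self", "w_res_self"}
    if set(omega_sweep) != needed:
        raise ValueError(f"omega_sweep must have keys {sorted(needed)}")
    arrays = {}
    for key, vals in omega_sweep.items():
        v = np.asarray(vals, float)
        if v.shape != k.shape:
            raise ValueError("omega arrays must match the grid length")
        arrays[key] = _midpoint_refine(v)
    k_fine = _midpoint_refine(k)
    trace = []
    for idx, rate in enumerate(k_fine):
        wi = arrays["w_inv_mixed"][idx]
        wr = arrays["w_res_mixed"][idx]
        wis = arrays["w_inv_self"][idx]
        wrs = arrays["w_res_self"][idx]
        I_loc = _ratio(wi, wr)
        loc = InvasionOutcome("local", _verdict(I_loc, band=band), I_loc,
                              params={"k_fire": float(rate)}, neutral_band=band)
        I1 = _ratio(wi, wrs)
        I2 = _ratio(wis, wr)
        glo = InvasionOutcome("global", _verdict(I1, I2, guard_ge=True, band=band),
                              I1, I2, params={"k_fire": float(rate)},
                              neutral_band=band)
        trace.append({"k_fire": float(rate), "interpolated": idx % 2 == 1,
                      "local": loc, "global": glo})
    return trace


@dataclass
class PIPResult:
    """Pairwise invasibility matrix: rows = resident rates, cols = mutant rates."""

    k_resident: np.ndarray
    k_mutant: np.ndarray
    I: np.ndarray
    se: np.ndarray
    missing: np.ndarray
    scale: str
    replicates: int

    def region(self, band: float = 0.0) -> np.ndarray:
        """+1 where the mutant invades, -1 where it cannot, 0 neutral/missing."""
        out = np.zeros_like(self.I, dtype=int)
        out[self.I > 1 + band] = 1
        out[self.I < 1 - band] = -1
        out[self.missing] = 0
        return out


def pairwise_invasion_plot(k_res_grid, k_mut_grid, simulator,
                           scale: str = "local", replicates: int = 1,
                           seed: int = 0) -> PIPResult:
    """Fill the invasion-index matrix over resident x mutant rate grids.

    ``simulator(k_res, k_mut, seed)`` must return a dict with keys
    'w_mut_mixed' (mutant fitness in the mixed patch), 'w_res_mixed'
    (resident fitness in the same patch) and, for the global scale,
    'w_res_self' (resident fitness among its own kind).  omega values are
    averaged over replicates before the ratio is taken.  A simulation
    failure marks the matrix entry missing rather than fabricating it.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if scale not in ("local", "global"):
        raise ValueError("scale must be 'local' or 'global'")
    kr = np.asarray(k_res_grid, float)
    km = np.asarray(k_mut_grid, float)
    I = np.full((kr.size, km.size), np.nan)
    se = np.zeros_like(I)
    missing = np.zeros(I.shape, bool)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(kr.size * km.size * replicates).reshape(
        kr.size, km.size, replicates
    ) % (2**31)
    for i, k1 in enumerate(kr):
        for j, k2 in enumerate(km):
            nums, dens = [], []
            try:
                for r in range(replicates):
                    res = simulator(float(k1), float(k2), int(seeds[i, j, r]))
                    nums.append(res["w_mut_mixed"])
                    dens.append(res["w_res_self" if scale == "global" else "w_res_mixed"])
            except Exception:
                missing[i, j] = True
                continue
            num = NEG_INF if any(v == NEG_INF for v in nums) else float(np.mean(nums))
            den = NEG_INF if any(v == NEG_INF for v in dens) else float(np.mean(dens))
            I[i, j] = _ratio(num, den)
            if len(nums) > 1 and np.isfinite(nums).all() and np.isfinite(dens).all():
                rel = (np.std(nums, ddof=1) / math.sqrt(len(nums)) / abs(num)) ** 2 \
                    + (np.std(dens, ddof=1) / math.sqrt(len(dens)) / abs(den)) ** 2
                se[i, j] = abs(I[i, j]) * math.sqrt(rel)
    return PIPResult(kr, km, I, se, missing, scale, replicates)


@dataclass
class ESSResult:
    """ESS candidates on the grid plus the incremental-invasion walks."""

    ess_rates: list
    walk_up: list
    walk_down: list
    converged: bool
    diagnostic: str = ""


def find_ess(pip: PIPResult | np.ndarray, k_grid=None, band: float = 0.0) -> ESSResult:
    """Grid rates no mutant can invade, and delta-walks from both grid ends.

    A resident rate k* is an ESS when every mutant row entry satisfies
    I <= 1 + band.  The delta-walk iterates single-grid-step invasions: from
    resident index i, move to i+1 (preferring higher rates) or i-1 whenever
    that one-step mutant invades; it reports convergence when the walks from
    both ends terminate at the same ESS rate.
    """
    if isinstance(pip, PIPResult):
        I = pip.I
        k = pip.k_resident
        if k_grid is not None:
            k = np.asarray(k_grid, float)
    else:
        I = np.asarray(pip, float)
        if k_grid is None:
            raise ValueError("k_grid required when passing a bare matrix")
        k = np.asarray(k_grid, float)
    n = k.size
    if I.shape != (n, n):
        raise ValueError("matrix must be square over the grid")

    # an ESS needs uninvadable mutants on BOTH sides, so only interior grid
    # points qualify; an uninvadable boundary rate is a truncation artifact
    ess = []
    boundary_note = ""
    for i in range(n):
        row = np.delete(I[i], i)
        if np.all(np.isfinite(row)) and np.all(row <= 1 + band):
            if 0 < i < n - 1:
                ess.append(float(k[i]))
            else:
                boundary_note = (f"rate {k[i]} is uninvadable but sits on the "
                                 "grid boundary; extend the grid")

    def walk(start: int) -> list:
        traj = [start]
        i = start
        for _ in range(3 * n):
            moved = False
            for j in (i + 1, i - 1):
                if 0 <= j < n and np.isfinite(I[i, j]) and I[i, j] > 1 + band:
                    i = j
                    traj.append(i)
                    moved = True
                    break
            if not moved:
                break
        return traj

    up = walk(0)
    down = walk(n - 1)
    converged = bool(ess) and k[up[-1]] in ess and k[down[-1]] in ess \
        and up[-1] == down[-1]
    diag = "" if ess else (boundary_note or "no resident rate uninvadable on this grid")
    return ESSResult([float(v) for v in ess],
                     [float(k[i]) for i in up],
                     [float(k[i]) for i in down],
                     converged, diag)
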