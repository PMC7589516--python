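"""Domain types, parameterization and seeded initial conditions.

The simulation world is a flat circular patch on which spherocylindrical
("capsule") cells live in the z = 0 plane.  Each cell belongs to a genotype
whose behaviour is described by a :class:`StrategySpec` (whether it carries a
T6SS, how it schedules firings, whom it is immune to).  A
:class:`PatchState` holds the full mutable state of one patch simulation:
cell pose/size arrays, the remaining resource quota ``E``, the clock and a
seeded RNG stream.

All state-changing operations elsewhere in the package are pure functions of
``(PatchState, params)`` plus the patch's own RNG, so identical seeds give
bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimParams",
    "StrategySpec",
    "Cell",
    "PatchState",
    "capsule_volume",
    "seg_length_for_volume",
    "make_initial_patch",
    "load_config",
    "strategy_presets",
    "InvalidGeometryError",
    "DensityTooHighError",
    "ConfigError",
]


class InvalidGeometryError(ValueError):
    """Raised for negative lengths/radii in capsule geometry."""


class DensityTooHighError(RuntimeError):
    """Raised when rejection sampling cannot place the requested cells."""


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration keys."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimParams:
    """Physical and numerical parameters of a patch simulation.

    Units are micrometres and hours throughout.

    Parameters
    ----------
    k_max : float
        Maximum specific growth rate (h^-1).  Default 2.08 (20-min doubling).
    V_0 : float
        Birth volume of a cell (µm^3).
    R_cell : float
        Capsule radius (µm).
    eta_division : float
        Amplitude of the uniform noise added to the division volume
        threshold ``2 V_0 + U[0, eta_division)`` (µm^3).  Also used to
        jitter initial volumes so division times desynchronize.
    eta_orientations : float
        Half-width of the uniform in-plane angle (radians) by which each
        daughter axis is perturbed at division.
    dt : float
        Timestep (h).
    E_0 : float
        Patch resource quota (µm^3 of producible biovolume at rate k_max).
    L_needle : float
        T6SS needle length (µm).
    L_penetration : float
        Hit-detection tolerance depth (µm); a needle must approach a target
        axis closer than ``R_cell - L_penetration`` to register a hit.
    N_hits : float
        Toxin translocations tolerated before lysis commits.  ``math.inf``
        models a fully immune strain.
    k_lysis : float
        Lysis rate (h^-1); lysing cells are removed after a delay 1/k_lysis.
    c_upfront : float
        Growth-rate fraction paid for T6SS gene carriage.
    c : float
        Pro-rata cost per firing (h); growth cost is ``c * N_firings / dt``.
    alpha : float
        Regularization weight of the mechanical relaxation solve.
    drag_coeff : float
        Per-unit-length drag entry of the diagonal drag matrix M.
    relax_tol : float
        Relaxation stops when the deepest residual overlap is below this (µm).
    relax_max_iter : int
        Iteration cap for the relaxation loop.
    max_steps : int
        Hard stop for a run (summary flagged "censored" if reached).
    arena_radius : float
        Radius of the disc in which initial cells are scattered (µm).
    """

    k_max: float = 2.08
    V_0: float = 1.57
    R_cell: float = 0.5
    eta_division: float = 0.5
    eta_orientations: float = 0.1
    dt: float = 0.005
    E_0: float = 4000.0
    L_needle: float = 1.0
    L_penetration: float = 0.05
    N_hits: float = 2
    k_lysis: float = 20.0
    c_upfront: float = 0.05
    c: float = 0.001
    alpha: float = 0.01
    drag_coeff: float = 1.0
    relax_tol: float = 0.05
    relax_max_iter: int = 12
    max_steps: int = 5000
    arena_radius: float = 28.0

    def __post_init__(self) -> None:
        positive = (
            "k_max", "V_0", "R_cell", "dt", "L_needle", "k_lysis",
            "drag_coeff", "relax_tol", "arena_radius",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"SimParams.{name} must be strictly positive")
        for name in ("eta_division", "eta_orientations", "L_penetration",
                     "E_0", "c", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimParams.{name} must be non-negative")
        if self.dt * self.k_max >= 0.1:
            raise ValueError("dt * k_max must be < 0.1 for stable stepping")
        if self.L_penetration >= self.R_cell:
            raise ValueError("L_penetration must be < R_cell")
        if not 0 <= self.c_upfront < 1:
            raise ValueError("c_upfront must lie in [0, 1)")
        if not (self.N_hits >= 1):
            raise ValueError("N_hits must be >= 1 (or inf for immune strains)")

    def with_(self, **kwargs) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StrategySpec:
    """A T6SS firing phenotype.

    ``k_fire`` is the constitutive (Poisson) firing rate used by random
    firers; retaliators leave it at 0 and instead answer each incoming hit
    with ``retaliation_multiplicity`` counterattacks.  ``aiming`` selects
    whether counterattacks are launched from the recorded entry point along
    the reversed attack direction (spatial sensing) or from random membrane
    sites.  ``cost_saving`` selects whether firing costs are paid per actual
    firing or at the flat reference rate ``k_fire_ref`` (the
    "no-cost-saving" knockout, which pays like a random firer of that rate).
    """

    name: str
    genotype: int
    carries_t6ss: bool = True
    k_fire: float = 0.0
    retaliation_multiplicity: int = 0
    aiming: bool = True
    cost_saving: bool = True
    k_fire_ref: float = 0.0
    immune_to: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.carries_t6ss:
            if self.k_fire != 0 or self.retaliation_multiplicity != 0:
                raise ValueError("a T6SS- strategist cannot fire or retaliate")
        if self.k_fire < 0 or self.k_fire_ref < 0:
            raise ValueError("firing rates must be non-negative")
        if self.retaliation_multiplicity < 0:
            raise ValueError("retaliation_multiplicity must be >= 0")
        object.__setattr__(
            self, "immune_to", frozenset(self.immune_to) | {self.genotype}
        )

    @property
    def is_retaliator(self) -> bool:
        return self.retaliation_multiplicity > 0


def strategy_presets(genotype_a: int = 0, genotype_b: int = 1):
    """Return a dict of standard strategist constructors.

    Each value is ``f(genotype, k_fire=...) -> StrategySpec`` for the field
    strategies: unarmed (U), random firer (R), tit-for-tat (TFT),
    2-tits-for-tat (2TFT) and the non-firing cheater (Rc).
    """

    def U(genotype, **kw):
        return StrategySpec("U", genotype, carries_t6ss=False, **kw)

    def R(genotype, k_fire=50.0, **kw):
        return StrategySpec("R", genotype, k_fire=k_fire, **kw)

    def TFT(genotype, **kw):
        return StrategySpec("TFT", genotype, retaliation_multiplicity=1, **kw)

    def TFT2(genotype, **kw):
        return StrategySpec("2TFT", genotype, retaliation_multiplicity=2, **kw)

    def Rc(genotype, **kw):
        return StrategySpec("Rc", genotype, k_fire=0.0, **kw)

    return {"U": U, "R": R, "TFT": TFT, "2TFT": TFT2, "Rc": Rc}


# ---------------------------------------------------------------------------
# capsule geometry
# ---------------------------------------------------------------------------


def capsule_volume(seg_length, radius):
    """Volume of a spherocylinder: pi r^2 L + (4/3) pi r^3.

    ``seg_length`` is the cylindrical section length (the full capsule spans
    ``seg_length + 2 radius`` tip to tip).
    """
    seg_length = np.asarray(seg_length, dtype=float)
    if np.any(seg_length < 0) or radius <= 0:
        raise InvalidGeometryError("seg_length must be >= 0 and radius > 0")
    vol = math.pi * radius**2 * seg_length + (4.0 / 3.0) * math.pi * radius**3
    return float(vol) if vol.ndim == 0 else vol


def seg_length_for_volume(volume, radius):
    """Inverse of :func:`capsule_volume` at fixed radius."""
    volume = np.asarray(volume, dtype=float)
    cap = (4.0 / 3.0) * math.pi * radius**3
    if np.any(volume < cap - 1e-12) or radius <= 0:
        raise InvalidGeometryError("volume below spherical minimum")
    seg = np.maximum(volume - cap, 0.0) / (math.pi * radius**2)
    return float(seg) if seg.ndim == 0 else seg


# ---------------------------------------------------------------------------
# cells and patch state
# ---------------------------------------------------------------------------


@dataclass
class Cell:
    """A read-mostly view of one cell, for inspection and small-scale APIs.

    The engine itself operates on the structure-of-arrays in
    :class:`PatchState`; ``Cell`` objects are materialized on demand.
    """

    id: int
    genotype: int
    strategy: StrategySpec
    center: np.ndarray
    axis: np.ndarray
    seg_length: float
    volume: float
    k_grow: float = 0.0
    translocations: int = 0
    lysing: bool = False
    lysis_deadline: float = math.inf
    pending_retaliations: list = field(default_factory=list)
    firings_last_step: int = 0


class PatchState:
    """Mutable state of one patch: cell arrays, resource, clock, RNG, log.

    Cell attributes are stored as parallel numpy arrays indexed 0..n-1;
    ``ids`` are stable unique integers.  ``pending`` maps cell id to the
    list of queued (entry_point, incoming_direction) retaliations.
    """

    def __init__(self, params: SimParams, strategies, rng: np.random.Generator):
        self.params = params
        # genotype id -> StrategySpec
        self.strategies = {s.genotype: s for s in strategies}
        self.rng = rng
        self.t = 0.0
        self.E = params.E_0
        self.step_count = 0
        self.depleted = params.E_0 <= 0
        self.censored = False
        self.next_id = 0
        self.events: list[dict] = []
        self.death_counts: dict[int, int] = {g: 0 for g in self.strategies}
        self.birth_counts: dict[int, int] = {g: 0 for g in self.strategies}
        n = 0
        self.ids = np.empty(n, dtype=np.int64)
        self.genotype = np.empty(n, dtype=np.int64)
        self.center = np.empty((n, 3), dtype=float)
        self.axis = np.empty((n, 3), dtype=float)
        self.seg_length = np.empty(n, dtype=float)
        self.volume = np.empty(n, dtype=float)
        self.div_threshold = np.empty(n, dtype=float)
        self.k_grow = np.empty(n, dtype=float)
        self.translocations = np.empty(n, dtype=np.int64)
        self.lysing = np.empty(n, dtype=bool)
        self.lysis_deadline = np.empty(n, dtype=float)
        self.firings_last_step = np.empty(n, dtype=np.int64)
        self.pending: dict[int, list] = {}

    # -- bookkeeping --------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.ids.size

    _ARRAYS = (
        "ids", "genotype", "center", "axis", "seg_length", "volume",
        "div_threshold", "k_grow", "translocations", "lysing",
        "lysis_deadline", "firings_last_step",
    )

    def append_cells(self, **cols) -> None:
        for name in self._ARRAYS:
            cur = getattr(self, name)
            new = np.asarray(cols[name], dtype=cur.dtype)
            setattr(self, name, np.concatenate([cur, new.reshape((-1,) + cur.shape[1:])]))

    def keep(self, mask: np.ndarray) -> None:
        removed = self.ids[~mask]
        for name in self._ARRAYS:
            setattr(self, name, getattr(self, name)[mask])
        for cid in removed:
            self.pending.pop(int(cid), None)

    def alive_mask(self) -> np.ndarray:
        """Living, non-lysing cells (the ones that grow and eat)."""
        return ~self.lysing

    def genotype_counts(self, include_lysing: bool = False) -> dict[int, int]:
        mask = np.ones(self.n_cells, bool) if include_lysing else ~self.lysing
        return {
            g: int(np.sum((self.genotype == g) & mask)) for g in self.strategies
        }

    def genotype_biovolume(self, include_lysing: bool = False) -> dict[int, float]:
        mask = np.ones(self.n_cells, bool) if include_lysing else ~self.lysing
        return {
            g: float(np.sum(self.volume[(self.genotype == g) & mask]))
            for g in self.strategies
        }

    def log(self, kind: str, **fields) -> None:
        self.events.append({"step": self.step_count, "t": self.t, "type": kind, **fields})

    # -- views --------------------------------------------------------------

    def cell(self, index: int) -> Cell:
        cid = int(self.ids[index])
        return Cell(
            id=cid,
            genotype=int(self.genotype[index]),
            strategy=self.strategies[int(self.genotype[index])],
            center=self.center[index].copy(),
            axis=self.axis[index].copy(),
            seg_length=float(self.seg_length[index]),
            volume=float(self.volume[index]),
            k_grow=float(self.k_grow[index]),
            translocations=int(self.translocations[index]),
            lysing=bool(self.lysing[index]),
            lysis_deadline=float(self.lysis_deadline[index]),
            pending_retaliations=list(self.pending.get(cid, [])),
            firings_last_step=int(self.firings_last_step[index]),
        )

    @property
    def cells(self) -> list[Cell]:
        return [self.cell(i) for i in range(self.n_cells)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "genotype": self.genotype,
                "x": self.center[:, 0],
                "y": self.center[:, 1],
                "z": self.center[:, 2],
                "ax": self.axis[:, 0],
                "ay": self.axis[:, 1],
                "az": self.axis[:, 2],
                "seg_length": self.seg_length,
                "volume": self.volume,
                "k_grow": self.k_grow,
                "translocations": self.translocations,
                "lysing": self.lysing,
            }
        )


# ---------------------------------------------------------------------------
# initial-condition generation
# ---------------------------------------------------------------------------


def _segment_gap(c1, a1, l1, c2, a2, l2, R):
    """Scalar capsule-capsule gap used during placement (small n)."""
    from .mechanics import seg_seg_closest  # local import to avoid a cycle

    p1 = (c1 - a1 * (l1 / 2))[None, :]
    d1 = (a1 * l1)[None, :]
    p2 = (c2 - a2 * (l2 / 2))[None, :]
    d2 = (a2 * l2)[None, :]
    _, _, cp1, cp2, dist = seg_seg_closest(p1, d1, p2, d2)
    return float(dist[0]) - 2.0 * R


def make_initial_patch(params: SimParams, strategies, counts, seed) -> PatchState:
    """Scatter a seeded mixture of strategists uniformly in the arena disc.

    Cells are placed by rejection sampling (uniform position in the disc,
    uniform in-plane orientation) until all pairwise capsule gaps are
    non-negative; initial volumes are ``V_0 + U[0, eta_division)`` so that
    division times desynchronize.  Identical seeds give identical patches.
    """
    strategies = list(strategies)
    counts = list(counts)
    if len(counts) != len(strategies):
        raise ValueError("counts and strategies must have the same length")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")

    rng = np.random.default_rng(seed)
    patch = PatchState(params, strategies, rng)
    R = params.R_cell
    total = int(sum(counts))
    if total == 0:
        return patch

    genotypes = np.concatenate(
        [np.full(c, s.genotype, dtype=np.int64) for s, c in zip(strategies, counts)]
    )
    volumes = params.V_0 + rng.uniform(0.0, params.eta_division, total)
    div_thresholds = 2 * params.V_0 + rng.uniform(0.0, params.eta_division, total)
    seg = seg_length_for_volume(volumes, R)

    centers = np.zeros((total, 3))
    axes = np.zeros((total, 3))
    max_attempts = 5000
    from .mechanics import seg_seg_closest

    for i in range(total):
        placed = False
        for _ in range(max_attempts):
            r = params.arena_radius * math.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2 * math.pi)
            theta = rng.uniform(0.0, 2 * math.pi)
            c = np.array([r * math.cos(phi), r * math.sin(phi), 0.0])
            a = np.array([math.cos(theta), math.sin(theta), 0.0])
            if i == 0:
                placed = True
                break
            p1 = np.repeat((c - a * seg[i] / 2)[None, :], i, axis=0)
            d1 = np.repeat((a * seg[i])[None, :], i, axis=0)
            p2 = centers[:i] - axes[:i] * seg[:i, None] / 2
            d2 = axes[:i] * seg[:i, None]
            _, _, _, _, dist = seg_seg_closest(p1, d1, p2, d2)
            if np.min(dist) - 2 * R >= 0:
                placed = True
                break
        if not placed:
            raise DensityTooHighError(
                f"could not place cell {i + 1}/{total} after {max_attempts} attempts"
            )
        centers[i] = c
        axes[i] = a

    patch.append_cells(
        ids=np.arange(total, dtype=np.int64),
        genotype=genotypes,
        center=centers,
        axis=axes,
        seg_length=seg,
        volume=volumes,
        div_threshold=div_thresholds,
        k_grow=np.full(total, params.k_max),
        translocations=np.zeros(total, dtype=np.int64),
        lysing=np.zeros(total, dtype=bool),
        lysis_deadline=np.full(total, math.inf),
        firings_last_step=np.zeros(total, dtype=np.int64),
    )
    patch.next_id = total
    for g, c in zip([s.genotype for s in strategies], counts):
        patch.birth_counts[g] += int(c)
    return patch


# ---------------------------------------------------------------------------
# configuration documents
# ---------------------------------------------------------------------------

_STRATEGY_FIELDS = {f.name for f in fields(StrategySpec)}
_PARAM_FIELDS = {f.name for f in fields(SimParams)}
_EXPERIMENT_FIELDS = {
    "counts", "seed", "snapshot_every", "label",
}


def _build_params(doc: dict) -> SimParams:
    unknown = set(doc) - _PARAM_FIELDS
    if unknown:
        raise ConfigError(f"unknown params keys: {sorted(unknown)}")
    doc = dict(doc)
    if isinstance(doc.get("N_hits"), str):
        if doc["N_hits"].lower() in ("inf", "infinity"):
            doc["N_hits"] = math.inf
        else:
            raise ConfigError("N_hits must be a number or 'inf'")
    return SimParams(**doc)


def _build_strategy(doc: dict) -> StrategySpec:
    unknown = set(doc) - _STRATEGY_FIELDS
    if unknown:
        raise ConfigError(f"unknown strategy keys: {sorted(unknown)}")
    doc = dict(doc)
    if "immune_to" in doc:
        doc["immune_to"] = frozenset(doc["immune_to"])
    return StrategySpec(**doc)


def load_config(source) -> dict:
    """Parse a YAML/JSON config document with blocks {params, strategies, experiment}.

    ``source`` may be a path, a file object or a YAML string.  Unknown keys
    anywhere are rejected.  Returns a dict with 'params' (:class:`SimParams`),
    'strategies' (list of :class:`StrategySpec`) and 'experiment' (dict).
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    elif isinstance(source, str) and "\n" in source:
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(doc) - {"params", "strategies", "experiment"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    params = _build_params(doc.get("params", {}) or {})
    strategies = [_build_strategy(s) for s in doc.get("strategies", []) or []]
    experiment = dict(doc.get("experiment", {}) or {})
    unknown = set(experiment) - _EXPERIMENT_FIELDS
    if unknown:
        raise ConfigError(f"unknown experiment keys: {sorted(unknown)}")
    genos = [s.genotype for s in strategies]
    if len(set(genos)) != len(genos):
        raise ConfigError("strategy genotype ids must be unique")
    return {"params": params, "strategies": strategies, "experiment": experiment}


def export_patch_csv(patch: PatchState, path) -> None:
    """Write the initial-condition fixture CSV (one row per cell)."""
    cols = ["id", "genotype", "x", "y", "z", "ax", "ay", "az", "seg_length", "volume"]
    patch.to_dataframe()[cols].to_csv(path, index=False)
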