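"""Shared fixtures: hand-built patches and strategy constructors."""

import math

import numpy as np
import pytest

from t6duel.world import PatchState, SimParams, capsule_volume, strategy_presets


@pytest.fixture
def presets():
    return strategy_presets()


@pytest.fixture
def patch_factory():
    """Build a PatchState with explicit cell poses.

    ``poses`` is a list of (center, axis, seg_length[, genotype]) tuples;
    axes are normalized and z-components dropped.
    """

    def build(params: SimParams, strategies, poses, seed=0):
        patch = PatchState(params, strategies, np.random.default_rng(seed))
        n = len(poses)
        centers, axes, segs, genos = [], [], [], []
        for pose in poses:
            c, a, L = pose[0], pose[1], pose[2]
            g = pose[3] if len(pose) > 3 else strategies[0].genotype
            a = np.asarray(a, float)
            a[2] = 0.0
            a = a / np.linalg.norm(a)
            centers.append([c[0], c[1], 0.0])
            axes.append(a)
            segs.append(float(L))
            genos.append(int(g))
        segs = np.asarray(segs)
        vols = capsule_volume(segs, params.R_cell)
        patch.append_cells(
            ids=np.arange(n, dtype=np.int64),
            genotype=np.asarray(genos, dtype=np.int64),
            center=np.asarray(centers),
            axis=np.asarray(axes),
            seg_length=segs,
            volume=np.atleast_1d(vols),
            div_threshold=np.full(n, 2 * params.V_0 + params.eta_division),
            k_grow=np.full(n, params.k_max),
            translocations=np.zeros(n, dtype=np.int64),
            lysing=np.zeros(n, dtype=bool),
            lysis_deadline=np.full(n, math.inf),
            firings_last_step=np.zeros(n, dtype=np.int64),
        )
        patch.next_id = n
        for g in set(genos):
            patch.birth_counts[g] = patch.birth_counts.get(g, 0) + genos.count(g)
        return patch

    return build
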