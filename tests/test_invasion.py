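"""Invasion algebra, weighted indices, PIP machinery and ESS search."""

import math

import numpy as np
import pytest

from t6duel.invasion import (
    ESSResult,
    FitnessTable,
    PIPResult,
    build_invasion_trace,
    cheater_triplet,
    find_ess,
    global_invasion_check,
    local_invasion_index,
    mutual_immunity_indices,
    pairwise_invasion_plot,
    relatedness_indices,
)
from t6duel.world import StrategySpec, strategy_presets


def _table(entries):
    t = FitnessTable()
    for (f, o, pr), w in entries.items():
        t.add(f, o, w, primed=pr)
    return t


def random_table(rng, names=("R", "U")):
    ent = {}
    for f in names:
        for o in names:
            for pr in (False, True):
                ent[(f, o, pr)] = rng.uniform(0.2, 3.0)
    return ent


class TestLocalIndex:
    def test_neutral(self):
        t = _table({("R", "U", False): 1.5, ("U", "R", False): 1.5})
        assert local_invasion_index(t, "R", "U") == 1.0

    def test_arithmetic(self):
        t = _table({("R", "U", False): math.log(4), ("U", "R", False): math.log(2)})
        assert local_invasion_index(t, "R", "U") == pytest.approx(2.0)

    def test_sentinels(self):
        t = _table({("R", "U", False): 1.0, ("U", "R", False): -1.0})
        assert local_invasion_index(t, "R", "U") == math.inf
        t = _table({("R", "U", False): float("-inf"), ("U", "R", False): 1.0})
        assert local_invasion_index(t, "R", "U") == 0.0


class TestGlobalCheck:
    def test_symmetric_table_neutral_boundary(self):
        t = _table({(f, o, False): 1.0 for f in "RU" for o in "RU"})
        I1, I2, verdict = global_invasion_check(t, "R", "U")
        assert I1 == I2 == 1.0
        assert verdict == "neutral_boundary"

    def test_substitution_example(self):
        t = _table({("R", "U", False): 2.0, ("U", "U", False): 1.0,
                    ("R", "R", False): 1.0, ("U", "R", False): 0.5})
        I1, I2, verdict = global_invasion_check(t, "R", "U")
        assert I1 == pytest.approx(2.0)
        assert I2 == pytest.approx(2.0)
        assert verdict == "invades_and_resists"

    def test_mutual_exclusion_for_paired_firers(self):
        """If R2 invades-and-resists R1, R1 cannot pass the entry test."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            ent = random_table(rng, names=("R1", "R2"))
            # the mixed patch is shared: both focal entries come from it
            t = _table(ent)
            I1_21, I2_21, v21 = global_invasion_check(t, "R2", "R1")
            I1_12, I2_12, v12 = global_invasion_check(t, "R1", "R2")
            # guard of one invasion is the reciprocal of the other's entry
            assert I1_12 == pytest.approx(1.0 / I2_21, rel=1e-12)
            if v21 == "invades_and_resists":
                assert v12 != "invades_and_resists"


class TestWeightedIndicesAgainstPlainArithmetic:
    """Spreadsheet-style literal evaluation on randomized tables."""

    def setup_method(self):
        pre = strategy_presets()
        self.R = pre["R"](0, k_fire=50.0)
        self.U = pre["U"](1)
        self.T2 = pre["2TFT"](1)
        self.Rc = pre["Rc"](2)

    def test_mutual_immunity_r_vs_u(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(100):
            e = random_table(rng, names=("R", "U"))
            t = _table(e)
            for p_s in (0.0, 0.37, 1.0):
                I1, I2, _ = mutual_immunity_indices(t, p_s, (self.R, self.U))
                # literal printed forms (U never immune)
                oracle1 = e[("R", "U", False)] / e[("U", "U", False)]
                oracle2 = e[("U", "R", False)] / (
                    p_s * e[("R", "R", True)] + (1 - p_s) * e[("R", "R", False)])
                worst = max(worst, abs(I1 - oracle1), abs(I2 - oracle2))
        assert worst < 1e-12

    def test_mutual_immunity_r_vs_retaliator(self):
        rng = np.random.default_rng(12)
        worst = 0.0
        for _ in range(100):
            e = random_table(rng, names=("R", "2TFT"))
            t = _table(e)
            for p_s in (0.0, 0.37, 1.0):
                I1, I2, _ = mutual_immunity_indices(t, p_s, (self.R, self.T2))
                oracle1 = (p_s * e[("R", "2TFT", True)]
                           + (1 - p_s) * e[("R", "2TFT", False)]) / e[("2TFT", "2TFT", False)]
                oracle2 = (p_s * e[("2TFT", "R", True)]
                           + (1 - p_s) * e[("2TFT", "R", False)]) / (
                    p_s * e[("R", "R", True)] + (1 - p_s) * e[("R", "R", False)])
                worst = max(worst, abs(I1 - oracle1), abs(I2 - oracle2))
        assert worst < 1e-12

    def test_ps_zero_reduces_to_plain_global(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            t = _table(random_table(rng, names=("R", "U")))
            I1, I2, _ = mutual_immunity_indices(t, 0.0, (self.R, self.U))
            G1, G2, _ = global_invasion_check(t, "R", "U")
            assert I1 == pytest.approx(G1, rel=1e-14)
            assert I2 == pytest.approx(1.0 / G2, rel=1e-14)

    def test_ps_one_limit(self):
        rng = np.random.default_rng(14)
        e = random_table(rng, names=("R", "2TFT"))
        t = _table(e)
        I1, _, _ = mutual_immunity_indices(t, 1.0, (self.R, self.T2))
        assert I1 == pytest.approx(
            e[("R", "2TFT", True)] / e[("2TFT", "2TFT", False)], rel=1e-14)

    def test_relatedness_local_oracle_and_limits(self):
        rng = np.random.default_rng(15)
        worst = 0.0
        for _ in range(100):
            e = random_table(rng, names=("R", "U"))
            t = _table(e)
            for Iw in (0.01, 0.5, 0.99):
                idx = relatedness_indices(t, Iw, (self.R, self.U), scale="local")
                # U is passive with self: its primed self entry reduces
                oracle = (Iw * e[("R", "R", True)] + (1 - Iw) * e[("R", "U", False)]) / (
                    Iw * e[("U", "U", False)] + (1 - Iw) * e[("U", "R", False)])
                worst = max(worst, abs(idx - oracle))
            # I = 0 recovers the plain local index
            assert relatedness_indices(t, 0.0, (self.R, self.U), scale="local") \
                == pytest.approx(local_invasion_index(t, "R", "U"), rel=1e-14)
            # I = 1: pure self-pairing ratio
            assert relatedness_indices(t, 1.0, (self.R, self.U), scale="local") \
                == pytest.approx(e[("R", "R", True)] / e[("U", "U", False)], rel=1e-14)
        assert worst < 1e-12

    def test_relatedness_global_oracle(self):
        rng = np.random.default_rng(16)
        worst = 0.0
        for _ in range(100):
            e = random_table(rng, names=("R", "2TFT"))
            t = _table(e)
            for Iw in (0.01, 0.5, 0.99):
                I1, I2, _ = relatedness_indices(t, Iw, (self.R, self.T2), scale="global")
                num = Iw * e[("R", "R", True)] + (1 - Iw) * e[("R", "2TFT", False)]
                # retaliator never fires at its own strategy: primed = plain
                y_selfp = e[("2TFT", "2TFT", False)]
                o1 = num / (Iw * y_selfp + (1 - Iw) * e[("2TFT", "2TFT", False)])
                o2 = (Iw * y_selfp + (1 - Iw) * e[("2TFT", "R", False)]) / (
                    Iw * e[("R", "R", True)] + (1 - Iw) * e[("R", "R", False)])
                worst = max(worst, abs(I1 - o1), abs(I2 - o2))
        assert worst < 1e-12

    def test_cheater_triplet_six_indices(self):
        rng = np.random.default_rng(17)
        e = random_table(rng, names=("R", "U", "Rc"))
        t = _table(e)
        out = cheater_triplet(t, 0.4, self.R, self.U, self.Rc)
        assert set(out) == {"R_vs_U", "Rc_vs_R", "Rc_vs_U"}
        # six index values in total
        vals = [v for pair in out.values() for v in pair[:2]]
        assert len(vals) == 6
        # cheater vs parent entry index, literal arithmetic (Rc passive with self)
        I1, I2, _ = out["Rc_vs_R"]
        o1 = (0.4 * e[("Rc", "R", True)] + 0.6 * e[("Rc", "R", False)]) / (
            0.4 * e[("R", "R", True)] + 0.6 * e[("R", "R", False)])
        assert I1 == pytest.approx(o1, rel=1e-12)


class TestInvasionTrace:
    def _sweep(self, k, f):
        return {key: f(key, k) for key in
                ("w_inv_mixed", "w_res_mixed", "w_inv_self", "w_res_self")}

    def test_midpoint_grid(self):
        k = np.array([0.0, 50.0])
        sweep = {key: np.array([1.0, 2.0]) for key in
                 ("w_inv_mixed", "w_res_mixed", "w_inv_self", "w_res_self")}
        trace = build_invasion_trace(k, sweep)
        assert [pt["k_fire"] for pt in trace] == [0.0, 25.0, 50.0]
        assert [pt["interpolated"] for pt in trace] == [False, True, False]

    def test_constant_omegas_uniform_classification(self):
        k = np.array([10.0, 20.0, 30.0])
        sweep = {"w_inv_mixed": np.full(3, 2.0), "w_res_mixed": np.full(3, 1.0),
                 "w_inv_self": np.full(3, 2.0), "w_res_self": np.full(3, 1.0)}
        trace = build_invasion_trace(k, sweep)
        verdicts = {pt["global"].verdict for pt in trace}
        assert verdicts == {"invades_and_resists"}

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            build_invasion_trace([2.0, 1.0], {
                "w_inv_mixed": [1, 1], "w_res_mixed": [1, 1],
                "w_inv_self": [1, 1], "w_res_self": [1, 1]})


def _stub_simulator(f):
    """Deterministic simulator stub with a known omega surface."""

    def simulate(k_res, k_mut, seed):
        return {
            "w_mut_mixed": f(k_mut, k_res),
            "w_res_mixed": f(k_res, k_mut),
            "w_res_self": f(k_res, k_res),
        }

    return simulate


class TestPairwiseInvasionPlot:
    def test_matrix_matches_closed_form(self):
        k = np.array([0.0, 25.0, 50.0])

        def f(mine, theirs):
            return 1.0 + 0.01 * (mine - theirs) - 1e-5 * mine**2

        pip = pairwise_invasion_plot(k, k, _stub_simulator(f), scale="local",
                                     replicates=2, seed=1)
        for i, kr in enumerate(k):
            for j, km in enumerate(k):
                assert pip.I[i, j] == pytest.approx(f(km, kr) / f(kr, km), rel=1e-12)

    def test_diagonal_neutral(self):
        k = np.array([10.0, 30.0])
        pip = pairwise_invasion_plot(k, k, _stub_simulator(lambda a, b: 1.0 + 0.01 * (a - b)),
                                     scale="local", replicates=1, seed=0)
        np.testing.assert_allclose(np.diag(pip.I), 1.0)

    def test_failures_marked_missing(self):
        def bad(k_res, k_mut, seed):
            if k_mut > 20:
                raise RuntimeError("boom")
            return {"w_mut_mixed": 1.0, "w_res_mixed": 1.0, "w_res_self": 1.0}

        k = np.array([10.0, 30.0])
        pip = pairwise_invasion_plot(k, k, bad, scale="local", replicates=1, seed=0)
        assert pip.missing[0, 1] and pip.missing[1, 1]
        assert not pip.missing[0, 0]


class TestFindESS:
    def _stub_matrix(self, k, K):
        kk_res, kk_mut = np.meshgrid(k, k, indexing="ij")
        return 1.0 + (kk_mut - kk_res) * (K - kk_res) / K**2

    def test_known_root_localized_exactly(self):
        k = np.arange(0.0, 251.0, 25.0)
        K = 150.0
        I = self._stub_matrix(k, K)
        res = find_ess(I, k_grid=k)
        assert res.ess_rates == [K]

    def test_walks_converge_from_both_ends(self):
        k = np.arange(0.0, 251.0, 25.0)
        K = 150.0
        res = find_ess(self._stub_matrix(k, K), k_grid=k)
        assert res.walk_up[-1] == K
        assert res.walk_down[-1] == K
        assert res.converged

    def test_monotone_matrix_has_no_ess(self):
        k = np.arange(0.0, 101.0, 25.0)
        kk_res, kk_mut = np.meshgrid(k, k, indexing="ij")
        I = 1.0 + 0.001 * (kk_mut - kk_res)  # faster always wins
        res = find_ess(I, k_grid=k)
        assert res.ess_rates == []
        assert res.diagnostic != ""

    def test_group_productivity_penalty_lowers_global_ess(self):
        """Global competition selects a lower stub ESS than local."""
        k = np.arange(0.0, 201.0, 10.0)
        a, b = 1e-5, 1e-3

        def f(mine, theirs):
            # benefit of outgunning the partner, own-rate quadratic cost;
            # analytic ESS: b/a locally, b/(2a) globally
            return 2.0 + b * (mine - theirs) - a * mine**2

        sim = _stub_simulator(f)
        loc = pairwise_invasion_plot(k, k, sim, scale="local", seed=0)
        glo = pairwise_invasion_plot(k, k, sim, scale="global", seed=0)
        ess_loc = find_ess(loc)
        ess_glo = find_ess(glo)
        assert ess_loc.ess_rates == [pytest.approx(b / a)]
        assert ess_glo.ess_rates == [pytest.approx(b / (2 * a))]
        assert min(ess_glo.ess_rates) < min(ess_loc.ess_rates)
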