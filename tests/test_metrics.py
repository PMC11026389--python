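"""Metrics: Fréchet distance, normalization, bootstrap null, dendrogram."""

import itertools

import numpy as np
import pytest
from scipy import linalg, stats

from perceptography import ParameterError
from perceptography.image_space import ImageRaster
from perceptography.metrics import (
    ClassMaxRegistry,
    DendrogramNode,
    FeatureSet,
    bootstrap_family_null,
    convergence_curve,
    empirical_p_value,
    enumerate_family_null,
    export_dendrogram_edgelist,
    frechet_distance,
    import_dendrogram_edgelist,
    motion_energy,
    normalized_frechet,
    normalized_frechet_two_pass,
    pixel_rmse,
    singleton_feature_set,
    welch_t,
)
from perceptography.trials import TrialRecord


def fset(arr):
    return FeatureSet(np.asarray(arr, dtype=float))


class TestFrechet:
    def test_identical_sets_have_zero_distance(self, rng):
        x = rng.normal(size=(20, 4))
        assert frechet_distance(fset(x), fset(x)) == pytest.approx(0.0, abs=1e-8)

    def test_one_dimensional_closed_form(self):
        # samples fitted as Normal(0,1) vs Normal(1,1): distance is exactly 1
        a = fset([[-1.0], [0.0], [1.0]])
        b = fset([[0.0], [1.0], [2.0]])
        assert frechet_distance(a, b) == pytest.approx(1.0, abs=1e-8)

    def test_matches_independent_sqrtm_formula(self, rng):
        """Textbook formula via scipy.linalg.sqrtm as the oracle."""
        for _ in range(5):
            x = rng.normal(size=(30, 4))
            y = rng.normal(loc=0.3, size=(25, 4)) @ rng.normal(size=(4, 4))
            mu_x, mu_y = x.mean(0), y.mean(0)
            cx = np.cov(x, rowvar=False, ddof=1)
            cy = np.cov(y, rowvar=False, ddof=1)
            eps_x = 1e-6 * np.trace(cx) / 4
            eps_y = 1e-6 * np.trace(cy) / 4
            cx = cx + eps_x * np.eye(4)
            cy = cy + eps_y * np.eye(4)
            covmean = linalg.sqrtm(cx @ cy)
            if np.iscomplexobj(covmean):
                covmean = covmean.real
            want = float(
                (mu_x - mu_y) @ (mu_x - mu_y)
                + np.trace(cx) + np.trace(cy) - 2 * np.trace(covmean)
            )
            assert frechet_distance(fset(x), fset(y)) == pytest.approx(want, abs=1e-6)

    def test_symmetry_and_nonnegativity(self, rng):
        x, y = rng.normal(size=(12, 6)), rng.normal(size=(15, 6))
        d_ab = frechet_distance(fset(x), fset(y))
        d_ba = frechet_distance(fset(y), fset(x))
        assert d_ab == pytest.approx(d_ba, rel=1e-9)
        assert d_ab >= 0

    def test_input_validation(self, rng):
        with pytest.raises(ParameterError):
            frechet_distance(fset(rng.normal(size=(1, 3))), fset(rng.normal(size=(5, 3))))
        with pytest.raises(ParameterError):
            frechet_distance(fset(rng.normal(size=(5, 3))), fset(rng.normal(size=(5, 4))))


class TestNormalizedFrechet:
    def test_streaming_vs_two_pass(self):
        raws = [2.0, 5.0, 3.0]
        reg = ClassMaxRegistry()
        streamed = []
        for raw in raws:
            m = reg.observe("cls", raw)
            streamed.append(raw / m)
        assert streamed == pytest.approx([1.0, 1.0, 0.6])
        assert normalized_frechet_two_pass(raws, ["cls"] * 3) == pytest.approx(
            [0.4, 1.0, 0.6]
        )

    def test_maxima_never_decrease(self):
        reg = ClassMaxRegistry()
        reg.observe("c", 5.0)
        reg.observe("c", 2.0)
        assert reg.maximum("c") == 5.0

    def test_unseen_class_instructs_initialization(self, rng):
        reg = ClassMaxRegistry()
        with pytest.raises(ParameterError, match="initialize"):
            reg.maximum("never_seen")

    def test_endpoints(self, rng):
        x = rng.normal(size=(10, 3))
        y = rng.normal(loc=2.0, size=(10, 3))
        reg = ClassMaxRegistry()
        v = normalized_frechet(fset(x), fset(y), "c", reg)
        assert v == pytest.approx(1.0)  # raw equals the (fresh) class max
        assert normalized_frechet(fset(x), fset(x), "c", reg) == pytest.approx(0.0)


class TestPixelMetrics:
    def test_rmse_identity_and_extremes(self):
        zeros = ImageRaster(np.zeros((8, 8, 3)))
        ones = ImageRaster(np.ones((8, 8, 3)))
        assert pixel_rmse(zeros, zeros) == 0.0
        assert pixel_rmse(zeros, ones) == pytest.approx(1.0)

    def test_rmse_matches_double_loop(self, rng):
        a, b = rng.random((6, 5, 3)), rng.random((6, 5, 3))
        total = 0.0
        for i in range(6):
            for j in range(5):
                for c in range(3):
                    total += (a[i, j, c] - b[i, j, c]) ** 2
        want = np.sqrt(total / (6 * 5 * 3))
        assert pixel_rmse(a, b) == pytest.approx(want, rel=1e-12)

    def test_motion_energy_zero_for_constant_sequence(self):
        f = np.full((4, 4, 3), 0.3)
        assert motion_energy([f, f, f]) == 0.0

    def test_motion_energy_increases_with_perturbation_frame(self, rng):
        seed = rng.random((8, 8, 3))
        pert = np.clip(seed + 0.2, 0, 1)
        quiet = motion_energy([seed, seed, seed])
        loud = motion_energy([seed, pert, seed])
        assert loud > quiet

    def test_motion_energy_brute_force(self, rng):
        frames = [rng.random((5, 5, 3)) for _ in range(4)]
        want = sum(
            np.mean((frames[i + 1] - frames[i]) ** 2) for i in range(3)
        )
        assert motion_energy(frames) == pytest.approx(want, rel=1e-12)

    def test_motion_energy_needs_two_frames(self):
        with pytest.raises(ParameterError):
            motion_energy([np.zeros((4, 4, 3))])


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_samples(self, rng):
        a = 0.001 * rng.normal(size=6)
        b = 1.0 + 0.001 * rng.normal(size=6)
        _, _, p = welch_t(a, b)
        assert p < 1e-3

    def test_matches_scipy_reference(self, rng):
        for _ in range(5):
            a = rng.normal(size=rng.integers(5, 30))
            b = rng.normal(loc=0.4, scale=2.0, size=rng.integers(5, 30))
            t, df, p = welch_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)
            assert df == pytest.approx(ref.df, abs=1e-8)


def nostim_record(i, image_id, fa):
    return TrialRecord(
        trial_id=i,
        session_id="s",
        seed_id="seed",
        image_id=image_id,
        stimulated=False,
        response="stimulated" if fa else "not_stimulated",
        outcome="false_alarm" if fa else "correct_rejection",
    )


class TestBootstrapNull:
    def test_degenerate_instance_forces_max_of_one(self, rng):
        records = [nostim_record(0, "a", True), nostim_record(1, "b", False)]
        families = {"A": ["a"], "B": ["b"]}
        maxima = bootstrap_family_null(records, families, 200, rng)
        assert np.all(maxima == 1.0)

    def test_enumeration_matches_analytic_case(self):
        """Families with (3, 1) presentations and one FA: the max family rate
        is 1.0 with probability 1/4, else 1/3."""
        records = [
            nostim_record(0, "a", True),
            nostim_record(1, "a", False),
            nostim_record(2, "a", False),
            nostim_record(3, "b", False),
        ]
        families = {"A": ["a"], "B": ["b"]}
        dist = enumerate_family_null(records, families)
        assert dist[1.0] == pytest.approx(0.25)
        third = [v for k, v in dist.items() if np.isclose(k, 1 / 3)]
        assert sum(third) == pytest.approx(0.75)

    def test_monte_carlo_matches_enumeration(self, rng):
        records = [
            nostim_record(i, img, fa)
            for i, (img, fa) in enumerate(
                [("a", True), ("a", False), ("b", True), ("b", False),
                 ("c", False), ("c", False), ("d", False)]
            )
        ]
        families = {"F1": ["a", "b"], "F2": ["c"], "F3": ["d"]}
        exact = enumerate_family_null(records, families)
        n_boot = 4000
        maxima = bootstrap_family_null(records, families, n_boot, rng)
        for value, prob in exact.items():
            freq = np.mean(np.isclose(maxima, value))
            se = np.sqrt(prob * (1 - prob) / n_boot)
            assert freq == pytest.approx(prob, abs=4 * se + 1e-9)

    def test_empirical_p_is_direct_count(self, rng):
        maxima = rng.random(1000)
        obs = 0.7
        assert empirical_p_value(maxima, obs) == np.mean(maxima >= obs)

    def test_needs_at_least_one_fa(self, rng):
        records = [nostim_record(0, "a", False)]
        with pytest.raises(ParameterError):
            bootstrap_family_null(records, {"A": ["a"]}, 10, rng)


class TestConvergence:
    def test_identical_pools_give_zero_curve(self, rng):
        ref = fset(rng.normal(size=(10, 4)))
        curve = convergence_curve([ref, ref, ref], ref)
        assert all(v == pytest.approx(0.0, abs=1e-8) for v in curve)

    def test_constructed_drift_decreases(self, rng):
        target = rng.normal(size=4)
        pools = []
        for lam in (1.0, 0.6, 0.3, 0.05):
            pools.append(fset(target + lam * (rng.normal(size=(12, 4)) + 3.0)))
        curve = convergence_curve(pools, singleton_feature_set(target))
        assert all(b < a for a, b in zip(curve, curve[1:]))

    def test_empty_pool_reported_missing(self, rng):
        ref = fset(rng.normal(size=(5, 3)))
        curve = convergence_curve([None, ref], ref)
        assert curve[0] is None and curve[1] is not None


class TestDendrogram:
    def test_round_trip_edge_list(self, tmp_path):
        nodes = [
            DendrogramNode("root", None, 0, 0.0, 0.6),
            DendrogramNode("kid1", "root", 1, 1.2, 0.7),
            DendrogramNode("kid2", "root", 1, 0.8, None),
            DendrogramNode("grand", "kid1", 2, 2.0, 0.9),
        ]
        path = tmp_path / "tree.tsv"
        export_dendrogram_edgelist(nodes, path)
        back = import_dendrogram_edgelist(path)
        assert {(n.image_id, n.parent) for n in back} == {
            (n.image_id, n.parent) for n in nodes
        }
        assert all(
            a.fid_to_seed == pytest.approx(b.fid_to_seed)
            for a, b in zip(sorted(back, key=lambda n: n.image_id),
                            sorted(nodes, key=lambda n: n.image_id))
        )

    def test_graph_is_tree(self):
        import networkx as nx

        from perceptography.metrics import dendrogram_to_graph

        nodes = [
            DendrogramNode("r", None, 0, 0.0, 0.5),
            DendrogramNode("a", "r", 1, 1.0, 0.5),
            DendrogramNode("b", "r", 1, 1.0, 0.5),
            DendrogramNode("c", "a", 2, 2.0, 0.5),
        ]
        g = dendrogram_to_graph(nodes)
        assert g.number_of_nodes() == 4
        assert nx.is_arborescence(g)
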