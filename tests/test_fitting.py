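"""Observation mapping, objectives, pre-screen and GA tests."""

import numpy as np
import pandas as pd
import pytest

from jakstat.engine import run_ensemble
from jakstat.fitting import (
    GASettings,
    ObservationMapping,
    SnapshotDataset,
    deterministic_objective,
    ga_optimize,
    map_observable,
    moment_prescreen,
    snapshot_objective,
)
from jakstat.model import build_canonical_model
from jakstat.synthetic import DEFAULT_MAPPINGS, GeneratorConfig, generate_snapshots


def small_snapshot_dataset(
    cells=300, doses=(250.0,), times=(8.0, 16.0, 32.0), noise_cv=0.0, seed=11,
    theta_true=None, equilibrate=True,
):
    config = GeneratorConfig(
        theta_true=theta_true or {},
        doses_iu=doses,
        times_h=times,
        cells_per_timepoint=cells,
        noise_cv=noise_cv,
        master_seed=seed,
        equilibrate=equilibrate,
    )
    return generate_snapshots(config)


@pytest.fixture(scope="module")
def snapshot_ds(snapshot_panel):
    return snapshot_panel


@pytest.fixture(scope="module")
def net5000():
    return build_canonical_model(ifn_molecules=5000)


class TestMapObservable:
    def test_identity_mapping(self, net5000):
        ens = run_ensemble(net5000, n_reps=3, t_grid=np.array([0.0, 60.0]),
                           master_seed=1)
        m = ObservationMapping(("MxA",), scale=1.0, offset=0.0)
        np.testing.assert_array_equal(
            map_observable(ens, m), ens.species_matrix("MxA")
        )

    def test_affine_arithmetic(self, net5000):
        ens = run_ensemble(net5000, n_reps=2, t_grid=np.array([0.0]), master_seed=2)
        m = ObservationMapping(("MxA",), scale=2.0, offset=10.0)
        np.testing.assert_allclose(map_observable(ens, m), 2.0 * 1582 + 10.0)

    def test_composite_sum(self, net5000):
        ens = run_ensemble(net5000, n_reps=2, t_grid=np.array([0.0]), master_seed=3)
        m = ObservationMapping(("STAT2_c", "STAT2_n"), scale=1.0)
        np.testing.assert_allclose(map_observable(ens, m), 9325 + 150)

    def test_unknown_species_rejected(self, net5000):
        ens = run_ensemble(net5000, n_reps=1, t_grid=np.array([0.0]), master_seed=4)
        with pytest.raises(KeyError):
            map_observable(ens, ObservationMapping(("NOPE",), 1.0))

    def test_invalid_mapping_params(self):
        with pytest.raises(ValueError):
            ObservationMapping(("MxA",), scale=0.0)
        with pytest.raises(ValueError):
            ObservationMapping(("MxA",), scale=1.0, offset=-1.0)


class TestDeterministicObjective:
    def test_identical(self):
        x = np.arange(6.0).reshape(2, 3)
        assert deterministic_objective(x, x) == 0.0

    def test_single_difference(self):
        assert deterministic_objective([1.0, 3.0], [1.0, 1.0]) == 4.0

    def test_hand_sum(self):
        sim = np.array([[1.0, 2.0], [3.0, 4.0]])
        data = np.array([[1.0, 0.0], [0.0, 4.0]])
        assert deterministic_objective(sim, data) == 13.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            deterministic_objective(np.zeros(3), np.zeros(4))


class TestSnapshotDataset:
    def test_round_trip(self, snapshot_ds, tmp_path):
        p = tmp_path / "snap.csv"
        snapshot_ds.to_csv(p)
        back = SnapshotDataset.from_csv(p)
        pd.testing.assert_frame_equal(
            back.table, snapshot_ds.table[back.table.columns], check_like=True
        )

    def test_values_lookup(self, snapshot_ds):
        v = snapshot_ds.values("MxA", 250.0, 8.0)
        assert v.size == 150
        with pytest.raises(KeyError):
            snapshot_ds.values("MxA", 123.0, 8.0)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            SnapshotDataset(pd.DataFrame({"gene": ["MxA"]}))


class TestSnapshotObjective:
    def test_self_consistent_theta_scores_low(self, snapshot_ds, net5000):
        """A dataset generated from the nominal parameters scores near the
        finite-sample KS floor when re-simulated under the same parameters."""
        res = snapshot_objective(
            {}, snapshot_ds, net5000, DEFAULT_MAPPINGS["MxA"],
            gene="MxA", dose=250.0, n_sim_reps=100, seed=5,
        )
        floor = 1.36 * np.sqrt(1 / 100 + 1 / 150)
        assert res["score"] < floor
        assert set(res["per_time"]) == {0.0, 8.0, 12.0, 16.0, 20.0, 32.0}
        assert res["max_ks"] >= res["score"]

    def test_shifted_data_scores_one(self, snapshot_ds, net5000):
        shifted = SnapshotDataset(
            snapshot_ds.table.assign(
                fluorescence_au=snapshot_ds.table.fluorescence_au + 1e9
            )
        )
        res = snapshot_objective(
            {}, shifted, net5000, DEFAULT_MAPPINGS["MxA"],
            gene="MxA", dose=250.0, n_sim_reps=60, seed=6, equilibrate=False,
        )
        assert res["score"] == pytest.approx(1.0)

    def test_min_reps_enforced(self, snapshot_ds, net5000):
        with pytest.raises(ValueError):
            snapshot_objective({}, snapshot_ds, net5000, DEFAULT_MAPPINGS["MxA"],
                               n_sim_reps=10)

    def test_score_shrinks_with_more_reps(self, net5000):
        """Sampling error shrinks as the simulated ensemble grows (dose-0
        panels keep this cheap)."""
        ds = small_snapshot_dataset(cells=500, doses=(0.0,), times=(8.0, 32.0),
                                    seed=21, equilibrate=False)
        small = snapshot_objective(
            {}, ds, build_canonical_model(0), DEFAULT_MAPPINGS["MxA"],
            gene="MxA", dose=0.0, n_sim_reps=60, seed=7, equilibrate=False,
        )
        big = snapshot_objective(
            {}, ds, build_canonical_model(0), DEFAULT_MAPPINGS["MxA"],
            gene="MxA", dose=0.0, n_sim_reps=400, seed=7, equilibrate=False,
        )
        assert big["score"] < small["score"]


class TestMomentPrescreen:
    def test_truth_accepted_and_gross_misfit_rejected(self, snapshot_ds, net5000):
        mapping = DEFAULT_MAPPINGS["MxA"]
        candidates = [
            {},  # the generating parameters
            {"k_22": net5000.parameters["k_22"] * 100.0},  # transcription x100
        ]
        accepted = moment_prescreen(
            candidates, snapshot_ds, net5000, mapping, tolerance=0.5
        )
        assert accepted == [True, False]

    def test_rejects_most_random_candidates(self, snapshot_ds, net5000):
        """Log-uniform random rate constants rarely reproduce the data means:
        acceptance below 50% at tolerance 0.5."""
        rng = np.random.default_rng(13)
        names = ["k_22", "k_34", "k_38"]
        candidates = []
        for _ in range(40):
            candidates.append(
                {
                    n: net5000.parameters[n] * 10 ** rng.uniform(-2, 2)
                    for n in names
                }
            )
        accepted = moment_prescreen(
            candidates, snapshot_ds, net5000, DEFAULT_MAPPINGS["MxA"],
            tolerance=0.5, equilibrate=False,
        )
        rate = np.mean(accepted)
        assert rate < 0.5

    def test_bad_tolerance(self, snapshot_ds, net5000):
        with pytest.raises(ValueError):
            moment_prescreen([{}], snapshot_ds, net5000, DEFAULT_MAPPINGS["MxA"],
                             tolerance=0.0)


class TestGa:
    def test_convex_bowl(self):
        """Known 2-D convex objective: optimum recovered within 1e-2 in
        log10 space."""
        target = {"a": 1.0, "b": 10.0}

        def objective(theta):
            return sum(
                (np.log10(theta[k]) - np.log10(target[k])) ** 2 for k in target
            )

        res = ga_optimize(
            objective,
            {"a": (1e-2, 1e2), "b": (1e-1, 1e3)},
            GASettings(population=40, generations=30),
            seed=3,
        )
        assert res.score < 1e-2
        assert abs(np.log10(res.theta["a"])) < 0.1
        assert abs(np.log10(res.theta["b"]) - 1.0) < 0.1

    def test_trace_nonincreasing_with_elitism(self):
        def objective(theta):
            return (np.log10(theta["a"]) - 0.5) ** 2

        res = ga_optimize(
            objective, {"a": (1e-3, 1e3)},
            GASettings(population=20, generations=15), seed=1,
        )
        best = res.trace["best_score"].to_numpy()
        assert np.all(np.diff(best) <= 1e-12)

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ValueError):
            ga_optimize(lambda t: 0.0, {"a": (1.0, 0.1)})

    def test_reproducible(self):
        def objective(theta):
            return abs(np.log10(theta["a"]))

        r1 = ga_optimize(objective, {"a": (1e-2, 1e2)},
                         GASettings(population=10, generations=5), seed=42)
        r2 = ga_optimize(objective, {"a": (1e-2, 1e2)},
                         GASettings(population=10, generations=5), seed=42)
        assert r1.theta == r2.theta
        pd.testing.assert_frame_equal(r1.trace, r2.trace)

    def test_recovers_birth_rate_of_birth_death(self):
        """1-parameter recovery: fit the birth rate of a birth-death process
        to snapshot means (truth k_b = 5), expected within 10%."""
        from tests.conftest import make_birth_death

        truth = 5.0
        bd = make_birth_death(k_b=truth, k_d=1.0, x0=0.0)
        grid = np.array([0.0, 5.0, 50.0])
        data = run_ensemble(bd, n_reps=800, t_grid=grid, master_seed=17,
                            engine="exact")
        data_means = data.species_matrix("X").mean(axis=0)[1:]

        def objective(theta):
            from jakstat.model import ParameterSet

            params = ParameterSet(
                {"k_b": theta["k_b"], "k_d": 1.0},
                {"k_b": "1/min", "k_d": "1/min"},
            )
            sim = run_ensemble(bd, params=params, n_reps=400, t_grid=grid,
                               master_seed=18)
            sim_means = sim.species_matrix("X").mean(axis=0)[1:]
            return float(np.sum((sim_means - data_means) ** 2))

        res = ga_optimize(
            objective, {"k_b": (0.05, 500.0)},
            GASettings(population=24, generations=12), seed=9,
        )
        assert abs(res.theta["k_b"] - truth) / truth < 0.10
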