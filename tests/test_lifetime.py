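"""Min-coupled lifetime model: expectation, likelihood, simulation."""

import math

import numpy as np
import pandas as pd
import pytest

from eggfr import (
    EggParams,
    FRParams,
    ModelSpec,
    dataset_loglik,
    expected_parasitized,
    expected_trajectory,
    female_loglik,
    fr_expected,
    simulate_female,
)
from eggfr.lifetime import MODEL_GRID, ExperimentDataset
from eggfr._fast import loglik_packed, pack_dataset

import _checks
from conftest import make_dataset


class TestExpectedParasitized:
    def test_egg_limited_minimum(self):
        # f = 0.5 * 10 = 5 under equation A, but only 2 eggs left
        model = ModelSpec.from_name("A1")
        p = expected_parasitized(model, FRParams(a=0.5), EggParams(), 10, 1, stock=2.0)
        assert p == 2.0

    def test_fr_limited_day_one(self, cachamai_c5):
        model, frp, eggp = cachamai_c5
        p = expected_parasitized(model, frp, eggp, 13, 1, stock=56.0)
        assert p == pytest.approx(1.45, abs=0.02)
        # egg stock is slack, so the functional response is the binding term
        assert p == fr_expected(model.fr, frp, 13)

    def test_three_day_trajectory_matches_frozen_oracle(self, cachamai_c5):
        """Frozen from an independent step-by-step spreadsheet-style oracle
        computed before the build (expected-laying propagation)."""
        model, frp, eggp = cachamai_c5
        ps, traj = expected_trajectory(model, frp, eggp, [60, 60, 60])
        assert np.allclose(ps, [14.10911794776466] * 3, atol=1e-9)
        assert np.allclose(
            traj.stock, [56.0, 34.169754902872015, 26.900857736499674], atol=1e-9
        )


class TestLoglik:
    def test_closed_form_binomial(self):
        # p = 5 of n = 10: log C(10,5) - 10 log 2
        model = ModelSpec.from_name("A1")
        ll = female_loglik(model, FRParams(a=0.5), EggParams(), [10], [5])
        assert ll == pytest.approx(math.log(252) - 10 * math.log(2), abs=1e-12)

    def test_zero_probability_zero_count(self):
        model = ModelSpec.from_name("A1")
        assert female_loglik(model, FRParams(a=0.0), EggParams(), [10, 5], [0, 0]) == 0.0

    def test_zero_probability_positive_count_is_neg_inf(self):
        model = ModelSpec.from_name("A1")
        ll = female_loglik(model, FRParams(a=0.0), EggParams(), [10], [3])
        assert ll == -math.inf

    def test_certain_path_has_zero_loglik(self):
        model = ModelSpec.from_name("A1")
        ll = female_loglik(model, FRParams(a=1.0), EggParams(), [7, 4], [7, 4])
        assert ll == 0.0

    def test_additive_and_exchangeable(self, cachamai_c5, tiny_dataset):
        model, frp, eggp = cachamai_c5
        one = make_dataset(
            [{"female_id": "X", "day": d, "n_offered": 12, "n_parasitized": 1}
             for d in (1, 2)]
        )
        two = make_dataset(
            [{"female_id": f, "day": d, "n_offered": 12, "n_parasitized": 1}
             for f in ("X", "Y") for d in (1, 2)]
        )
        assert dataset_loglik(model, frp, eggp, two) == pytest.approx(
            2 * dataset_loglik(model, frp, eggp, one)
        )
        shuffled = ExperimentDataset(
            tiny_dataset.df.sort_values(["female_id", "day"], ascending=False)
        )
        assert dataset_loglik(model, frp, eggp, shuffled) == pytest.approx(
            dataset_loglik(model, frp, eggp, tiny_dataset)
        )

    def test_matches_enumeration_oracle(self):
        _checks.check_loglik_against_enumeration(seed=2)

    def test_fast_kernel_agrees_with_reference(self, rng):
        """The packed (numba) kernel and the readable recursion give the
        same value on random models and datasets."""
        for _ in range(30):
            model = MODEL_GRID[int(rng.integers(len(MODEL_GRID)))]
            frp = FRParams(a=rng.uniform(0, 0.4), b=rng.uniform(0, 0.3),
                           H=rng.uniform(0, 0.05), s=rng.uniform(1, 2.5))
            eggp = EggParams(e0=rng.uniform(0, 60), h0=rng.uniform(0, 12),
                             g=rng.uniform(0.6, 1.4), r=rng.uniform(0, 1),
                             u=rng.uniform(0, 25), cap=rng.uniform(10, 80))
            rows = []
            for fid in range(3):
                n_arr = rng.integers(0, 90, size=int(rng.integers(1, 7)))
                k_arr, _ = simulate_female(model, frp, eggp, n_arr, rng)
                rows += [{"female_id": f"F{fid}", "day": d + 1,
                          "n_offered": int(n_arr[d]), "n_parasitized": int(k_arr[d])}
                         for d in range(len(n_arr))]
            data = make_dataset(rows)
            theta = {"a": frp.a, "b": frp.b, "H": frp.H, "s": frp.s,
                     "e0": eggp.e0, "h0": eggp.h0, "g": eggp.g, "r": eggp.r,
                     "u": eggp.u, "cap": eggp.cap}
            ref = dataset_loglik(model, frp, eggp, data)
            fast = loglik_packed(model, theta, pack_dataset(data))
            assert fast == pytest.approx(ref, rel=1e-10, abs=1e-10)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            make_dataset([])


class TestSimulation:
    def test_no_hosts_no_parasitism(self, cachamai_c5):
        model, frp, eggp = cachamai_c5
        ks, _ = simulate_female(model, frp, eggp, [0, 0, 0], 7)
        assert list(ks) == [0, 0, 0]

    def test_same_seed_identical(self, cachamai_c5):
        model, frp, eggp = cachamai_c5
        k1, t1 = simulate_female(model, frp, eggp, [20, 30, 40], 99)
        k2, t2 = simulate_female(model, frp, eggp, [20, 30, 40], 99)
        assert np.array_equal(k1, k2)
        assert t1.stock == t2.stock

    def test_day_one_mean_matches_expectation(self, cachamai_c5):
        """Monte-Carlo check: mean of k_1 over 10,000 replicates within
        3 standard errors of the model expectation at n = 13."""
        model, frp, eggp = cachamai_c5
        expected = expected_parasitized(model, frp, eggp, 13, 1, stock=56.0)
        rng = np.random.default_rng(42)
        draws = np.array(
            [simulate_female(model, frp, eggp, [13], rng)[0][0] for _ in range(10_000)]
        )
        prob = expected / 13
        se = math.sqrt(13 * prob * (1 - prob) / 10_000)
        assert abs(draws.mean() - expected) < 3 * se

    def test_unlimited_eggs_mean_path_matches_expectation(self, cachamai_c5):
        """With the egg constraint slack the simulated daily means converge
        to the deterministic expected path."""
        _, frp, _ = cachamai_c5
        model = ModelSpec.from_name("C1")
        schedule = [40, 40, 40]
        ps, _ = expected_trajectory(model, frp, EggParams(), schedule)
        rng = np.random.default_rng(5)
        sims = np.array(
            [simulate_female(model, frp, EggParams(), schedule, rng)[0]
             for _ in range(10_000)]
        )
        prob = ps / 40
        se = np.sqrt(40 * prob * (1 - prob) / 10_000)
        assert np.all(np.abs(sims.mean(axis=0) - ps) < 3 * se)

    def test_unlimited_eggs_p_equals_fr(self, cachamai_c5):
        _, frp, _ = cachamai_c5
        model = ModelSpec.from_name("C1")
        for n in (5, 40, 110):
            p = expected_parasitized(model, frp, EggParams(), n, 3, stock=math.inf)
            assert p == fr_expected(model.fr, frp, n)

    def test_empty_complement_never_parasitizes(self):
        model = ModelSpec.from_name("C2")
        ks, _ = simulate_female(
            model, FRParams(b=0.2, a=0.01, H=0.01), EggParams(e0=0.0), [50] * 5, 3
        )
        assert np.all(ks == 0)

    def test_path_invariants(self):
        _checks.check_path_invariants(n_paths=1000, seed=4)


class TestDatasetValidation:
    def test_requires_consecutive_days(self):
        with pytest.raises(ValueError, match="consecutive"):
            make_dataset(
                [{"female_id": "F1", "day": 2, "n_offered": 5, "n_parasitized": 0}]
            )

    def test_rejects_k_above_n(self):
        with pytest.raises(ValueError):
            make_dataset(
                [{"female_id": "F1", "day": 1, "n_offered": 5, "n_parasitized": 6}]
            )

    def test_extra_columns_ignored_with_warning(self, caplog):
        df = pd.DataFrame(
            [{"female_id": "F1", "day": 1, "n_offered": 5, "n_parasitized": 1,
              "species": "x"}]
        )
        with caplog.at_level("WARNING"):
            data = ExperimentDataset(df)
        assert "species" in caplog.text
        assert list(data.df.columns) == [
            "female_id", "day", "n_offered", "n_parasitized"
        ]

    def test_model_name_round_trip(self):
        assert ModelSpec.from_name("C5").name == "C5"
        assert ModelSpec.from_name("C5").param_names == (
            "b", "a", "H", "e0", "h0", "g", "r", "u"
        )
        with pytest.raises(ValueError):
            ModelSpec.from_name("G3")
        with pytest.raises(ValueError):
            ModelSpec.from_name("C9")
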