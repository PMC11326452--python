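import numpy as np
import pandas as pd
import pytest

from polrboot.bootstrap_engine import (
    BootstrapConfig,
    ReplicateEstimates,
    aggregate_replicates,
    bootstrap_fit,
    replication_sweep,
    resample_indices,
)
from polrboot.data_model import (
    CategoricalPredictorSpec,
    OrdinalOutcomeSpec,
    StudyDataset,
)
from polrboot.synthetic_data import make_toy_config, simulate_dataset


def make_stub_replicates(estimates, converged=None):
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    B = estimates.shape[0]
    if converged is None:
        converged = np.ones(B, dtype=bool)
    p = estimates.shape[1]
    return ReplicateEstimates(
        estimates=estimates,
        nlls=np.ones(B),
        null_nlls=np.full(B, 2.0),
        converged=np.asarray(converged),
        redraw_count=0,
        term_labels=[f"t{i}" for i in range(p)],
        n_thresholds=0,
    )


class TestResampleIndices:
    def test_single_index_always_itself(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert resample_indices(1, rng) == [0]

    def test_same_seed_identical_sequences(self):
        a = resample_indices(50, np.random.default_rng(7))
        b = resample_indices(50, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_inclusion_frequency_matches_closed_form(self):
        """P(index included in a resample of n=5) = 1 - (1 - 1/5)^5 ~ 0.672."""
        rng = np.random.default_rng(123)
        n, draws = 5, 4000
        included = np.zeros(n)
        for _ in range(draws):
            included[np.unique(resample_indices(n, rng))] += 1
        expected = 1 - (1 - 1 / n) ** n
        np.testing.assert_allclose(included / draws, expected, atol=0.04)


class TestAggregateReplicates:
    def test_two_replicates_standard_and_replicate_mean_modes(self):
        reps = make_stub_replicates([[1.0], [3.0]])
        std = aggregate_replicates(reps, "standard").frame
        assert std["estimate"].iloc[0] == pytest.approx(2.0)
        assert std["std_error"].iloc[0] == pytest.approx(np.sqrt(2))
        rep_mean = aggregate_replicates(reps, "replicate_mean").frame
        assert rep_mean["std_error"].iloc[0] == pytest.approx(1.0)

    def test_degenerate_identical_replicates_flagged(self):
        reps = make_stub_replicates([[2.5]] * 10)
        frame = aggregate_replicates(reps, "standard").frame
        assert frame["std_error"].iloc[0] == 0.0
        assert np.isnan(frame["z_value"].iloc[0])

    def test_standard_se_recovers_unit_normal_spread(self):
        rng = np.random.default_rng(99)
        reps = make_stub_replicates(rng.normal(0.0, 1.0, size=(1000, 1)))
        frame = aggregate_replicates(reps, "standard").frame
        assert abs(frame["std_error"].iloc[0] - 1.0) < 0.05

    def test_insufficient_converged_replicates_error(self):
        reps = make_stub_replicates([[1.0], [3.0]], converged=[True, False])
        with pytest.raises(ValueError, match="converged"):
            aggregate_replicates(reps, "standard")

    def test_non_converged_replicates_excluded(self):
        reps = make_stub_replicates(
            [[1.0], [3.0], [1000.0]], converged=[True, True, False]
        )
        frame = aggregate_replicates(reps, "standard").frame
        assert frame["estimate"].iloc[0] == pytest.approx(2.0)


class TestBootstrapFit:
    @pytest.fixture(scope="class")
    def toy(self):
        return simulate_dataset(make_toy_config(seed=4, n=80))

    def test_deterministic_given_config(self, toy):
        cfg = BootstrapConfig(B=12, seed=31)
        a = bootstrap_fit(toy, cfg)
        b = bootstrap_fit(toy, cfg)
        np.testing.assert_array_equal(a.replicates.estimates, b.replicates.estimates)
        pd.testing.assert_frame_equal(a.table.frame, b.table.frame)

    def test_single_replicate_reports_se_not_available(self, toy):
        summary = bootstrap_fit(toy, BootstrapConfig(B=1, seed=5))
        frame = summary.table.frame
        np.testing.assert_array_equal(
            frame["estimate"].to_numpy(),
            np.concatenate(
                [
                    summary.replicates.estimates[0, 2:],
                    summary.replicates.estimates[0, :2],
                ]
            ),
        )
        assert frame["std_error"].isna().all()

    def test_redraws_happen_for_rare_levels(self):
        outcome = OrdinalOutcomeSpec("y", ("a", "b", "c"))
        pred = CategoricalPredictorSpec("x", ("u", "v"), reference="u")
        frame = pd.DataFrame(
            {
                "x": ["u", "v", "u", "v", "u", "v", "u", "v"],
                "y": ["a", "a", "b", "b", "a", "b", "c", "a"],
            }
        )
        ds = StudyDataset(outcome, [pred], frame)  # category "c" appears once
        summary = bootstrap_fit(ds, BootstrapConfig(B=30, seed=2))
        assert summary.replicates.redraw_count > 0
        # every accepted resample re-observed all three categories
        assert np.isfinite(summary.replicates.nlls).all()

    def test_exhausting_redraws_errors(self):
        outcome = OrdinalOutcomeSpec("y", ("a", "b", "c"))
        frame = pd.DataFrame({"y": ["a"] * 6 + ["b"] * 6 + ["c"]})
        ds = StudyDataset(outcome, [], frame)
        with pytest.raises(RuntimeError, match="redraws"):
            bootstrap_fit(ds, BootstrapConfig(B=50, seed=0, max_redraws=0))

    def test_standard_se_stabilises_in_B(self):
        """The conventional bootstrap SE converges to a constant as B grows."""
        ds = simulate_dataset(make_toy_config(seed=8, n=60))
        se = {}
        for B in (2000, 8000):
            summary = bootstrap_fit(ds, BootstrapConfig(B=B, seed=17))
            frame = summary.table.frame
            se[B] = frame.loc[~frame["term"].str.contains(r"\|"), "std_error"]
        ratio = (se[2000].to_numpy() / se[8000].to_numpy())
        assert np.all(np.abs(ratio - 1) < 0.10)


class TestReplicationSweep:
    def test_smoke_single_b_with_baseline(self):
        ds = simulate_dataset(make_toy_config(seed=6, n=80))
        sweep = replication_sweep(ds, [15], BootstrapConfig(B=15, seed=3))
        comp = sweep.comparison
        assert list(comp.columns) == ["Ordinal regression method", "15"]
        assert np.isfinite(comp.to_numpy(dtype=float)).all()
        aic = comp.loc["Akaike information criterion (AIC)"]
        bic = comp.loc["Bayesian information criterion (BIC)"]
        assert (bic >= aic).all()  # n_effective >= 8 throughout

    def test_empty_b_list_rejected(self):
        ds = simulate_dataset(make_toy_config(seed=6, n=80))
        with pytest.raises(ValueError):
            replication_sweep(ds, [], BootstrapConfig())
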