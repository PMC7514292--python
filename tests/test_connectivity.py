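"""Transfer entropy, surrogate normalization and the connectivity matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corehub import (
    AnalysisConfig,
    ConnectivityMatrix,
    ParameterError,
    Recording,
    SymbolSeries,
    conditional_entropy,
    connectivity_matrix,
    discretize,
    nte,
    read_connectivity,
    transfer_entropy,
    write_connectivity,
)
from corehub.synthetic import CouplingSpec, simulate_var


class TestDiscretize:
    @pytest.mark.parametrize(
        "signal,n_bins,expected",
        [
            ([0, 1, 2, 3], 2, [0, 0, 1, 1]),
            ([5, 5, 5, 5], 8, [0, 0, 0, 0]),
            ([0, 0.5, 1.0], 3, [0, 1, 2]),
        ],
    )
    def test_equal_width_examples(self, signal, n_bins, expected):
        assert discretize(signal, n_bins).symbols.tolist() == expected

    def test_max_value_in_top_bin(self):
        sym = discretize(np.linspace(0, 1, 101), 10)
        assert sym.symbols.max() == 9

    def test_too_few_bins(self):
        with pytest.raises(ParameterError):
            discretize([0.0, 1.0], 1)


class TestTransferEntropy:
    def test_matches_bruteforce_on_printed_pair(self, te_oracle):
        x = SymbolSeries([0, 1, 0, 1, 0, 1], 2)
        y = SymbolSeries([1, 0, 1, 0, 1, 0], 2)
        assert transfer_entropy(x, y) == pytest.approx(
            te_oracle(x.symbols, y.symbols), abs=1e-12
        )

    def test_matches_bruteforce_on_random_pairs(self, te_oracle):
        rng = np.random.default_rng(11)
        for _ in range(50):
            xs = rng.integers(0, 3, 40)
            ys = rng.integers(0, 3, 40)
            x, y = SymbolSeries(xs, 3), SymbolSeries(ys, 3)
            assert transfer_entropy(x, y) == pytest.approx(
                te_oracle(xs, ys), abs=1e-10
            )

    def test_copy_process_is_one_bit(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 10_001)
        x = np.roll(y, 1)  # x_{t+1} = y_t
        te = transfer_entropy(SymbolSeries(x, 2), SymbolSeries(y, 2))
        assert te == pytest.approx(1.0, abs=0.05)

    def test_independent_pair_vanishes(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 10_000)
        y = rng.integers(0, 2, 10_000)
        assert transfer_entropy(SymbolSeries(x, 2), SymbolSeries(y, 2)) < 0.005

    def test_full_disclosure_equals_conditional_entropy(self):
        # y_t = x_{t+1}: the source reveals the target's future entirely,
        # so TE exhausts H(x_{t+1}|x_t)
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.integers(0, 3, 30)
            y = np.roll(x, -1)
            te = transfer_entropy(SymbolSeries(x, 3), SymbolSeries(y, 3))
            h = conditional_entropy(SymbolSeries(x, 3))
            assert te == pytest.approx(h, abs=1e-10)

    def test_nonnegative_and_asymmetric(self):
        rng = np.random.default_rng(3)
        x = SymbolSeries(rng.integers(0, 2, 200), 2)
        y_vals = (np.roll(x.symbols, 1) + rng.integers(0, 2, 200)) % 2
        y = SymbolSeries(y_vals, 2)
        assert transfer_entropy(x, y) >= 0
        assert transfer_entropy(y, x) >= 0

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            transfer_entropy(SymbolSeries([0, 1, 0], 2), SymbolSeries([0, 1], 2))


class TestConditionalEntropy:
    def test_deterministic_alternation_is_zero(self):
        assert conditional_entropy(SymbolSeries([0, 1] * 10, 2)) == 0.0

    def test_iid_uniform_approaches_one_bit(self):
        rng = np.random.default_rng(4)
        x = SymbolSeries(rng.integers(0, 2, 20_000), 2)
        assert conditional_entropy(x) == pytest.approx(1.0, abs=0.01)

    def test_matches_bruteforce(self, cond_entropy_oracle):
        x = [0, 0, 1, 1, 0, 0, 1, 1]
        assert conditional_entropy(SymbolSeries(x, 2)) == pytest.approx(
            cond_entropy_oracle(x), abs=1e-12
        )


class TestNTE:
    def test_independent_pair_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=10_000)
        b = rng.normal(size=10_000)
        assert abs(nte(a, b, AnalysisConfig(seed=5))) < 0.01

    def test_copy_process_directionality(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 10_001).astype(float)
        x = np.roll(y, 1)
        cfg = AnalysisConfig(n_bins=2, seed=6)
        assert nte(x, y, cfg) == pytest.approx(1.0, abs=0.1)
        assert nte(y, x, cfg) == pytest.approx(0.0, abs=0.1)

    def test_bit_identical_given_seed(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=2_000)
        b = rng.normal(size=2_000)
        cfg = AnalysisConfig(seed=123)
        assert nte(a, b, cfg) == nte(a, b, cfg)

    def test_surrogate_correction_unbiased_over_seeds(self):
        # mean NTE for independent pairs stays within +/-0.005 of zero
        values = []
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            a = rng.normal(size=10_000)
            b = rng.normal(size=10_000)
            values.append(nte(a, b, AnalysisConfig(seed=seed)))
        assert abs(np.mean(values)) < 0.005

    def test_deterministic_target_yields_zero(self):
        x = np.tile([0.0, 1.0], 500)
        rng = np.random.default_rng(8)
        y = rng.normal(size=1_000)
        assert nte(x, y, AnalysisConfig(n_bins=2, seed=8)) == 0.0


class TestDirectionalityRecovery:
    def test_two_node_var_direction_recovered(self):
        wins = 0
        cfg = AnalysisConfig(seed=0)
        for seed in range(100):
            spec = CouplingSpec(
                n_nodes=2, edges=[("N00", "N01", 0.6)], ar_coeff=0.3,
                n_samples=10_000, seed=20_000 + seed,
            )
            rec = simulate_var(spec)
            forward = nte(rec.data[1], rec.data[0], cfg)
            reverse = nte(rec.data[0], rec.data[1], cfg)
            wins += forward > reverse
        assert wins >= 95


class TestConnectivityMatrix:
    def test_independent_channels_empty_graph(self):
        rng = np.random.default_rng(9)
        rec = Recording(rng.normal(size=(3, 10_000)), 250.0, ["a", "b", "c"])
        cm = connectivity_matrix(rec, AnalysisConfig(seed=9))
        off = cm.weights[~np.eye(3, dtype=bool)]
        assert (off < 0.01).all()

    def test_planted_chain_recovered(self):
        spec = CouplingSpec(
            n_nodes=3,
            edges=[("N00", "N01", 0.6), ("N01", "N02", 0.6)],
            ar_coeff=0.3, n_samples=10_000, seed=10,
        )
        rec = simulate_var(spec)
        cm = connectivity_matrix(rec, AnalysisConfig(seed=10))
        w = cm.weights
        planted = [w[1, 0], w[2, 1]]  # B<-A and C<-B
        others = [w[0, 1], w[0, 2], w[2, 0], w[1, 2]]
        assert min(planted) > max(others)

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        data = rng.normal(size=(4, 3_000))
        cfg = AnalysisConfig(seed=12, n_surrogates=5)
        rec = Recording(data, 250.0, ["a", "b", "c", "d"])
        perm = [2, 0, 3, 1]
        rec_p = Recording(data[perm], 250.0, [rec.channel_labels[i] for i in perm])
        w = connectivity_matrix(rec, cfg).weights
        w_p = connectivity_matrix(rec_p, cfg).weights
        np.testing.assert_allclose(w_p, w[np.ix_(perm, perm)], atol=1e-12)

    def test_diagonal_zero_and_nonnegative(self, small_recording):
        cm = connectivity_matrix(small_recording, AnalysisConfig(seed=1, n_surrogates=5))
        assert (np.diag(cm.weights) == 0).all()
        assert (cm.weights >= 0).all()

    def test_few_channels_warns(self):
        rng = np.random.default_rng(13)
        rec = Recording(rng.normal(size=(2, 500)), 100.0, ["a", "b"])
        with pytest.warns(UserWarning, match="fewer than 3"):
            connectivity_matrix(rec, AnalysisConfig(seed=13, n_surrogates=3))

    def test_serialization_roundtrip(self, tmp_path, small_recording):
        cm = connectivity_matrix(small_recording, AnalysisConfig(seed=2, n_surrogates=5))
        path = tmp_path / "cm.tsv"
        write_connectivity(cm, path)
        back = read_connectivity(path)
        np.testing.assert_array_equal(back.weights, cm.weights)
        assert back.channel_labels == cm.channel_labels
        assert back.params == cm.params

    def test_negative_weight_rejected(self):
        with pytest.raises(Exception):
            ConnectivityMatrix(np.array([[0.0, -0.1], [0.2, 0.0]]), ["a", "b"])


@settings(max_examples=30, deadline=None)
@given(st.lists(st.integers(0, 3), min_size=5, max_size=60))
def test_te_nonnegative_property(symbols):
    x = SymbolSeries(symbols + [0], 4)
    y = SymbolSeries([0] + symbols, 4)
    assert transfer_entropy(x, y) >= 0.0
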