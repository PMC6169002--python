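"""Delay embedding, Ragwitz selection and TE estimation."""

import numpy as np
import pytest

from cmcoupling import (
    EmbeddingSpec,
    analytic_linear_te,
    default_theiler,
    delay_embed,
    gen_coupled_ar,
    ragwitz_optimize,
    scan_prediction_time,
    te_bidirectional,
    te_ksg,
)

FS = 2000.0
SPEC11 = EmbeddingSpec(d=1, tau=1, u=0.5, k=4)  # u = 1 sample at 2 kHz


class TestDelayEmbed:
    def test_by_definition(self):
        out = delay_embed(np.arange(1.0, 7.0), d=2, tau=2)
        assert np.array_equal(out, [[3, 1], [4, 2], [5, 3], [6, 4]])

    def test_d1_is_identity_column(self):
        s = np.arange(5.0)
        assert np.array_equal(delay_embed(s, 1, 3)[:, 0], s)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            delay_embed(np.arange(10.0), d=3, tau=5)

    def test_row_count(self):
        out = delay_embed(np.zeros(100), d=4, tau=3)
        assert out.shape == (100 - 9, 4)


class TestRagwitz:
    def test_ar1_prefers_low_dimension(self):
        hits = 0
        for seed in range(20):
            x, _ = gen_coupled_ar(1500, a_x=0.8, seed=seed)
            d, tau = ragwitz_optimize(x, d_range=range(1, 6),
                                      tau_range=range(1, 4))
            hits += d <= 2
        assert hits >= 18  # AR(1) needs only its last value

    def test_alternation_is_first_order(self):
        # a strict two-value alternation is already first-order Markov:
        # each value determines its successor, so d=1 is selected
        s = np.tile([0.0, 1.0], 200) + np.random.default_rng(0).normal(
            0, 1e-6, 400
        )
        d, tau = ragwitz_optimize(s, d_range=range(1, 4), tau_range=range(1, 3),
                                  k=2)
        assert d == 1

    def test_ambiguous_cycle_needs_d2(self):
        # in the cycle 0, 1, 0, -1 the value 0 is followed by +1 or -1
        # depending on history: one value cannot predict, two can exactly
        s = np.tile([0.0, 1.0, 0.0, -1.0], 100) + np.random.default_rng(
            1
        ).normal(0, 1e-6, 400)
        d, tau = ragwitz_optimize(s, d_range=range(1, 4), tau_range=range(1, 3),
                                  k=2)
        assert d == 2

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ragwitz_optimize(np.ones(500))

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            ragwitz_optimize(np.random.default_rng(1).standard_normal(500),
                             d_range=[])


class TestDefaultTheiler:
    def test_white_noise_short_window(self):
        x = np.random.default_rng(4).standard_normal(5000)
        assert default_theiler(x) <= 2

    def test_capped(self):
        t = np.arange(5000) / FS
        slow = np.sin(2 * np.pi * 0.1 * t)
        assert default_theiler(slow, cap=100) == 100


class TestTeKsg:
    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(6)
        te = te_ksg(rng.standard_normal(5000), rng.standard_normal(5000),
                    SPEC11, fs=FS)
        assert abs(te.value) < 0.02

    def test_coupled_ar_matches_granger_oracle(self):
        oracle = analytic_linear_te(c_xy=0.5, lag=1, n=400_000)
        vals = []
        for seed in range(5):
            x, y = gen_coupled_ar(8000, c_xy=0.5, lag=1, seed=seed)
            vals.append(te_ksg(x, y, SPEC11, fs=FS).value)
        assert np.mean(vals) == pytest.approx(oracle, rel=0.3)

    def test_uncoupled_direction_near_zero(self):
        x, y = gen_coupled_ar(8000, c_xy=0.5, c_yx=0.0, lag=1, seed=3)
        te_fwd = te_ksg(x, y, SPEC11, fs=FS).value
        te_rev = te_ksg(y, x, SPEC11, fs=FS).value
        assert te_rev < te_fwd
        assert abs(te_rev) < 0.03

    def test_deterministic_shift_map(self):
        # target is an exact copy of the source u samples later: TE in the
        # forward direction is large, reverse near zero
        rng = np.random.default_rng(8)
        x = rng.standard_normal(4000)
        u_samples = 10
        y = np.roll(x, u_samples)
        spec = EmbeddingSpec(d=1, tau=1, u=u_samples / FS * 1000, k=4)
        fwd = te_ksg(x, y, spec, fs=FS).value
        rev = te_ksg(y, x, spec, fs=FS).value
        assert fwd > 1.0
        assert rev < 0.1

    def test_u_rounding_to_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            te_ksg(np.zeros(100), np.zeros(100),
                   EmbeddingSpec(d=1, tau=1, u=0.1, k=4), fs=FS)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            te_ksg(np.zeros(100), np.zeros(101), SPEC11, fs=FS)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            te_ksg(np.array([]), np.array([]), SPEC11, fs=FS)

    def test_bias_window_on_independent_pairs(self):
        # mean TE over independent pairs sits in a narrow window around zero
        vals = []
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            vals.append(
                te_ksg(rng.standard_normal(3000), rng.standard_normal(3000),
                       SPEC11, fs=FS).value
            )
        assert -0.005 <= np.mean(vals) <= 0.01


class TestScanPredictionTime:
    def test_singleton_grid(self):
        x, y = gen_coupled_ar(2000, c_xy=0.5, seed=1)
        best_u, prof = scan_prediction_time(
            x, y, EmbeddingSpec(d=1, tau=1, u=10.0, k=4), u_grid_ms=[10.0],
            fs=FS,
        )
        assert best_u == 10.0 and prof.shape == (1,)

    def test_flat_profile_without_coupling(self):
        rng = np.random.default_rng(12)
        x, y = rng.standard_normal(5000), rng.standard_normal(5000)
        _, prof = scan_prediction_time(
            x, y, EmbeddingSpec(d=1, tau=1, u=10.0, k=4),
            u_grid_ms=np.arange(10.0, 50.0, 5.0), fs=FS,
        )
        assert prof.max() - prof.min() < 0.03

    def test_recovers_known_lag(self):
        # x drives y at lag 30 samples = 15 ms
        x, y = gen_coupled_ar(6000, c_xy=0.8, lag=30, seed=5)
        best_u, _ = scan_prediction_time(
            x, y, EmbeddingSpec(d=1, tau=1, u=10.0, k=4, theiler=5),
            u_grid_ms=np.arange(10.0, 25.0, 1.0), fs=FS,
        )
        assert best_u == pytest.approx(15.0, abs=1.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            scan_prediction_time(np.zeros(100), np.zeros(100), SPEC11,
                                 u_grid_ms=[], fs=FS)


class TestBidirectional:
    def test_unidirectional_system_labels_directions(self):
        x, y = gen_coupled_ar(6000, c_xy=0.6, c_yx=0.0, lag=1, seed=9)
        # x plays "lfp", y plays "emg": descending = x->y should dominate
        res = te_bidirectional(x, y, spec=SPEC11, fs=FS)
        assert set(res) == {"desc", "asc"}
        assert res["desc"].value > res["asc"].value

    def test_symmetric_coupling_gives_similar_te(self):
        diffs, scale = [], []
        for seed in range(5):
            x, y = gen_coupled_ar(5000, c_xy=0.4, c_yx=0.4, lag=1, seed=seed)
            res = te_bidirectional(x, y, spec=SPEC11, fs=FS)
            diffs.append(res["desc"].value - res["asc"].value)
            scale.append(res["desc"].value)
        assert abs(np.mean(diffs)) < 0.3 * np.mean(scale)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            te_bidirectional(np.array([]), np.array([]), spec=SPEC11, fs=FS)

    def test_ragwitz_route_runs_and_reports_embedding(self):
        x, y = gen_coupled_ar(1500, c_xy=0.6, lag=1, seed=2)
        res = te_bidirectional(x, y, spec=None, fs=FS,
                               d_range=range(1, 3), tau_range=range(1, 3))
        assert res["desc"].params["d_source"] >= 1
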