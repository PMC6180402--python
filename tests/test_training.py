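"""Training algorithms: float reference steps, the fixed-point oracle,
encrypted building blocks (sumslots, combine/expand, sigma evaluation,
learning-rate scaling) and exact trajectory equivalence across backends."""

import numpy as np
import pytest

from fhelogit import ParameterError
from fhelogit.bootstrap import TraceBackend
from fhelogit.fixedpoint import FixedPointCodec
from fhelogit.ring import balanced_scale
from fhelogit import training as T


def make_dataset(rng, n, d, y=None):
    X = np.hstack([np.ones((n, 1), dtype=np.int64),
                   rng.integers(0, 2, size=(n, d - 1))])
    if y is None:
        y = rng.integers(0, 2, size=n)
    return T.Dataset(X, np.asarray(y, dtype=np.int64))


class TestFloatGD:
    def test_zero_gradient_fixed_point(self):
        """Fractional labels y = sigma(0) = 0.5 make the zero-weight
        gradient vanish."""
        X = np.array([[1.0, 2.0], [1.0, -1.0]])
        w = T.gd_step([0, 0], X, [0.5, 0.5], alpha=1.0, sigmoid="exact")
        assert np.allclose(w, 0)

    def test_two_sample_hand_example(self):
        X = np.array([[1, 1], [1, -1]])
        w = T.gd_step([0, 0], X, [1, 0], alpha=1.0, sigmoid="exact")
        assert np.allclose(w, [0, 1])

    def test_shape_mismatch(self):
        with pytest.raises(ParameterError):
            T.gd_step([0, 0, 0], np.ones((2, 2)), [0, 1], 0.1)

    def test_loss_decreases_on_separable_data(self, rng):
        data = make_dataset(rng, 40, 3)
        y = (data.X[:, 1] > 0).astype(np.int64)   # separable by feature 1
        data = T.Dataset(data.X, y)
        _, losses = T.train_gd(data, T.TrainConfig(alpha=0.05, iterations=20,
                                                   sigmoid="exact"))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))


class TestOneBit:
    def test_zero_gradient_keeps_state(self):
        X = np.array([[1.0], [1.0]])
        w, res = T.onebit_gd_step([0.0], [0.0], X, [0.5, 0.5], 0.1, 0.2)
        assert np.allclose(w, 0) and np.allclose(res, 0)

    def test_single_coordinate_recurrence(self):
        """g = +0.7, beta = 0.2, alpha = 0.1, residue 0: the weight drops by
        alpha and the residue keeps the unused 0.6."""
        X = np.array([[1.0]])
        w0 = np.log(0.7 / 0.3)  # sigma(w0) = 0.7, label 0 -> g = 0.7
        w, res = T.onebit_gd_step([w0], [0.0], X, [0.0], 0.1, 0.2,
                                  sigmoid="exact")
        assert np.isclose(w[0], w0 - 0.1)
        assert np.isclose(res[0], 0.6)

    def test_beta_zero_disables_memory(self, rng):
        data = make_dataset(rng, 12, 3)
        w = rng.normal(size=3)
        for res in ([0.0, 0.0, 0.0], [5.0, -5.0, 5.0]):
            out, _ = T.onebit_gd_step(w, res, data.X, data.y, 0.1, 0.0)
            if res[0] == 0.0:
                first = out
        assert np.allclose(first, out)

    def test_decay_after_strategy(self):
        X = np.array([[1.0]])
        w0 = np.log(0.7 / 0.3)
        _, res = T.onebit_gd_step([w0], [0.0], X, [0.0], 0.1, 0.2,
                                  sigmoid="exact", strategy="decay_after")
        assert np.isclose(res[0], 0.2 * 0.6)

    def test_label_flip_flips_signs(self, rng):
        """At w = 0 the exact-sigmoid gradient is (0.5 - y) X^T, so flipping
        every label negates it and every extracted sign."""
        data = make_dataset(rng, 16, 4)
        w, _ = T.onebit_gd_step(np.zeros(4), np.zeros(4), data.X, data.y,
                                0.1, 0.0, sigmoid="exact")
        w2, _ = T.onebit_gd_step(np.zeros(4), np.zeros(4), data.X,
                                 1 - data.y, 0.1, 0.0, sigmoid="exact")
        assert np.allclose(w, -w2)


class TestSumslotsCombineExpand:
    def test_sumslots_values_and_rotation_count(self, trace127):
        k = trace127.k
        ct = trace127.encrypt_vec(list(range(1, k + 1)))
        out = trace127.decrypt_vec(T.sumslots(trace127, ct))
        assert out == [k * (k + 1) // 2] * k
        assert trace127.rotations == int(np.log2(k))
        unit = trace127.encrypt_vec([1] + [0] * (k - 1))
        assert trace127.decrypt_vec(T.sumslots(trace127, unit)) == [1] * k

    def test_sumslots_equals_naive_rotation_sum(self, trace127, rng):
        """Lemma: the doubling trick equals the sum of all k rotations."""
        k = trace127.k
        vals = [int(v) for v in rng.integers(-50, 50, size=k)]
        ct = trace127.encrypt_vec(vals)
        fast = trace127.decrypt_vec(T.sumslots(trace127, ct))
        naive = [0] * k
        for j in range(k):
            rot = trace127.rotate(ct, j)
            naive = [a + b for a, b in zip(naive, trace127.decrypt_vec(rot))]
        assert fast == trace127._wrap(naive).values

    def test_sumslots_real_backend(self, be_train, rng):
        k = be_train.k
        vals = [int(v) for v in rng.integers(0, 10, size=k)]
        before = be_train.rotations
        out = be_train.decrypt_vec(T.sumslots(be_train, be_train.encrypt_vec(vals)))
        assert out == [sum(vals)] * k
        assert be_train.rotations - before == int(np.log2(k))

    def test_combine_expand_roundtrip(self, trace127):
        k = trace127.k
        cts = [trace127.encrypt_vec([c] * k) for c in range(k)]
        packed = trace127.decrypt_vec(T.combine(trace127, cts))
        assert packed == list(range(k))
        back = T.expand(trace127, T.combine(trace127, cts))
        assert [trace127.decrypt_vec(ct) for ct in back] == \
            [[c] * k for c in range(k)]

    def test_combine_zeros_and_expand_unit(self, trace127):
        k = trace127.k
        zeros = [trace127.encrypt_vec([0] * k) for _ in range(k)]
        assert trace127.decrypt_vec(T.combine(trace127, zeros)) == [0] * k
        e0 = trace127.encrypt_vec([5] + [0] * (k - 1))
        out = T.expand(trace127, e0)
        assert trace127.decrypt_vec(out[0]) == [5] * k
        assert all(trace127.decrypt_vec(ct) == [0] * k for ct in out[1:])

    def test_combine_count_checked(self, trace127):
        with pytest.raises(ParameterError):
            T.combine(trace127, [trace127.encrypt_vec([0] * trace127.k)]
                      * (trace127.k + 1))


class TestSigmaCircuits:
    def test_sigma3_at_zero_gives_half(self, trace127):
        """x~ = 0: bscale(8064) = 63 at p = 127, decoding to ~0.496."""
        consts = T.SigmaConstants.for_base(127)
        ct = trace127.encrypt_vec([0] * trace127.k)
        out = trace127.decrypt_vec(T.eval_sigma3_encrypted(trace127, ct, consts))
        assert out == [63] * trace127.k
        assert abs(63 / 127 - 0.5) < 2 / 127

    def test_sigma3_accuracy_across_interval(self, trace127):
        """Decoded circuit output tracks the cubic approximation across the
        interval: three bscale roundings of half an ulp each, one of them
        amplified by |x| (the squared term is re-multiplied by x~), give
        the derived bound (3 + |x|) p^-f / 2."""
        consts = T.SigmaConstants.for_base(127)
        for x in [-5, -2.5, -1, 0.5, 2, 5]:
            xt = round(x * 127)
            ct = trace127.encrypt_vec([xt] * trace127.k)
            got = trace127.decrypt_vec(
                T.eval_sigma3_encrypted(trace127, ct, consts))[0] / 127
            s3 = 0.5 + 0.197 * x - 0.004 * x**3
            assert abs(got - s3) <= (3 + abs(x)) * 0.5 / 127, x
            if abs(x) <= 2:
                assert abs(got - s3) <= 2 / 127, x

    def test_sigma_circuits_backend_equivalence(self, be_train, rng):
        p = be_train.p
        consts = T.SigmaConstants.for_base(p)
        tr = TraceBackend(p, be_train.r, be_train.e, be_train.k)
        vals = [int(v) for v in rng.integers(-3 * p, 3 * p, size=be_train.k)]
        for fn in (T.eval_sigma3_encrypted, T.eval_sigma1_encrypted):
            out_real = be_train.decrypt_vec(
                fn(be_train, be_train.encrypt_vec(vals), consts))
            out_trace = tr.decrypt_vec(fn(tr, tr.encrypt_vec(vals), consts))
            assert out_real == out_trace

    def test_learning_rate_circuit(self, trace127):
        """digit 6 at p=127: bscale(6 bscale(6 x~)) approximates 0.002 x."""
        assert T.alpha_digit(0.002, 127) == 6
        ct0 = trace127.encrypt_vec([0] * trace127.k)
        assert trace127.decrypt_vec(
            T.mult_learning_rate(trace127, ct0, 6)) == [0] * trace127.k
        xt = 127  # x = 1
        ct = trace127.encrypt_vec([xt] * trace127.k)
        got = trace127.decrypt_vec(T.mult_learning_rate(trace127, ct, 6))[0]
        oracle = balanced_scale(6 * balanced_scale(6 * xt, 127), 127)
        assert got == oracle
        assert abs(got / 127 - (6 / 127) ** 2 * 1.0) <= 1 / 127


class TestTrajectoryEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("algorithm", ["gd", "onebit"])
    def test_trace_equals_fixed_point_oracle(self, seed, algorithm):
        """Encrypted training on the trace backend reproduces the plaintext
        fixed-point trainer coordinate for coordinate, iteration for
        iteration."""
        rng = np.random.default_rng(seed)
        p, r = 127, 3
        backend = TraceBackend(p, r, 5, 8)
        data = make_dataset(rng, 16, 4)
        oracle = T.FixedTrace(FixedPointCodec(p, 1, 1))
        if algorithm == "gd":
            cfg = T.TrainConfig(alpha=0.002, iterations=3, sigmoid="s3")
            adigit = T.alpha_digit(cfg.alpha, p)
            wq = [0] * data.n_features
            enc = T.encode_dataset(backend, data)
            model = T.init_encrypted_model(backend, data.n_features)
            for _ in range(cfg.iterations):
                model = T.encrypted_gd_iteration(backend, model, enc, cfg)
                wq = oracle.gd_iteration(wq, data, adigit)
                assert T.decrypt_model(backend, model) == [int(v) for v in wq]
        else:
            cfg = T.TrainConfig(alpha=0.1, beta=0.2, iterations=3, sigmoid="s1")
            wq, rq = [0] * data.n_features, [0] * data.n_features
            enc = T.encode_dataset(backend, data)
            model = T.init_encrypted_model(backend, data.n_features)
            for _ in range(cfg.iterations):
                model = T.encrypted_onebit_iteration(backend, model, enc, cfg)
                wq, rq = oracle.onebit_iteration(wq, rq, data, cfg.alpha,
                                                 cfg.beta)
                assert T.decrypt_model(backend, model) == [int(v) for v in wq]

    def test_onebit_trace_nonzero_signs(self):
        """With aligned labels the raw gradient crosses the MSD threshold,
        so the 1-bit path takes real (non-zero) steps and still matches."""
        rng = np.random.default_rng(7)
        backend = TraceBackend(127, 3, 5, 8)
        data = make_dataset(rng, 256, 3, y=np.zeros(256))
        cfg = T.TrainConfig(alpha=0.1, beta=0.2, iterations=2, sigmoid="s1")
        oracle = T.FixedTrace(FixedPointCodec(127, 1, 1))
        model = T.train_encrypted(backend, data, cfg, "onebit")
        wq, rq = [0] * 3, [0] * 3
        for _ in range(cfg.iterations):
            wq, rq = oracle.onebit_iteration(wq, rq, data, cfg.alpha, cfg.beta)
        got = T.decrypt_model(backend, model)
        assert got == [int(v) for v in wq]
        assert any(v != 0 for v in got)

    def test_combine_path_equals_unoptimised_path(self, rng):
        backend = TraceBackend(127, 3, 5, 8)
        data = make_dataset(rng, 24, 6)
        enc = T.encode_dataset(backend, data)
        model = T.init_encrypted_model(backend, data.n_features)
        cfg_on = T.TrainConfig(alpha=0.04, iterations=1, use_combine=True)
        cfg_off = T.TrainConfig(alpha=0.04, iterations=1, use_combine=False)
        w_on = T.decrypt_model(
            backend, T.encrypted_gd_iteration(backend, model, enc, cfg_on))
        w_off = T.decrypt_model(
            backend, T.encrypted_gd_iteration(backend, model, enc, cfg_off))
        assert w_on == w_off

    def test_zero_features_leave_weights_near_zero(self):
        """Bias-only data with sigma-consistent label mix: the gradient sums
        to zero, so one iteration leaves every weight unchanged."""
        backend = TraceBackend(17, 3, 6, 8)
        # sigma1(0) = 8 at p=17; 9 zeros and 8 ones: sum d = 9*8 - 8*9 = 0
        X = np.ones((17, 1), dtype=np.int64)
        y = np.array([0] * 9 + [1] * 8, dtype=np.int64)
        data = T.Dataset(X, y)
        cfg = T.TrainConfig(alpha=0.1, beta=0.2, iterations=1, sigmoid="s1")
        model = T.train_encrypted(backend, data, cfg, "onebit")
        assert T.decrypt_model(backend, model) == [0]


class TestRealBackendTrajectory:
    def test_gd_one_iteration_matches_oracle(self, be_train):
        rng = np.random.default_rng(3)
        data = make_dataset(rng, 8, 3, y=np.zeros(8))
        cfg = T.TrainConfig(alpha=0.04, iterations=1, sigmoid="s3")
        oracle = T.FixedTrace(FixedPointCodec(17, 1, 1))
        model = T.train_encrypted(be_train, data, cfg, "gd")
        wq = oracle.gd_iteration([0] * 3, data, T.alpha_digit(0.04, 17))
        got = T.decrypt_model(be_train, model)
        assert got == [int(v) for v in wq]
        assert any(v != 0 for v in got)

    def test_onebit_one_iteration_matches_oracle(self, be_train):
        rng = np.random.default_rng(4)
        data = make_dataset(rng, 24, 3, y=np.zeros(24))
        cfg = T.TrainConfig(alpha=0.1, beta=0.2, iterations=1, sigmoid="s1")
        oracle = T.FixedTrace(FixedPointCodec(17, 1, 1))
        model = T.train_encrypted(be_train, data, cfg, "onebit")
        wq, _ = oracle.onebit_iteration([0] * 3, [0] * 3, data, 0.1, 0.2)
        got = T.decrypt_model(be_train, model)
        assert got == [int(v) for v in wq]
        assert any(v != 0 for v in got)


class TestEncodedDataset:
    def test_vertical_encoding_roundtrip(self, trace127, rng):
        data = make_dataset(rng, 19, 3)  # 19 = 2 full blocks + padding
        enc = T.encode_dataset(trace127, data)
        assert len(enc.Xenc) == 3 and enc.masks[-1].count(1) == 3
        for b, (Xb, Yb, mask) in enumerate(zip(enc.Xenc, enc.Yenc, enc.masks)):
            rows = [b * trace127.k + s for s in range(mask.count(1))]
            for j in range(data.n_features):
                got = trace127.decrypt_vec(Xb[j])[: len(rows)]
                assert got == [int(data.X[i, j]) for i in rows]
            assert trace127.decrypt_vec(Yb)[: len(rows)] == \
                [127 * int(data.y[i]) for i in rows]

    def test_decrypt_model_requires_constant_slots(self, trace127):
        model = T.ModelState(w=[trace127.encrypt_vec(list(range(trace127.k)))])
        with pytest.raises(ParameterError):
            T.decrypt_model(trace127, model)


class TestFloatVsFixedDrift:
    def test_drift_within_propagated_bound(self, rng):
        """Float GD (same circuit constants) and fixed-point GD diverge by
        no more than an interval-propagated rounding bound: each iteration
        contributes O(p^-f) local quantisation, amplified by the computed
        Lipschitz factor of the update map (no magic constants)."""
        p = 127
        consts = T.SigmaConstants.for_base(p)
        adigit = T.alpha_digit(0.002, p)
        alpha_eff = (adigit / p) ** 2
        c0v, c1v, c8v = consts.c_half / p**2, consts.c_lin3 / p, consts.c_cub / p
        sigma_float = lambda z: c0v + c1v * z - (c8v * z) ** 2 * z
        data = make_dataset(rng, 64, 4)
        N, D = data.n_samples, data.n_features
        maxx = int(np.abs(data.X).max())
        oracle = T.FixedTrace(FixedPointCodec(p, 1, 1))
        w_float = np.zeros(D)
        wq = [0] * D
        bound = 0.0
        T_iter = 20
        for _ in range(T_iter):
            z = data.X @ w_float
            zmax = float(np.abs(z).max()) + bound * D * maxx + 1
            slope = c1v + 3 * c8v**2 * zmax**2
            # local quantisation of the sigma circuit and alpha circuit,
            # in value units (each bscale rounds by at most p^-f / 2,
            # amplified by the factors it later multiplies)
            quant_s = (0.5 / p) * (1 + c8v * zmax * 2 + zmax + 1)
            err_s = slope * (D * maxx * bound) + quant_s
            err_g = N * maxx * err_s
            err_upd = alpha_eff * err_g + (1.0 / p) * (1 + adigit / p)
            bound += err_upd
            w_float = w_float - alpha_eff * ((sigma_float(z) - data.y) @ data.X)
            wq = oracle.gd_iteration(wq, data, adigit)
        drift = float(np.max(np.abs(np.asarray(wq) / p - w_float)))
        assert drift <= bound
        assert bound <= T_iter * D * (1 / p) * (alpha_eff * N * maxx**2 * 10 + 1)
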