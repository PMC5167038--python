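import numpy as np
import pytest

from mastsecr import CaptureSession, DetectionParams, Mask, SecrModel, \
    SecrModelSpec, TrapArray, build_mask, param_ci, session_neg_loglik, \
    simulate_session
from mastsecr.detection import occasion_capture_probs

from _oracles import animal_integral, brute_force_mask_points, loop_neg_loglik


class TestBuildMask:
    def test_single_trap_small_buffer(self):
        traps = TrapArray(("t1",), np.array([[0.0, 0.0]]))
        mask = build_mask(traps, buffer=10.0, spacing=10.0)
        # trap cell plus the four orthogonal neighbours; diagonals at
        # sqrt(200) m are beyond the buffer
        assert mask.n_points == 5
        assert mask.cell_area == pytest.approx(0.01)

    def test_matches_brute_force_enumeration(self, grid8):
        mask = build_mask(grid8, buffer=100.0, spacing=10.0)
        ref = brute_force_mask_points(grid8, 100.0, 10.0)
        assert mask.n_points == len(ref)
        got = {tuple(np.round(p, 6)) for p in mask.points}
        want = {tuple(np.round(p, 6)) for p in ref}
        assert got == want

    def test_larger_buffer_never_drops_points(self, grid8):
        n1 = build_mask(grid8, buffer=50.0, spacing=10.0).n_points
        n2 = build_mask(grid8, buffer=100.0, spacing=10.0).n_points
        assert n2 > n1

    def test_invalid_arguments(self, grid8):
        with pytest.raises(ValueError):
            build_mask(grid8, buffer=-1.0)
        with pytest.raises(ValueError):
            build_mask(grid8, spacing=0.0)


class TestCaptureSession:
    def test_duplicate_animal_occasion_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CaptureSession(("s", 2010, 6), 5,
                           (("A1", 1, "a"), ("A1", 1, "b")))

    def test_occasion_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            CaptureSession(("s", 2010, 6), 5, (("A1", 6, "a"),))

    def test_unknown_trap_detected(self):
        traps = TrapArray(("a",), np.array([[0.0, 0.0]]))
        sess = CaptureSession(("s", 2010, 6), 5, (("A1", 1, "zzz"),))
        with pytest.raises(ValueError, match="unknown traps"):
            session_neg_loglik(sess, traps, build_mask(traps, 10, 10),
                               10.0, DetectionParams(0.5, 10.0))


def _random_toy_instance(rng):
    n_traps = int(rng.integers(1, 4))
    traps = TrapArray(tuple(f"t{i}" for i in range(n_traps)),
                      rng.uniform(0, 30, size=(n_traps, 2)))
    n_mask = int(rng.integers(2, 6))
    mask = Mask(points=rng.uniform(-10, 40, size=(n_mask, 2)),
                cell_area=0.04, buffer=50.0, spacing=20.0)
    K = int(rng.integers(1, 4))
    n_animals = int(rng.integers(0, 5))
    records = []
    for i in range(n_animals):
        occs = rng.permutation(K)[:rng.integers(1, K + 1)]
        for occ in occs:
            trap = traps.trap_ids[rng.integers(0, n_traps)]
            records.append((f"A{i}", int(occ) + 1, trap))
    sess = CaptureSession(("toy", 0, 0), K, tuple(records))
    params = DetectionParams(float(rng.uniform(0.1, 1.5)),
                             float(rng.uniform(4.0, 25.0)),
                             b_mult=float(rng.choice([1.0, 0.6, 1.8])))
    D = float(rng.uniform(1.0, 40.0))
    return sess, traps, mask, D, params


class TestLikelihoodOracle:
    def test_vectorized_equals_loop_oracle(self):
        """The array-algebra likelihood must agree with a naive
        per-animal, per-occasion, per-mask-point loop."""
        rng = np.random.default_rng(2016)
        checked = 0
        for _ in range(40):
            sess, traps, mask, D, params = _random_toy_instance(rng)
            got = session_neg_loglik(sess, traps, mask, D, params)
            want = loop_neg_loglik(sess, traps, mask, D, params)
            assert got == pytest.approx(want, abs=1e-8)
            checked += 1
        assert checked == 40

    def test_empty_session_is_exactly_poisson_zero_term(self):
        traps = TrapArray.grid(2, 2, 10.0)
        mask = build_mask(traps, 20, 10)
        params = DetectionParams(0.5, 8.0)
        sess = CaptureSession(("s", 0, 0), 3, ())
        D = 7.0
        a = sum(mask.cell_area
                * (1 - occasion_capture_probs(x, traps, params.lambda0,
                                              params.sigma)[1] ** 3)
                for x in mask.points)
        assert session_neg_loglik(sess, traps, mask, D, params) \
            == pytest.approx(D * a, rel=1e-12)

    def test_removing_one_animal_shifts_loglik_analytically(self):
        """Dropping animal i changes log L by log D + log(c sum Pr_i) - log n."""
        rng = np.random.default_rng(5)
        sess, traps, mask, D, params = _random_toy_instance(rng)
        while len({r[0] for r in sess.records}) < 2:
            sess, traps, mask, D, params = _random_toy_instance(rng)
        animals = sorted({r[0] for r in sess.records})
        drop = animals[0]
        reduced = CaptureSession(sess.session_id, sess.n_occasions,
                                 tuple(r for r in sess.records
                                       if r[0] != drop))
        full_nll = session_neg_loglik(sess, traps, mask, D, params)
        red_nll = session_neg_loglik(reduced, traps, mask, D, params)
        hist = {occ: t for a, occ, t in sess.records if a == drop}
        integral = animal_integral(hist, traps, mask, params,
                                   sess.n_occasions)
        delta = np.log(D) + np.log(integral) - np.log(len(animals))
        assert (-full_nll) - (-red_nll) == pytest.approx(delta, abs=1e-8)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(11)
        sess, traps, mask, D, params = _random_toy_instance(rng)
        while sess.n_individuals == 0:
            sess, traps, mask, D, params = _random_toy_instance(rng)
        base = session_neg_loglik(sess, traps, mask, D, params)
        # permute animal labels and trap labels consistently
        a_map = {a: f"Z{j}" for j, a in enumerate(reversed(sess.animal_ids))}
        perm = np.random.default_rng(1).permutation(traps.n_traps)
        t_map = {traps.trap_ids[i]: f"q{j}" for j, i in enumerate(perm)}
        traps2 = TrapArray(tuple(t_map[traps.trap_ids[i]] for i in perm),
                           traps.xy[perm])
        sess2 = CaptureSession(sess.session_id, sess.n_occasions,
                               tuple((a_map[a], occ, t_map[t])
                                     for a, occ, t in sess.records))
        assert session_neg_loglik(sess2, traps2, mask, D, params) \
            == pytest.approx(base, abs=1e-10)


class TestMaskRefinement:
    def test_halving_spacing_barely_moves_loglik(self, grid8, rng):
        """10-m vs 5-m mask spacing changes -log L by < 0.1 at study scale."""
        params = DetectionParams(0.5, 12.0)
        sess, _ = simulate_session(25.0, params, grid8, 5, 150.0, rng)
        m10 = build_mask(grid8, 100.0, 10.0)
        m5 = build_mask(grid8, 100.0, 5.0)
        v10 = session_neg_loglik(sess, grid8, m10, 25.0, params)
        v5 = session_neg_loglik(sess, grid8, m5, 25.0, params)
        assert abs(v10 - v5) < 0.1


class TestFit:
    def test_single_session_recovery_within_3se(self, grid8, mask8, rng):
        D, sigma, lam0 = 25.0, 12.0, 0.5
        sess, _ = simulate_session(D, DetectionParams(lam0, sigma),
                                   grid8, 5, 150.0, rng)
        res = SecrModel([sess], grid8, mask=mask8).fit()
        assert res.converged
        est = res.estimates().set_index("parameter")
        for name, truth in (("D", D), ("sigma", sigma), ("lambda0", lam0)):
            z = abs(np.log(truth) - np.log(est.loc[name, "estimate"])) \
                / est.loc[name, "se_log"]
            assert z < 3, f"{name} off by {z:.1f} SE"

    def test_replicated_session_gives_same_estimates(self, rng):
        traps = TrapArray.grid(5, 5, 10.0)
        mask = build_mask(traps, 60.0, 20.0)
        sess, _ = simulate_session(20.0, DetectionParams(0.5, 12.0),
                                   traps, 5, 80.0, rng)
        one = SecrModel([sess], traps, mask=mask).fit()
        sess_b = CaptureSession(("s", 0, 1), sess.n_occasions, sess.records)
        two = SecrModel([sess, sess_b], traps, mask=mask).fit()
        np.testing.assert_allclose(np.exp(two.params), np.exp(one.params),
                                   rtol=1e-4)
        # sessions are independent and identical, so the joint maximum
        # has exactly twice the single-session log-likelihood
        assert two.loglik == pytest.approx(2 * one.loglik, rel=1e-6)
        assert two.n_individuals == 2 * one.n_individuals

    def test_perturbing_estimates_lowers_likelihood(self, rng):
        traps = TrapArray.grid(6, 6, 10.0)
        mask = build_mask(traps, 60.0, 15.0)
        sess, _ = simulate_session(25.0, DetectionParams(0.5, 12.0),
                                   traps, 5, 80.0, rng)
        model = SecrModel([sess], traps, mask=mask)
        res = model.fit()
        peak = model.loglike(res.params)
        for i in range(res.params.size):
            for sign in (-1, 1):
                theta = res.params.copy()
                theta[i] += sign * 2 * res.bse[i]
                assert model.loglike(theta) < peak

    def test_degenerate_session_named_in_error(self, grid8, mask8):
        empty = CaptureSession(("siteX", 2011, 7), 5, ())
        with pytest.raises(ValueError, match="siteX"):
            SecrModel([empty], grid8, mask=mask8,
                      spec=SecrModelSpec(d_struct="by_session"))


class TestParamCI:
    @staticmethod
    def _fit(rng):
        traps = TrapArray.grid(5, 5, 10.0)
        mask = build_mask(traps, 60.0, 20.0)
        sess, _ = simulate_session(20.0, DetectionParams(0.5, 12.0),
                                   traps, 5, 80.0, rng)
        return SecrModel([sess], traps, mask=mask).fit()

    def test_wald_interval_arithmetic(self, rng):
        res = self._fit(rng)
        # impose log-estimate 0 and SE 1 on the first parameter
        res.params[0], res.bse[0] = 0.0, 1.0
        ci = param_ci(res, level=0.95)
        # exp(-/+ 1.959963984...), the exact 97.5% normal quantile
        assert ci["ci_low"].iloc[0] == pytest.approx(0.1408635, abs=1e-6)
        assert ci["ci_high"].iloc[0] == pytest.approx(7.0990714, abs=1e-6)

    def test_zero_se_degenerates_to_point(self, rng):
        res = self._fit(rng)
        res.bse[:] = 0.0
        ci = param_ci(res)
        assert np.allclose(ci["ci_low"], ci["estimate"])
        assert np.allclose(ci["ci_high"], ci["estimate"])

    def test_nested_levels(self, rng):
        res = self._fit(rng)
        c90 = param_ci(res, 0.90)
        c95 = param_ci(res, 0.95)
        assert np.all(c95["ci_low"] <= c90["ci_low"])
        assert np.all(c95["ci_high"] >= c90["ci_high"])

    def test_refuses_non_converged(self, rng):
        res = self._fit(rng)
        res.converged = False
        with pytest.raises(RuntimeError):
            param_ci(res)
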