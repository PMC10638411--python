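import numpy as np
import pytest

from semdem.dynamics import DynamicsParams, step, stimulus_vector
from semdem.plasticity import PlasticityRule, apply_hebbian_sparse, hebbian_update

RULE = PlasticityRule(theta_pre=0.5, theta_post=0.15, delta_ltp=0.01,
                      delta_ltd=0.01, delta_ltd_hetero=0.01, w_max=1.0)


class TestRuleArithmetic:
    def test_ltp_increment(self):
        w = hebbian_update(np.array([0.10]), np.array([0.9]), np.array([0.5]), RULE)
        assert w[0] == pytest.approx(0.11)

    def test_ceiling_preserved(self):
        w = hebbian_update(np.array([1.0]), np.array([0.9]), np.array([0.5]), RULE)
        assert w[0] == 1.0

    def test_floor_preserved(self):
        w = hebbian_update(np.array([0.0]), np.array([0.9]), np.array([0.0]), RULE)
        assert w[0] == 0.0

    def test_silence_leaves_weights_unchanged(self):
        w0 = np.linspace(0, 1, 11)
        w = hebbian_update(w0, np.zeros(11), np.zeros(11), RULE)
        assert np.array_equal(w, w0)

    def test_disabled_rule_is_identity(self):
        rule = PlasticityRule(enabled=False)
        w0 = np.array([0.3, 0.7])
        w = hebbian_update(w0, np.ones(2), np.ones(2), rule)
        assert np.array_equal(w, w0)

    def test_updatable_mask_freezes_links(self):
        w = hebbian_update(np.array([0.1, 0.1]), np.array([0.9, 0.9]),
                           np.array([0.5, 0.5]), RULE,
                           updatable=np.array([True, False]))
        assert w[0] == pytest.approx(0.11) and w[1] == 0.1

    def test_total_signed_change_matches_counting_oracle(self):
        rng = np.random.default_rng(0)
        n = 2000
        w0 = rng.uniform(0.3, 0.7, n)  # away from the clip boundaries
        pre = rng.uniform(0, 1, n)
        post = rng.uniform(0, 0.4, n)
        out = np.clip(post, 0, 1)
        w = hebbian_update(w0, pre, post, RULE, post_outputs=out)
        # element-wise classification, done independently of the implementation
        n_ltp = n_homo = n_het = 0
        for p, q, o in zip(pre, post, out):
            if p >= RULE.theta_pre and q >= RULE.theta_post:
                n_ltp += 1
            elif p >= RULE.theta_pre:
                n_homo += 1
            elif o >= RULE.theta_pre:
                n_het += 1
        expected = (n_ltp * RULE.delta_ltp - n_homo * RULE.delta_ltd
                    - n_het * RULE.delta_ltd_hetero)
        assert (w - w0).sum() == pytest.approx(expected, abs=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PlasticityRule(theta_pre=0.0)
        with pytest.raises(ValueError):
            PlasticityRule(delta_ltp=-1e-3)


class TestSparseDenseEquivalence:
    def test_sparse_path_equals_dense_reference(self, net):
        """The activity-sparse in-step update must equal the dense per-link rule."""
        rng = np.random.default_rng(1)
        net.O = np.where(rng.random(net.n_cells) < 0.03,
                         rng.uniform(0.3, 1.0, net.n_cells), 0.0)
        net.V = rng.normal(0.05, 0.15, net.n_cells)
        net.lesion_mask[net.area_slice("AT")][:100] = False
        net.plastic[::17] = False
        rule = PlasticityRule()

        src_of = np.repeat(np.arange(net.n_cells), np.diff(net.out_indptr))
        updatable = (net.plastic & net.lesion_mask[src_of]
                     & net.lesion_mask[net.out_tgt])
        pre_outputs = np.where(net.lesion_mask, net.O, 0.0)
        post_pot = np.where(net.lesion_mask, net.V, -np.inf)
        expected = hebbian_update(net.w.copy(), pre_outputs[src_of],
                                  post_pot[net.out_tgt], rule,
                                  updatable=updatable,
                                  post_outputs=pre_outputs[net.out_tgt])
        apply_hebbian_sparse(net, rule)
        assert np.allclose(net.w, expected, atol=1e-12)


class TestHebbianFixedPoint:
    def test_reciprocal_coactivation_converges_to_ceiling(self):
        """Two reciprocally linked cells repeatedly co-active end at w_max."""
        rule = PlasticityRule(delta_ltp=0.05)
        w = np.array([0.1, 0.2])
        pre = np.array([0.9, 0.9])
        post = np.array([0.8, 0.8])
        for _ in range(50):
            w = hebbian_update(w, pre, post, rule)
        assert np.all(w == rule.w_max)

    def test_training_step_changes_only_plastic_weights(self, net):
        rng = np.random.default_rng(3)
        net.plastic[:1000] = False
        before = net.w.copy()
        stim = stimulus_vector(net, {"A1": np.arange(19)}, amplitude=8.0)
        for _ in range(10):
            step(net, DynamicsParams(), rng, stimulus=stim, rule=PlasticityRule())
        assert np.array_equal(net.w[:1000], before[:1000])
        assert not np.array_equal(net.w[1000:], before[1000:])  # something learned


class TestRuleProperties:
    def test_range_preservation_for_arbitrary_inputs(self):
        """Weights remain in [0, w_max] after any update (property test)."""
        from hypothesis import given, settings, HealthCheck
        from hypothesis import strategies as st
        from hypothesis.extra import numpy as hnp

        rule = PlasticityRule(delta_ltp=0.5, delta_ltd=0.5, delta_ltd_hetero=0.5,
                              w_max=0.8)
        arrays = hnp.arrays(np.float64, 16,
                            elements=st.floats(-2, 2, allow_nan=False))

        @settings(max_examples=50, deadline=None, derandomize=True,
                  suppress_health_check=[HealthCheck.too_slow])
        @given(w=hnp.arrays(np.float64, 16,
                            elements=st.floats(0, 0.8, allow_nan=False)),
               pre=arrays, post=arrays)
        def check(w, pre, post):
            out = hebbian_update(w, np.clip(pre, 0, 1), post, rule)
            assert np.all(out >= 0.0) and np.all(out <= rule.w_max)
            # silence (both sides sub-threshold) leaves weights untouched
            silent = (np.clip(pre, 0, 1) < rule.theta_pre) & (post < rule.theta_post) \
                     & (np.clip(post, 0, 1) < rule.theta_pre)
            assert np.array_equal(out[silent], w[silent])

        check()
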