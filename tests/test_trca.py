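import numpy as np
import pytest

from ssvepdecode import (
    SimConfig,
    build_templates,
    fit_trca,
    pearson,
    signed_square_fuse,
    simulate_subject,
    trca_filter,
    trca_matrices,
    trca_score,
    tstrca_beta,
    tstrca_classify,
    tstrca_score,
    tstrca_scores,
)
from conftest import make_epochs


def naive_trca_matrices(trials):
    """Quadruple-loop oracle for S and Q, straight from the definitions."""
    nt = len(trials)
    nc, ns = trials[0].shape

    def cov(a, b):
        return np.mean((a - a.mean()) * (b - b.mean()))

    S = np.zeros((nc, nc))
    for t1 in range(nt):
        for t2 in range(nt):
            if t1 == t2:
                continue
            for c1 in range(nc):
                for c2 in range(nc):
                    S[c1, c2] += cov(trials[t1][c1], trials[t2][c2])
    centered = [t - t.mean(axis=1, keepdims=True) for t in trials]
    concat = np.hstack(centered)
    Q = np.zeros((nc, nc))
    for c1 in range(nc):
        for c2 in range(nc):
            Q[c1, c2] = cov(concat[c1], concat[c2])
    return S, Q


class TestTRCAMatrices:
    @pytest.mark.parametrize("nt,nc,ns", [(2, 2, 8), (3, 3, 50), (4, 4, 60), (2, 4, 17),
                                          (4, 2, 33)])
    def test_matches_quadruple_loop_oracle(self, nt, nc, ns, rng):
        trials = [rng.standard_normal((nc, ns)) for _ in range(nt)]
        m = trca_matrices(trials)
        S, Q = naive_trca_matrices(trials)
        np.testing.assert_allclose(m.S, S, atol=1e-10)
        np.testing.assert_allclose(m.Q, Q, atol=1e-10)
        np.testing.assert_allclose(m.S, m.S.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(m.Q) > -1e-10)

    def test_identical_trials_give_scaled_single_covariance(self, rng):
        x = rng.standard_normal((3, 100))
        nt = 4
        m = trca_matrices([x] * nt)
        xc = x - x.mean(axis=1, keepdims=True)
        C = xc @ xc.T / x.shape[1]
        np.testing.assert_allclose(m.S, nt * (nt - 1) * C, atol=1e-10)

    def test_independent_noise_has_near_zero_s(self):
        rng = np.random.default_rng(99)
        trials = [rng.standard_normal((2, 10000)) for _ in range(2)]
        m = trca_matrices(trials)
        assert np.max(np.abs(m.S)) < 0.05

    def test_single_trial_rejected(self, rng):
        with pytest.raises(ValueError, match="2 trials"):
            trca_matrices([rng.standard_normal((2, 10))])


class TestTRCAFilter:
    def test_reproducible_channel_dominates_weight(self):
        rng = np.random.default_rng(5)
        t = np.arange(500) / 250.0
        sig = np.sin(2 * np.pi * 10.0 * t)
        sigma = np.sqrt(np.mean(sig**2))  # noise sd = signal RMS
        trials = [np.vstack([sig, sigma * rng.standard_normal(500)]) for _ in range(6)]
        w, _ = trca_filter(trials)
        assert abs(w[0]) > 0.95

    def test_rayleigh_quotient_dominates_random_vectors(self, rng):
        trials = [rng.standard_normal((4, 60)) for _ in range(4)]
        m = trca_matrices(trials)
        w, lam = trca_filter(trials)
        best = (w @ m.S @ w) / (w @ m.Q @ w)
        assert lam == pytest.approx(best, rel=1e-6)
        vs = rng.standard_normal((1000, 4))
        vs /= np.linalg.norm(vs, axis=1, keepdims=True)
        quotients = np.einsum("ic,cd,id->i", vs, m.S, vs) / np.einsum(
            "ic,cd,id->i", vs, m.Q, vs)
        assert best >= quotients.max() - 1e-8

    def test_orthonormal_channel_rotation_rotates_filter(self, rng):
        trials = [rng.standard_normal((3, 80)) for _ in range(3)]
        R, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        w0, lam0 = trca_filter(trials)
        w1, lam1 = trca_filter([R @ t for t in trials])
        assert lam1 == pytest.approx(lam0, rel=1e-8)
        target = R @ w0
        i = np.argmax(np.abs(target))
        if target[i] < 0:
            target = -target
        np.testing.assert_allclose(w1, target, atol=1e-8)


class TestFitAndScore:
    def test_shapes_and_determinism(self, noisy_subject):
        bank, templates = fit_trca(noisy_subject)
        assert len(bank) == noisy_subject.n_classes
        assert bank[0].shape == (noisy_subject.n_channels,)
        assert templates[0].shape == (noisy_subject.n_channels, noisy_subject.n_samples)
        bank2, _ = fit_trca(noisy_subject)
        for i in range(len(bank)):
            np.testing.assert_array_equal(bank[i], bank2[i])

    def test_single_training_trial_rejected(self, noisy_subject):
        one = noisy_subject.with_data(noisy_subject.data[:, :1])
        with pytest.raises(ValueError, match="2 training trials"):
            fit_trca(one)

    def test_template_scores_one_for_its_own_class(self, noisy_subject):
        bank, templates = fit_trca(noisy_subject)
        sv = trca_score(templates[4], bank, templates)
        assert sv.scores[4] == pytest.approx(1.0, abs=1e-12)

    def test_score_invariant_to_filter_sign_flip(self, noisy_subject, rng):
        from ssvepdecode.trca import SpatialFilterBank
        bank, templates = fit_trca(noisy_subject)
        flipped = SpatialFilterBank(
            filters=tuple(-f if i % 2 else f for i, f in enumerate(bank.filters)),
            eigenvalues=bank.eigenvalues,
        )
        x = rng.standard_normal(templates[0].shape)
        np.testing.assert_allclose(trca_score(x, bank, templates).scores,
                                   trca_score(x, flipped, templates).scores, atol=1e-12)

    def test_high_snr_trial_classified_correctly(self):
        ep = simulate_subject(SimConfig(snr_db=10.0, mixing_seed=3, noise_seed=4))
        bank, templates = fit_trca(ep.with_data(ep.data[:, :5]))
        sv = trca_score(ep.data[2, 5], bank, templates)
        assert int(np.argmax(sv.scores)) == 2


class TestTwoStep:
    def test_beta_all_ones_for_self_pair(self, noisy_subject):
        bank, templates = fit_trca(noisy_subject)
        beta = tstrca_beta(templates[1], templates[1], bank)
        np.testing.assert_allclose(beta, 1.0, atol=1e-12)
        assert beta.shape == (len(bank) + 1,)

    def test_beta_all_minus_one_for_negated_pair(self, noisy_subject):
        bank, templates = fit_trca(noisy_subject)
        beta = tstrca_beta(-templates[1], templates[1], bank)
        np.testing.assert_allclose(beta, -1.0, atol=1e-12)

    def test_beta_matches_naive_loop(self, noisy_subject, rng):
        bank, templates = fit_trca(noisy_subject)
        x = rng.standard_normal(templates[0].shape)
        beta = tstrca_beta(x, templates[3], bank)
        assert beta[0] == pytest.approx(pearson(templates[3], x), abs=1e-12)
        for k in range(len(bank)):
            expect = pearson(bank[k] @ templates[3], bank[k] @ x)
            assert beta[k + 1] == pytest.approx(expect, abs=1e-12)

    def test_score_is_signed_square_fusion(self, rng):
        beta = rng.uniform(-1, 1, 9)
        assert tstrca_score(beta) == signed_square_fuse(beta)

    def test_own_filter_entry_reduces_to_standard_trca(self, noisy_subject, rng):
        """beta_{i,i} without squaring is exactly the standard TRCA score."""
        bank, templates = fit_trca(noisy_subject)
        x = rng.standard_normal(templates[0].shape)
        std = trca_score(x, bank, templates).scores
        restricted = np.array([
            tstrca_beta(x, templates[i], bank)[i + 1] for i in range(len(bank))
        ])
        np.testing.assert_allclose(restricted, std, atol=1e-12)

    def test_template_input_classified_as_its_class(self, noiseless_subject):
        bank, templates = fit_trca(noiseless_subject)
        for j in (0, 3, 7):
            assert tstrca_classify(templates[j], bank, templates) == j

    def test_scores_invariant_to_test_rescaling(self, noisy_subject, rng):
        bank, templates = fit_trca(noisy_subject)
        x = rng.standard_normal(templates[0].shape)
        s1 = tstrca_scores(x, bank, templates).scores
        s2 = tstrca_scores(7.3 * x, bank, templates).scores
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_two_step_not_worse_than_standard_at_short_window(self):
        """Paired comparison on held-out trials at a short analysis window."""
        from ssvepdecode import EvalConfig, loocv
        cfg = EvalConfig(tw_s=0.3)
        n_ts = n_std = 0
        for seed in range(4):
            ep = simulate_subject(SimConfig(mixing_seed=seed, noise_seed=100 + seed))
            n_ts += loocv(ep, "tstrca", cfg).accuracy
            n_std += loocv(ep, "trca", cfg).accuracy
        assert n_ts >= n_std
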