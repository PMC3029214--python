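import itertools

import numpy as np
import pytest

from voicelevel.hmm import (
    GaussianMixture,
    HMMModel,
    bakis_transmat,
    classify_word,
    forward_loglik,
    init_hmm,
    model_from_dict,
    model_to_dict,
    train_em,
)


def random_model(n_states, n_mix, dim, rng, left_right=False):
    emissions = []
    for _ in range(n_states):
        w = rng.dirichlet(np.ones(n_mix))
        emissions.append(
            GaussianMixture(w, rng.normal(0, 2, (n_mix, dim)), rng.uniform(0.5, 2, (n_mix, dim)))
        )
    if left_right:
        A = bakis_transmat(n_states, 0.7)
    else:
        A = np.triu(rng.uniform(0.1, 1.0, (n_states, n_states)))
        A /= A.sum(axis=1, keepdims=True)
    start = np.zeros(n_states)
    start[0] = 1.0
    return HMMModel(start, A, emissions)


def brute_force_loglik(model, seq):
    """Likelihood by exhaustive enumeration of all state paths."""
    T, S = seq.shape[0], model.n_states
    logb = model.emission_logprob(seq)
    total = -np.inf
    for path in itertools.product(range(S), repeat=T):
        lp = np.log(model.startprob[path[0]]) if model.startprob[path[0]] > 0 else -np.inf
        lp += logb[0, path[0]]
        for t in range(1, T):
            a = model.transmat[path[t - 1], path[t]]
            lp += (np.log(a) if a > 0 else -np.inf) + logb[t, path[t]]
        total = np.logaddexp(total, lp)
    return total


def sample_sequence(model, T, rng):
    s = 0
    out = []
    for t in range(T):
        g = model.emissions[s]
        k = rng.choice(g.n_components, p=g.weights)
        out.append(rng.normal(g.means[k], np.sqrt(g.variances[k])))
        if t < T - 1:
            s = rng.choice(model.n_states, p=model.transmat[s])
    return np.asarray(out)


class TestForward:
    def test_matches_exhaustive_path_enumeration(self, rng):
        for _ in range(10):
            S = rng.integers(1, 4)
            M = rng.integers(1, 3)
            T = rng.integers(1, 7)
            model = random_model(S, M, 2, rng)
            seq = rng.normal(0, 2, (T, 2))
            assert forward_loglik(model, seq) == pytest.approx(
                brute_force_loglik(model, seq), abs=1e-10
            )

    def test_single_frame_is_initial_weighted_emission(self, rng):
        model = random_model(3, 2, 2, rng)
        seq = rng.normal(0, 1, (1, 2))
        expected = model.emissions[0].log_density(seq)[0]  # start mass on state 0
        assert forward_loglik(model, seq) == pytest.approx(expected, abs=1e-12)

    def test_state_duplication_invariance(self, rng):
        """Splitting a state into two identical copies with shared probability
        mass leaves the sequence likelihood unchanged."""
        g = GaussianMixture([1.0], [[0.0, 1.0]], [[1.0, 1.0]])
        single = HMMModel([1.0], [[1.0]], [g])
        double = HMMModel([1.0, 0.0], [[0.5, 0.5], [0.0, 1.0]], [g, g])
        seq = rng.normal(0, 1, (5, 2))
        assert forward_loglik(double, seq) == pytest.approx(
            forward_loglik(single, seq), abs=1e-10
        )

    def test_dimension_mismatch_raises(self, rng):
        model = random_model(2, 1, 3, rng)
        with pytest.raises(ValueError):
            forward_loglik(model, rng.normal(0, 1, (4, 2)))


class TestInit:
    def test_contiguous_blocks_recover_separated_means(self, rng):
        seqs = [
            np.concatenate([rng.normal(0, 1, (50, 1)), rng.normal(10, 1, (50, 1))])
            for _ in range(10)
        ]
        model = init_hmm(seqs, n_states=2, n_mix=1, seed=0)
        means = sorted(float(g.means[0, 0]) for g in model.emissions)
        assert means[0] == pytest.approx(0.0, abs=0.5)
        assert means[1] == pytest.approx(10.0, abs=0.5)

    def test_deterministic_under_seed(self, rng):
        seqs = [rng.normal(0, 1, (40, 3)) for _ in range(5)]
        a = init_hmm(seqs, 4, 2, seed=9)
        b = init_hmm(seqs, 4, 2, seed=9)
        for ga, gb in zip(a.emissions, b.emissions):
            assert np.array_equal(ga.means, gb.means)
            assert np.array_equal(ga.weights, gb.weights)

    def test_insufficient_data_raises(self, rng):
        with pytest.raises(ValueError):
            init_hmm([rng.normal(0, 1, (5, 2))], n_states=4, n_mix=2, seed=0)


class TestTrainEM:
    def test_loglik_monotone_nondecreasing(self, rng):
        true = random_model(3, 1, 2, rng, left_right=True)
        seqs = [sample_sequence(true, 40, rng) for _ in range(10)]
        model = init_hmm(seqs, 3, 2, seed=1)
        _, history = train_em(model, seqs, max_iter=25, tol=0.0)
        diffs = np.diff(history)
        assert np.all(diffs >= -1e-8 * np.abs(history[:-1]))

    def test_structure_preserved_after_em(self, rng):
        true = random_model(3, 1, 2, rng, left_right=True)
        seqs = [sample_sequence(true, 40, rng) for _ in range(10)]
        model, _ = train_em(init_hmm(seqs, 3, 1, seed=1), seqs, max_iter=10)
        assert np.allclose(model.transmat.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(model.transmat[np.tril_indices(3, -1)] == 0.0)
        assert model.startprob[0] == 1.0

    def test_zero_variance_feature_floored(self, rng):
        seqs = [np.column_stack([rng.normal(0, 1, 30), np.full(30, 2.0)]) for _ in range(5)]
        model, _ = train_em(init_hmm(seqs, 2, 1, seed=0), seqs, max_iter=5)
        for g in model.emissions:
            assert np.all(g.variances >= 1e-3)

    def test_parameter_recovery_on_balanced_left_right(self, rng):
        emissions = [
            GaussianMixture([1.0], [[0.0, 0.0]], [[1.0, 1.0]]),
            GaussianMixture([1.0], [[4.0, 4.0]], [[1.0, 1.0]]),
            GaussianMixture([1.0], [[8.0, 0.0]], [[1.0, 1.0]]),
        ]
        true = HMMModel([1, 0, 0], bakis_transmat(3, 0.97), emissions)
        seqs = [sample_sequence(true, 100, rng) for _ in range(50)]
        model, _ = train_em(init_hmm(seqs, 3, 1, seed=1), seqs, max_iter=100, tol=1e-9)
        assert np.abs(model.transmat - true.transmat).max() < 0.1
        held = [sample_sequence(true, 100, rng) for _ in range(20)]
        ll_true = np.mean([forward_loglik(true, s) for s in held])
        ll_fit = np.mean([forward_loglik(model, s) for s in held])
        assert abs(ll_fit - ll_true) / abs(ll_true) < 0.02

    def test_agrees_with_hmmlearn_forward(self, rng):
        """Independent cross-check of the forward likelihood against hmmlearn
        on a single-component model."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        model = random_model(3, 1, 2, rng, left_right=True)
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        ref.startprob_ = model.startprob
        ref.transmat_ = model.transmat
        ref.means_ = np.vstack([g.means for g in model.emissions])
        ref.covars_ = np.vstack([g.variances for g in model.emissions])
        seq = rng.normal(0, 2, (20, 2))
        assert forward_loglik(model, seq) == pytest.approx(ref.score(seq), abs=1e-8)


class TestSerialization:
    def test_json_roundtrip_preserves_likelihood(self, rng):
        import json

        model = random_model(3, 2, 4, rng, left_right=True)
        model.feature_mean = rng.normal(0, 1, 4)
        model.feature_std = rng.uniform(0.5, 2, 4)
        back = model_from_dict(json.loads(json.dumps(model_to_dict(model))))
        seq = rng.normal(0, 2, (15, 4))
        assert forward_loglik(back, seq) == pytest.approx(
            forward_loglik(model, seq), abs=1e-12
        )
        assert np.allclose(back.feature_mean, model.feature_mean)


class TestClassify:
    def test_argmax_and_tie_rule(self, rng):
        g = GaussianMixture([1.0], [[0.0]], [[1.0]])
        base = HMMModel([1.0], [[1.0]], [g])
        shifted = HMMModel([1.0], [[1.0]], [GaussianMixture([1.0], [[5.0]], [[1.0]])])
        models = {1: base, 2: shifted, 3: base, 4: shifted}
        seq = np.zeros((10, 1))
        level, lls = classify_word(models, seq)
        assert level == 1  # exact tie between 1 and 3 resolves low
        assert lls[0] == lls[2] and lls[0] > lls[1]

    def test_well_separated_models_classified_accurately(self, rng):
        models = {}
        for lv in range(1, 5):
            mean = 3.0 * lv  # 3 SD apart at unit variance
            g = GaussianMixture([1.0], [[mean, mean]], [[1.0, 1.0]])
            models[lv] = HMMModel([1.0, 0.0], bakis_transmat(2, 0.8), [g, g])
        correct = 0
        for _ in range(200):
            lv = int(rng.integers(1, 5))
            seq = sample_sequence(models[lv], 20, rng)
            pred, _ = classify_word(models, seq)
            correct += pred == lv
        assert correct / 200 >= 0.90
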