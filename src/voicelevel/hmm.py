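"""Continuous left-right hidden Markov models with diagonal-GMM emissions.

One model is trained per (word, severity level) — 20 in total for the
five-word, four-level task — on the 8-dimensional frame-feature sequences
of that cell.  Training is k-means-initialized Baum-Welch (EM); scoring is
the scaled forward algorithm, and a word is classified to the level whose
model maximizes the forward log-likelihood.

Topology is Bakis-1: each state may self-loop or advance by one, with all
initial probability on the first state, so the state index tracks progress
through the word.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "GaussianMixture",
    "HMMModel",
    "init_hmm",
    "train_em",
    "forward_loglik",
    "classify_word",
    "model_to_dict",
    "model_from_dict",
]

VARIANCE_FLOOR = 1e-3
LOG_ZERO = -1e30


@dataclass
class GaussianMixture:
    """Diagonal-covariance Gaussian mixture emission density."""

    weights: np.ndarray  # (M,)
    means: np.ndarray  # (M, D)
    variances: np.ndarray  # (M, D), diagonal, floored

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=np.float64))
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-8):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")

    @property
    def n_components(self) -> int:
        return self.weights.size

    def component_log_densities(self, X: np.ndarray) -> np.ndarray:
        """(T, M) log N(x_t | mu_m, diag var_m)."""
        X = np.atleast_2d(X)
        diff = X[:, None, :] - self.means[None, :, :]  # (T, M, D)
        inv = 1.0 / self.variances
        quad = np.einsum("tmd,md->tm", diff**2, inv)
        log_norm = -0.5 * (
            self.means.shape[1] * np.log(2 * np.pi) + np.log(self.variances).sum(axis=1)
        )
        return log_norm[None, :] - 0.5 * quad

    def log_density(self, X: np.ndarray) -> np.ndarray:
        """(T,) log sum_m w_m N(x_t | m)."""
        comp = self.component_log_densities(X)
        with np.errstate(divide="ignore"):
            logw = np.where(self.weights > 0, np.log(self.weights), LOG_ZERO)
        return _logsumexp(comp + logw[None, :], axis=1)


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    amax = np.max(a, axis=axis, keepdims=True)
    amax = np.where(np.isfinite(amax), amax, 0.0)
    out = np.log(np.sum(np.exp(a - amax), axis=axis)) + np.squeeze(amax, axis=axis)
    return out


@dataclass
class HMMModel:
    """Left-right HMM with per-state GMM emissions.

    ``feature_mean``/``feature_std`` hold the per-feature z-scoring
    statistics learned on the training split; sequences must be normalized
    with them before scoring.
    """

    startprob: np.ndarray  # (S,), all mass on state 0
    transmat: np.ndarray  # (S, S), upper-triangular bakis-1
    emissions: list[GaussianMixture]
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=np.float64)
        self.transmat = np.asarray(self.transmat, dtype=np.float64)
        S = self.startprob.size
        if self.transmat.shape != (S, S):
            raise ValueError("transmat shape must match startprob")
        if len(self.emissions) != S:
            raise ValueError("one emission density per state required")
        rows = self.transmat.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")

    @property
    def n_states(self) -> int:
        return self.startprob.size

    @property
    def n_features(self) -> int:
        return self.emissions[0].means.shape[1]

    def emission_logprob(self, seq: np.ndarray) -> np.ndarray:
        """(T, S) per-state log emission densities."""
        seq = np.atleast_2d(seq)
        if seq.shape[1] != self.n_features:
            raise ValueError(
                f"sequence dimension {seq.shape[1]} != model dimension {self.n_features}"
            )
        return np.column_stack([gmm.log_density(seq) for gmm in self.emissions])

    def normalize(self, seq: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return np.atleast_2d(np.asarray(seq, dtype=np.float64))
        return (np.atleast_2d(seq) - self.feature_mean) / self.feature_std


def bakis_transmat(n_states: int, self_prob: float = 0.5) -> np.ndarray:
    """Uniform left-right transition matrix: self-loop + single forward jump."""
    A = np.zeros((n_states, n_states))
    for s in range(n_states - 1):
        A[s, s] = self_prob
        A[s, s + 1] = 1.0 - self_prob
    A[-1, -1] = 1.0
    return A


def init_hmm(
    seqs: list[np.ndarray],
    n_states: int = 8,
    n_mix: int = 4,
    seed: int = 0,
) -> HMMModel:
    """K-means initialization from uniform time segmentation.

    Each sequence is split into ``n_states`` contiguous blocks; the pooled
    frames of block s seed state s's mixture via k-means (means from the
    cluster centers, weights from cluster occupancy, variances from cluster
    scatter, floored).
    """
    seqs = [np.atleast_2d(np.asarray(s, dtype=np.float64)) for s in seqs]
    if not seqs:
        raise ValueError("no training sequences")
    total = sum(s.shape[0] for s in seqs)
    if total < n_states * n_mix:
        raise ValueError(
            f"{total} pooled frames cannot support {n_states} states x {n_mix} mixtures"
        )
    d = seqs[0].shape[1]
    pooled: list[list[np.ndarray]] = [[] for _ in range(n_states)]
    for seq in seqs:
        bounds = np.linspace(0, seq.shape[0], n_states + 1).astype(int)
        for s in range(n_states):
            if bounds[s + 1] > bounds[s]:
                pooled[s].append(seq[bounds[s] : bounds[s + 1]])

    rng_seed = int(seed) % (2**31)
    emissions = []
    all_frames = np.vstack(seqs)
    global_var = np.maximum(all_frames.var(axis=0), VARIANCE_FLOOR)
    for s in range(n_states):
        block = np.vstack(pooled[s]) if pooled[s] else all_frames
        k = min(n_mix, block.shape[0])
        km = KMeans(n_clusters=k, n_init=1, random_state=rng_seed + s).fit(block)
        labels = km.labels_
        weights = np.zeros(n_mix)
        means = np.zeros((n_mix, d))
        variances = np.tile(global_var, (n_mix, 1))
        for c in range(k):
            members = block[labels == c]
            weights[c] = members.shape[0]
            means[c] = km.cluster_centers_[c]
            if members.shape[0] > 1:
                variances[c] = np.maximum(members.var(axis=0), VARIANCE_FLOOR)
        if k < n_mix:  # duplicate clusters to fill the requested mixture size
            for c in range(k, n_mix):
                means[c] = means[c % k]
                weights[c] = 1e-3
        weights = weights / weights.sum()
        emissions.append(GaussianMixture(weights, means, variances))

    start = np.zeros(n_states)
    start[0] = 1.0
    return HMMModel(startprob=start, transmat=bakis_transmat(n_states), emissions=emissions)


def _forward_scaled(model: HMMModel, logb: np.ndarray):
    """Scaled forward pass; returns (alpha_hat, log c_t sums per step)."""
    T, S = logb.shape
    # work with linear probabilities of the emission, rescaled per frame
    bmax = logb.max(axis=1, keepdims=True)
    b = np.exp(logb - bmax)
    alpha = np.empty((T, S))
    logscale = np.empty(T)
    a = model.startprob * b[0]
    norm = a.sum()
    if norm <= 0:
        raise FloatingPointError("forward underflow at t=0")
    alpha[0] = a / norm
    logscale[0] = np.log(norm) + bmax[0, 0]
    At = model.transmat.T
    for t in range(1, T):
        a = (At @ alpha[t - 1]) * b[t]
        norm = a.sum()
        if norm <= 0:
            raise FloatingPointError(f"forward underflow at t={t}")
        alpha[t] = a / norm
        logscale[t] = np.log(norm) + bmax[t, 0]
    return alpha, logscale


def _backward_scaled(model: HMMModel, logb: np.ndarray, logscale: np.ndarray):
    T, S = logb.shape
    bmax = logb.max(axis=1, keepdims=True)
    b = np.exp(logb - bmax)
    beta = np.empty((T, S))
    beta[-1] = 1.0
    A = model.transmat
    for t in range(T - 2, -1, -1):
        scale = np.exp(logscale[t + 1] - bmax[t + 1, 0])
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / scale
    return beta


def forward_loglik(model: HMMModel, seq: np.ndarray) -> float:
    """Exact log P(seq | model) by the forward recursion in log space.

    Log space (rather than per-frame rescaling) keeps the computation
    finite even when a sequence is scored under a badly mismatched model,
    as happens constantly during classification.
    """
    seq = np.atleast_2d(np.asarray(seq, dtype=np.float64))
    logb = model.emission_logprob(seq)
    with np.errstate(divide="ignore"):
        log_start = np.where(model.startprob > 0, np.log(model.startprob), LOG_ZERO)
        log_A = np.where(model.transmat > 0, np.log(model.transmat), LOG_ZERO)
    log_alpha = log_start + logb[0]
    for t in range(1, logb.shape[0]):
        log_alpha = _logsumexp(log_alpha[:, None] + log_A, axis=0) + logb[t]
    return float(_logsumexp(log_alpha[None, :], axis=1)[0])


def train_em(
    model: HMMModel,
    seqs: list[np.ndarray],
    max_iter: int = 50,
    tol: float = 1e-5,
) -> tuple[HMMModel, list[float]]:
    """Baum-Welch training; returns the refit model and per-iteration log-likelihoods.

    The left-right zero pattern of the transition matrix and the all-mass-on-
    state-1 start distribution are preserved exactly; variances are floored
    at ``VARIANCE_FLOOR``.  Stops when the relative improvement in total
    log-likelihood drops below ``tol``.
    """
    seqs = [np.atleast_2d(np.asarray(s, dtype=np.float64)) for s in seqs]
    if not seqs:
        raise ValueError("no training sequences")
    S = model.n_states
    zero_mask = model.transmat == 0.0
    history: list[float] = []
    model = replace(model)

    for _ in range(max_iter):
        trans_num = np.zeros((S, S))
        post_sum = [np.zeros(gmm.n_components) for gmm in model.emissions]
        mean_num = [np.zeros_like(gmm.means) for gmm in model.emissions]
        var_num = [np.zeros_like(gmm.variances) for gmm in model.emissions]
        total_ll = 0.0

        for si, seq in enumerate(seqs):
            T = seq.shape[0]
            comp_ld = [gmm.component_log_densities(seq) for gmm in model.emissions]
            with np.errstate(divide="ignore"):
                logw = [
                    np.where(g.weights > 0, np.log(g.weights), LOG_ZERO)
                    for g in model.emissions
                ]
            logb = np.column_stack(
                [_logsumexp(comp_ld[s] + logw[s][None, :], axis=1) for s in range(S)]
            )
            try:
                alpha, logscale = _forward_scaled(model, logb)
                beta = _backward_scaled(model, logb, logscale)
            except FloatingPointError as exc:
                raise RuntimeError(f"EM underflow on sequence {si}") from exc
            total_ll += float(logscale.sum())

            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)

            # transition counts: xi_t(i,j) ∝ alpha_t(i) a_ij b_j(t+1) beta_{t+1}(j)
            bmax = logb.max(axis=1, keepdims=True)
            b = np.exp(logb - bmax)
            for t in range(T - 1):
                xi = (
                    alpha[t][:, None]
                    * model.transmat
                    * (b[t + 1] * beta[t + 1])[None, :]
                )
                ssum = xi.sum()
                if ssum > 0:
                    trans_num += xi / ssum

            # per-state, per-component responsibilities
            for s in range(S):
                log_post = comp_ld[s] + logw[s][None, :]
                log_post -= _logsumexp(log_post, axis=1)[:, None]
                resp = np.exp(log_post) * gamma[:, s][:, None]  # (T, M)
                post_sum[s] += resp.sum(axis=0)
                mean_num[s] += resp.T @ seq
                var_num[s] += resp.T @ (seq**2)

        history.append(total_ll)

        # M-step
        trans_num[zero_mask] = 0.0
        rows = trans_num.sum(axis=1, keepdims=True)
        new_trans = np.where(rows > 0, trans_num / np.maximum(rows, 1e-300), model.transmat)
        new_trans[zero_mask] = 0.0
        new_trans /= new_trans.sum(axis=1, keepdims=True)

        new_emissions = []
        for s, gmm in enumerate(model.emissions):
            occ = post_sum[s]
            weights = occ / occ.sum() if occ.sum() > 0 else gmm.weights
            means = gmm.means.copy()
            variances = gmm.variances.copy()
            nz = occ > 1e-10
            means[nz] = mean_num[s][nz] / occ[nz, None]
            ex2 = np.empty_like(variances)
            ex2[nz] = var_num[s][nz] / occ[nz, None]
            variances[nz] = np.maximum(ex2[nz] - means[nz] ** 2, VARIANCE_FLOOR)
            new_emissions.append(GaussianMixture(weights, means, variances))

        model = HMMModel(
            startprob=model.startprob,
            transmat=new_trans,
            emissions=new_emissions,
            feature_mean=model.feature_mean,
            feature_std=model.feature_std,
            meta=model.meta,
        )

        if len(history) >= 2:
            prev, cur = history[-2], history[-1]
            if abs(cur - prev) < tol * abs(prev):
                break
    return model, history


def model_to_dict(model: HMMModel) -> dict:
    """JSON-serializable snapshot of an HMM (topology, parameters, stats)."""
    return {
        "startprob": model.startprob.tolist(),
        "transmat": model.transmat.tolist(),
        "emissions": [
            {
                "weights": g.weights.tolist(),
                "means": g.means.tolist(),
                "variances": g.variances.tolist(),
            }
            for g in model.emissions
        ],
        "feature_mean": None if model.feature_mean is None else model.feature_mean.tolist(),
        "feature_std": None if model.feature_std is None else model.feature_std.tolist(),
        "meta": model.meta,
    }


def model_from_dict(payload: dict) -> HMMModel:
    emissions = [
        GaussianMixture(e["weights"], e["means"], e["variances"])
        for e in payload["emissions"]
    ]
    fm = payload.get("feature_mean")
    fsd = payload.get("feature_std")
    return HMMModel(
        startprob=np.asarray(payload["startprob"]),
        transmat=np.asarray(payload["transmat"]),
        emissions=emissions,
        feature_mean=None if fm is None else np.asarray(fm),
        feature_std=None if fsd is None else np.asarray(fsd),
        meta=payload.get("meta", {}),
    )


def classify_word(models: dict[int, HMMModel], seq: np.ndarray):
    """Level decision for one utterance from that word's four level models.

    Returns ``(level, logliks)`` with logliks ordered by level; ties break
    toward the lower level.
    """
    levels = sorted(models)
    lls = np.array([forward_loglik(models[lv], seq) for lv in levels])
    return levels[int(np.argmax(lls))], lls
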