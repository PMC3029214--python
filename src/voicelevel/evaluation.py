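"""End-to-end training/evaluation protocol with random-subsampling CV.

The experimental unit for fusion is an *utterance set*: one child saying
all five words once (one repetition).  Splits are drawn at the
utterance-set level — 60 % of sets train the base classifiers, 40 % test
them — stratified by level, repeated with fresh random permutations, and
accuracies averaged over repetitions.  Children may appear on both sides
of a split (their individual utterances never do); a child-disjoint mode
is available for the stricter generalization check.  For stacked fusion
the test split is halved again into meta-training and final-test parts, so
the meta-classifier never sees base-classifier training data.

Per-level accuracies below 50 % are flagged "not classified".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio_io import LEVELS, WORDS, UtteranceRecord, trim_endpoints
from .config import SystemConfig
from .frame_features import FRAME_FEATURE_NAMES, extract_frame_features
from .fusion import LogLikMatrix, fuse_linear, fuse_mvr, fuse_stacked, scale_levels
from .hmm import HMMModel, classify_word, init_hmm, train_em
from .neural_net import MLPModel, init_mlp, one_hot_levels, predict_level, train_mlp
from .word_features import WORD_FEATURE_NAMES, WaveletConfig, extract_word_features

__all__ = [
    "FeatureSet",
    "SplitPlan",
    "AccuracyReport",
    "extract_features",
    "save_features",
    "load_features",
    "make_splits",
    "train_system",
    "save_system",
    "load_system",
    "score_group",
    "evaluate",
]

NOT_CLASSIFIED_THRESHOLD = 50.0
FUSION_RULES = ("mvr", "linear", "stacked")


@dataclass
class FeatureSet:
    """Cached per-utterance features for a whole corpus.

    ``index`` has one row per utterance (child_id, word, level, repetition,
    group) where ``group`` identifies the utterance set (child, repetition).
    ``frame_features[i]`` is the (T_i, 8) observation matrix;
    ``word_features[i]`` the 5-vector of word-level features.
    """

    index: pd.DataFrame
    frame_features: list[np.ndarray]
    word_features: np.ndarray

    @property
    def groups(self) -> pd.DataFrame:
        """One row per utterance set: group id and its level."""
        return self.index.groupby("group").agg(level=("level", "first")).reset_index()


def extract_features(
    records: list[UtteranceRecord],
    config: SystemConfig | None = None,
    trim: bool = True,
) -> FeatureSet:
    """Run both feature extractors over a corpus (trimming endpoints first)."""
    cfg = config or SystemConfig()
    wavelet_cfg = WaveletConfig(order=cfg.wavelet_order, scales=tuple(cfg.wavelet_scales))
    rows, frame_feats, word_feats = [], [], []
    for rec in records:
        w = rec.waveform
        if trim:
            w = trim_endpoints(w, cfg.trim_threshold_db, cfg.trim_min_voiced_s)
        ff = extract_frame_features(
            w,
            frame_length_s=cfg.frame_length_s,
            overlap=cfg.overlap,
            fmin=cfg.f0_fmin,
            fmax=cfg.f0_fmax,
            apen_m=cfg.apen_m,
            apen_r=cfg.apen_r,
        )
        wf = extract_word_features(
            w,
            wavelet_cfg=wavelet_cfg,
            kmax=cfg.higuchi_kmax,
            lyap_dimension=cfg.lyapunov_dimension,
            lyap_delay=cfg.lyapunov_delay,
        )
        frame_feats.append(ff[list(FRAME_FEATURE_NAMES)].to_numpy())
        word_feats.append([wf[name] for name in WORD_FEATURE_NAMES])
        rows.append(
            {
                "child_id": rec.child_id,
                "word": rec.word,
                "level": rec.level,
                "repetition": rec.repetition,
                "group": f"{rec.child_id}#r{rec.repetition}",
            }
        )
    return FeatureSet(
        index=pd.DataFrame(rows),
        frame_features=frame_feats,
        word_features=np.asarray(word_feats, dtype=np.float64),
    )


def save_features(features: FeatureSet, out_dir) -> None:
    """Write a FeatureSet as TSV files: one frame table per utterance plus a
    word_features.tsv carrying the index and word-level features."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    word_df = features.index.copy()
    for j, name in enumerate(WORD_FEATURE_NAMES):
        word_df[name] = features.word_features[:, j]
    word_df.to_csv(out / "word_features.tsv", sep="\t", index=False)
    for i, row in features.index.iterrows():
        frame_df = pd.DataFrame(features.frame_features[i], columns=FRAME_FEATURE_NAMES)
        name = f"{row.child_id}_{row.word}_r{row.repetition}.frames.tsv"
        frame_df.to_csv(out / name, sep="\t", index=False)


def load_features(feature_dir) -> FeatureSet:
    """Read back a FeatureSet written by :func:`save_features`."""
    from pathlib import Path

    d = Path(feature_dir)
    word_df = pd.read_csv(d / "word_features.tsv", sep="\t", dtype={"child_id": str})
    index = word_df[["child_id", "word", "level", "repetition", "group"]].copy()
    word_feats = word_df[list(WORD_FEATURE_NAMES)].to_numpy()
    frames = []
    for row in index.itertuples(index=False):
        name = f"{row.child_id}_{row.word}_r{row.repetition}.frames.tsv"
        frames.append(pd.read_csv(d / name, sep="\t")[list(FRAME_FEATURE_NAMES)].to_numpy())
    return FeatureSet(index=index, frame_features=frames, word_features=word_feats)


@dataclass(frozen=True)
class SplitPlan:
    """Utterance-row index sets for one repetition of the protocol."""

    train1: np.ndarray
    test1: np.ndarray
    train2: np.ndarray | None = None  # meta-training rows (subset of test1)
    test2: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if np.intersect1d(self.train1, self.test1).size:
            raise ValueError("train1 and test1 overlap")
        if self.train2 is not None:
            if np.intersect1d(self.train2, self.test2).size:
                raise ValueError("train2 and test2 overlap")
            union = np.union1d(self.train2, self.test2)
            if not np.array_equal(union, np.sort(self.test1)):
                raise ValueError("train2 and test2 must partition test1")


def _split_groups(groups: pd.DataFrame, frac: float, rng, by_child: bool):
    """Stratified-by-level split of utterance-set (or child) identifiers."""
    first = []
    second = []
    key = "child" if by_child else "group"
    if by_child:
        groups = groups.assign(child=groups["group"].str.split("#").str[0])
        units = groups.groupby("child").agg(level=("level", "first")).reset_index()
    else:
        units = groups
    for _, sub in units.groupby("level"):
        ids = sub[key].to_numpy()
        perm = rng.permutation(len(ids))
        n_first = max(1, int(round(frac * len(ids))))
        n_first = min(n_first, len(ids) - 1) if len(ids) > 1 else n_first
        first.extend(ids[perm[:n_first]])
        second.extend(ids[perm[n_first:]])
    return set(first), set(second)


def make_splits(
    index: pd.DataFrame,
    train_frac: float = 0.6,
    n_reps: int = 10,
    stacked: bool = False,
    seed: int = 0,
    split_mode: str = "utterance",
) -> list[SplitPlan]:
    """Random-subsampling split plans over utterance sets.

    ``split_mode='utterance'`` permutes utterance sets (a child's sets may
    land on both sides, individual utterances never do);
    ``split_mode='child'`` keeps each child wholly on one side.
    Every (word, level) cell must be populated in each training split.
    """
    if split_mode not in ("utterance", "child"):
        raise ValueError("split_mode must be 'utterance' or 'child'")
    rng = np.random.default_rng(int(seed) % (2**31))
    groups = index.groupby("group").agg(level=("level", "first")).reset_index()
    plans = []
    for rep in range(n_reps):
        train_ids, test_ids = _split_groups(
            groups, train_frac, rng, by_child=split_mode == "child"
        )
        if split_mode == "child":
            child = index["group"].str.split("#").str[0]
            train_mask = child.isin(train_ids)
        else:
            train_mask = index["group"].isin(train_ids)
        train1 = np.flatnonzero(train_mask)
        test1 = np.flatnonzero(~train_mask)

        cells = index.iloc[train1].groupby(["word", "level"]).size()
        expected = len(WORDS) * len(LEVELS)
        if len(cells) < expected:
            raise ValueError(
                f"split {rep}: some (word, level) cell has no training utterances"
            )

        train2 = test2 = None
        if stacked:
            test_groups = groups[groups["group"].isin(test_ids)]
            meta_ids, final_ids = _split_groups(test_groups, 0.5, rng, by_child=False)
            train2 = np.flatnonzero(index["group"].isin(meta_ids))
            test2 = np.flatnonzero(index["group"].isin(final_ids))
        plans.append(SplitPlan(train1=train1, test1=test1, train2=train2, test2=test2, seed=seed + rep))
    return plans


@dataclass
class TrainedSystem:
    """All base classifiers for one training split."""

    hmm_banks: dict[str, dict[int, HMMModel]]  # word -> level -> model
    word_nn: MLPModel
    feature_mean: np.ndarray
    feature_std: np.ndarray


def train_system(
    features: FeatureSet,
    train_rows: np.ndarray,
    config: SystemConfig | None = None,
    seed: int = 0,
) -> TrainedSystem:
    """Train the 20 per-(word, level) HMMs and the word-feature MLP."""
    cfg = config or SystemConfig()
    idx = features.index
    train_frames = np.vstack([features.frame_features[i] for i in train_rows])
    mean = train_frames.mean(axis=0)
    std = train_frames.std(axis=0)
    std = np.where(std > 1e-8, std, 1.0)

    banks: dict[str, dict[int, HMMModel]] = {}
    for word in WORDS:
        banks[word] = {}
        for level in LEVELS:
            rows = [
                i
                for i in train_rows
                if idx.at[i, "word"] == word and idx.at[i, "level"] == level
            ]
            if not rows:
                raise ValueError(f"no training data for ({word}, level {level})")
            seqs = [(features.frame_features[i] - mean) / std for i in rows]
            model = init_hmm(
                seqs, n_states=cfg.hmm_n_states, n_mix=cfg.hmm_n_mix,
                seed=seed + 1000 * level + WORDS.index(word),
            )
            model.feature_mean, model.feature_std = mean, std
            model, _ = train_em(model, seqs, max_iter=cfg.em_max_iter, tol=cfg.em_tol)
            banks[word][level] = model

    X = features.word_features[train_rows]
    Y = one_hot_levels(idx.iloc[train_rows]["level"].to_numpy())
    nn = init_mlp(X.shape[1], n_hidden=cfg.mlp_hidden, seed=seed + 7)
    nn, _ = train_mlp(nn, X, Y, epochs=cfg.mlp_epochs, lr=cfg.mlp_lr)
    return TrainedSystem(hmm_banks=banks, word_nn=nn, feature_mean=mean, feature_std=std)


def save_system(system: TrainedSystem, out_dir) -> None:
    """Serialize all trained classifiers as JSON, one file per model."""
    import json
    from pathlib import Path

    from .hmm import model_to_dict
    from .neural_net import mlp_to_dict

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for word, bank in system.hmm_banks.items():
        for level, model in bank.items():
            (out / f"hmm_{word}_level{level}.json").write_text(
                json.dumps(model_to_dict(model))
            )
    (out / "word_nn.json").write_text(json.dumps(mlp_to_dict(system.word_nn)))


def load_system(model_dir) -> TrainedSystem:
    import json
    from pathlib import Path

    from .hmm import model_from_dict
    from .neural_net import mlp_from_dict

    d = Path(model_dir)
    banks: dict[str, dict[int, HMMModel]] = {}
    for word in WORDS:
        banks[word] = {}
        for level in LEVELS:
            payload = json.loads((d / f"hmm_{word}_level{level}.json").read_text())
            banks[word][level] = model_from_dict(payload)
    nn = mlp_from_dict(json.loads((d / "word_nn.json").read_text()))
    any_model = banks[WORDS[0]][1]
    return TrainedSystem(
        hmm_banks=banks,
        word_nn=nn,
        feature_mean=any_model.feature_mean,
        feature_std=any_model.feature_std,
    )


def score_group(
    system: TrainedSystem, features: FeatureSet, rows: np.ndarray
) -> dict:
    """Base-classifier outputs for one utterance set (one child, one repetition).

    Returns crisp votes and soft evidence for all six base classifiers:
    five word-HMM banks (level log-likelihoods) plus the word-feature MLP
    (soft outputs averaged over the set's words, entering linear fusion on
    the log scale).
    """
    idx = features.index
    votes, ll_rows = [], []
    nn_softs = []
    for i in rows:
        word = idx.at[i, "word"]
        seq = (features.frame_features[i] - system.feature_mean) / system.feature_std
        level, lls = classify_word(system.hmm_banks[word], seq)
        votes.append(level)
        ll_rows.append(lls)
        _, soft = predict_level(system.word_nn, features.word_features[i])
        nn_softs.append(soft)
    nn_soft = np.mean(nn_softs, axis=0)
    nn_level = int(np.argmax(nn_soft)) + 1
    return {
        "hmm_votes": np.asarray(votes),
        "hmm_logliks": np.asarray(ll_rows),
        "nn_level": nn_level,
        "nn_soft": nn_soft,
        "words": [idx.at[i, "word"] for i in rows],
    }


def _fusion_inputs(out: dict):
    votes6 = np.concatenate([out["hmm_votes"], [out["nn_level"]]])
    ll6 = np.vstack([out["hmm_logliks"], np.log(out["nn_soft"] + 1e-12)[None, :]])
    return votes6, LogLikMatrix(ll6)


@dataclass
class AccuracyReport:
    """Mean per-level accuracies (%) over repetitions, Table-style.

    ``per_level`` is indexed by classifier name ('word:mashin', ..., or a
    fusion rule) with columns level_1..level_4 and 'average'; entries under
    50 % carry a ``not_classified`` flag in the companion frame.
    """

    per_level: pd.DataFrame
    not_classified: pd.DataFrame
    n_reps: int

    def to_markdown(self) -> str:
        df = self.per_level.copy()
        flagged = df.copy().astype(object)
        for r in df.index:
            for c in df.columns:
                v = df.at[r, c]
                if c.startswith("level") and self.not_classified.at[r, c]:
                    flagged.at[r, c] = f"{v:.1f} (not classified)"
                else:
                    flagged.at[r, c] = f"{v:.1f}"
        return flagged.to_markdown()


def _per_level_accuracy(true_levels: np.ndarray, pred_levels: np.ndarray) -> np.ndarray:
    accs = np.full(len(LEVELS), np.nan)
    for li, level in enumerate(LEVELS):
        mask = true_levels == level
        if mask.any():
            accs[li] = 100.0 * np.mean(pred_levels[mask] == level)
    return accs


def evaluate(
    features: FeatureSet,
    rules: tuple[str, ...] = ("mvr", "linear"),
    config: SystemConfig | None = None,
    n_reps: int | None = None,
    seed: int = 0,
    split_mode: str = "utterance",
) -> AccuracyReport:
    """Full protocol: repeated 60/40 subsampling, training, scoring, averaging.

    Reports per-level accuracies for every isolated word classifier and
    every requested fusion rule, averaged over repetitions.  Repetitions
    whose split cannot train every (word, level) model are dropped with a
    warning rather than aborting the run.
    """
    import warnings

    cfg = config or SystemConfig()
    for rule in rules:
        if rule not in FUSION_RULES:
            raise ValueError(f"unknown fusion rule {rule!r}")
    reps = n_reps if n_reps is not None else cfg.n_reps
    stacked = "stacked" in rules
    plans = make_splits(
        features.index,
        train_frac=cfg.train_frac,
        n_reps=reps,
        stacked=stacked,
        seed=seed,
        split_mode=split_mode,
    )

    names = [f"word:{w}" for w in WORDS] + [f"fused:{r}" for r in rules]
    acc_sums = {n: [] for n in names}

    for rep, plan in enumerate(plans):
        try:
            system = train_system(features, plan.train1, config=cfg, seed=seed + 101 * rep)
        except ValueError as exc:
            warnings.warn(f"repetition {rep} skipped: {exc}", stacklevel=2)
            continue

        idx = features.index

        def group_rows(rows):
            sub = idx.iloc[rows]
            return {g: rows[np.asarray(sub["group"] == g)] for g in sub["group"].unique()}

        test_groups = group_rows(plan.test1)
        outputs = {g: score_group(system, features, rows) for g, rows in test_groups.items()}
        true = {g: int(idx.iloc[rows[0]]["level"]) for g, rows in test_groups.items()}

        # isolated per-word classifiers
        for wi, word in enumerate(WORDS):
            t, p = [], []
            for g, out in outputs.items():
                if word in out["words"]:
                    t.append(true[g])
                    p.append(out["hmm_votes"][out["words"].index(word)])
            acc_sums[f"word:{word}"].append(_per_level_accuracy(np.array(t), np.array(p)))

        meta = None
        if stacked:
            meta_groups = group_rows(plan.train2)
            meta_out = {g: score_group(system, features, rows) for g, rows in meta_groups.items()}
            Xm = np.array([scale_levels(_fusion_inputs(o)[0]) for o in meta_out.values()])
            ym = np.array([int(idx.iloc[meta_groups[g][0]]["level"]) for g in meta_out])
            meta = init_mlp(Xm.shape[1], n_hidden=cfg.mlp_hidden, seed=seed + 13 * rep)
            # meta inputs are already on [0,1]; a larger step than the
            # word-feature net's suits this small, well-conditioned problem
            meta, _ = train_mlp(
                meta, Xm, one_hot_levels(ym), epochs=cfg.mlp_epochs, lr=0.5,
                normalize_inputs=False,
            )
            final_groups = group_rows(plan.test2)
            final_out = {g: score_group(system, features, rows) for g, rows in final_groups.items()}

        for rule in rules:
            t, p = [], []
            src = final_out if rule == "stacked" else outputs
            for g, out in src.items():
                votes6, ll = _fusion_inputs(out)
                if rule == "mvr":
                    decision = fuse_mvr(votes6, ll)
                elif rule == "linear":
                    decision = fuse_linear(ll)
                else:
                    decision = fuse_stacked(votes6, meta)
                t.append(true[g] if rule != "stacked" else int(idx.iloc[final_groups[g][0]]["level"]))
                p.append(decision.level)
            acc_sums[f"fused:{rule}"].append(_per_level_accuracy(np.array(t), np.array(p)))

    cols = [f"level_{lv}" for lv in LEVELS]
    data = {}
    for name, rows in acc_sums.items():
        if rows:
            mean = np.nanmean(np.vstack(rows), axis=0)
        else:
            mean = np.full(len(LEVELS), np.nan)
        data[name] = list(mean) + [np.nanmean(mean)]
    per_level = pd.DataFrame.from_dict(data, orient="index", columns=cols + ["average"])
    not_classified = per_level[cols] < NOT_CLASSIFIED_THRESHOLD
    not_classified["average"] = per_level["average"] < NOT_CLASSIFIED_THRESHOLD
    return AccuracyReport(per_level=per_level, not_classified=not_classified, n_reps=len(plans))
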