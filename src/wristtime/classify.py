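"""Balanced random forest + hidden Markov model behaviour classification.

Every 30-s epoch is first classified into three behaviours — sleep,
sedentary, and other non-sedentary — by a random forest whose trees are
grown on class-balanced bootstraps (equal draws per class, count set by the
minority class) to counter the heavy label imbalance of free-living data.
The forest's out-of-bag predictions then calibrate a hidden Markov model
(prior, transition and emission matrices with add-one smoothing) whose
Viterbi decoding smooths the per-epoch sequence, exploiting the strong
temporal persistence of human behaviour.  Finally, non-sedentary epochs are
sub-classified as LIPA or MVPA at the 100 mg epoch-ENMO threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .rawproc import FEATURE_NAMES, EpochSeries
from .synth import BEHAVIOURS

#: 3-class training labels, in fixed tie-break order
CLASSES3 = ("sleep", "sedentary", "non-sedentary")
MISSING_LABEL = "missing"

#: map 4-class schedule/ground-truth labels onto the 3 training classes
TO3 = {"sleep": "sleep", "sedentary": "sedentary",
       "LIPA": "non-sedentary", "MVPA": "non-sedentary"}


class NotTrainedError(RuntimeError):
    pass


@dataclass
class LabelledEpochSet:
    """Training epochs: features, 3-class labels, participant grouping."""

    features: np.ndarray          # (n, n_features)
    labels: np.ndarray            # (n,) str from CLASSES3
    participant: np.ndarray       # (n,) participant ids, epochs ordered within
    feature_names: tuple = FEATURE_NAMES

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.participant = np.asarray(self.participant)
        if not np.isfinite(self.features).all():
            raise ValueError("training features must be finite")
        bad = set(np.unique(self.labels)) - set(CLASSES3)
        if bad:
            raise ValueError(f"labels outside the 3-class set: {sorted(bad)}")


class BalancedRandomForest:
    """Random forest with per-tree class-balanced bootstraps and OOB votes.

    Each tree is grown on a bootstrap drawing ``n_min`` samples per class
    with replacement, where ``n_min`` is the minority class size; split
    candidates per node are ``floor(sqrt(n_features))``.  Out-of-bag hard
    votes are retained for every training sample to estimate the HMM
    emission matrix without a held-out set.  Deterministic given the seed.
    """

    def __init__(self, n_trees: int = 100, seed: int = 0):
        self.n_trees = n_trees
        self.seed = seed
        self.trees_: list[DecisionTreeClassifier] = []
        self.classes_: np.ndarray | None = None
        self.oob_votes_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return bool(self.trees_)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.array([c for c in CLASSES3 if c in set(y)])
        if len(self.classes_) < 2:
            raise ValueError("training set must contain at least 2 classes")
        rng = np.random.default_rng(self.seed)
        class_idx = [np.flatnonzero(y == c) for c in self.classes_]
        n_min = min(len(ix) for ix in class_idx)
        n = len(y)
        votes = np.zeros((n, len(self.classes_)))
        self.trees_ = []
        self.per_tree_class_counts_ = n_min
        for _ in range(self.n_trees):
            boot = np.concatenate([rng.choice(ix, size=n_min, replace=True)
                                   for ix in class_idx])
            tree = DecisionTreeClassifier(
                max_features="sqrt",
                random_state=int(rng.integers(2 ** 31)))
            tree.fit(X[boot], y[boot])
            self.trees_.append(tree)
            oob = np.ones(n, dtype=bool)
            oob[boot] = False
            if oob.any():
                pred = tree.predict(X[oob])
                order = {c: k for k, c in enumerate(self.classes_)}
                cols = np.array([order[p] for p in pred])
                votes[np.flatnonzero(oob), cols] += 1
        self.oob_votes_ = votes
        return self

    def _check(self):
        if not self.fitted:
            raise NotTrainedError("forest has not been fitted")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        self._check()
        X = np.asarray(X, dtype=float)
        order = {c: k for k, c in enumerate(self.classes_)}
        proba = np.zeros((len(X), len(self.classes_)))
        for tree in self.trees_:
            pred = tree.predict(X)
            cols = np.array([order[p] for p in pred])
            proba[np.arange(len(X)), cols] += 1
        return proba / self.n_trees

    def predict(self, X: np.ndarray) -> np.ndarray:
        # ties broken by fixed class order (sleep < sedentary < non-sedentary)
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    @property
    def oob_prediction_(self) -> np.ndarray:
        """Hard OOB label per training sample (forest fallback if no votes)."""
        self._check()
        return self.classes_[self.oob_votes_.argmax(axis=1)]

    def oob_accuracy(self, y: np.ndarray) -> float:
        return float(np.mean(self.oob_prediction_ == np.asarray(y)))


@dataclass
class HmmParams:
    prior: np.ndarray            # (3,)
    transition: np.ndarray       # (3, 3) P(next | current)
    emission: np.ndarray         # (3, 3) P(predicted | true)
    classes: tuple = CLASSES3


@dataclass
class BehaviourModel:
    """Trained balanced forest + HMM + the LIPA/MVPA intensity threshold."""

    forest: BalancedRandomForest
    hmm: HmmParams
    intensity_threshold: float = 100.0    # mg
    feature_names: tuple = FEATURE_NAMES
    seed: int = 0

    def save(self, path: str | Path) -> None:
        """Model directory: forest dump + plain-text HMM and feature list."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.forest, path / "forest.joblib")
        with open(path / "hmm.txt", "w") as fh:
            for name, mat in (("prior", self.hmm.prior[None, :]),
                              ("transition", self.hmm.transition),
                              ("emission", self.hmm.emission)):
                fh.write(f"# {name}\n")
                for row in mat:
                    fh.write(" ".join(repr(float(v)) for v in row) + "\n")
        (path / "features.txt").write_text("\n".join(self.feature_names) + "\n")
        (path / "meta.json").write_text(json.dumps(
            {"intensity_threshold_mg": self.intensity_threshold,
             "n_trees": self.forest.n_trees, "seed": self.seed,
             "classes": list(CLASSES3)}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "BehaviourModel":
        path = Path(path)
        forest = joblib.load(path / "forest.joblib")
        rows = []
        for line in (path / "hmm.txt").read_text().splitlines():
            if line and not line.startswith("#"):
                rows.append([float(v) for v in line.split()])
        prior = np.array(rows[0])
        transition = np.array(rows[1:4])
        emission = np.array(rows[4:7])
        meta = json.loads((path / "meta.json").read_text())
        names = tuple((path / "features.txt").read_text().split())
        return cls(forest=forest,
                   hmm=HmmParams(prior, transition, emission),
                   intensity_threshold=meta["intensity_threshold_mg"],
                   feature_names=names, seed=meta["seed"])


@dataclass
class BehaviourSequence:
    """Per-epoch 4-class labels on the same grid as the input epochs."""

    labels: np.ndarray            # (n,) str: BEHAVIOURS or "missing"
    smoothed: bool = True


def train_forest(train: LabelledEpochSet, n_trees: int = 100,
                 seed: int = 0) -> BalancedRandomForest:
    """Fit the balanced forest on a labelled 3-class epoch set."""
    return BalancedRandomForest(n_trees=n_trees, seed=seed).fit(
        train.features, train.labels)


def estimate_hmm(train: LabelledEpochSet, oob_predictions: np.ndarray,
                 smoothing: float = 1.0) -> HmmParams:
    """Estimate prior/transition/emission from labels and OOB predictions.

    Transitions are counted over consecutive epochs within each participant;
    add-one (Laplace, or ``smoothing``) counts keep every entry positive so
    Viterbi never hits a -inf log path.  Rows normalise to 1.
    """
    labels = np.asarray(train.labels)
    pred = np.asarray(oob_predictions)
    k = len(CLASSES3)
    order = {c: i for i, c in enumerate(CLASSES3)}
    li = np.array([order[v] for v in labels])
    pi = np.array([order[v] for v in pred])

    prior = np.full(k, smoothing)
    np.add.at(prior, li, 1.0)
    prior /= prior.sum()

    trans = np.full((k, k), smoothing)
    same = train.participant[1:] == train.participant[:-1]
    np.add.at(trans, (li[:-1][same], li[1:][same]), 1.0)
    trans /= trans.sum(axis=1, keepdims=True)

    emis = np.full((k, k), smoothing)
    np.add.at(emis, (li, pi), 1.0)
    emis /= emis.sum(axis=1, keepdims=True)
    return HmmParams(prior=prior, transition=trans, emission=emis)


def viterbi(observations: np.ndarray, hmm: HmmParams) -> np.ndarray:
    """Maximum-a-posteriori state path in log space.

    ``observations`` is a sequence of predicted 3-class labels (or indices).
    Ties are broken by the fixed state order sleep < sedentary <
    non-sedentary.
    """
    obs = np.asarray(observations)
    if obs.dtype.kind in "UO":
        order = {c: i for i, c in enumerate(hmm.classes)}
        obs = np.array([order[v] for v in obs])
    n = len(obs)
    if n == 0:
        return np.array([], dtype=object)
    log_prior = np.log(hmm.prior)
    log_trans = np.log(hmm.transition)
    log_emis = np.log(hmm.emission)
    k = len(hmm.prior)
    delta = log_prior + log_emis[:, obs[0]]
    back = np.zeros((n, k), dtype=np.int64)
    for t in range(1, n):
        cand = delta[:, None] + log_trans          # (from, to)
        back[t] = cand.argmax(axis=0)              # first index wins ties
        delta = cand[back[t], np.arange(k)] + log_emis[:, obs[t]]
    path = np.zeros(n, dtype=np.int64)
    path[-1] = int(delta.argmax())
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return np.asarray(hmm.classes, dtype=object)[path]


def split_intensity(sequence: np.ndarray, epochs: EpochSeries,
                    threshold_mg: float = 100.0) -> BehaviourSequence:
    """Sub-classify non-sedentary epochs as LIPA or MVPA at the threshold.

    Sleep and sedentary pass through; the threshold is applied to epoch mean
    ENMO only where the smoothed 3-class label is non-sedentary.
    """
    sequence = np.asarray(sequence, dtype=object)
    if len(sequence) != epochs.n_epochs:
        raise ValueError("sequence and epoch grid lengths differ")
    out = sequence.copy()
    ns = sequence == "non-sedentary"
    enmo = epochs.enmo_mean
    out[ns & (enmo >= threshold_mg)] = "MVPA"
    out[ns & ~(enmo >= threshold_mg)] = "LIPA"
    return BehaviourSequence(labels=out)


def train(train_set: LabelledEpochSet, n_trees: int = 100, seed: int = 0,
          intensity_threshold: float = 100.0,
          smoothing: float = 1.0) -> BehaviourModel:
    """Full training chain: balanced forest, then HMM from OOB predictions."""
    forest = train_forest(train_set, n_trees=n_trees, seed=seed)
    hmm = estimate_hmm(train_set, forest.oob_prediction_, smoothing=smoothing)
    return BehaviourModel(forest=forest, hmm=hmm,
                          intensity_threshold=intensity_threshold, seed=seed)


def predict(epochs: EpochSeries, model: BehaviourModel) -> BehaviourSequence:
    """Forest prediction, Viterbi smoothing, then the intensity split.

    Missing epochs carry the ``"missing"`` label for the wear module;
    Viterbi runs independently over each contiguous observed run.
    """
    if not model.forest.fitted:
        raise NotTrainedError("model forest is untrained")
    n = epochs.n_epochs
    labels3 = np.full(n, MISSING_LABEL, dtype=object)
    if n == 0:
        return BehaviourSequence(labels=labels3)
    observed = ~epochs.missing
    if epochs.features is not None:
        observed &= ~np.isnan(epochs.features).any(axis=1)
    if observed.any():
        raw = model.forest.predict(epochs.features[observed])
        filled = np.full(n, None, dtype=object)
        filled[observed] = raw
        o = np.concatenate(([0], observed.view(np.int8), [0]))
        for i0, i1 in np.flatnonzero(np.diff(o)).reshape(-1, 2):
            labels3[i0:i1] = viterbi(filled[i0:i1].astype("U32"), model.hmm)
    seq = split_intensity_masked(labels3, epochs, model.intensity_threshold)
    return seq


def split_intensity_masked(labels3: np.ndarray, epochs: EpochSeries,
                           threshold_mg: float) -> BehaviourSequence:
    out = np.asarray(labels3, dtype=object).copy()
    ns = out == "non-sedentary"
    out[ns & (epochs.enmo_mean >= threshold_mg)] = "MVPA"
    out[ns & ~(epochs.enmo_mean >= threshold_mg)] = "LIPA"
    return BehaviourSequence(labels=out)


def confusion_matrix(pred: BehaviourSequence, truth: np.ndarray,
                     epoch_s: float = 30.0) -> pd.DataFrame:
    """4x4 confusion counts (true rows, predicted columns) with marginals.

    Epochs whose truth or prediction is outside the four behaviours
    (missing, non-wear) are excluded.  A companion minute-valued table is
    attached as ``.attrs["minutes"]``.
    """
    truth = np.asarray(truth, dtype=object)
    p = np.asarray(pred.labels, dtype=object)
    keep = np.isin(truth, BEHAVIOURS) & np.isin(p, BEHAVIOURS)
    counts = pd.DataFrame(0, index=list(BEHAVIOURS), columns=list(BEHAVIOURS))
    for t, q in zip(truth[keep], p[keep]):
        counts.loc[t, q] += 1
    counts["total"] = counts.sum(axis=1)
    counts.loc["total"] = counts.sum(axis=0)
    counts.attrs["minutes"] = counts * (epoch_s / 60.0)
    return counts


def accuracy(pred: BehaviourSequence, truth: np.ndarray) -> float:
    """Epoch-level 4-class accuracy over jointly classified epochs."""
    truth = np.asarray(truth, dtype=object)
    p = np.asarray(pred.labels, dtype=object)
    keep = np.isin(truth, BEHAVIOURS) & (p != MISSING_LABEL)
    if not keep.any():
        return np.nan
    return float(np.mean(p[keep] == truth[keep]))
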