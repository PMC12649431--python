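"""Tabular Q-learning over discretised CNN feature states.

The agent's state is a 64-bit sign pattern of the CNN embedding against
per-feature medians of the training set; actions are class labels.  Each
training episode streams ``max_steps`` seeded image samples: the agent
picks an action epsilon-greedily, earns +1 for a correct prediction and
-1 otherwise, and applies the Bellman update

    Q(s,a) <- Q(s,a) + alpha * [r + gamma * max_a' Q(s',a') - Q(s,a)]

with s' the state of the next sampled image and a zero bootstrap term at
the episode's final (terminal) step.  Prediction is the greedy argmax of
the learned table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .metrics import ClassificationReport, classification_report

__all__ = [
    "StateEncoder",
    "QTable",
    "QConfig",
    "EpisodeLog",
    "fit_state_encoder",
    "select_action",
    "compute_reward",
    "q_update",
    "train_agent",
    "predict",
    "evaluate_agent",
    "save_qtable",
    "load_qtable",
    "QLearningClassifier",
]


class StateEncoder:
    """Deterministic discretisation of feature vectors into table keys.

    Thresholds are the per-feature medians of the training features; a
    vector encodes to the bit pattern (feature > threshold), serialised
    as a hex string.  Identical vectors always map to the same key and
    any vector encodes to some key.
    """

    def __init__(self, thresholds: np.ndarray):
        self.thresholds = np.asarray(thresholds, dtype=np.float64)

    @classmethod
    def fit(cls, features) -> "StateEncoder":
        feats = np.asarray(features, dtype=np.float64)
        if feats.ndim != 2 or len(feats) < 2:
            raise ValueError("need at least 2 feature vectors to fit the encoder")
        return cls(np.median(feats, axis=0))

    def encode(self, f) -> str:
        f = np.asarray(f, dtype=np.float64)
        if f.shape != self.thresholds.shape:
            raise ValueError(f"feature dim {f.shape} != encoder dim {self.thresholds.shape}")
        bits = f > self.thresholds
        key = 0
        for b in bits:
            key = (key << 1) | int(b)
        return format(key, "x")

    def encode_many(self, feats) -> list[str]:
        return [self.encode(f) for f in np.asarray(feats, dtype=np.float64)]


def fit_state_encoder(features) -> StateEncoder:
    """Median-threshold encoder fitted on training feature vectors."""
    return StateEncoder.fit(features)


class QTable:
    """Map (state key, action) -> Q-value; unseen pairs read exactly 0.0."""

    def __init__(self, num_actions: int):
        if num_actions < 1:
            raise ValueError("num_actions must be >= 1")
        self.num_actions = num_actions
        self.table: dict[str, np.ndarray] = {}

    def row(self, state: str) -> np.ndarray:
        r = self.table.get(state)
        return r if r is not None else np.zeros(self.num_actions)

    def get(self, state: str, action: int) -> float:
        return float(self.row(state)[action])

    def set(self, state: str, action: int, value: float) -> None:
        if not np.isfinite(value):
            raise ValueError("Q-values must be finite")
        if state not in self.table:
            self.table[state] = np.zeros(self.num_actions)
        self.table[state][action] = value

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class QConfig:
    alpha: float = 0.1
    gamma: float = 0.6
    epsilon: float = 0.1
    episodes: int = 1000
    max_steps: int = 100
    seed: int = 0
    reward_correct: int = 1
    reward_incorrect: int = -1
    sample_with_replacement: bool = True

    def validate(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        if self.episodes < 0 or self.max_steps < 1:
            raise ValueError("episodes must be >= 0 and max_steps >= 1")
        if (self.reward_correct, self.reward_incorrect) != (1, -1):
            raise ValueError("rewards are fixed at +1 (correct) and -1 (incorrect)")


@dataclass
class EpisodeLog:
    episode_index: int
    total_reward: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)


def select_action(q: QTable, state: str, epsilon: float,
                  rng: np.random.Generator) -> int:
    """Epsilon-greedy action: uniform with probability epsilon, else the
    greedy argmax with ties broken toward the lowest action index."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    if rng.random() < epsilon:
        return int(rng.integers(q.num_actions))
    return int(np.argmax(q.row(state)))


def compute_reward(predicted: int, truth: int) -> int:
    """+1 for a correct class prediction, -1 otherwise."""
    return 1 if predicted == truth else -1


def q_update(q: QTable, s: str, a: int, r: float, s_next: str | None,
             terminal: bool, alpha: float, gamma: float) -> float:
    """One Bellman update; returns and stores the new Q(s, a)."""
    if not (np.isfinite(r) and np.isfinite(alpha) and np.isfinite(gamma)):
        raise ValueError("non-finite update inputs")
    bootstrap = 0.0 if terminal else gamma * float(q.row(s_next).max())
    new = q.get(s, a) + alpha * (r + bootstrap - q.get(s, a))
    q.set(s, a, new)
    return new


def train_agent(features_train, cfg: QConfig,
                encoder: StateEncoder) -> tuple[QTable, list[EpisodeLog]]:
    """Run epsilon-greedy Q-learning over episode streams of images.

    ``features_train`` is a list of (feature vector, label) pairs or a
    tuple (F, y).  Sampling within an episode is with replacement by
    default (mandatory when the set is smaller than ``max_steps``).
    """
    cfg.validate()
    if isinstance(features_train, tuple):
        feats, labels = features_train
    else:
        feats = [f for f, _ in features_train]
        labels = [lab for _, lab in features_train]
    feats = np.asarray(feats, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if len(feats) == 0:
        raise ValueError("empty training set")
    num_actions = int(labels.max()) + 1
    keys = encoder.encode_many(feats)
    q = QTable(num_actions)
    rng = np.random.default_rng(cfg.seed)
    logs: list[EpisodeLog] = []
    n = len(feats)
    replace = cfg.sample_with_replacement or n < cfg.max_steps
    for ep in range(cfg.episodes):
        idx = rng.choice(n, size=cfg.max_steps, replace=replace)
        states = [keys[i] for i in idx]
        log = EpisodeLog(episode_index=ep, total_reward=0)
        for t in range(cfg.max_steps):
            s = states[t]
            a = select_action(q, s, cfg.epsilon, rng)
            r = compute_reward(a, int(labels[idx[t]]))
            terminal = t == cfg.max_steps - 1
            s_next = None if terminal else states[t + 1]
            q_update(q, s, a, r, s_next, terminal, cfg.alpha, cfg.gamma)
            log.steps.append((s, a, r))
            log.total_reward += r
        logs.append(log)
    return q, logs


def predict(q: QTable, encoder: StateEncoder, f) -> int:
    """Greedy argmax prediction; an unseen state reads an all-zero row and
    therefore falls back to action 0."""
    return int(np.argmax(q.row(encoder.encode(f))))


def evaluate_agent(q: QTable, encoder: StateEncoder,
                   features_test) -> tuple[float, np.ndarray, ClassificationReport]:
    """Greedy evaluation: (accuracy %, confusion matrix, full report).

    Also warns with the unseen-state rate when test images map to states
    the table never visited (those fall back to action 0).
    """
    if isinstance(features_test, tuple):
        feats, labels = features_test
    else:
        feats = [f for f, _ in features_test]
        labels = [lab for _, lab in features_test]
    feats = np.asarray(feats, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if len(feats) == 0:
        raise ValueError("empty test set")
    keys = encoder.encode_many(feats)
    unseen = sum(k not in q.table for k in keys)
    if unseen:
        warnings.warn(f"{unseen}/{len(keys)} test images map to unseen states "
                      "(predicted as class 0)", stacklevel=2)
    preds = np.array([int(np.argmax(q.row(k))) for k in keys])
    report = classification_report(labels, preds, q.num_actions)
    return report.overall_accuracy, report.confusion, report


def save_qtable(q: QTable, encoder: StateEncoder, cfg: QConfig, path) -> None:
    """Persist the table as JSON: config header, encoder thresholds, rows."""
    payload = {
        "config": cfg.__dict__,
        "num_actions": q.num_actions,
        "thresholds": encoder.thresholds.tolist(),
        "table": {k: v.tolist() for k, v in q.table.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_qtable(path) -> tuple[QTable, StateEncoder, QConfig]:
    with open(path) as fh:
        payload = json.load(fh)
    q = QTable(payload["num_actions"])
    for k, v in payload["table"].items():
        q.table[k] = np.asarray(v, dtype=np.float64)
    return q, StateEncoder(np.asarray(payload["thresholds"])), QConfig(**payload["config"])


class QLearningClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn classifier wrapping the state encoder + tabular Q-agent.

    ``fit(F, y)`` expects feature vectors (typically the frozen CNN
    embeddings from :class:`~gastroql.features.CNNFeatureExtractor`, so the
    two compose in a Pipeline).  Defaults follow the reference protocol:
    alpha=0.1, gamma=0.6, epsilon=0.1, 1000 episodes of 100 steps.

    Fitted attributes: ``encoder_``, ``q_table_``, ``episode_logs_``,
    ``classes_``.
    """

    def __init__(self, alpha: float = 0.1, gamma: float = 0.6,
                 epsilon: float = 0.1, episodes: int = 1000,
                 max_steps: int = 100, sample_with_replacement: bool = True,
                 random_state: int = 0):
        self.alpha = alpha
        self.gamma = gamma
        self.epsilon = epsilon
        self.episodes = episodes
        self.max_steps = max_steps
        self.sample_with_replacement = sample_with_replacement
        self.random_state = random_state

    def _config(self) -> QConfig:
        return QConfig(alpha=self.alpha, gamma=self.gamma, epsilon=self.epsilon,
                       episodes=self.episodes, max_steps=self.max_steps,
                       sample_with_replacement=self.sample_with_replacement,
                       seed=self.random_state)

    def fit(self, F, y):
        F = np.asarray(F, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        actions = np.searchsorted(self.classes_, y)
        self.encoder_ = fit_state_encoder(F)
        self.q_table_, self.episode_logs_ = train_agent(
            (F, actions), self._config(), self.encoder_)
        # the table indexes all classes even if late ones never won an episode
        self.q_table_.num_actions = max(self.q_table_.num_actions, len(self.classes_))
        return self

    def predict(self, F) -> np.ndarray:
        check_is_fitted(self, "q_table_")
        F = np.asarray(F, dtype=np.float64)
        actions = [predict(self.q_table_, self.encoder_, f) for f in F]
        return self.classes_[np.asarray(actions, dtype=np.int64)]

    def reward_curve(self) -> np.ndarray:
        """(episodes, 2) array of episode index and total reward."""
        check_is_fitted(self, "episode_logs_")
        return np.array([[log.episode_index, log.total_reward]
                         for log in self.episode_logs_])
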