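"""Model training, grid search and threshold selection.

Training runs Adam on minibatches of the L2-penalised binary cross-entropy,
with spatial dropout on the embedding and batch-norm statistics updated in
training mode only. Model selection is AUPR-driven: after every epoch the
validation AUPR is measured in inference mode and the parameter snapshot from
the best epoch is returned. The learning rate is held fixed during grid
search; grid points are compared by validation AUPR with ties broken by
smaller parameter count, then enumeration order.

The classification threshold is chosen by the equal-error-rate (EER) rule:
theta minimising |1 - recall| + gamma * |1 - precision| over all achievable
thresholds, with gamma (default 2) weighting precision errors. A literal
mode with a minus sign between the two terms is retained behind a flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .encoding import DEFAULT_VOCABULARY, Vocabulary, encode_sequence
from .evaluation import aupr, auc
from .fingerprints import featurize_table
from .io_data import InteractionDataset
from .nn.layers import Adam
from .nn.model import DTIModel, ModelConfig, ModelState


@dataclass
class TrainingHistory:
    train_loss: list[float]
    val_aupr: list[float]
    val_auc: list[float]

    @property
    def best_epoch(self) -> int:
        """0-based index of the epoch with the highest validation AUPR."""
        if not self.val_aupr:
            raise ValueError("empty history has no best epoch")
        return int(np.argmax(self.val_aupr))


@dataclass
class GridSearchResult:
    configs: list[ModelConfig]
    val_auprs: list[float]
    best_index: int

    @property
    def best_config(self) -> ModelConfig:
        return self.configs[self.best_index]


def encode_dataset(
    dataset: InteractionDataset,
    config: ModelConfig,
    vocabulary: Vocabulary = DEFAULT_VOCABULARY,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorise an interaction dataset into network inputs.

    Returns (labels (N, MPL), true lengths (N,), fingerprints (N, bits),
    interaction labels (N,)), rows aligned with ``dataset.pairs``.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    encoded = {
        pid: encode_sequence(rec.sequence, vocabulary, config.mpl, protein_id=pid)
        for pid, rec in dataset.proteins.items()
    }
    drug_ids = sorted(dataset.drugs)
    fps = featurize_table([dataset.drugs[d] for d in drug_ids],
                          n_bits=config.fingerprint_bits)
    fp_row = {d: i for i, d in enumerate(drug_ids)}
    n = len(dataset)
    labels = np.zeros((n, config.mpl), dtype=np.int64)
    lengths = np.zeros(n, dtype=np.int64)
    fmat = np.zeros((n, config.fingerprint_bits), dtype=np.float64)
    y = np.zeros(n, dtype=np.int64)
    for i, (d, p, lab) in enumerate(dataset.pairs):
        labels[i] = encoded[p].labels
        lengths[i] = encoded[p].true_length
        fmat[i] = fps[fp_row[d]]
        y[i] = lab
    return labels, lengths, fmat, y


def train(
    config: ModelConfig,
    train_set: InteractionDataset,
    val_set: InteractionDataset,
    seed: int,
    vocabulary: Vocabulary = DEFAULT_VOCABULARY,
) -> tuple[ModelState, TrainingHistory]:
    """Train a model and return the best-validation-AUPR parameter snapshot.

    Fully reproducible from ``seed`` (weight init, minibatch order, dropout).
    Raises if either dataset is empty or the validation set is single-class
    (AUPR undefined).
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if len(set(int(y) for _, _, y in val_set.pairs)) < 2:
        raise ValueError("validation set must contain both classes (AUPR undefined)")
    overlap = set((d, p) for d, p, _ in train_set.pairs) & \
        set((d, p) for d, p, _ in val_set.pairs)
    if overlap:
        raise ValueError(f"validation pairs overlap training pairs: {sorted(overlap)[:3]}")

    config = replace(config, seed=seed)
    model = DTIModel(config, vocabulary)
    xl, xn, xf, y = encode_dataset(train_set, config, vocabulary)
    vl, vn, vf, vy = encode_dataset(val_set, config, vocabulary)
    rng = np.random.default_rng([seed, 1])
    optimizer = Adam(model.params(), lr=config.learning_rate)
    history = TrainingHistory([], [], [])
    best_state = model.get_state()
    best_aupr = -np.inf
    n = len(y)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            out = model.forward_batch(xl[idx], xn[idx], xf[idx],
                                      training=True, rng=rng)
            probs = out["probability"]
            epoch_losses.append(model.penalized_loss(probs, y[idx]))
            optimizer.zero_grad()
            model.backward_batch((probs - y[idx]) / len(idx))
            model.add_l2_gradients()
            optimizer.step()
        val_probs = model.predict(vl, vn, vf)
        ep_aupr = aupr(val_probs, vy)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_aupr.append(ep_aupr)
        history.val_auc.append(auc(val_probs, vy))
        if ep_aupr > best_aupr:
            best_aupr = ep_aupr
            best_state = model.get_state()
    return best_state, history


def grid_search(
    space: dict[str, list],
    train_set: InteractionDataset,
    val_set: InteractionDataset,
    seed: int,
    base_config: ModelConfig | None = None,
    vocabulary: Vocabulary = DEFAULT_VOCABULARY,
) -> GridSearchResult:
    """Exhaustive hyperparameter search selected by validation AUPR.

    ``space`` maps ModelConfig field names to candidate value lists; one model
    is trained per Cartesian-product point (learning rate stays fixed at the
    base config's value). Ties break to the smaller parameter count, then to
    enumeration order.
    """
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("grid-search space must be non-empty")
    if "learning_rate" in space:
        raise ValueError("learning rate is held fixed during grid search")
    base = base_config or ModelConfig()
    names = list(space)
    configs, scores = [], []
    for values in itertools.product(*(space[k] for k in names)):
        cfg = replace(base, **dict(zip(names, values)))
        _state, history = train(cfg, train_set, val_set, seed, vocabulary)
        configs.append(cfg)
        scores.append(history.val_aupr[history.best_epoch] if history.val_aupr else 0.0)
    best = 0
    for i in range(1, len(configs)):
        if scores[i] > scores[best] or (
            scores[i] == scores[best]
            and configs[i].parameter_count() < configs[best].parameter_count()
        ):
            best = i
    return GridSearchResult(configs, scores, best)


def eer_candidates(scores: np.ndarray) -> np.ndarray:
    """Candidate thresholds: the unique scores plus midpoints between
    consecutive unique scores, ascending."""
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.unique(np.concatenate([uniq, mids]))


def select_threshold_eer(
    scores, labels, gamma: float = 2.0, *, literal: bool = False
) -> float:
    """Pick the classification threshold by the equal-error-rate cost.

    cost(theta) = |1 - recall(theta)| + gamma * |1 - precision(theta)|, with a
    score >= theta positive call; the smallest theta attaining the minimum is
    returned. ``literal=True`` uses a minus sign between the two terms
    instead (a degenerate variant kept for completeness).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    if len(set(labels.tolist())) < 2:
        raise ValueError("EER threshold needs both classes present")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    p_total = int(labels.sum())
    best_theta, best_cost = None, np.inf
    for theta in eer_candidates(scores):
        calls = scores >= theta
        tp = int(np.sum(calls & (labels == 1)))
        fp = int(np.sum(calls & (labels == 0)))
        recall = tp / p_total
        precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        if literal:
            cost = abs(1 - recall) - gamma * abs(1 - precision)
        else:
            cost = abs(1 - recall) + gamma * abs(1 - precision)
        if cost < best_cost - 1e-15:
            best_cost, best_theta = cost, float(theta)
    return best_theta
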