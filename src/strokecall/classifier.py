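"""Ensemble of five MLPs with fold-rotated early stopping and grid search.

Each ensemble member early-stops on one training fold (monitoring F1 at
threshold 0.5) while training on the remaining folds plus, optionally, the
supplementary emergency-line data; member *k* stops on fold *k*, so the five
members see pairwise different training/stopping splits.  A configurable
hyperparameter grid is searched by validation F1 of the calibrated ensemble.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse

from . import calibration
from .mlp import DenseNet, sigmoid

__all__ = [
    "MLPConfig",
    "TrainedMember",
    "EnsembleModel",
    "GridSearchResult",
    "train_member",
    "train_ensemble",
    "grid_search",
    "default_demo_grid",
]


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters of one ensemble member.

    The published study does not disclose its architecture or grid; these
    defaults are a deliberately small network suited to the synthetic scale
    and are fully overridable.
    """

    hidden_sizes: tuple[int, ...] = (32,)
    activation: str = "relu"
    dropout: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 20
    patience: int = 5
    l2: float = 1e-5
    seed: int = 0
    pos_weight: Optional[float] = None

    def __post_init__(self):
        if self.activation != "relu":
            raise ValueError("only 'relu' activation is supported")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d

    @classmethod
    def from_dict(cls, d) -> "MLPConfig":
        d = dict(d)
        d["hidden_sizes"] = tuple(d.get("hidden_sizes", (32,)))
        return cls(**d)


def _f1_at_half(net: DenseNet, X, y: np.ndarray) -> float:
    pred = net.logits(X) >= 0.0  # score >= 0.5
    tp = int(np.sum(pred & (y > 0.5)))
    fp = int(np.sum(pred & (y <= 0.5)))
    fn = int(np.sum(~pred & (y > 0.5)))
    denom = 2 * tp + fp + fn
    return 2.0 * tp / denom if denom else 0.0


@dataclass
class TrainedMember:
    net: DenseNet
    config: MLPConfig
    best_stop_f1: float
    stop_f1_trajectory: list[float]
    n_epochs: int

    def logits(self, X) -> np.ndarray:
        return self.net.logits(X)

    def scores(self, X) -> np.ndarray:
        return sigmoid(self.net.logits(X))


def train_member(
    train_X,
    train_y: np.ndarray,
    stop_X,
    stop_y: np.ndarray,
    config: MLPConfig,
    extra: Optional[tuple] = None,
) -> TrainedMember:
    """Train one member with early stopping on the held-out stop fold.

    Training halts once the stop-fold F1 (at threshold 0.5) has failed to
    improve for ``config.patience`` consecutive epoch-end evaluations; the
    best-F1 checkpoint is returned.  Deterministic given the config seed.
    """
    if extra is not None:
        train_X = sparse.vstack([sparse.csr_matrix(train_X), sparse.csr_matrix(extra[0])], format="csr")
        train_y = np.concatenate([train_y, extra[1]])
    train_y = np.asarray(train_y, dtype=np.float64)
    stop_y = np.asarray(stop_y, dtype=np.float64)
    if len(np.unique(train_y)) < 2:
        raise ValueError("degenerate training data: only one class present")

    net = DenseNet(
        n_features=train_X.shape[1],
        hidden_sizes=tuple(config.hidden_sizes),
        dropout=config.dropout,
        l2=config.l2,
        seed=config.seed,
    )
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]).generate_state(1)[0])

    best_f1 = -np.inf
    best_params = net.get_params()
    best_epoch = 0
    since_improve = 0
    trajectory: list[float] = []
    n = train_X.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            net.train_step(train_X[idx], train_y[idx], config.learning_rate, config.pos_weight)
        f1 = _f1_at_half(net, stop_X, stop_y)
        trajectory.append(f1)
        if f1 > best_f1:
            best_f1, best_params, best_epoch = f1, net.get_params(), epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break
    net.set_params(best_params)
    return TrainedMember(
        net=net,
        config=config,
        best_stop_f1=float(max(best_f1, 0.0)),
        stop_f1_trajectory=trajectory,
        n_epochs=best_epoch,
    )


@dataclass
class EnsembleModel:
    """Five independently trained members; member k early-stopped on fold k."""

    members: list[TrainedMember]
    member_configs: list[MLPConfig]
    fold_assignment: list[int]

    @property
    def N(self) -> int:
        return len(self.members)

    def member_logits(self, X) -> np.ndarray:
        """Logit matrix of shape (N, n_documents)."""
        return np.stack([m.logits(X) for m in self.members])

    def member_scores(self, X) -> np.ndarray:
        return sigmoid(self.member_logits(X))


def _member_seed(base_seed: int, k: int) -> int:
    return int(np.random.SeedSequence([base_seed, 7919, k]).generate_state(1)[0] % (2**31))


def train_ensemble(
    folds: Sequence[tuple],
    extra: Optional[tuple],
    config: MLPConfig,
) -> EnsembleModel:
    """Train one ensemble from fold datasets ``[(X_1, y_1), ...]``.

    Member k uses fold k for early stopping and the remaining folds (plus
    ``extra``, when given) for training; members differ only in fold rotation
    and seed.
    """
    members = []
    configs = []
    for k, (stop_X, stop_y) in enumerate(folds):
        train_parts = [folds[j] for j in range(len(folds)) if j != k]
        train_X = sparse.vstack([sparse.csr_matrix(p[0]) for p in train_parts], format="csr")
        train_y = np.concatenate([p[1] for p in train_parts])
        member_config = dataclasses.replace(config, seed=_member_seed(config.seed, k))
        members.append(train_member(train_X, train_y, stop_X, stop_y, member_config, extra=extra))
        configs.append(member_config)
    return EnsembleModel(members=members, member_configs=configs, fold_assignment=list(range(len(folds))))


@dataclass
class GridSearchResult:
    best_ensemble: EnsembleModel
    best_config: MLPConfig
    best_thresholds: "calibration.ThresholdSet"
    best_f1: float
    table: list[dict]  # one row per grid point: config + validation F1


def grid_search(
    grid: Sequence[MLPConfig],
    folds: Sequence[tuple],
    extra: Optional[tuple],
    val_X,
    val_y: np.ndarray,
    reference_sensitivity: float,
    reference_ppv: float,
) -> GridSearchResult:
    """Select the grid configuration maximising calibrated-ensemble validation F1.

    Each candidate ensemble is threshold-calibrated on the validation set and
    scored by the F1 of its decisions at the centred threshold 0.5; ties are
    broken by earliest grid order.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    best = None
    table = []
    for position, cfg in enumerate(grid):
        ensemble = train_ensemble(folds, extra, cfg)
        thresholds = calibration.ThresholdSet.calibrate(
            ensemble.member_scores(val_X), val_y, reference_sensitivity, reference_ppv
        )
        score = calibration.ensemble_score(ensemble.member_logits(val_X), thresholds)
        pred = score.predictions
        tp = int(np.sum(pred & (val_y > 0.5)))
        fp = int(np.sum(pred & (val_y <= 0.5)))
        fn = int(np.sum(~pred & (val_y > 0.5)))
        denom = 2 * tp + fp + fn
        f1 = 2.0 * tp / denom if denom else 0.0
        table.append({"config": cfg.to_dict(), "validation_f1": f1})
        if best is None or f1 > best[0]:
            best = (f1, position, ensemble, cfg, thresholds)
    f1, _, ensemble, cfg, thresholds = best
    return GridSearchResult(
        best_ensemble=ensemble, best_config=cfg, best_thresholds=thresholds, best_f1=f1, table=table
    )


def default_demo_grid(base_seed: int = 0) -> list[MLPConfig]:
    """A small 8-point demonstration grid (the study's 96-point grid is not
    public); arbitrary grids can be supplied instead."""
    grid = []
    for hidden in ((32,), (64, 32)):
        for lr in (1e-3, 3e-3):
            for dropout in (0.0, 0.3):
                grid.append(
                    MLPConfig(hidden_sizes=hidden, learning_rate=lr, dropout=dropout, seed=base_seed)
                )
    return grid
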