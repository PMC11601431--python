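"""Graph-attention pKa-shift regressor, ensemble, and pretrain/fine-tune.

One combined model serves acids and bases — the acid/base character of the
central residue is a node feature, and sharing the trunk lets scarce
residue types (Cys, Tyr) borrow statistical strength.  Predictions are
pKa shifts; adding the residue type's solution pKa recovers the absolute
value.  The ensemble averages members trained on distinct train:validation
(9:1) splits of the same training graphs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ..features import model_pka
from . import nn
from .graph import ResidueGraph

__all__ = ["GATConfig", "GATRegressor", "GATEnsemble", "train_gat",
           "train_ensemble", "predict_ensemble", "pretrain_finetune",
           "save_gat", "load_gat"]


@dataclass
class GATConfig:
    """Architecture/optimization preset.

    The default values are the reference preset: 3 single-head attention
    convolutions with 42 channels, global average pooling, a 32/16 MLP head
    with dropout 0.2, Adam at 1e-3 with early stopping (patience 20).
    """

    conv_layers: int = 3
    heads: int = 1
    channels: int = 42
    hidden: tuple[int, ...] = (32, 16)
    dropout: float = 0.2
    lr: float = 1e-3
    epochs: int = 200
    patience: int = 20
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.heads != 1:
            raise ValueError("only single-head attention is supported")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


def _labels_of(graphs, y=None) -> np.ndarray:
    if y is not None:
        y = np.asarray(y, dtype=float)
    else:
        labels = [g.label for g in graphs]
        if any(lab is None for lab in labels):
            raise ValueError("unlabeled graph(s); pass y explicitly")
        y = np.array(labels, dtype=float)
    if len(y) != len(graphs):
        raise ValueError("label/graph length mismatch")
    if not np.all(np.isfinite(y)):
        raise ValueError("labels must be finite")
    return y


def _check_width(graphs, expected: int | None = None) -> int:
    widths = {g.node_features.shape[1] for g in graphs}
    if len(widths) != 1:
        raise ValueError(f"inconsistent node feature widths: {sorted(widths)}")
    width = widths.pop()
    if expected is not None and width != expected:
        raise ValueError(f"node feature width {width} does not match "
                         f"model width {expected}")
    return width


class GATRegressor(RegressorMixin, BaseEstimator):
    """Numpy graph-attention network regressing per-graph pKa shifts.

    Minimizes MSE with full-batch Adam; when ``val_fraction > 0`` a
    held-out slice of the training graphs drives early stopping (the
    parameters with the best validation loss are restored).  Training is
    bit-reproducible given ``random_state``; conv layers ``0..frozen_layers-1``
    are excluded from updates (for fine-tuning a pretrained trunk).
    """

    def __init__(self, conv_layers: int = 3, channels: int = 42,
                 hidden: tuple[int, ...] = (32, 16), dropout: float = 0.2,
                 lr: float = 1e-3, epochs: int = 200, patience: int = 20,
                 val_fraction: float = 0.1, frozen_layers: int = 0,
                 warm_start_params: dict | None = None, random_state: int = 0):
        self.conv_layers = conv_layers
        self.channels = channels
        self.hidden = hidden
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.frozen_layers = frozen_layers
        self.warm_start_params = warm_start_params
        self.random_state = random_state

    # sklearn's tag machinery is bypassed: X is a list of graphs
    def fit(self, graphs: list[ResidueGraph], y=None):
        if len(graphs) < 1:
            raise ValueError("no graphs to fit")
        if not 0 <= self.frozen_layers <= 2:
            raise ValueError("frozen_layers must be 0, 1 or 2")
        y = _labels_of(graphs, y)
        width = _check_width(graphs)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.random_state), 11]))
        if self.warm_start_params is not None:
            self.params_ = copy.deepcopy(self.warm_start_params)
            _ = _check_width(graphs, self.params_["conv0_W"].shape[0])
        else:
            self.params_ = nn.init_params(width, self.channels,
                                          self.conv_layers, tuple(self.hidden),
                                          rng)
        self.node_dim_ = width
        frozen = frozenset(
            name for layer in range(self.frozen_layers)
            for name in nn.conv_layer_names(layer))
        n = len(graphs)
        use_val = (self.val_fraction > 0 and self.patience is not None
                   and n >= 5)
        order = rng.permutation(n)
        if use_val:
            n_val = max(1, int(round(self.val_fraction * n)))
            val_idx, train_idx = order[:n_val], order[n_val:]
        else:
            val_idx, train_idx = np.array([], dtype=int), order
        self.train_indices_ = np.sort(train_idx)
        self.val_indices_ = np.sort(val_idx)
        train_batch = nn.assemble_batch([graphs[i] for i in train_idx])
        y_train = y[train_idx]
        if use_val:
            val_batch = nn.assemble_batch([graphs[i] for i in val_idx])
            y_val = y[val_idx]
        opt = nn.Adam(self.params_, lr=self.lr, frozen=frozen)
        best = copy.deepcopy(self.params_)
        best_val = np.inf
        stall = 0
        history = []
        for epoch in range(self.epochs):
            pred, cache = nn.forward(self.params_, train_batch,
                                     dropout=self.dropout, rng=rng,
                                     training=True)
            loss, dpred = nn.mse_loss_grad(pred, y_train)
            grads = nn.backward(self.params_, cache, dpred)
            opt.step(self.params_, grads)
            entry = {"epoch": epoch, "train_mse": loss}
            if use_val:
                vp, _ = nn.forward(self.params_, val_batch)
                vloss = float(np.mean((vp - y_val) ** 2))
                entry["val_mse"] = vloss
                if vloss < best_val - 1e-12:
                    best_val = vloss
                    best = copy.deepcopy(self.params_)
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        history.append(entry)
                        break
            history.append(entry)
        if use_val and self.epochs > 0:
            self.params_ = best
            self.best_val_mse_ = best_val
        self.history_ = history
        return self

    def predict(self, graphs: list[ResidueGraph]) -> np.ndarray:
        """Predicted pKa shifts (no dropout)."""
        if not hasattr(self, "params_"):
            raise ValueError("model is not fitted")
        if len(graphs) == 0:
            return np.empty(0)
        _check_width(graphs, self.params_["conv0_W"].shape[0])
        batch = nn.assemble_batch(graphs)
        pred, _ = nn.forward(self.params_, batch)
        return pred

    def predict_pka(self, graphs: list[ResidueGraph]) -> np.ndarray:
        shifts = self.predict(graphs)
        return shifts + np.array([model_pka(g.aa) for g in graphs])

    def training_mse(self, graphs: list[ResidueGraph], y=None) -> float:
        y = _labels_of(graphs, y)
        return float(np.mean((self.predict(graphs) - y) ** 2))


class GATEnsemble:
    """k attention networks on k distinct 9:1 train:validation splits."""

    def __init__(self, k: int = 10, config: GATConfig = GATConfig(),
                 random_state: int = 0):
        if k < 1:
            raise ValueError("ensemble needs k >= 1")
        self.k = k
        self.config = config
        self.random_state = random_state

    def fit(self, graphs: list[ResidueGraph], y=None):
        _check_width(graphs)
        seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                 np.random.SeedSequence(self.random_state).spawn(self.k)]
        self.members_ = []
        for seed in seeds:
            member = GATRegressor(
                conv_layers=self.config.conv_layers,
                channels=self.config.channels, hidden=self.config.hidden,
                dropout=self.config.dropout, lr=self.config.lr,
                epochs=self.config.epochs, patience=self.config.patience,
                val_fraction=self.config.val_fraction, random_state=seed)
            member.fit(graphs, y)
            self.members_.append(member)
        return self

    def predict(self, graphs: list[ResidueGraph]) -> np.ndarray:
        """Mean predicted shift over members."""
        if not getattr(self, "members_", None):
            raise ValueError("ensemble has no trained members")
        return np.mean([m.predict(graphs) for m in self.members_], axis=0)

    def predict_pka(self, graphs: list[ResidueGraph]) -> np.ndarray:
        shifts = self.predict(graphs)
        return shifts + np.array([model_pka(g.aa) for g in graphs])


def train_gat(graphs, config: GATConfig = GATConfig(),
              seed: int = 0) -> GATRegressor:
    if len(graphs) < 20:
        raise ValueError(f"need >= 20 graphs, got {len(graphs)}")
    model = GATRegressor(conv_layers=config.conv_layers,
                         channels=config.channels, hidden=config.hidden,
                         dropout=config.dropout, lr=config.lr,
                         epochs=config.epochs, patience=config.patience,
                         val_fraction=config.val_fraction, random_state=seed)
    return model.fit(graphs)


def train_ensemble(graphs, k: int = 10, config: GATConfig = GATConfig(),
                   seed: int = 0) -> GATEnsemble:
    return GATEnsemble(k=k, config=config, random_state=seed).fit(graphs)


def predict_ensemble(ensemble: GATEnsemble | GATRegressor,
                     graphs) -> np.ndarray:
    """Absolute pKa's: residue model pKa plus (mean) predicted shift."""
    single = isinstance(graphs, ResidueGraph)
    batch = [graphs] if single else list(graphs)
    out = ensemble.predict_pka(batch)
    return float(out[0]) if single else out


def save_gat(model: GATRegressor, directory) -> None:
    """Checkpoint bundle: params.npz + config.json."""
    import json
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "params.npz", **model.params_)
    cfg = {k: v for k, v in model.get_params().items()
           if k != "warm_start_params"}
    cfg["hidden"] = list(cfg["hidden"])
    (directory / "config.json").write_text(json.dumps(cfg, indent=1))


def load_gat(directory) -> GATRegressor:
    import json
    from pathlib import Path
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text())
    cfg["hidden"] = tuple(cfg["hidden"])
    model = GATRegressor(**cfg)
    with np.load(directory / "params.npz") as data:
        model.params_ = {k: data[k] for k in data.files}
    model.node_dim_ = model.params_["conv0_W"].shape[0]
    return model


def pretrain_finetune(pretrain_graphs, finetune_graphs, frozen_layers: int,
                      config: GATConfig = GATConfig(), seed: int = 0,
                      pretrain_y=None, finetune_y=None,
                      finetune_epochs: int | None = None) -> GATRegressor:
    """Pretrain on theoretical labels, fine-tune on experimental ones.

    ``frozen_layers`` conv blocks (counting from the input) keep their
    pretrained weights during fine-tuning.  ``finetune_epochs=0`` returns a
    model identical to the pretrained one.
    """
    if frozen_layers not in (0, 1, 2):
        raise ValueError("frozen_layers must be 0, 1 or 2")
    pre = GATRegressor(conv_layers=config.conv_layers,
                       channels=config.channels, hidden=config.hidden,
                       dropout=config.dropout, lr=config.lr,
                       epochs=config.epochs, patience=config.patience,
                       val_fraction=config.val_fraction, random_state=seed)
    pre.fit(pretrain_graphs, pretrain_y)
    n_epochs = config.epochs if finetune_epochs is None else finetune_epochs
    fine = GATRegressor(conv_layers=config.conv_layers,
                        channels=config.channels, hidden=config.hidden,
                        dropout=config.dropout, lr=config.lr,
                        epochs=n_epochs, patience=config.patience,
                        val_fraction=config.val_fraction,
                        frozen_layers=frozen_layers,
                        warm_start_params=pre.params_,
                        random_state=seed + 1)
    if n_epochs == 0:
        fine.params_ = copy.deepcopy(pre.params_)
        fine.node_dim_ = pre.node_dim_
        fine.history_ = []
        return fine
    fine.fit(finetune_graphs, finetune_y)
    return fine
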