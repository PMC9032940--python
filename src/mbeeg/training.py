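"""Within-subject training: Adam on cross-entropy with best-checkpoint recall.

The protocol trains on one recording session and tests on another. Each
epoch the decoder's accuracy on a held-out monitor split of the training
session is recorded; at the end the weights from the epoch with the highest
monitor accuracy are restored ("best checkpoint"), not the final ones.
Monitoring the test session itself would leak information into model
selection, so the monitor split defaults to a seeded, class-stratified 20%
of the training trials; an explicit external monitor set can be supplied
instead for replication experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .config import ModelSpec, TrainConfig
from .containers import TrialDataset
from .model import MultiBranchEEGNet
from .nn.functional import cross_entropy, softmax_probabilities

__all__ = [
    "TrainingHistory",
    "train_within_subject",
    "stratified_split",
    "save_checkpoint",
    "load_checkpoint",
    "Adam",
]


@dataclass
class TrainingHistory:
    """Per-epoch curves and the best-checkpoint bookkeeping (1-based epochs)."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    monitor_accuracy: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        return int(np.argmax(self.monitor_accuracy)) + 1

    @property
    def best_monitor_accuracy(self) -> float:
        return float(np.max(self.monitor_accuracy))

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, self.n_epochs + 1),
            "train_loss": self.train_loss,
            "train_acc": self.train_accuracy,
            "monitor_acc": self.monitor_accuracy,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class Adam:
    """Adam optimizer over a model's parameter arrays."""

    def __init__(self, model: MultiBranchEEGNet, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = {}
        self._v = {}
        for lname, pname, arr in model.parameters():
            key = (lname, pname)
            self._m[key] = np.zeros_like(arr, dtype=np.float64)
            self._v[key] = np.zeros_like(arr, dtype=np.float64)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for lname, layer in self.model.layers():
            for pname, arr in layer.params.items():
                g = layer.grads.get(pname)
                if g is None:
                    continue
                key = (lname, pname)
                m = self._m[key]
                v = self._v[key]
                m += (1 - b1) * (g - m)
                v += (1 - b2) * (g.astype(np.float64) ** 2 - v)
                update = self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
                arr -= update.astype(arr.dtype)
            layer.apply_constraints()


def stratified_split(labels: np.ndarray, fraction: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Split trial indices into (main, held_out) stratified by class.

    At least one trial per class goes to the held-out part when the class
    has more than one trial.
    """
    main, held = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        k = int(round(fraction * len(idx)))
        if len(idx) > 1:
            k = min(max(k, 1), len(idx) - 1)
        else:
            k = 0
        held.append(idx[:k])
        main.append(idx[k:])
    return np.sort(np.concatenate(main)), np.sort(np.concatenate(held))


def _accuracy(model: MultiBranchEEGNet, data: TrialDataset,
              batch_size: int = 256) -> float:
    pred = model.predict_labels(data.signals, batch_size=batch_size)
    return float(np.mean(pred == data.labels))


def train_within_subject(
    train_data: TrialDataset,
    spec: ModelSpec,
    cfg: TrainConfig,
    *,
    include_se: bool = True,
    monitor_data: TrialDataset | None = None,
    verbose: bool = False,
) -> tuple[MultiBranchEEGNet, TrainingHistory]:
    """Train a decoder on one session and return the best-checkpoint model.

    Parameters
    ----------
    train_data : TrialDataset
        The training session.
    spec, cfg : architecture and protocol configuration.
    monitor_data : TrialDataset, optional
        Explicit checkpoint-monitor set. By default a stratified
        ``cfg.monitor_fraction`` of ``train_data`` is held out.

    Returns
    -------
    (model, history) with the weights of the epoch whose monitor accuracy
    was highest (earliest epoch on ties).
    """
    n = spec.n_classes
    if train_data.labels.min() < 1 or train_data.labels.max() > n:
        raise ValueError(
            f"labels outside 1..{n}: range "
            f"[{train_data.labels.min()}, {train_data.labels.max()}]"
        )
    if len(np.unique(train_data.labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")

    rng = np.random.default_rng(cfg.seed)
    if monitor_data is None:
        fit_idx, mon_idx = stratified_split(train_data.labels,
                                            cfg.monitor_fraction, rng)
        fit_data = train_data.subset(fit_idx)
        monitor_data = train_data.subset(mon_idx)
    else:
        fit_data = train_data

    batch_size = cfg.batch_size
    if batch_size > fit_data.n_trials:
        warnings.warn(
            f"batch size {batch_size} exceeds {fit_data.n_trials} trials; "
            "clipping to the dataset size", stacklevel=2)
        batch_size = fit_data.n_trials

    model = MultiBranchEEGNet(spec, include_se=include_se, seed=cfg.seed)
    opt = Adam(model, lr=cfg.learning_rate, beta1=cfg.beta1,
               beta2=cfg.beta2, eps=cfg.adam_eps)
    history = TrainingHistory()
    x = fit_data.signals.astype(model.dtype, copy=False)
    y01 = fit_data.labels - 1

    best_acc = -np.inf
    best_state = None
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(fit_data.n_trials)
        losses, hits, seen = 0.0, 0, 0
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            xb, yb = x[idx], y01[idx]
            logits = model.forward(xb, training=True)
            probs = softmax_probabilities(logits)
            losses += cross_entropy(probs, yb) * len(idx)
            hits += int(np.sum(probs.argmax(axis=1) == yb))
            seen += len(idx)
            dlogits = (probs - np.eye(n)[yb]) / len(idx)
            model.backward(dlogits.astype(model.dtype))
            opt.step()
        mon_acc = _accuracy(model, monitor_data)
        history.train_loss.append(losses / seen)
        history.train_accuracy.append(hits / seen)
        history.monitor_accuracy.append(mon_acc)
        if mon_acc > best_acc:
            best_acc = mon_acc
            best_state = model.get_weights()
        if verbose and (epoch % 10 == 0 or epoch == 1):
            print(f"epoch {epoch:4d}  loss {history.train_loss[-1]:.4f}  "
                  f"train_acc {history.train_accuracy[-1]:.3f}  "
                  f"monitor_acc {mon_acc:.3f}")

    if best_state is not None:
        model.set_weights(best_state)
    return model, history


def save_checkpoint(model: MultiBranchEEGNet, path) -> None:
    """Write weights plus the embedded architecture spec to an HDF5 file."""
    with h5py.File(path, "w") as fh:
        fh.attrs["model_spec"] = model.spec.to_json()
        fh.attrs["include_se"] = model.include_se
        for lname, layer in model.layers():
            grp = fh.create_group(lname)
            for pname, arr in layer.params.items():
                grp.create_dataset(pname, data=arr)
            if hasattr(layer, "running_mean"):
                grp.create_dataset("running_mean", data=layer.running_mean)
                grp.create_dataset("running_var", data=layer.running_var)


def load_checkpoint(path) -> MultiBranchEEGNet:
    """Rebuild a model from a checkpoint, validating every weight shape."""
    from .config import ModelSpec

    with h5py.File(path, "r") as fh:
        spec = ModelSpec.from_json(fh.attrs["model_spec"])
        model = MultiBranchEEGNet(spec, include_se=bool(fh.attrs["include_se"]))
        state = {}
        for lname, layer in model.layers():
            grp = fh[lname]
            entry = {k: np.asarray(grp[k]) for k in grp}
            state[lname] = entry
        model.set_weights(state)
    return model
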