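"""Assembly of the multi-branch EEGNet decoder with SE channel attention.

Each branch runs the compact EEGNet sequence — temporal convolution
(frequency filters), batch-norm, depthwise spatial convolution across
electrodes (spatial filters), batch-norm, ELU, average-pool, dropout,
separable temporal convolution, batch-norm, ELU, average-pool, dropout —
followed by a squeeze-and-excitation gate over its feature maps. The three
flattened branch outputs are concatenated and a single fully connected
softmax layer produces the class probabilities.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._alloc import tune_allocator
from .config import BranchConfig, ModelSpec
from .nn.functional import softmax_probabilities
from .nn.layers import (
    AvgPoolTime,
    BatchNorm,
    Dense,
    DepthwiseSpatialConv,
    Dropout,
    ELU,
    Layer,
    SeparableTemporalConv,
    SEBlock,
    TemporalConv,
)

__all__ = ["MultiBranchEEGNet", "ParamBreakdown", "count_parameters"]


@dataclass
class ParamBreakdown:
    """Per-layer trainable-parameter accounting.

    ``entries`` is a list of (branch, layer, count) rows; ``branch`` is the
    1-based branch index or 0 for the shared output layer.
    """

    entries: list[tuple[int, str, int]]

    @property
    def total(self) -> int:
        return sum(c for _, _, c in self.entries)

    def branch_total(self, branch: int) -> int:
        return sum(c for b, _, c in self.entries if b == branch)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["branch", "layer", "count"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __str__(self) -> str:
        lines = [f"{'branch':>6}  {'layer':<22} {'count':>8}"]
        for b, name, c in self.entries:
            lines.append(f"{b:>6}  {name:<22} {c:>8}")
        lines.append(f"{'':>6}  {'TOTAL':<22} {self.total:>8}")
        return "\n".join(lines)


def _branch_layer_counts(spec: ModelSpec, branch: BranchConfig,
                         include_se: bool) -> list[tuple[str, int]]:
    f1, k = branch.f1_temporal_filters, branch.kernel_length
    f2 = spec.f2(branch)
    c = spec.channels
    rows = [
        ("temporal_conv", f1 * k + (f1 if spec.conv_bias else 0)),
        ("batchnorm_1", 2 * f1),
        ("depthwise_conv", f1 * spec.depth_multiplier * c
         + (f2 if spec.conv_bias else 0)),
        ("batchnorm_2", 2 * f2),
        ("separable_conv", spec.separable_kernel * f2 + f2 * f2
         + (f2 if spec.conv_bias else 0)),
        ("batchnorm_3", 2 * f2),
    ]
    if include_se:
        hidden = f2 // branch.se_reduction_ratio
        rows.append(("se_fc1", f2 * hidden + (hidden if spec.se_bias else 0)))
        rows.append(("se_fc2", hidden * f2 + (f2 if spec.se_bias else 0)))
    return rows


def count_parameters(spec: ModelSpec, include_se: bool = True) -> ParamBreakdown:
    """Closed-form trainable-parameter count of the assembled model.

    Counts convolution kernels (bias-free by default), 2 trainable
    batch-norm parameters per map, both SE fully connected layers with
    biases, and the final dense layer with bias. The test suite asserts
    this agrees exactly with enumeration over a built model's weights.
    """
    entries: list[tuple[int, str, int]] = []
    for i, branch in enumerate(spec.branches, start=1):
        for name, cnt in _branch_layer_counts(spec, branch, include_se):
            entries.append((i, name, cnt))
    dense = spec.feature_length * spec.n_classes \
        + (spec.n_classes if spec.dense_bias else 0)
    entries.append((0, "dense", dense))
    return ParamBreakdown(entries)


class MultiBranchEEGNet:
    """The assembled decoder: (batch, C, T) trials -> class probabilities.

    Parameters
    ----------
    spec : ModelSpec
    include_se : bool
        Build squeeze-and-excitation gates after each branch (the ablation
        without them is the plain multi-branch EEGNet).
    seed : int
        Seeds weight initialization and the dropout stream.
    dtype : numpy dtype
        float32 by default; float64 for numerical verification.
    """

    def __init__(self, spec: ModelSpec, include_se: bool = True,
                 seed: int = 0, dtype=np.float32) -> None:
        tune_allocator()
        self.spec = spec
        self.include_se = include_se
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
        self.branches: list[list[Layer]] = []
        for br in spec.branches:
            f1, f2 = br.f1_temporal_filters, spec.f2(br)
            layers: list[Layer] = [
                TemporalConv(f1, br.kernel_length, bias=spec.conv_bias,
                             rng=rng, dtype=dtype),
                BatchNorm(f1, dtype=dtype),
                DepthwiseSpatialConv(f1, spec.depth_multiplier, spec.channels,
                                     bias=spec.conv_bias, rng=rng, dtype=dtype),
                BatchNorm(f2, dtype=dtype),
                ELU(),
                AvgPoolTime(spec.pool1),
                Dropout(br.dropout_rate),
                SeparableTemporalConv(f2, spec.separable_kernel,
                                      bias=spec.conv_bias, rng=rng, dtype=dtype),
                BatchNorm(f2, dtype=dtype),
                ELU(),
                AvgPoolTime(spec.pool2),
                Dropout(br.dropout_rate),
            ]
            if include_se:
                layers.append(SEBlock(f2, br.se_reduction_ratio,
                                      bias=spec.se_bias, rng=rng, dtype=dtype))
            self.branches.append(layers)
        self.dense = Dense(spec.feature_length, spec.n_classes,
                           bias=spec.dense_bias, rng=rng, dtype=dtype)
        # start inside the constraint set so the first optimizer step does
        # not project the weights abruptly
        for _, layer in self.layers():
            layer.apply_constraints()

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Run the network; returns logits of shape (batch, n_classes)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 3 or x.shape[1] != self.spec.channels \
                or x.shape[2] != self.spec.time_samples:
            raise ValueError(
                f"expected (batch, {self.spec.channels}, "
                f"{self.spec.time_samples}), got {x.shape}"
            )
        h = x[:, None, :, :]
        feats = []
        self._branch_shapes = []
        for layers in self.branches:
            z = h
            for layer in layers:
                z = layer.forward(z, training=training, rng=self._dropout_rng)
            self._branch_shapes.append(z.shape)
            feats.append(z.reshape(z.shape[0], -1))
        concat = np.concatenate(feats, axis=1)
        return self.dense.forward(concat, training=training)

    def backward(self, dlogits: np.ndarray) -> None:
        dconcat = self.dense.backward(dlogits)
        offset = 0
        for layers, shape in zip(self.branches, self._branch_shapes):
            width = int(np.prod(shape[1:]))
            dz = dconcat[:, offset:offset + width].reshape(shape)
            offset += width
            for layer in reversed(layers):
                dz = layer.backward(dz)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode class probabilities, computed in chunks."""
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size], training=False)
            out.append(softmax_probabilities(logits))
        return np.concatenate(out, axis=0)

    def predict_labels(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Argmax decisions as 1-based labels; ties go to the lowest class."""
        return self.predict_proba(x, batch_size).argmax(axis=1) + 1

    # -- parameter plumbing ----------------------------------------------
    def layers(self):
        """Yield (name, layer) for every layer holding parameters or state."""
        for i, layers in enumerate(self.branches, start=1):
            for j, layer in enumerate(layers):
                yield f"branch{i}/{j:02d}_{type(layer).__name__}", layer
        yield "dense", self.dense

    def parameters(self):
        """Yield (layer_name, param_name, array) in a fixed order."""
        for name, layer in self.layers():
            for pname, arr in layer.params.items():
                yield name, pname, arr

    def parameter_count(self) -> int:
        """Trainable parameters by enumeration over the built weight arrays."""
        return int(sum(arr.size for _, _, arr in self.parameters()))

    def get_weights(self) -> dict:
        """Deep copy of all trainable parameters and batch-norm buffers."""
        state = {}
        for name, layer in self.layers():
            state[name] = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, BatchNorm):
                state[name]["running_mean"] = layer.running_mean.copy()
                state[name]["running_var"] = layer.running_var.copy()
        return copy.deepcopy(state)

    def set_weights(self, state: dict) -> None:
        for name, layer in self.layers():
            saved = state[name]
            for k in layer.params:
                if layer.params[k].shape != saved[k].shape:
                    raise ValueError(
                        f"{name}/{k}: shape {saved[k].shape} does not match "
                        f"model shape {layer.params[k].shape}"
                    )
                layer.params[k] = saved[k].copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = saved["running_mean"].copy()
                layer.running_var = saved["running_var"].copy()
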