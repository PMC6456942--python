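"""Dual-branch densely connected convolutional network, in pure numpy.

The model has three parts. A DNA branch one-hot encodes a 1000-bp region and
scans it with an initial bank of convolutional kernels (the published shape
is 128 kernels of width 4 and length 9), followed by two densely connected
convolutional blocks, each closed by a transition convolution and a (1,4)
max-pooling stage. A DNase branch applies the identical architecture to the
per-base chromatin-accessibility signal, except that its initial convolution
is one-dimensional. A joint head concatenates the two branch feature vectors
and feeds them through a small feedforward network ending in 7 independent
sigmoid outputs — one per histone mark — because a region can carry several
marks at once (no softmax).

Inside a dense block every convolution is preceded by batch normalization
and a ReLU, and each of the three layers sees the concatenation of the block
input and all earlier layer outputs, so early features reach every later
layer directly.

Everything — convolutions, batch norm, pooling, and all backward passes —
runs on numpy float32 arrays. Convolutions are evaluated as one GEMM per
kernel offset over a channels-first (C, N, L) layout, which keeps the work
inside BLAS without im2col buffers. Batch-norm running statistics are
frozen in evaluation mode, so eval-mode forward passes are deterministic.
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

__all__ = [
    "NetworkSpec",
    "ModelHandle",
    "build_network",
    "forward",
    "first_layer_kernels",
    "save_checkpoint",
    "load_checkpoint",
]

MODES = ("standard", "dna_only", "dnase_only")


@dataclass
class NetworkSpec:
    """Architecture hyperparameters; the published defaults, scaled sizes
    allowed for CPU-scale experiments."""

    n_markers: int = 7
    seq_len: int = 1000
    init_kernels: int = 128
    kernel_len: int = 9
    pool_len: int = 4
    dense_block_layers: int = 3
    n_dense_blocks: int = 2
    growth: int = 128
    head_hidden_sizes: Tuple[int, ...] = (256,)
    mode: str = "standard"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.kernel_len % 2 == 0:
            raise ValueError("kernel_len must be odd (symmetric same-padding)")
        if min(self.init_kernels, self.growth, self.pool_len, self.seq_len) <= 0:
            raise ValueError("all sizes must be positive")
        self.head_hidden_sizes = tuple(int(h) for h in self.head_hidden_sizes)
        length = self.seq_len
        for stage in range(self.n_dense_blocks):
            length = -(-length // self.pool_len)  # ceil-mode pooling
            if length < 1:
                raise ValueError(
                    f"pooling stage {stage} reduces the feature length below 1"
                )
        self.final_len = length

    def to_json(self) -> str:
        d = asdict(self)
        d["head_hidden_sizes"] = list(self.head_hidden_sizes)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        d.pop("final_len", None)
        d["head_hidden_sizes"] = tuple(d["head_hidden_sizes"])
        return cls(**d)


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name


# ---------------------------------------------------------------------------
# Primitive layers — all activations are (C, N, L) float32
# ---------------------------------------------------------------------------

class Conv1d:
    """Same-padded 1-D convolution via one GEMM per kernel offset.

    With the flattened (C, N*Lp) view of the padded input, output position u
    needs input positions u..u+k-1 of the same example; per-example padding
    guarantees those never cross an example boundary, so
    ``Y[:, :M-t] += W[:, :, t] @ X[:, t:]`` accumulates the exact
    convolution in k BLAS calls.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 name: str, need_input_grad: bool = True):
        std = math.sqrt(2.0 / (c_in * k))
        self.W = Param(rng.normal(0.0, std, size=(c_out, c_in, k)).astype(np.float32), f"{name}.W")
        self.b = Param(np.zeros(c_out, dtype=np.float32), f"{name}.b")
        self.k = k
        self.need_input_grad = need_input_grad
        self._cache = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c_in, n, length = x.shape
        k = self.k
        c_out = self.W.value.shape[0]
        if k > 1:
            xp = np.pad(x, ((0, 0), (0, 0), ((k - 1) // 2, k - 1 - (k - 1) // 2)))
        else:
            xp = np.ascontiguousarray(x)
        lp = xp.shape[2]
        m = n * lp
        X = xp.reshape(c_in, m)
        Yb = np.zeros((c_out, m), dtype=np.float32)
        W = self.W.value
        for t in range(k):
            Yb[:, : m - t] += W[:, :, t] @ X[:, t:]
        y = np.ascontiguousarray(Yb.reshape(c_out, n, lp)[:, :, :length])
        y += self.b.value[:, None, None]
        self._cache = (X, n, lp, length) if train else None
        return y

    def backward(self, dy: np.ndarray) -> Optional[np.ndarray]:
        X, n, lp, length = self._cache
        k = self.k
        c_out, c_in, _ = self.W.value.shape
        m = n * lp
        if dy.shape[2] == lp:
            dYb = dy.reshape(c_out, m)
        else:
            buf = np.zeros((c_out, n, lp), dtype=np.float32)
            buf[:, :, :length] = dy
            dYb = buf.reshape(c_out, m)
        W = self.W.value
        dW = self.W.grad
        for t in range(k):
            dW[:, :, t] += dYb[:, : m - t] @ X[:, t:].T
        self.b.grad += dy.sum(axis=(1, 2))
        if not self.need_input_grad:
            return None
        dXp = np.zeros((c_in, m), dtype=np.float32)
        for t in range(k):
            dXp[:, t:] += W[:, :, t].T @ dYb[:, : m - t]
        left = (k - 1) // 2
        dx = dXp.reshape(c_in, n, lp)[:, :, left : left + length]
        return np.ascontiguousarray(dx)


class BatchNorm1d:
    """Per-channel batch normalization over the batch and length axes."""

    def __init__(self, channels: int, name: str, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c = x.shape[0]
        if train:
            flat = x.reshape(c, -1)
            m = flat.shape[1]
            mean = flat.mean(axis=1)
            sq = np.einsum("ij,ij->i", flat, flat, optimize=True) / m
            var = np.maximum(sq - mean * mean, 0.0)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = np.subtract(x, mean.astype(np.float32)[:, None, None])
        xhat *= inv_std[:, None, None]
        y = xhat * self.gamma.value[:, None, None]
        y += self.beta.value[:, None, None]
        self._cache = (xhat, inv_std) if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        c = dy.shape[0]
        m = dy.shape[1] * dy.shape[2]
        dyf = dy.reshape(c, -1)
        xf = xhat.reshape(c, -1)
        self.gamma.grad += np.einsum("ij,ij->i", dyf, xf, optimize=True)
        self.beta.grad += dyf.sum(axis=1)
        dxhat = dy  # consume dy in place; callers never reuse it
        dxhat *= self.gamma.value[:, None, None]
        s1 = dxhat.reshape(c, -1).sum(axis=1)
        s2 = np.einsum("ij,ij->i", dxhat.reshape(c, -1), xf, optimize=True)
        xhat *= (s2 / m)[:, None, None]
        dxhat -= (s1 / m)[:, None, None]
        dxhat -= xhat
        dxhat *= inv_std[:, None, None]
        return dxhat


class ReLU:
    def __init__(self) -> None:
        self._mask = None

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0 if train else None
        # BN hands over a freshly allocated array, so rectify in place
        return np.maximum(x, 0.0, out=x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy *= self._mask
        return dy


class MaxPool1d:
    """Ceil-mode max pooling: the trailing remainder is padded with -inf so
    any running length is poolable."""

    def __init__(self, pool: int) -> None:
        self.pool = pool
        self._cache = None

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c, n, length = x.shape
        p = self.pool
        out_len = -(-length // p)
        pad = out_len * p - length
        if pad:
            x = np.pad(x, ((0, 0), (0, 0), (0, pad)), constant_values=-np.inf)
        xr = x.reshape(c, n, out_len, p)
        idx = xr.argmax(axis=3)
        y = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
        self._cache = (idx, length) if train else None
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, length = self._cache
        c, n, out_len = dy.shape
        dxr = np.zeros((c, n, out_len, self.pool), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=3)
        dx = dxr.reshape(c, n, out_len * self.pool)
        return np.ascontiguousarray(dx[:, :, :length])


class Linear:
    """Fully connected layer on (N, F) arrays (joint head only)."""

    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator, name: str):
        std = math.sqrt(2.0 / f_in)
        self.W = Param(rng.normal(0.0, std, size=(f_out, f_in)).astype(np.float32), f"{name}.W")
        self.b = Param(np.zeros(f_out, dtype=np.float32), f"{name}.b")
        self._cache = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._cache = x if train else None
        return x @ self.W.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.W.grad += dy.T @ x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


# ---------------------------------------------------------------------------
# Dense block and transition
# ---------------------------------------------------------------------------

class _BnReluConv:
    def __init__(self, c_in, c_out, k, rng, name):
        self.bn = BatchNorm1d(c_in, f"{name}.bn")
        self.act = ReLU()
        self.conv = Conv1d(c_in, c_out, k, rng, f"{name}.conv")

    def params(self):
        return self.bn.params() + self.conv.params()

    def forward(self, x, train):
        return self.conv.forward(self.act.forward(self.bn.forward(x, train), train), train)

    def backward(self, dy):
        return self.bn.backward(self.act.backward(self.conv.backward(dy)))


class DenseBlock:
    """Three BN-ReLU-Conv layers; each layer consumes the concatenation of
    the block input and every earlier layer's output, and the block emits
    the full concatenation, so the first layers feed all later ones both
    directly and through skips."""

    def __init__(self, c_in: int, growth: int, n_layers: int, k: int,
                 rng: np.random.Generator, name: str):
        self.layers = [
            _BnReluConv(c_in + i * growth, growth, k, rng, f"{name}.layer{i}")
            for i in range(n_layers)
        ]
        self.c_in = c_in
        self.growth = growth
        self.c_out = c_in + n_layers * growth
        self._feat_channels: List[int] = []

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        feats = [x]
        for layer in self.layers:
            inp = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=0)
            feats.append(layer.forward(inp, train))
        self._feat_channels = [f.shape[0] for f in feats]
        return np.concatenate(feats, axis=0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        chans = self._feat_channels
        cuts = np.cumsum(chans)[:-1]
        dfeats = [np.ascontiguousarray(part) for part in np.split(dy, cuts, axis=0)]
        for i in range(len(self.layers) - 1, -1, -1):
            dinp = self.layers[i].backward(dfeats[i + 1])
            icuts = np.cumsum(chans[: i + 1])[:-1]
            for j, part in enumerate(np.split(dinp, icuts, axis=0)):
                dfeats[j] += part
        return dfeats[0]


class Transition:
    """BN -> ReLU -> 1x1 convolution -> max pool, between dense blocks."""

    def __init__(self, c_in, c_out, pool, rng, name):
        self.brc = _BnReluConv(c_in, c_out, 1, rng, name)
        self.pool = MaxPool1d(pool)

    def params(self):
        return self.brc.params()

    def forward(self, x, train):
        return self.pool.forward(self.brc.forward(x, train), train)

    def backward(self, dy):
        return self.brc.backward(self.pool.backward(dy))


class Branch:
    """Initial convolution, then (dense block -> transition) stages."""

    def __init__(self, c_in: int, spec: NetworkSpec, rng: np.random.Generator, name: str):
        F, g = spec.init_kernels, spec.growth
        self.init_conv = Conv1d(c_in, F, spec.kernel_len, rng, f"{name}.init",
                                need_input_grad=False)
        self.stages: List[Tuple[DenseBlock, Transition]] = []
        for s in range(spec.n_dense_blocks):
            block = DenseBlock(F, g, spec.dense_block_layers, spec.kernel_len, rng,
                               f"{name}.block{s}")
            trans = Transition(block.c_out, F, spec.pool_len, rng, f"{name}.trans{s}")
            self.stages.append((block, trans))
        self.out_channels = F

    def params(self):
        out = self.init_conv.params()
        for block, trans in self.stages:
            out += block.params() + trans.params()
        return out

    def forward(self, x, train):
        h = self.init_conv.forward(x, train)
        for block, trans in self.stages:
            h = trans.forward(block.forward(h, train), train)
        return h

    def backward(self, dy):
        for block, trans in reversed(self.stages):
            dy = block.backward(trans.backward(dy))
        self.init_conv.backward(dy)


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

PROB_EPS = 1e-7


class ModelHandle:
    """The assembled network plus its spec; built via :func:`build_network`."""

    def __init__(self, spec: NetworkSpec, seed: int):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.dna_branch = None
        self.dnase_branch = None
        feat_dim = 0
        if spec.mode in ("standard", "dna_only"):
            self.dna_branch = Branch(4, spec, rng, "dna")
            feat_dim += spec.init_kernels * spec.final_len
        if spec.mode in ("standard", "dnase_only"):
            self.dnase_branch = Branch(1, spec, rng, "dnase")
            feat_dim += spec.init_kernels * spec.final_len
        self.head: List = []
        f_in = feat_dim
        for i, h in enumerate(spec.head_hidden_sizes):
            self.head.append(Linear(f_in, h, rng, f"head.fc{i}"))
            self.head.append(ReLU())
            f_in = h
        self.out_layer = Linear(f_in, spec.n_markers, rng, "head.out")
        self.training_log: List[dict] = []
        self._flat_shapes = None

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> List[Param]:
        out: List[Param] = []
        for branch in (self.dna_branch, self.dnase_branch):
            if branch is not None:
                out += branch.params()
        for layer in self.head:
            out += layer.params()
        out += self.out_layer.params()
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def _bn_layers(self):
        out = []
        for branch in (self.dna_branch, self.dnase_branch):
            if branch is None:
                continue
            for block, trans in branch.stages:
                for layer in block.layers:
                    out.append(layer.bn)
                out.append(trans.brc.bn)
        return out

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.parameters()}
        for i, bn in enumerate(self._bn_layers()):
            state[f"bn{i}.running_mean"] = bn.running_mean.copy()
            state[f"bn{i}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value[...] = state[p.name]
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean[...] = state[f"bn{i}.running_mean"]
            bn.running_var[...] = state[f"bn{i}.running_var"]

    # -- forward / backward -------------------------------------------------

    def _check_shapes(self, seq, openness):
        L = self.spec.seq_len
        if self.dna_branch is not None:
            if seq is None:
                raise ValueError("this model requires a sequence input")
            if seq.ndim != 3 or seq.shape[1] != 4 or seq.shape[2] != L:
                raise ValueError(f"seq must have shape (n, 4, {L}), got {seq.shape}")
        if self.dnase_branch is not None:
            if openness is None:
                raise ValueError("this model requires an openness input")
            if openness.ndim != 3 or openness.shape[1] != 1 or openness.shape[2] != L:
                raise ValueError(f"openness must have shape (n, 1, {L}), got {openness.shape}")

    def forward_logits(self, seq: Optional[np.ndarray] = None,
                       openness: Optional[np.ndarray] = None,
                       train: bool = False) -> np.ndarray:
        self._check_shapes(seq, openness)
        feats = []
        for branch, data in ((self.dna_branch, seq), (self.dnase_branch, openness)):
            if branch is None:
                continue
            x = np.ascontiguousarray(
                np.asarray(data, dtype=np.float32).transpose(1, 0, 2)
            )
            h = branch.forward(x, train)  # (F, N, L2)
            n = h.shape[1]
            feats.append(np.ascontiguousarray(h.transpose(1, 0, 2)).reshape(n, -1))
        x = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)
        self._flat_shapes = [(f.shape[1]) for f in feats]
        for layer in self.head:
            x = layer.forward(x, train)
        return self.out_layer.forward(x, train)

    def forward(self, seq: Optional[np.ndarray] = None,
                openness: Optional[np.ndarray] = None,
                train: bool = False) -> np.ndarray:
        """Per-marker probabilities, each strictly inside (0, 1)."""
        logits = self.forward_logits(seq, openness, train)
        probs = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
        return np.clip(probs, PROB_EPS, 1.0 - PROB_EPS)

    def backward_logits(self, dlogits: np.ndarray) -> None:
        dx = self.out_layer.backward(dlogits.astype(np.float32))
        for layer in reversed(self.head):
            dx = layer.backward(dx)
        cuts = np.cumsum(self._flat_shapes)[:-1]
        parts = np.split(dx, cuts, axis=1)
        i = 0
        for branch in (self.dna_branch, self.dnase_branch):
            if branch is None:
                continue
            flat = parts[i]
            i += 1
            n = flat.shape[0]
            dh = np.ascontiguousarray(
                flat.reshape(n, branch.out_channels, -1).transpose(1, 0, 2)
            )
            branch.backward(dh)

    # -- introspection ------------------------------------------------------

    def first_layer_kernels(self) -> List[np.ndarray]:
        """The DNA branch's initial-convolution weights, one 4 x k matrix per
        kernel, in kernel order."""
        if self.dna_branch is None:
            raise ValueError(
                f"model mode {self.spec.mode!r} has no DNA branch; "
                "first-layer kernels are undefined"
            )
        W = self.dna_branch.init_conv.W.value
        return [W[i].copy() for i in range(W.shape[0])]

    def summary(self) -> str:
        spec = self.spec
        buf = io.StringIO()
        buf.write(f"mode={spec.mode} seq_len={spec.seq_len} markers={spec.n_markers}\n")
        for branch, label, c_in in (
            (self.dna_branch, "dna", 4),
            (self.dnase_branch, "dnase", 1),
        ):
            if branch is None:
                continue
            L = spec.seq_len
            buf.write(f"[{label}] init conv ({spec.init_kernels},{c_in},{spec.kernel_len})"
                      f" -> ({spec.init_kernels},{L})\n")
            for s, (block, trans) in enumerate(branch.stages):
                buf.write(f"[{label}] dense block {s}: {spec.dense_block_layers} x "
                          f"BN-ReLU-Conv(k={spec.kernel_len}, growth={spec.growth})"
                          f" -> ({block.c_out},{L})\n")
                L = -(-L // spec.pool_len)
                buf.write(f"[{label}] transition: 1x1 conv + pool({spec.pool_len})"
                          f" -> ({spec.init_kernels},{L})\n")
        n_branches = (self.dna_branch is not None) + (self.dnase_branch is not None)
        feat = n_branches * spec.init_kernels * spec.final_len
        buf.write(f"[joint] concat -> {feat} features\n")
        f_in = feat
        for h in spec.head_hidden_sizes:
            buf.write(f"[joint] linear {f_in} -> {h}, ReLU\n")
            f_in = h
        buf.write(f"[joint] linear {f_in} -> {spec.n_markers}, {spec.n_markers} x sigmoid\n")
        n_params = sum(p.value.size for p in self.parameters())
        buf.write(f"parameters: {n_params}\n")
        return buf.getvalue()


def build_network(spec: NetworkSpec, seed: int = 0) -> ModelHandle:
    """Construct a model with seed-deterministic initial parameters."""
    return ModelHandle(spec, seed)


def forward(model: ModelHandle, batch) -> np.ndarray:
    """Evaluation-mode probabilities for an EncodedBatch (or anything with
    ``seq`` / ``openness`` attributes)."""
    seq = getattr(batch, "seq", None)
    openness = getattr(batch, "openness", None)
    return model.forward(seq=seq, openness=openness, train=False)


def first_layer_kernels(model: ModelHandle) -> List[np.ndarray]:
    return model.first_layer_kernels()


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: ModelHandle, path: Union[str, os.PathLike]) -> None:
    state = model.state_dict()
    np.savez_compressed(path, __spec__=model.spec.to_json(), __seed__=model.seed, **state)


def load_checkpoint(path: Union[str, os.PathLike]) -> ModelHandle:
    with np.load(path, allow_pickle=False) as data:
        spec = NetworkSpec.from_json(str(data["__spec__"]))
        seed = int(data["__seed__"])
        model = ModelHandle(spec, seed)
        state = {k: data[k] for k in data.files if k not in ("__spec__", "__seed__")}
        model.load_state_dict(state)
    return model
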