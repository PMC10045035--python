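"""Lightweight convolutional classifier for candidate-SV images.

Architecture: three identical convolution blocks (3x3 kernel over the 3 input
channels, ReLU, 2x2 max-pool), followed by two fully connected layers each
with dropout, and a single sigmoid output unit. A candidate whose score
exceeds 0.5 (strictly) is kept as a true variant; otherwise it is dropped as
a false positive.

The network is implemented directly in numpy (forward and backward passes,
Adam optimizer, binary cross-entropy on the logit for numerical stability).
The models involved are small — three conv blocks at 16/32/64 channels on a
64–128 px image — so plain vectorized numpy trains them in minutes on one
core, and the absence of a deep-learning runtime keeps the dependency
surface to the scientific stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class NetworkSpec:
    conv_channels: tuple[int, int, int] = (16, 32, 64)
    fc_widths: tuple[int, int] = (256, 64)
    dropout: float = 0.5
    kernel: int = 3

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 3:
            raise ValueError("exactly three convolution blocks")
        if len(self.fc_widths) != 2:
            raise ValueError("exactly two fully connected layers")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout rate must be in [0, 1)")


@dataclass
class TrainReport:
    losses: list[float]
    aucs: list[float]
    best_auc: float
    best_epoch: int
    checkpoint_path: str | None
    seed: int


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution. x: (N,C,H,W); W: (F,C,3,3)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((n, W.shape[0], h, w), dtype=x.dtype)
    for dy in range(3):
        for dx in range(3):
            out += np.einsum(
                "nchw,fc->nfhw", xp[:, :, dy : dy + h, dx : dx + w], W[:, :, dy, dx],
                optimize=True,
            )
    return out + b[None, :, None, None]


def _conv_backward(x, W, dout):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dW = np.zeros_like(W)
    dxp = np.zeros_like(xp)
    for dy in range(3):
        for dx in range(3):
            patch = xp[:, :, dy : dy + h, dx : dx + w]
            dW[:, :, dy, dx] = np.einsum("nchw,nfhw->fc", patch, dout, optimize=True)
            dxp[:, :, dy : dy + h, dx : dx + w] += np.einsum(
                "nfhw,fc->nchw", dout, W[:, :, dy, dx], optimize=True
            )
    db = dout.sum(axis=(0, 2, 3))
    return dxp[:, :, 1:-1, 1:-1], dW, db


def _pool_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(dout, idx, shape):
    n, c, h, w = shape
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dx.reshape(n, c, h, w)


class CNNClassifier:
    """Numpy implementation of the 3-conv-block + 2-FC sigmoid classifier."""

    def __init__(self, spec: NetworkSpec, image_height: int, image_width: int, seed: int = 0):
        if image_height % 8 or image_width % 8:
            raise ValueError(
                f"image dims ({image_height}x{image_width}) must be divisible by 8 "
                "(three 2x2 max-pools)"
            )
        self.spec = spec
        self.image_height = image_height
        self.image_width = image_width
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 3
        for i, c_out in enumerate(spec.conv_channels):
            fan_in = c_in * 9
            self.params[f"Wc{i}"] = rng.normal(
                0, np.sqrt(2.0 / fan_in), (c_out, c_in, 3, 3)
            ).astype(np.float32)
            self.params[f"bc{i}"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
        flat = c_in * (image_height // 8) * (image_width // 8)
        widths = [flat, *spec.fc_widths, 1]
        for i, (a, b) in enumerate(zip(widths, widths[1:])):
            self.params[f"Wf{i}"] = rng.normal(0, np.sqrt(2.0 / a), (a, b)).astype(np.float32)
            self.params[f"bf{i}"] = np.zeros(b, dtype=np.float32)

    @property
    def parameter_count(self) -> int:
        return sum(p.size for p in self.params.values())

    def _forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        cache = {"x0": x}
        h = x
        for i in range(3):
            z = _conv_forward(h, self.params[f"Wc{i}"], self.params[f"bc{i}"])
            a = np.maximum(z, 0)
            p, idx = _pool_forward(a)
            cache[f"conv{i}"] = (h, z, a.shape, idx)
            h = p
        n = h.shape[0]
        cache["pre_flat_shape"] = h.shape
        h = h.reshape(n, -1)
        for i in range(3):  # two hidden FC + output
            cache[f"fc{i}_in"] = h
            z = h @ self.params[f"Wf{i}"] + self.params[f"bf{i}"]
            if i < 2:
                h = np.maximum(z, 0)
                cache[f"fc{i}_z"] = z
                if train and self.spec.dropout > 0:
                    keep = 1.0 - self.spec.dropout
                    mask = (rng.random(h.shape) < keep).astype(h.dtype) / keep
                    h = h * mask
                    cache[f"fc{i}_mask"] = mask
            else:
                logits = z[:, 0]
        cache["logits"] = logits
        return logits, cache

    def _backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        dh = dlogits[:, None]
        for i in (2, 1, 0):
            h_in = cache[f"fc{i}_in"]
            grads[f"Wf{i}"] = h_in.T @ dh
            grads[f"bf{i}"] = dh.sum(axis=0)
            dh = dh @ self.params[f"Wf{i}"].T
            if i > 0:
                j = i - 1
                if f"fc{j}_mask" in cache:
                    dh = dh * cache[f"fc{j}_mask"]
                dh = dh * (cache[f"fc{j}_z"] > 0)
        dh = dh.reshape(cache["pre_flat_shape"])
        for i in (2, 1, 0):
            h_in, z, a_shape, idx = cache[f"conv{i}"]
            da = _pool_backward(dh, idx, a_shape)
            dz = da * (z > 0)
            dh, dW, db = _conv_backward(h_in, self.params[f"Wc{i}"], dz)
            grads[f"Wc{i}"] = dW
            grads[f"bc{i}"] = db
        return grads

    def predict(self, images: Sequence, batch_size: int = 64) -> np.ndarray:
        """Scores in (0,1) for a batch of images; order preserved."""
        x = images_to_tensor(images, self.image_height, self.image_width)
        scores = np.empty(x.shape[0], dtype=np.float64)
        for i in range(0, x.shape[0], batch_size):
            logits, _ = self._forward(x[i : i + batch_size])
            scores[i : i + batch_size] = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
        return scores

    def save(self, path: str | Path) -> None:
        meta = {
            "spec": asdict(self.spec),
            "image_height": self.image_height,
            "image_width": self.image_width,
            "seed": self.seed,
        }
        np.savez(
            str(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "CNNClassifier":
        with np.load(str(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            spec_d = meta["spec"]
            spec = NetworkSpec(
                conv_channels=tuple(spec_d["conv_channels"]),
                fc_widths=tuple(spec_d["fc_widths"]),
                dropout=spec_d["dropout"],
                kernel=spec_d["kernel"],
            )
            clf = cls(spec, meta["image_height"], meta["image_width"], meta["seed"])
            for k in clf.params:
                clf.params[k] = data[k]
        return clf


def build_network(
    spec: NetworkSpec, image_dims: tuple[int, int], seed: int = 0
) -> CNNClassifier:
    return CNNClassifier(spec, image_dims[0], image_dims[1], seed)


def images_to_tensor(images: Sequence, height: int, width: int) -> np.ndarray:
    """Stack EncodedImage/array inputs into a float32 (N, 3, H, W) tensor in [0,1]."""
    arrays = []
    for im in images:
        a = im.pixels if hasattr(im, "pixels") else np.asarray(im)
        if a.shape != (height, width, 3):
            raise ValueError(f"image shape {a.shape} does not match model ({height},{width},3)")
        arrays.append(a)
    x = np.stack(arrays).astype(np.float32) / 255.0
    return x.transpose(0, 3, 1, 2)


def train(
    clf: CNNClassifier,
    images: Sequence,
    labels: Sequence[int],
    valid_fraction: float = 0.2,
    epochs: int = 15,
    batch_size: int = 64,
    lr: float = 1e-3,
    seed: int = 0,
    checkpoint_path: str | Path | None = None,
) -> TrainReport:
    """Adam-optimized binary cross-entropy training with a held-out AUC curve.

    The held-out split, batch order, dropout masks and parameter updates all
    derive from ``seed``, so a rerun reproduces the report exactly. The best
    held-out-AUC parameters are restored at the end (and saved when
    ``checkpoint_path`` is given).
    """
    y = np.asarray(labels, dtype=np.float32)
    if len(set(y.tolist())) < 2:
        raise ValueError("training set has a single class; need positives and negatives")
    x = images_to_tensor(images, clf.image_height, clf.image_width)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_valid = max(1, int(round(valid_fraction * len(y))))
    valid_idx, train_idx = order[:n_valid], order[n_valid:]
    if len(set(y[valid_idx].tolist())) < 2 or len(set(y[train_idx].tolist())) < 2:
        # stratified fallback: interleave classes before splitting
        pos = [i for i in order if y[i] == 1]
        neg = [i for i in order if y[i] == 0]
        valid_idx = np.array(pos[: max(1, n_valid // 2)] + neg[: max(1, n_valid // 2)])
        train_idx = np.array([i for i in order if i not in set(valid_idx.tolist())])
    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[valid_idx], y[valid_idx]

    m = {k: np.zeros_like(v, dtype=np.float64) for k, v in clf.params.items()}
    v2 = {k: np.zeros_like(v, dtype=np.float64) for k, v in clf.params.items()}
    t = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    losses, aucs = [], []
    best_auc, best_epoch = -1.0, -1
    best_params = {k: p.copy() for k, p in clf.params.items()}
    for epoch in range(epochs):
        perm = rng.permutation(len(yt))
        epoch_loss = 0.0
        for i in range(0, len(yt), batch_size):
            idx = perm[i : i + batch_size]
            xb, yb = xt[idx], yt[idx]
            logits, cache = clf._forward(xb, train=True, rng=rng)
            z = logits.astype(np.float64)
            loss = float(np.mean(np.maximum(z, 0) - z * yb + np.log1p(np.exp(-np.abs(z)))))
            epoch_loss += loss * len(yb)
            dlogits = ((1.0 / (1.0 + np.exp(-z)) - yb) / len(yb)).astype(np.float32)
            grads = clf._backward(cache, dlogits)
            t += 1
            for k in clf.params:
                g = grads[k].astype(np.float64)
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v2[k] = beta2 * v2[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**t)
                vhat = v2[k] / (1 - beta2**t)
                clf.params[k] = (
                    clf.params[k].astype(np.float64) - lr * mhat / (np.sqrt(vhat) + eps)
                ).astype(np.float32)
        losses.append(epoch_loss / len(yt))
        val_logits, _ = clf._forward(xv)
        val_scores = 1.0 / (1.0 + np.exp(-val_logits.astype(np.float64)))
        auc = float(roc_auc_score(yv, val_scores)) if len(set(yv.tolist())) > 1 else float("nan")
        aucs.append(auc)
        if auc > best_auc:
            best_auc, best_epoch = auc, epoch
            best_params = {k: p.copy() for k, p in clf.params.items()}
    clf.params = best_params
    ckpt = None
    if checkpoint_path is not None:
        clf.save(checkpoint_path)
        ckpt = str(checkpoint_path)
    return TrainReport(losses, aucs, best_auc, best_epoch, ckpt, seed)


def predict_filter(
    clf: CNNClassifier, images: Sequence, threshold: float = 0.5
) -> np.ndarray:
    """Keep/drop flags per candidate: keep iff score strictly exceeds the threshold."""
    return clf.predict(images) > threshold
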