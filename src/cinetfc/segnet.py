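"""Desk-scale Bayesian dilated-residual segmentation network.

A deliberately small 2D convolutional network — two 3×3 convolutions (the
second dilated, with an identity residual connection), Monte-Carlo dropout,
and a 1×1 classification head over {background, LV, RV} — implemented in
numpy with hand-written backpropagation.  It exists to exercise the
training loss (soft-Dice + cross-entropy), MC-dropout inference (mean
softmax over stochastic forward passes) and the largest-connected-component
post-processing at toy scale; clinical-scale segmentation fidelity is out
of scope.

Coordinate channels are appended to the grayscale input so that the tiny
receptive field can still separate the left from the right ventricle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "TrainConfig",
    "DilatedResSegNet",
    "soft_dice",
    "cross_entropy",
    "mc_predict",
    "largest_component_filter",
    "train",
]

N_CLASSES = 3
EPS = 1e-7


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------
def soft_dice(a_c: np.ndarray, r_c: np.ndarray, variant: str = "standard") -> float:
    """Soft Dice between a probability map and a binary reference map.

    ``standard`` is the conventional 2·ΣRA/(ΣR+ΣA) (1 at perfect binary
    overlap); ``as_printed`` omits the factor 2 (maximum ½).  Two empty maps
    are defined as 0 with a warning.
    """
    if variant not in ("standard", "as_printed"):
        raise ValueError("variant must be 'standard' or 'as_printed'")
    a = np.asarray(a_c, dtype=float)
    r = np.asarray(r_c, dtype=float)
    if a.shape != r.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {r.shape}")
    if (a < 0).any() or (a > 1).any():
        raise ValueError("probability map must lie in [0, 1]")
    denom = r.sum() + a.sum()
    if denom == 0:
        warnings.warn("both maps empty: soft dice defined as 0")
        return 0.0
    num = (r * a).sum()
    return float((2.0 if variant == "standard" else 1.0) * num / denom)


def cross_entropy(prob_maps: np.ndarray, reference: np.ndarray) -> float:
    """Mean per-voxel cross-entropy −log p(true class).

    ``prob_maps`` has shape (n_classes, *spatial); ``reference`` holds
    integer class labels on the spatial grid.  Probabilities are clamped at
    1e-7 before the log.
    """
    p = np.asarray(prob_maps, dtype=float)
    ref = np.asarray(reference)
    if p.shape[1:] != ref.shape:
        raise ValueError(f"shape mismatch: {p.shape[1:]} vs {ref.shape}")
    idx = (ref[np.newaxis] == np.arange(p.shape[0]).reshape(-1, *([1] * ref.ndim)))
    p_true = p[idx].reshape(ref.shape)
    return float(-np.log(np.clip(p_true, EPS, 1.0)).mean())


# --------------------------------------------------------------------------
# minimal conv machinery (im2col)
# --------------------------------------------------------------------------
def _im2col(x: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C*k*k, H*W), 'same' padding."""
    b, c, h, w = x.shape
    pad = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((b, c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i * dilation:i * dilation + h,
                                  j * dilation:j * dilation + w]
    return cols.reshape(b, c * k * k, h * w)


def _col2im(dcols: np.ndarray, shape: tuple, k: int, dilation: int) -> np.ndarray:
    b, c, h, w = shape
    pad = dilation * (k - 1) // 2
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(b, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i * dilation:i * dilation + h,
                j * dilation:j * dilation + w] += dcols[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp


class _Conv2d:
    def __init__(self, c_in: int, c_out: int, k: int, dilation: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k, self.dilation = k, dilation
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k, self.dilation)
        bsz, _, hw = self._cols.shape
        c_out = self.w.shape[0]
        y = self.w.reshape(c_out, -1) @ self._cols + self.b[:, None]
        h, w = x.shape[2:]
        return y.reshape(bsz, c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        bsz, c_out, h, w = dy.shape
        dyf = dy.reshape(bsz, c_out, h * w)
        self.dw = np.einsum("bop,bcp->oc", dyf, self._cols).reshape(self.w.shape)
        self.db = dyf.sum(axis=(0, 2))
        dcols = np.einsum("oc,bop->bcp", self.w.reshape(c_out, -1), dyf)
        return _col2im(dcols, self._x_shape, self.k, self.dilation)

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


@dataclass
class TrainConfig:
    """Training recipe; defaults are the clinical-scale recipe scaled to a
    CPU toy run (the full-scale values are 160×160 patches and 160,000
    iterations with the learning rate decayed every 40,000 steps)."""

    patch_size: tuple[int, int] = (64, 64)
    batch_size: int = 16
    iterations: int = 400
    learning_rate: float = 0.001
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 40_000
    weight_decay: float = 0.0005
    dropout_rate: float = 0.1
    mc_samples: int = 15
    hidden_channels: int = 16
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be at least 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")


class DilatedResSegNet:
    """Tiny dilated-residual segmentation net with MC dropout.

    conv3×3 → ReLU → conv3×3(dilation 2) → ReLU → +residual → dropout →
    conv1×1 → softmax over {background, LV, RV}.
    """

    def __init__(self, hidden: int = 16, dropout_rate: float = 0.1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dropout_rate = dropout_rate
        self.conv1 = _Conv2d(3, hidden, 3, 1, rng)
        self.conv2 = _Conv2d(hidden, hidden, 3, 2, rng)
        self.head = _Conv2d(hidden, N_CLASSES, 1, 1, rng)

    @property
    def layers(self):
        return (self.conv1, self.conv2, self.head)

    @staticmethod
    def _with_coords(images: np.ndarray) -> np.ndarray:
        """Stack (B, H, W) grayscale with normalized coordinate channels."""
        b, h, w = images.shape
        yy, xx = np.mgrid[0:h, 0:w]
        yy = 2.0 * yy / max(h - 1, 1) - 1.0
        xx = 2.0 * xx / max(w - 1, 1) - 1.0
        coords = np.broadcast_to(np.stack([yy, xx]), (b, 2, h, w))
        return np.concatenate([images[:, None], coords], axis=1)

    def forward(self, images: np.ndarray,
                dropout_rng: np.random.Generator | None = None) -> np.ndarray:
        """Softmax probability maps (B, 3, H, W); dropout is active only
        when a generator is supplied (training or MC sampling)."""
        x = self._with_coords(np.asarray(images, dtype=float))
        h1 = self.conv1.forward(x)
        self._m1 = h1 > 0
        a1 = h1 * self._m1
        h2 = self.conv2.forward(a1)
        self._m2 = h2 > 0
        a2 = h2 * self._m2 + a1  # identity residual
        if dropout_rng is not None and self.dropout_rate > 0:
            keep = 1.0 - self.dropout_rate
            self._drop = (dropout_rng.random(a2.shape) < keep) / keep
        else:
            self._drop = np.ones_like(a2)
        a2 = a2 * self._drop
        logits = self.head.forward(a2)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        self._probs = e / e.sum(axis=1, keepdims=True)
        return self._probs

    def backward(self, dlogits: np.ndarray) -> None:
        da2 = self.head.backward(dlogits) * self._drop
        dh2 = da2 * self._m2
        da1 = self.conv2.backward(dh2) + da2  # residual branch
        dh1 = da1 * self._m1
        self.conv1.backward(dh1)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout off) for a single image."""
        return self.forward(image[np.newaxis])[0]

    def parameters(self):
        for layer in self.layers:
            yield from layer.params

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.parameters(), weights):
            p[...] = w


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------
def mc_predict(model: DilatedResSegNet, image: np.ndarray,
               n_samples: int = 15, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo dropout inference.

    Averages the softmax output of ``n_samples`` stochastic forward passes;
    the label map is the argmax of the mean.  With dropout rate 0 every pass
    is identical to the deterministic forward pass.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)
    mean = np.zeros((N_CLASSES, *np.shape(image)), dtype=float)
    for _ in range(n_samples):
        mean += model.forward(np.asarray(image)[np.newaxis], dropout_rng=rng)[0]
    mean /= n_samples
    return mean, mean.argmax(axis=0).astype(np.uint8)


def largest_component_filter(labels3d: np.ndarray,
                             connectivity: int = 26) -> np.ndarray:
    """Retain only the largest 3D connected component of each foreground
    class; everything else becomes background.

    26-connectivity by default (6 available); size ties break to the
    component labelled first by the deterministic scan order.
    """
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    lab = np.asarray(labels3d)
    if lab.ndim != 3:
        raise ValueError("expected a 3D label grid (slices stacked)")
    struct = ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    out = np.zeros_like(lab)
    for cls in np.unique(lab):
        if cls == 0:
            continue
        comp, n = ndimage.label(lab == cls, structure=struct)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
        keep = 1 + int(np.argmax(sizes))  # argmax keeps the first maximum
        out[comp == keep] = cls
    return out


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------
def _loss_and_grad(probs: np.ndarray, refs: np.ndarray) -> tuple[float, np.ndarray]:
    """Combined loss (mean CE + 1 − mean foreground soft-Dice) and its
    gradient w.r.t. the logits."""
    b, c, h, w = probs.shape
    onehot = (refs[:, None] == np.arange(c).reshape(1, c, 1, 1)).astype(float)
    nvox = b * h * w
    ce = float(-(onehot * np.log(np.clip(probs, EPS, 1.0))).sum() / nvox)
    dlogits = (probs - onehot) / nvox

    # soft-Dice over the foreground classes, batch pooled
    g = np.zeros_like(probs)
    dice_sum = 0.0
    fg = (1, 2)
    for cls in fg:
        r, a = onehot[:, cls], probs[:, cls]
        denom = r.sum() + a.sum()
        if denom == 0:
            dice_sum += 1.0
            continue
        num = (r * a).sum()
        dice_sum += 2.0 * num / denom
        # d(2*num/denom)/da = (2*r*denom - 2*num) / denom^2
        g[:, cls] = -(2.0 * r * denom - 2.0 * num) / denom**2 / len(fg)
    dice_loss = 1.0 - dice_sum / len(fg)
    # chain dL/dp through softmax: dL/dz_k = p_k (g_k - sum_j g_j p_j)
    inner = (g * probs).sum(axis=1, keepdims=True)
    dlogits += probs * (g - inner)
    return ce + dice_loss, dlogits


def _augment_patch(img: np.ndarray, ref: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """90° rotations, a light elastic-style shift, and gamma transform."""
    k = int(rng.integers(4))
    img, ref = np.rot90(img, k).copy(), np.rot90(ref, k).copy()
    if rng.random() < 0.5:  # small random translation stands in for elastic warp
        shift = rng.integers(-3, 4, size=2)
        img = np.roll(img, shift, axis=(0, 1))
        ref = np.roll(ref, shift, axis=(0, 1))
    if rng.random() < 0.5:
        gamma = rng.uniform(0.7, 1.4)
        img = np.clip(img, 0, None) ** gamma
    return img, ref


def train(dataset: list[tuple[np.ndarray, np.ndarray]],
          config: TrainConfig | None = None,
          model: DilatedResSegNet | None = None) -> tuple[DilatedResSegNet, list[float]]:
    """Train the toy net with Adam on random patches; returns the model and
    the per-iteration loss curve.  Aborts on divergence (NaN loss)."""
    if not dataset:
        raise ValueError("dataset is empty")
    cfg = config or TrainConfig()
    model = model or DilatedResSegNet(cfg.hidden_channels, cfg.dropout_rate,
                                      seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    ph, pw = cfg.patch_size
    params = list(model.parameters())
    m = [np.zeros_like(p) for p, _ in params]
    v = [np.zeros_like(p) for p, _ in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    history: list[float] = []
    for it in range(cfg.iterations):
        imgs = np.empty((cfg.batch_size, ph, pw))
        refs = np.empty((cfg.batch_size, ph, pw), dtype=np.int64)
        for bi in range(cfg.batch_size):
            img, ref = dataset[int(rng.integers(len(dataset)))]
            if img.shape[0] < ph or img.shape[1] < pw:
                raise ValueError("image smaller than the training patch size")
            y0 = int(rng.integers(img.shape[0] - ph + 1))
            x0 = int(rng.integers(img.shape[1] - pw + 1))
            pi, pr = img[y0:y0 + ph, x0:x0 + pw], ref[y0:y0 + ph, x0:x0 + pw]
            if cfg.augment:
                pi, pr = _augment_patch(pi, pr, rng)
            imgs[bi], refs[bi] = pi, pr
        probs = model.forward(imgs, dropout_rng=rng)
        loss, dlogits = _loss_and_grad(probs, refs)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged at iteration {it}: loss={loss}")
        history.append(loss)
        model.backward(dlogits)
        lr = cfg.learning_rate * cfg.lr_decay_factor ** (it // cfg.lr_decay_every)
        t = it + 1
        for i, (p, dp) in enumerate(params):
            grad = dp + cfg.weight_decay * p
            m[i] = beta1 * m[i] + (1 - beta1) * grad
            v[i] = beta2 * v[i] + (1 - beta2) * grad**2
            mhat = m[i] / (1 - beta1**t)
            vhat = v[i] / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
    return model, history
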