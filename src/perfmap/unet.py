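"""U-Net-style map regression, implemented on numpy with manual backprop.

The architecture follows the modified U-Net used for perfusion-map
regression: 2x2 convolution kernels throughout, average pooling instead of
max pooling, 2x2 up-convolutions, skip connections per stage, and a 1x1
output head producing a single map channel.  Time frames enter as input
channels.  Training minimizes MSE with Adam (lr 1e-5, b1 0.9, b2 0.999,
batch size 8) in two stages: pre-training on sub-sampled inputs followed by
full-resolution fine-tuning.

Everything is deterministic given the seeds; no GPU or autograd framework
is required, which keeps desk-scale experiments reproducible anywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "FoldResult",
    "Sample",
    "UNet2D",
    "build_model",
    "count_parameters",
    "evaluate_mse",
    "load_model",
    "make_dataset",
    "predict",
    "predict_volume",
    "save_model",
    "threefold_cv",
    "train",
]


# ---------------------------------------------------------------------------
# configs

@dataclass
class UNetConfig:
    input_size: int = 512          # square spatial size the model is built for
    in_channels: int = 89          # time frames as channels
    depth: int = 4                 # encoding stages before the bottleneck
    base_width: int = 64           # filters at the top level, doubling per stage
    out_channels: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.input_size <= 0 or self.in_channels <= 0 or self.base_width <= 0:
            raise ValueError("sizes must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth")


@dataclass
class TrainConfig:
    lr: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 8
    pretrain_epochs: int = 250
    pretrain_size: int | None = None   # None -> input_size // 4 (e.g. 512->128)
    finetune_epochs: int = 50
    seed: int = 0
    #: zero the head weights and set its bias to the target mean, so the
    #: net starts at the best constant predictor regardless of input scale
    init_output_bias: bool = True
    plateau_decay: float | None = None  # optional lr decay factor on plateau
    plateau_patience: int = 20


@dataclass
class FoldResult:
    fold: int
    train_mse: float
    val_mse: float
    history: dict
    val_subjects: tuple
    model: object = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# layers (NHWC, float32)

_SHIFTS = ((0, 0), (0, 1), (1, 0), (1, 1))


class _Conv2x2:
    """'Same' 2x2 convolution (implicit right/bottom zero pad).

    Computed as one (C_in -> 4*C_out) matmul followed by shifted-output
    accumulation, which avoids materializing a 4*C_in im2col buffer.  The
    weight column block for shift k of ``_SHIFTS`` is ``W[:, k*C_out:(k+1)*C_out]``.
    """

    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / (4 * c_in))
        self.W = rng.normal(0, scale, size=(c_in, 4 * c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_out = c_out

    def forward(self, x):
        n, h, w, c = x.shape
        self._x = x
        z = (x.reshape(-1, c) @ self.W).reshape(n, h, w, 4, self.c_out)
        y = z[:, :, :, 0, :].copy()          # shift (0, 0)
        for k, (di, dj) in enumerate(_SHIFTS[1:], start=1):
            y[:, :h - di, :w - dj] += z[:, di:, dj:, k]
        y += self.b
        return y

    def backward(self, dy):
        x = self._x
        n, h, w, c = x.shape
        co = self.c_out
        dz = np.empty((n, h, w, 4, co), dtype=dy.dtype)
        dz[:, :, :, 0, :] = dy
        for k, (di, dj) in enumerate(_SHIFTS[1:], start=1):
            dz[:, di:, dj:, k] = dy[:, :h - di, :w - dj]
            if di:
                dz[:, :di, :, k] = 0.0
            if dj:
                dz[:, :, :dj, k] = 0.0
        dzf = dz.reshape(-1, 4 * co)
        self.dW = x.reshape(-1, c).T @ dzf
        self.db = dy.reshape(-1, co).sum(axis=0)
        self._x = None
        return (dzf @ self.W.T).reshape(x.shape)


class _Conv1x1:
    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / c_in)
        self.W = rng.normal(0, scale, size=(c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        xf = self._x.reshape(-1, self._x.shape[-1])
        dyf = dy.reshape(-1, dy.shape[-1])
        self.dW = xf.T @ dyf
        self.db = dyf.sum(axis=0)
        self._x = None
        return dy @ self.W.T


class _UpConv2x2:
    """2x stride-2 transposed convolution with a 2x2 kernel."""

    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / c_in)
        self.W = rng.normal(0, scale, size=(c_in, 4 * c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_out = c_out

    def forward(self, x):
        n, h, w, c = x.shape
        self._x = x
        y = (x.reshape(-1, c) @ self.W).reshape(n, h, w, 2, 2, self.c_out)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, self.c_out)
        return y + self.b

    def backward(self, dy):
        n, h2, w2, co = dy.shape
        h, w = h2 // 2, w2 // 2
        dyb = dy.reshape(n, h, 2, w, 2, co).transpose(0, 1, 3, 2, 4, 5)
        dyf = dyb.reshape(-1, 4 * co)
        xf = self._x.reshape(-1, self._x.shape[-1])
        self.dW = xf.T @ dyf
        self.db = dy.reshape(-1, co).sum(axis=0)
        dx = (dyf @ self.W.T).reshape(self._x.shape)
        self._x = None
        return dx


class _ReLU:
    # operates in place: the input is always a fresh conv output, and the
    # incoming gradient a fresh array from the next layer's backward
    def forward(self, x):
        np.maximum(x, 0.0, out=x)
        self._mask = x > 0
        return x

    def backward(self, dy):
        np.multiply(dy, self._mask, out=dy)
        self._mask = None
        return dy


def _avgpool(x):
    n, h, w, c = x.shape
    return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))


def _avgpool_back(dy, shape):
    n, h, w, c = shape
    return np.broadcast_to(
        dy[:, :, None, :, None, :] * dy.dtype.type(0.25),
        (n, h // 2, 2, w // 2, 2, c)).reshape(n, h, w, c)


# ---------------------------------------------------------------------------
# model

class UNet2D:
    """Encoder-decoder with skip connections; see module docstring."""

    #: compute dtype; float64 is only useful for numerical gradient checks
    dtype = np.float32

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.base_width
        self.enc = []
        c = config.in_channels
        for d in range(config.depth):
            cw = w * 2 ** d
            self.enc.append([_Conv2x2(c, cw, rng), _ReLU(),
                             _Conv2x2(cw, cw, rng), _ReLU()])
            c = cw
        cb = w * 2 ** config.depth
        self.bottleneck = [_Conv2x2(c, cb, rng), _ReLU(),
                           _Conv2x2(cb, cb, rng), _ReLU()]
        self.dec = []
        c = cb
        for d in reversed(range(config.depth)):
            cw = w * 2 ** d
            self.dec.append({
                "up": _UpConv2x2(c, cw, rng),
                "convs": [_Conv2x2(2 * cw, cw, rng), _ReLU(),
                          _Conv2x2(cw, cw, rng), _ReLU()],
            })
            c = cw
        self.head = _Conv1x1(c, config.out_channels, rng)

    # -- plumbing ----------------------------------------------------------
    def _modules(self):
        for block in self.enc:
            yield from block
        yield from self.bottleneck
        for stage in self.dec:
            yield stage["up"]
            yield from stage["convs"]
        yield self.head

    def param_arrays(self):
        out = []
        for m in self._modules():
            if hasattr(m, "W"):
                out.append((m, "W"))
                out.append((m, "b"))
        return out

    # -- compute -----------------------------------------------------------
    def forward(self, x):
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        n, h, w, c = x.shape
        if c != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} input "
                             f"channels, got {c}")
        div = 2 ** self.config.depth
        if h % div or w % div:
            raise ValueError(f"spatial size {(h, w)} not divisible by {div}")
        skips, pool_shapes = [], []
        for block in self.enc:
            for layer in block:
                x = layer.forward(x)
            skips.append(x)
            pool_shapes.append(x.shape)
            x = _avgpool(x)
        for layer in self.bottleneck:
            x = layer.forward(x)
        self._skip_channels = []
        for stage, skip in zip(self.dec, reversed(skips)):
            x = stage["up"].forward(x)
            x = np.concatenate([skip, x], axis=3)
            self._skip_channels.append(skip.shape[3])
            for layer in stage["convs"]:
                x = layer.forward(x)
        self._pool_shapes = pool_shapes
        return self.head.forward(x)

    def backward(self, dy):
        dy = np.asarray(dy, dtype=self.dtype)
        dx = self.head.backward(dy)
        dskips = []
        for i in range(len(self.dec) - 1, -1, -1):
            stage = self.dec[i]
            for layer in reversed(stage["convs"]):
                dx = layer.backward(dx)
            cs = self._skip_channels[i]
            dskip, dup = dx[..., :cs], dx[..., cs:]
            dskips.append(dskip)
            dx = stage["up"].backward(dup)
        for layer in reversed(self.bottleneck):
            dx = layer.backward(dx)
        # dskips was filled top-stage-first, i.e. already in encoder order
        for i in range(len(self.enc) - 1, -1, -1):
            dx = _avgpool_back(dx, self._pool_shapes[i])
            dx = dx + dskips[i]
            for layer in reversed(self.enc[i]):
                dx = layer.backward(dx)
        return dx


def build_model(config: UNetConfig) -> UNet2D:
    return UNet2D(config)


def count_parameters(model: UNet2D) -> int:
    return int(sum(getattr(m, name).size for m, name in model.param_arrays()))


# ---------------------------------------------------------------------------
# training

class _Adam:
    def __init__(self, model, lr, beta1, beta2, eps=1e-8):
        self.slots = [(m, n, np.zeros_like(getattr(m, n)),
                       np.zeros_like(getattr(m, n)))
                      for m, n in model.param_arrays()]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for mod, name, m, v in self.slots:
            g = getattr(mod, "d" + name)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            upd = (self.lr / b1t) * m / (np.sqrt(v / b2t) + self.eps)
            getattr(mod, name)[...] = getattr(mod, name) - upd


def _block_downsample(img, factor):
    """Mean-pool an (H, W, C) image by an integer factor."""
    if factor == 1:
        return img
    h, w, c = img.shape
    return img.reshape(h // factor, factor, w // factor, factor, c).mean((1, 3))


@dataclass
class Sample:
    """One training pair: (H, W, t) input slice and (H, W, 1) target map."""
    x: np.ndarray
    y: np.ndarray
    subject: int


def make_dataset(stacks, gt_maps, map_name, t_stride=1):
    """Build per-slice training samples from stacks and their GT maps.

    Inputs are standardized to zero mean / unit sd over the brain mask (all
    frames pooled); targets are the normalized (0-1) maps.  Each z-slice of
    each subject becomes one 2-D sample tagged with its subject id.
    ``t_stride`` sub-samples the time axis (coarser input granularity; the
    ground-truth maps always use every frame).
    """
    samples = []
    for subject, (stack, maps) in enumerate(zip(stacks, gt_maps)):
        mask = stack.brain_mask
        vals = stack.data[mask] if mask is not None and mask.any() else stack.data
        mu, sd = float(vals.mean()), float(vals.std())
        sd = sd if sd > 0 else 1.0
        x = ((stack.data[..., ::t_stride] - mu) / sd).astype(np.float32)
        y = maps.normalized(map_name).astype(np.float32)
        for z in range(x.shape[2]):
            samples.append(Sample(x=np.ascontiguousarray(x[:, :, z, :]),
                                  y=y[:, :, z][..., None],
                                  subject=subject))
    return samples


def _epoch(model, opt, xs, ys, batch_size, rng):
    # large batches are split into cache-sized micro-batches with gradient
    # accumulation; identical semantics, ~20% faster at full resolution
    micro = 1 if xs[0].shape[0] * xs[0].shape[1] >= 64 * 64 else batch_size
    slots = model.param_arrays()
    total, count = 0.0, 0
    order = rng.permutation(len(xs))
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        n_elem = len(idx) * ys[idx[0]].size
        acc = None
        batch_loss = 0.0
        for mstart in range(0, len(idx), micro):
            midx = idx[mstart:mstart + micro]
            xb = np.stack([xs[i] for i in midx])
            yb = np.stack([ys[i] for i in midx])
            diff = model.forward(xb) - yb
            batch_loss += float(np.sum(diff ** 2))
            model.backward(2.0 * diff / n_elem)
            if acc is None and len(midx) < len(idx):
                acc = [getattr(mod, "d" + name).copy() for mod, name in slots]
            elif acc is not None:
                for a, (mod, name) in zip(acc, slots):
                    a += getattr(mod, "d" + name)
        if acc is not None:
            for a, (mod, name) in zip(acc, slots):
                setattr(mod, "d" + name, a)
        batch_loss /= n_elem
        if not np.isfinite(batch_loss):
            raise RuntimeError("training diverged: non-finite loss")
        opt.step()
        total += batch_loss * len(idx)
        count += len(idx)
    return total / count


def evaluate_mse(model, samples, batch_size=8):
    """Mean squared error of clipped predictions over a sample list."""
    total, count = 0.0, 0
    for start in range(0, len(samples), batch_size):
        batch = samples[start:start + batch_size]
        xb = np.stack([s.x for s in batch])
        yb = np.stack([s.y for s in batch])
        pred = np.clip(model.forward(xb), 0.0, 1.0)
        total += float(np.sum((pred - yb) ** 2))
        count += pred.size
    return total / count


def train(model: UNet2D, dataset, config: TrainConfig):
    """Two-stage training (sub-sampled pre-training, full-res fine-tuning).

    Returns the model and a history dict with per-epoch training MSE for
    both stages.  Fully deterministic given ``config.seed`` and the model's
    init seed.
    """
    cfg = config
    if not dataset:
        raise ValueError("empty dataset")
    ys_full = [s.y for s in dataset]
    for y in ys_full:
        if y.min() < 0 or y.max() > 1:
            raise ValueError("targets must be normalized to [0, 1]")
    if cfg.init_output_bias:
        model.head.W[...] = 0.0
        model.head.b[...] = np.float32(np.mean([y.mean() for y in ys_full]))

    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model, cfg.lr, cfg.beta1, cfg.beta2)
    history = {"pretrain": [], "finetune": [], "lr": []}

    size = dataset[0].x.shape[0]
    pre_size = cfg.pretrain_size or max(size // 4, 2 ** model.config.depth)
    factor = size // pre_size

    stages = []
    if cfg.pretrain_epochs > 0 and factor > 1:
        xs = [_block_downsample(s.x, factor) for s in dataset]
        ys = [_block_downsample(s.y, factor) for s in dataset]
        stages.append(("pretrain", xs, ys, cfg.pretrain_epochs))
    elif cfg.pretrain_epochs > 0:
        stages.append(("pretrain", [s.x for s in dataset], ys_full,
                       cfg.pretrain_epochs))
    stages.append(("finetune", [s.x for s in dataset], ys_full,
                   cfg.finetune_epochs))

    best, since_best = np.inf, 0
    for stage, xs, ys, n_epochs in stages:
        for _ in range(n_epochs):
            loss = _epoch(model, opt, xs, ys, cfg.batch_size, rng)
            history[stage].append(loss)
            history["lr"].append(opt.lr)
            if cfg.plateau_decay is not None:
                if loss < best * (1 - 1e-4):
                    best, since_best = loss, 0
                else:
                    since_best += 1
                    if since_best >= cfg.plateau_patience:
                        opt.lr *= cfg.plateau_decay
                        since_best = 0
    return model, history


def save_model(model: UNet2D, path):
    """Checkpoint: config fields + all weight arrays in one ``.npz``."""
    import dataclasses as _dc
    arrays = {f"p{i}": getattr(m, n)
              for i, (m, n) in enumerate(model.param_arrays())}
    arrays["_config"] = np.array(
        [list(_dc.asdict(model.config).items())], dtype=object)
    np.savez(path, **arrays)


def load_model(path) -> UNet2D:
    with np.load(path, allow_pickle=True) as data:
        cfg = UNetConfig(**dict(data["_config"][0]))
        model = build_model(cfg)
        for i, (m, n) in enumerate(model.param_arrays()):
            getattr(m, n)[...] = data[f"p{i}"]
    return model


def predict(model: UNet2D, x) -> np.ndarray:
    """Predict one normalized map per input; values clipped to [0, 1].

    ``x`` is an (H, W, t) slice or an (N, H, W, t) batch; returns the same
    leading shape with a trailing singleton channel.
    """
    single = np.asarray(x).ndim == 3
    out = np.clip(model.forward(x), 0.0, 1.0)
    return out[0] if single else out


def predict_volume(model: UNet2D, stack, t_stride=1) -> np.ndarray:
    """Predict a normalized 3-D map slice-by-slice from a standardized stack."""
    mask = stack.brain_mask
    vals = stack.data[mask] if mask is not None and mask.any() else stack.data
    mu, sd = float(vals.mean()), float(vals.std())
    sd = sd if sd > 0 else 1.0
    x = ((stack.data[..., ::t_stride] - mu) / sd).astype(np.float32)
    slices = np.ascontiguousarray(np.moveaxis(x, 2, 0))  # (Z, H, W, t)
    out = predict(model, slices)
    return np.moveaxis(out[..., 0], 0, 2)


def threefold_cv(dataset, model_config: UNetConfig, train_config: TrainConfig,
                 seed: int = 0, n_folds: int = 3):
    """Subject-wise k-fold cross-validation (never splits within a subject).

    Subjects are shuffled (seeded) and partitioned into ``n_folds`` groups;
    each group serves once as the validation fold.  Returns a list of
    :class:`FoldResult` with final train/val MSE and loss curves.
    """
    subjects = sorted({s.subject for s in dataset})
    if len(subjects) < n_folds:
        raise ValueError(f"need at least {n_folds} subjects, "
                         f"got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    folds = [sorted(np.asarray(subjects)[order[i::n_folds]].tolist())
             for i in range(n_folds)]

    results = []
    for i, val_subjects in enumerate(folds):
        val_set = set(val_subjects)
        train_samples = [s for s in dataset if s.subject not in val_set]
        val_samples = [s for s in dataset if s.subject in val_set]
        model = build_model(replace(model_config,
                                    seed=model_config.seed + 1000 * i))
        model, history = train(model, train_samples,
                               replace(train_config,
                                       seed=train_config.seed + 1000 * i))
        results.append(FoldResult(
            fold=i,
            train_mse=evaluate_mse(model, train_samples),
            val_mse=evaluate_mse(model, val_samples),
            history=history,
            val_subjects=tuple(val_subjects),
            model=model))
    return results
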