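"""Dual-branch residual network for read-level m6A probability.

Each enabled branch processes one feature matrix: the raw-signal branch a
``5 x 325`` matrix (stem: 1-D conv, 32 channels, kernel 7, then max
pooling), the basecalling-error branch an ``8 x 5`` matrix (stem: 32
channels, kernel 3, then max pooling).  Both branches then pass through
four residual blocks of four convolutional layers each, with output
channels 32, 64, 128 and 256 and batch normalization + ReLU around every
convolution, followed by global average pooling.  The pooled branch
outputs are concatenated, flattened and fed to a fully connected head with
two hidden layers; the single output x becomes the read-level methylation
probability through the logistic function

    Pr = 1 / (1 + exp(-x)).

The raw-signal branch halves its temporal length at the entry of blocks
2-4 (stride-2 first convolution, matched by a stride-2 1x1 projection on
the skip path); the error branch, whose length is only 5, never
downsamples below length 1.  Ablation variants enable a single branch via
``ModelConfig.branch_enable``.

Training minimizes binary cross-entropy on read-level labels with Adam,
early-stops on validation loss and restores the best checkpoint; it is
fully seeded and reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from m6aduet import nn
from m6aduet.features import SiteReadFeatures, stack_features

logger = logging.getLogger(__name__)

BRANCHES = ("raw_signal", "error")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    ``branch_enable`` selects which feature branches exist -- both by
    default; single-branch configurations are the ablation variants.
    ``block_channels`` are the per-residual-block output channels and must
    be strictly increasing.
    """

    branch_enable: tuple[str, ...] = ("raw_signal", "error")
    block_channels: tuple[int, ...] = (32, 64, 128, 256)
    convs_per_block: int = 4
    stem_raw_channels: int = 32
    stem_raw_kernel: int = 7
    stem_error_channels: int = 32
    stem_error_kernel: int = 3
    raw_block_strides: tuple[int, ...] = (1, 2, 2, 2)
    head_hidden: tuple[int, ...] = (128, 32)
    L: int = 65
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 8
    patience: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.branch_enable:
            raise ValueError("branch_enable must not be empty")
        unknown = set(self.branch_enable) - set(BRANCHES)
        if unknown:
            raise ValueError(f"unknown branches {sorted(unknown)}; valid: {BRANCHES}")
        if len(self.block_channels) != 4 or any(
            a >= b for a, b in zip(self.block_channels, self.block_channels[1:])
        ):
            raise ValueError("block_channels must be strictly increasing, length 4")
        if len(self.raw_block_strides) != len(self.block_channels):
            raise ValueError("raw_block_strides must match block_channels in length")
        if self.convs_per_block < 2:
            raise ValueError("convs_per_block must be >= 2")
        if len(self.head_hidden) != 2:
            raise ValueError("head has exactly two hidden layers")
        if self.learning_rate <= 0 or self.batch_size < 2 or self.epochs < 1:
            raise ValueError("invalid optimizer parameters")


@dataclass(frozen=True)
class ReadLevelPrediction:
    """Per-(site, read) methylation probability Pr."""

    transcript_id: str
    position: int
    read_id: str
    pr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pr <= 1.0:
            raise ValueError(f"pr = {self.pr} outside [0, 1]")


class _ResidualBlock(nn.Layer):
    """conv-BN-ReLU x (n-1), conv-BN, + skip, ReLU; 1x1 projection on the
    skip path whenever channels or stride change."""

    def __init__(self, in_ch: int, out_ch: int, n_convs: int, stride: int, *,
                 rng: np.random.Generator):
        self.convs = [
            nn.Conv1d(in_ch if i == 0 else out_ch, out_ch, 3,
                      stride if i == 0 else 1, rng=rng)
            for i in range(n_convs)
        ]
        self.bns = [nn.BatchNorm1d(out_ch) for _ in range(n_convs)]
        self.relus = [nn.ReLU() for _ in range(n_convs - 1)]
        self.proj = (
            nn.Conv1d(in_ch, out_ch, 1, stride, rng=rng)
            if (in_ch != out_ch or stride != 1)
            else None
        )

    def params(self) -> list[nn.Param]:
        out = []
        for conv, bn in zip(self.convs, self.bns):
            out += conv.params() + bn.params()
        if self.proj is not None:
            out += self.proj.params()
        return out

    def batchnorms(self) -> list[nn.BatchNorm1d]:
        return list(self.bns)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = x
        n = len(self.convs)
        for i in range(n):
            h = self.bns[i].forward(self.convs[i].forward(h, train), train)
            if i < n - 1:
                h = self.relus[i].forward(h, train)
        identity = self.proj.forward(x, train) if self.proj is not None else x
        pre = h + identity
        if train:
            self._mask = pre > 0
        return np.maximum(pre, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._mask
        g_skip = self.proj.backward(g) if self.proj is not None else g
        g_main = g
        n = len(self.convs)
        for i in reversed(range(n)):
            if i < n - 1:
                g_main = self.relus[i].backward(g_main)
            g_main = self.convs[i].backward(self.bns[i].backward(g_main))
        return g_main + g_skip


class _Branch(nn.Layer):
    def __init__(self, in_ch: int, stem_ch: int, stem_kernel: int,
                 block_channels: Sequence[int], convs_per_block: int,
                 strides: Sequence[int], *, rng: np.random.Generator):
        self.stem = nn.Conv1d(in_ch, stem_ch, stem_kernel, rng=rng)
        self.stem_relu = nn.ReLU()
        self.pool = nn.MaxPool1d(2)
        self.blocks = []
        prev = stem_ch
        for ch, st in zip(block_channels, strides):
            self.blocks.append(_ResidualBlock(prev, ch, convs_per_block, st, rng=rng))
            prev = ch
        self.gap = nn.GlobalAvgPool1d()

    def params(self) -> list[nn.Param]:
        out = self.stem.params()
        for b in self.blocks:
            out += b.params()
        return out

    def batchnorms(self) -> list[nn.BatchNorm1d]:
        return [bn for b in self.blocks for bn in b.batchnorms()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.pool.forward(self.stem_relu.forward(self.stem.forward(x, train), train), train)
        for b in self.blocks:
            h = b.forward(h, train)
        return self.gap.forward(h, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.gap.backward(grad)
        for b in reversed(self.blocks):
            g = b.backward(g)
        return self.stem.backward(self.stem_relu.backward(self.pool.backward(g)))


class DualResNet:
    """The read-level classifier; see module docstring for the architecture."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x6D6F64]))
        self.branches: dict[str, _Branch] = {}
        if "raw_signal" in cfg.branch_enable:
            self.branches["raw_signal"] = _Branch(
                5, cfg.stem_raw_channels, cfg.stem_raw_kernel, cfg.block_channels,
                cfg.convs_per_block, cfg.raw_block_strides, rng=rng,
            )
        if "error" in cfg.branch_enable:
            self.branches["error"] = _Branch(
                8, cfg.stem_error_channels, cfg.stem_error_kernel, cfg.block_channels,
                cfg.convs_per_block, [1] * len(cfg.block_channels), rng=rng,
            )
        feat_dim = cfg.block_channels[-1] * len(self.branches)
        h1, h2 = cfg.head_hidden
        self.head = nn.Sequential(
            nn.Linear(feat_dim, h1, rng=rng),
            nn.ReLU(),
            nn.Linear(h1, h2, rng=rng),
            nn.ReLU(),
            nn.Linear(h2, 1, rng=rng),
        )

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for name in BRANCHES:
            if name in self.branches:
                out += self.branches[name].params()
        return out + self.head.params()

    def batchnorms(self) -> list[nn.BatchNorm1d]:
        return [bn for name in BRANCHES if name in self.branches
                for bn in self.branches[name].batchnorms()]

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.params()]
        for bn in self.batchnorms():
            arrays += [bn.running_mean, bn.running_var]
        return arrays

    def set_state(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.params()
        bns = self.batchnorms()
        if len(arrays) != len(params) + 2 * len(bns):
            raise ValueError("state array count does not match this architecture")
        for p, a in zip(params, arrays):
            p.value = a.astype(np.float32).reshape(p.value.shape)
        rest = arrays[len(params):]
        for bn, mean, var in zip(bns, rest[0::2], rest[1::2]):
            bn.running_mean = mean.astype(np.float32)
            bn.running_var = var.astype(np.float32)

    def snapshot(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    # -- forward / backward -------------------------------------------------

    def _check_shapes(self, raw: np.ndarray | None, err: np.ndarray | None) -> None:
        if "raw_signal" in self.branches:
            if raw is None:
                raise ValueError("model expects the raw-signal matrix")
            if raw.ndim != 3 or raw.shape[1] != 5 or raw.shape[2] != 5 * self.cfg.L:
                raise ValueError(
                    f"raw-signal matrix must be (n, 5, {5 * self.cfg.L}); got {raw.shape}"
                )
        if "error" in self.branches:
            if err is None:
                raise ValueError("model expects the basecalling-error matrix")
            if err.ndim != 3 or err.shape[1:] != (8, 5):
                raise ValueError(f"error matrix must be (n, 8, 5); got {err.shape}")

    def forward_logits(self, raw: np.ndarray | None, err: np.ndarray | None,
                       train: bool = False) -> np.ndarray:
        self._check_shapes(raw, err)
        outs = []
        if "raw_signal" in self.branches:
            outs.append(self.branches["raw_signal"].forward(raw.astype(np.float32), train))
        if "error" in self.branches:
            outs.append(self.branches["error"].forward(err.astype(np.float32), train))
        z = np.concatenate(outs, axis=1)
        self._split = [o.shape[1] for o in outs]
        return self.head.forward(z, train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits[:, None])
        offset = 0
        parts = []
        for width in self._split:
            parts.append(g[:, offset : offset + width])
            offset += width
        i = 0
        if "raw_signal" in self.branches:
            self.branches["raw_signal"].backward(parts[i])
            i += 1
        if "error" in self.branches:
            self.branches["error"].backward(parts[i])

    def predict_proba(self, raw: np.ndarray | None, err: np.ndarray | None,
                      batch_size: int = 256) -> np.ndarray:
        n = raw.shape[0] if raw is not None else err.shape[0]
        out = np.empty(n, dtype=np.float64)
        for lo in range(0, n, batch_size):
            hi = min(lo + batch_size, n)
            logits = self.forward_logits(
                raw[lo:hi] if raw is not None else None,
                err[lo:hi] if err is not None else None,
                train=False,
            )
            out[lo:hi] = nn.sigmoid(logits)
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save weights + config to an ``.npz`` checkpoint."""
        payload = {f"arr_{i}": a for i, a in enumerate(self.state_arrays())}
        payload["config_json"] = np.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8
        )
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str | Path) -> "DualResNet":
        with np.load(path) as data:
            cfg_dict = json.loads(bytes(data["config_json"]).decode())
            for key in ("branch_enable", "block_channels", "raw_block_strides", "head_hidden"):
                cfg_dict[key] = tuple(cfg_dict[key])
            cfg = ModelConfig(**cfg_dict)
            model = cls(cfg)
            n = len(model.params()) + 2 * len(model.batchnorms())
            model.set_state([data[f"arr_{i}"] for i in range(n)])
        return model


def build_model(cfg: ModelConfig) -> DualResNet:
    """Construct the network; deterministic parameter layout and count for a
    given config."""
    return DualResNet(cfg)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingResult:
    """Per-epoch log, the best checkpoint and headline validation metrics."""

    log: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    best_val_auc: float = float("nan")
    n_train: int = 0
    n_val: int = 0

    def summary(self) -> str:
        lines = [
            "Read-level classifier training",
            f"  train examples: {self.n_train}   validation examples: {self.n_val}",
            f"  epochs run: {len(self.log)}   best epoch: {self.best_epoch}",
            f"  best val loss: {self.best_val_loss:.4f}   val AUC at best: {self.best_val_auc:.4f}",
        ]
        return "\n".join(lines)

    def write_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\ttrain_loss\tval_loss\tval_auc\n")
            for row in self.log:
                fh.write(
                    f"{row['epoch']}\t{row['train_loss']:.6f}\t"
                    f"{row['val_loss']:.6f}\t{row['val_auc']:.6f}\n"
                )


def _as_arrays(feats, require_labels: bool):
    if isinstance(feats, tuple) and len(feats) == 3:
        raw, err, y = feats
        return (None if raw is None else np.asarray(raw, np.float32),
                None if err is None else np.asarray(err, np.float32),
                None if y is None else np.asarray(y))
    _, raw, err, y = stack_features(feats)
    if require_labels and (y < 0).any():
        raise ValueError("all training/validation records must carry labels")
    return raw, err, y


def train_model(
    model: DualResNet,
    train_feats,
    val_feats,
    *,
    verbose: bool = False,
) -> TrainingResult:
    """Train the classifier on labeled read-level features.

    ``train_feats`` / ``val_feats`` are either iterables of
    :class:`SiteReadFeatures` (with labels) or pre-stacked
    ``(raw, err, labels)`` tuples.  Optimizes binary cross-entropy with
    Adam, logs per-epoch train/validation loss and validation AUC, early
    stops on validation loss (``cfg.patience``) and restores the best
    checkpoint.  Fully seeded via ``cfg.seed``.
    """
    cfg = model.cfg
    raw_tr, err_tr, y_tr = _as_arrays(train_feats, require_labels=True)
    raw_va, err_va, y_va = _as_arrays(val_feats, require_labels=True)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set contains a single class; refusing to train")
    use_raw = "raw_signal" in model.branches
    use_err = "error" in model.branches

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7472]))
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    result = TrainingResult(n_train=len(y_tr), n_val=len(y_va))
    best_state = model.snapshot()
    stall = 0

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(y_tr))
        losses, weights = [], []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            if idx.size < 2:  # batch statistics need >= 2 examples
                continue
            opt.zero_grad()
            logits = model.forward_logits(
                raw_tr[idx] if use_raw else None,
                err_tr[idx] if use_err else None,
                train=True,
            )
            loss, dlogits = nn.bce_with_logits(logits, y_tr[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            weights.append(idx.size)
        train_loss = float(np.average(losses, weights=weights))

        val_probs = model.predict_proba(
            raw_va if use_raw else None, err_va if use_err else None
        )
        eps = 1e-12
        val_loss = float(
            -np.mean(y_va * np.log(val_probs + eps) + (1 - y_va) * np.log(1 - val_probs + eps))
        )
        val_auc = (
            float(roc_auc_score(y_va, val_probs)) if len(np.unique(y_va)) > 1 else float("nan")
        )
        result.log.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "val_auc": val_auc}
        )
        if verbose:
            logger.info(
                "epoch %d: train_loss=%.4f val_loss=%.4f val_auc=%.4f",
                epoch, train_loss, val_loss, val_auc,
            )
        if val_loss < result.best_val_loss:
            result.best_val_loss = val_loss
            result.best_val_auc = val_auc
            result.best_epoch = epoch
            best_state = model.snapshot()
            stall = 0
        else:
            stall += 1
            if stall > cfg.patience:
                break

    model.set_state(best_state)
    return result


def predict_read_level(
    model: DualResNet, features: Iterable[SiteReadFeatures]
) -> list[ReadLevelPrediction]:
    """Score a stream of feature records; one prediction per record, in
    input order, deterministic for fixed weights."""
    feats = list(features)
    if not feats:
        return []
    keys, raw, err, _ = stack_features(feats)
    probs = model.predict_proba(
        raw if "raw_signal" in model.branches else None,
        err if "error" in model.branches else None,
    )
    return [
        ReadLevelPrediction(tx, pos, rid, float(p))
        for (tx, pos, rid), p in zip(keys, probs)
    ]
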