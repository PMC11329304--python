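"""Training loops and cross-validation splitting.

Both stages train the same way: Adam on the soft dice loss, shuffled
mini-batches (default batch size 2, learning rate 1e-4), optional seeded
geometric augmentation.  Presegmenters consume (image, mask) pairs; the
cascade second stage consumes (image, saliency, mask) triples.  Everything
randomized — shuffling, augmentation draws, weight init — is driven by
explicit seeds so identical configs reproduce identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .networks import CascadeAttentionUNet, UNet
from .preprocess import augment_pair

__all__ = ["TrainConfig", "train_model", "kfold_split", "FoldSplit"]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 2
    epochs: int = 10
    seed: int = 0
    augment: bool = False
    threshold: float = 0.5
    dice_eps: float = 1e-6

    def validate(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")


@dataclass
class FoldSplit:
    k: int
    assignments: dict[str, int]

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignments.items() if f != fold]


def kfold_split(ids: list[str], k: int, seed: int = 0) -> FoldSplit:
    """Seeded shuffle then round-robin fold assignment; fold sizes differ by
    at most one."""
    ids = list(ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of ids ({len(ids)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    assignments = {ids[idx]: i % k for i, idx in enumerate(order)}
    return FoldSplit(k=k, assignments=assignments)


def _stack_batch(samples, augment: bool, rng: np.random.Generator):
    """samples: list of (image HWC, [saliency HW,] mask HW) tuples ->
    batched NCHW arrays."""
    imgs, sals, masks = [], [], []
    has_sal = len(samples[0]) == 3
    for s in samples:
        if has_sal:
            img, sal, msk = s
        else:
            img, msk = s
            sal = None
        if augment:
            seed = int(rng.integers(0, 2 ** 31))
            stacked = np.concatenate(
                [np.atleast_3d(img)] + ([sal[..., None]] if sal is not None else []),
                axis=-1)
            aug, msk = augment_pair(stacked, msk, params=None, seed=seed)
            if sal is not None:
                img, sal = aug[..., :-1], aug[..., -1]
            else:
                img = aug
        imgs.append(np.atleast_3d(img).transpose(2, 0, 1))
        masks.append(np.asarray(msk, dtype=np.float32)[None])
        if sal is not None:
            sals.append(np.asarray(sal, dtype=np.float32)[None])
    batch_img = np.stack(imgs).astype(np.float32)
    batch_msk = np.stack(masks).astype(np.float32)
    batch_sal = np.stack(sals).astype(np.float32) if sals else None
    return batch_img, batch_sal, batch_msk


def train_model(model, dataset: list, config: TrainConfig):
    """Train a presegmenter or cascade model on an in-memory dataset.

    ``dataset``: list of (image, mask) or (image, saliency, mask) tuples in
    HWC/HW [0,1] layout.  Returns ``(model, history)`` where history is the
    per-epoch mean training dice loss.  ``epochs=0`` returns the model
    untouched with an empty history.
    """
    config.validate()
    if not dataset:
        raise ValueError("empty dataset")
    is_cascade = isinstance(model, CascadeAttentionUNet) and model.with_psa
    if is_cascade and len(dataset[0]) != 3:
        raise ValueError("cascade training requires (image, saliency, mask) triples")

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history: list[float] = []
    model.train()
    n = len(dataset)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = [dataset[i] for i in order[start:start + config.batch_size]]
            img, sal, msk = _stack_batch(batch, config.augment, rng)
            x = nn.Tensor(img)
            if is_cascade:
                prob = model.forward(x, nn.Tensor(sal))
            elif isinstance(model, (UNet, CascadeAttentionUNet)):
                prob = model.forward(x)
            else:
                raise TypeError(f"unsupported model type {type(model)!r}")
            loss = nn.dice_loss_tensor(prob, msk, eps=config.dice_eps)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return model, history
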