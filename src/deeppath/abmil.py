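"""Gated-attention multiple-instance classifier for immune-metabolic subtypes.

A slide is a bag of patch embeddings h_i. Each instance receives an attention
logit

    e_i = w^T ( tanh(U h_i) * sigmoid(V h_i) )

where * is the elementwise product; a = softmax(e) are nonnegative weights
summing to one, and the bag representation z = sum_i a_i h_i is a weighted
average of instances, invariant to instance order and to duplication of the
whole bag. The sigmoid gate modulates the tanh pathway, adding a learnable
nonlinearity to the attention scores. A linear head on z produces the 4-class
subtype probabilities, and the attention weights themselves yield per-patch
heatmaps.

Training runs Monte Carlo cross-validation: repeated stratified random splits
(default 5), each optimizing the embedding layer, attention and classifier
head with Adam on cross-entropy (patch features stay frozen, having been
extracted once by the backbone).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedShuffleSplit

from . import _autodiff as ad
from ._autodiff import Tensor
from .embedding import FeatureBag
from .slide_prep import SlideRaster

__all__ = [
    "SUBTYPES",
    "GatedAttentionParams",
    "AttentionOutput",
    "SubtypeProbs",
    "TrainConfig",
    "gated_attention",
    "MILSubtypeModel",
    "classify_bag",
    "train_subtype_model",
    "per_class_roc",
    "attention_heatmap",
]

SUBTYPES = ("iFA", "iAA", "iGlu", "iFolate")


@dataclass
class GatedAttentionParams:
    """Gated-attention parameters: U, V map M-dim instances to the L-dim
    attention space; w scores the gated activation."""

    U: np.ndarray  # L_att x M
    V: np.ndarray  # L_att x M
    w: np.ndarray  # L_att

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=np.float64)
        self.V = np.asarray(self.V, dtype=np.float64)
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.U.shape != self.V.shape or self.U.shape[0] != self.w.shape[0]:
            raise ValueError("inconsistent attention parameter shapes")
        for a in (self.U, self.V, self.w):
            if not np.isfinite(a).all():
                raise ValueError("attention parameters must be finite")

    @staticmethod
    def random(l_att: int, m: int, rng: np.random.Generator) -> "GatedAttentionParams":
        s = 1.0 / np.sqrt(m)
        return GatedAttentionParams(
            U=rng.normal(0, s, (l_att, m)),
            V=rng.normal(0, s, (l_att, m)),
            w=rng.normal(0, 1.0 / np.sqrt(l_att), l_att),
        )


@dataclass
class AttentionOutput:
    a: np.ndarray  # N attention weights, sum to 1
    z: np.ndarray  # bag representation, sum_i a_i h_i


def _gated_attention_core(H, Ut, Vt, w):
    """Shared forward (ndarray or autodiff Tensor). Ut, Vt are M x L_att."""
    gate = ad.tanh(H @ Ut) * ad.sigmoid(H @ Vt)
    logits = gate @ w  # (..., N)
    a = ad.softmax(logits, axis=-1)
    if isinstance(a, Tensor) or isinstance(H, Tensor):
        B = a.shape[:-1]
        n = a.shape[-1]
        z = (a.reshape(*B, 1, n) @ H).reshape(*B, H.shape[-1]) if B else a @ H
    else:
        z = np.einsum("...n,...nm->...m", a, H)
    return a, z


def gated_attention(H: np.ndarray, p: GatedAttentionParams) -> AttentionOutput:
    """Attention-pool a bag: a_i = softmax_i w^T(tanh(U h_i) * sigmoid(V h_i)),
    z = sum_i a_i h_i."""
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("H must be a non-empty N x M matrix")
    if H.shape[1] != p.U.shape[1]:
        raise ValueError(
            f"embedding dim mismatch: H has M={H.shape[1]}, params expect M={p.U.shape[1]}"
        )
    a, z = _gated_attention_core(H, p.U.T, p.V.T, p.w)
    return AttentionOutput(a=a, z=z)


@dataclass
class SubtypeProbs:
    probs: np.ndarray  # 4 probabilities over SUBTYPES

    @property
    def label(self) -> str:
        return SUBTYPES[int(np.argmax(self.probs))]

    def as_dict(self) -> dict:
        return dict(zip(SUBTYPES, self.probs.tolist()))


@dataclass
class TrainConfig:
    folds: int = 5
    epochs: int = 150
    lr: float = 1e-3
    weight_decay: float = 1e-2
    seed: int = 0
    embed_dim: int = 512
    att_dim: int = 256
    val_frac: float = 0.2
    batch_size: int = 8
    patience: int = 10

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


class MILSubtypeModel:
    """Embedding layer + gated attention + linear 4-class head."""

    def __init__(self, in_dim: int, embed_dim: int = 512, att_dim: int = 256,
                 n_classes: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_dim, self.embed_dim, self.att_dim = in_dim, embed_dim, att_dim
        self.n_classes = n_classes

        def lin(m, n):
            return Tensor.param(rng.normal(0, 1.0 / np.sqrt(m), (m, n)))

        self.We, self.be = lin(in_dim, embed_dim), Tensor.param(np.zeros(embed_dim))
        self.Ut, self.Vt = lin(embed_dim, att_dim), lin(embed_dim, att_dim)
        self.w = Tensor.param(rng.normal(0, 1.0 / np.sqrt(att_dim), att_dim))
        self.Wc, self.bc = lin(embed_dim, n_classes), Tensor.param(np.zeros(n_classes))

    def parameters(self):
        return [self.We, self.be, self.Ut, self.Vt, self.w, self.Wc, self.bc]

    def _np(self, t):
        return t.data if isinstance(t, Tensor) else t

    def forward(self, H, train: bool = False):
        """H: (N, M) or batched (B, N, M). Returns (probs, a, z)."""
        We, be = (self.We, self.be) if train else (self.We.data, self.be.data)
        Ut, Vt, w = ((self.Ut, self.Vt, self.w) if train
                     else (self.Ut.data, self.Vt.data, self.w.data))
        Wc, bc = (self.Wc, self.bc) if train else (self.Wc.data, self.bc.data)
        h = ad.relu(H @ We + be)
        a, z = _gated_attention_core(h, Ut, Vt, w)
        probs = ad.softmax(z @ Wc + bc, axis=-1)
        return probs, a, z

    def predict_bag(self, H: np.ndarray):
        H = np.asarray(H, dtype=np.float64)
        if H.ndim != 2 or len(H) == 0:
            raise ValueError("bag must be a non-empty N x M matrix")
        if H.shape[1] != self.in_dim:
            raise ValueError(f"bag feature dim {H.shape[1]} != model in_dim {self.in_dim}")
        probs, a, z = self.forward(H, train=False)
        return probs, a, z


def classify_bag(bag: FeatureBag, model: MILSubtypeModel) -> SubtypeProbs:
    """Deterministic subtype probabilities for one feature bag."""
    if len(bag) == 0:
        raise ValueError("cannot classify an empty bag")
    probs, _, _ = model.predict_bag(bag.H)
    return SubtypeProbs(probs=np.asarray(probs, dtype=np.float64))


def bag_attention(bag: FeatureBag, model: MILSubtypeModel) -> AttentionOutput:
    probs, a, z = model.predict_bag(bag.H)
    return AttentionOutput(a=np.asarray(a), z=np.asarray(z))


@dataclass
class FoldMetrics:
    fold: int
    aucs: dict
    mean_auc: float
    val_idx: np.ndarray = field(repr=False, default=None)


@dataclass
class TrainResult:
    model: MILSubtypeModel
    folds: list
    best_fold: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.mean_auc for f in self.folds]))

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            row = {"fold": f.fold, "mean_auc": f.mean_auc}
            row.update({f"auc_{k}": v for k, v in f.aucs.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def _val_loss(bags, y, idx, model: MILSubtypeModel) -> float:
    tot = 0.0
    for i in idx:
        probs, _, _ = model.forward(bags[i].H.astype(np.float64), train=False)
        tot -= np.log(probs[y[i]] + 1e-12)
    return tot / len(idx)


def _train_one(bags, y, train_idx, val_idx, model: MILSubtypeModel, cfg: TrainConfig,
               rng: np.random.Generator) -> None:
    """Adam on cross-entropy with early stopping on validation loss;
    equal-size bags are stacked into batched matmuls."""
    opt = ad.Adam(model.parameters(), lr=cfg.lr)
    # group training bags by size so each mini-batch stacks to (B, N, M)
    by_size: dict[int, list[int]] = {}
    for i in train_idx:
        by_size.setdefault(len(bags[i]), []).append(i)
    best_loss, best_state, since_best = np.inf, None, 0
    for _ in range(cfg.epochs):
        batches = []
        for idxs in by_size.values():
            idxs = np.asarray(idxs)
            rng.shuffle(idxs)
            for s in range(0, len(idxs), cfg.batch_size):
                batches.append(idxs[s : s + cfg.batch_size])
        order = rng.permutation(len(batches))
        for bi in order:
            idx = batches[bi]
            H = np.stack([bags[i].H.astype(np.float64) for i in idx])
            yy = y[idx]
            probs, _, _ = model.forward(H, train=True)
            logp = ad.log(probs + 1e-12)
            loss = -(logp[np.arange(len(idx)), yy]).mean()
            opt.zero_grad()
            loss.backward()
            if cfg.weight_decay:
                for p in model.parameters():
                    p.grad = (p.grad if p.grad is not None else 0.0) \
                        + 2.0 * cfg.weight_decay * p.data
            opt.step()
        vloss = _val_loss(bags, y, val_idx, model)
        if vloss < best_loss - 1e-6:
            best_loss, since_best = vloss, 0
            best_state = [p.data.copy() for p in model.parameters()]
        else:
            since_best += 1
            if cfg.patience and since_best >= cfg.patience:
                break
    if best_state is not None:
        for p, s in zip(model.parameters(), best_state):
            p.data = s


def train_subtype_model(bags: list, cfg: TrainConfig | None = None,
                        labels: list | None = None) -> TrainResult:
    """Monte Carlo cross-validated training of the MIL subtype classifier.

    Labels come from ``bag.label`` unless given explicitly. Each of ``folds``
    repeats draws a stratified random train/validation split; per-class
    one-vs-rest AUCs are computed on the validation bags and the model from
    the best fold (highest mean validation AUC) is returned.
    """
    cfg = cfg or TrainConfig()
    if labels is None:
        labels = [b.label for b in bags]
    classes = sorted(set(labels), key=lambda c: SUBTYPES.index(c) if c in SUBTYPES else str(c))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    y = np.asarray([classes.index(l) for l in labels])
    in_dim = bags[0].H.shape[1]

    splitter = StratifiedShuffleSplit(n_splits=cfg.folds, test_size=cfg.val_frac,
                                      random_state=cfg.seed)
    folds, models = [], []
    for fold, (tr, va) in enumerate(splitter.split(np.zeros(len(y)), y)):
        if len(set(y[tr])) < len(classes):
            raise ValueError(
                "a class is absent from a training split; provide more data or fewer folds"
            )
        rng = np.random.default_rng(cfg.seed + 1000 * fold + 1)
        model = MILSubtypeModel(in_dim, cfg.embed_dim, cfg.att_dim,
                                n_classes=len(classes), seed=cfg.seed + fold)
        _train_one(bags, y, tr, va, model, cfg, rng)
        scores = np.stack([np.asarray(model.predict_bag(bags[i].H)[0]) for i in va])
        aucs = {}
        for ci, cname in enumerate(classes):
            yv = (y[va] == ci).astype(int)
            if yv.min() == yv.max():
                continue
            fpr, tpr, _ = roc_curve(yv, scores[:, ci])
            aucs[cname] = float(_sk_auc(fpr, tpr))
        mean_auc = float(np.mean(list(aucs.values()))) if aucs else float("nan")
        folds.append(FoldMetrics(fold=fold, aucs=aucs, mean_auc=mean_auc, val_idx=va))
        models.append(model)
    best = int(np.nanargmax([f.mean_auc for f in folds]))
    return TrainResult(model=models[best], folds=folds, best_fold=best)


def per_class_roc(scores: np.ndarray, labels: np.ndarray):
    """One-vs-rest ROC curves and AUCs.

    ``scores``: (n, C) class scores; ``labels``: integer class per sample.
    AUC equals the normalized Mann-Whitney count of concordant score pairs.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    out = {}
    for ci in range(scores.shape[1]):
        yv = (labels == ci).astype(int)
        if yv.min() == yv.max():
            raise ValueError(f"class {ci}: need both positives and negatives for ROC")
        fpr, tpr, thr = roc_curve(yv, scores[:, ci])
        out[ci] = {"fpr": fpr, "tpr": tpr, "auc": float(_sk_auc(fpr, tpr))}
    return out


# navy (low attention) -> crimson (high attention)
_NAVY = np.array([0.0, 0.0, 0.5])
_CRIMSON = np.array([0.863, 0.078, 0.235])


def attention_heatmap(slide: SlideRaster, bag: FeatureBag, a: np.ndarray,
                      patch_size: int, alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend a navy-to-crimson attention overlay onto patch footprints.

    Attention is min-max scaled to [0, 1] across the bag (uniform attention
    maps to mid-scale 0.5); pixels outside any patch footprint are untouched.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    if len(a) != len(bag):
        raise ValueError("attention length must match bag size")
    H, W = slide.shape
    if ((bag.coords[:, 0] < 0).any() or (bag.coords[:, 1] < 0).any()
            or (bag.coords[:, 0] + patch_size > W).any()
            or (bag.coords[:, 1] + patch_size > H).any()):
        raise ValueError("patch coordinates fall outside the slide")
    span = a.max() - a.min()
    scaled = (a - a.min()) / span if span > 0 else np.full_like(a, 0.5)
    out = slide.pixels.astype(np.float64).copy()
    for (x, y), s in zip(bag.coords, scaled):
        color = (1 - s) * _NAVY + s * _CRIMSON
        tile = out[y : y + patch_size, x : x + patch_size]
        out[y : y + patch_size, x : x + patch_size] = (
            (1 - alpha) * tile + alpha * color[None, None, :] * 255.0
        )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
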