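"""Query-routed multimodal fusion and survival risk head.

Each modality (pathology bag representation, lncRNA panel expression, 28
immune-cell enrichment scores, encoded clinical covariates) is encoded into a
short sequence of tokens. A learned query-router decides, per token, whether
it keeps its place in the attention query pathway:

    Q_emb_out = Q_in + Q_in * MLP(mean of active tokens)     (residual)
    r        = row-softmax(MLP(Q_emb_out))  in R^{L x 2},  r = [alpha, 1-alpha]

Binary routes R in {0,1}^L are drawn from r with the Gumbel-Softmax trick
(temperature tau; hard straight-through sampling keeps gradients flowing
through the relaxed sample). Routes start at all-ones and are hierarchical:
a token dropped at one routing block stays dropped in every later block.
Routed attention masks dropped queries (their output rows contribute zero);
keys and values keep all tokens so retained queries still see the full
context. Modality latents are concatenated in a fixed order and a linear head
emits the event-status probabilities and a time-based risk level; the
composite risk score is max(status probability) x time risk.

Training optimizes cross-entropy on event status plus the Cox partial
likelihood (Breslow form) on the time risk, summed 1:1, under Monte Carlo
cross-validation stratified by event status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = [
    "ModalityFeatureSet",
    "RouteState",
    "RiskOutput",
    "RouterParams",
    "route_logits",
    "sample_route",
    "routed_attention",
    "fuse",
    "risk_head",
    "MultimodalRiskModel",
    "PGMTrainConfig",
    "train_pgm",
]

MODALITY_ORDER = ("pathology", "lncrna", "immune", "clinical")


@dataclass
class ModalityFeatureSet:
    """Per-patient input vectors, one per modality (fixed fusion order:
    pathology, lncrna, immune, clinical)."""

    pathology: np.ndarray
    lncrna: np.ndarray
    immune: np.ndarray
    clinical: np.ndarray

    def __post_init__(self):
        for name in MODALITY_ORDER:
            v = np.asarray(getattr(self, name), dtype=np.float64).ravel()
            if not np.isfinite(v).all():
                raise ValueError(f"modality '{name}' contains non-finite values")
            setattr(self, name, v)


@dataclass
class RouteState:
    """One routing decision: keep/drop probabilities and the sampled route."""

    Q_in: np.ndarray
    Q_emb_out: np.ndarray
    r: np.ndarray          # L x 2 rows summing to 1; column 0 = keep
    R: np.ndarray          # binary route, 1 = kept
    tau: float

    @property
    def alpha(self) -> np.ndarray:
        return self.r[..., 0]


@dataclass
class RiskOutput:
    status_probs: np.ndarray  # (no-event, event) probabilities
    time_risk: float

    @property
    def risk_score(self) -> float:
        return float(np.max(self.status_probs) * self.time_risk)


@dataclass
class RouterParams:
    """Two ELU MLPs: one pools global context, one scores keep/drop."""

    W1: np.ndarray  # d x h
    b1: np.ndarray
    W2: np.ndarray  # h x d
    b2: np.ndarray
    W3: np.ndarray  # d x h
    b3: np.ndarray
    W4: np.ndarray  # h x 2
    b4: np.ndarray

    @staticmethod
    def random(d: int, hidden: int, rng: np.random.Generator,
               keep_bias: float = 2.0) -> "RouterParams":
        """``keep_bias`` biases the keep/drop head toward keeping at
        initialization, so routes start near their all-ones state."""

        def lin(m, n):
            return rng.normal(0, 1.0 / np.sqrt(m), (m, n))

        return RouterParams(lin(d, hidden), np.zeros(hidden), lin(hidden, d),
                            np.zeros(d), lin(d, hidden), np.zeros(hidden),
                            lin(hidden, 2), np.array([keep_bias, -keep_bias]))

    @staticmethod
    def zeros(d: int, hidden: int) -> "RouterParams":
        z = np.zeros
        return RouterParams(z((d, hidden)), z(hidden), z((hidden, d)), z(d),
                            z((d, hidden)), z(hidden), z((hidden, 2)), z(2))


def _mlp(x, W_in, b_in, W_out, b_out):
    return ad.elu(x @ W_in + b_in) @ W_out + b_out


def route_logits(Q_in, active_mask, params: RouterParams):
    """Compute the residual-modified query and keep/drop probabilities.

    ``Q_in``: (L, d) or batched (B, L, d) token matrix. ``active_mask``: same
    leading shape, 1 for tokens still in the query pathway. Pooling averages
    only active tokens; the global MLP output gates Q_in through a Hadamard
    product with a residual connection, and a second MLP row-softmaxed over
    two columns yields r = [keep, drop] per token.
    """
    mask = np.asarray(active_mask, dtype=np.float64)
    data = Q_in.data if isinstance(Q_in, Tensor) else np.asarray(Q_in, dtype=np.float64)
    if mask.shape != data.shape[:-1]:
        raise ValueError("active_mask must match the token layout of Q_in")
    denom = mask.sum(axis=-1)
    if np.any(denom == 0):
        raise ValueError("routing requires at least one active token")
    pooled = (Q_in * mask[..., None]).sum(axis=-2) * (1.0 / denom)[..., None] \
        if isinstance(Q_in, Tensor) else (data * mask[..., None]).sum(-2) / denom[..., None]
    g = _mlp(pooled, params.W1, params.b1, params.W2, params.b2)
    if isinstance(g, Tensor) or isinstance(Q_in, Tensor):
        g_b = g.reshape(*g.shape[:-1], 1, g.shape[-1])
    else:
        g_b = g[..., None, :]
    Q_emb_out = Q_in + Q_in * g_b
    r = ad.softmax(_mlp(Q_emb_out, params.W3, params.b3, params.W4, params.b4), axis=-1)
    return Q_emb_out, r


def sample_route(r, tau: float, rng: np.random.Generator, hard: bool = True):
    """Gumbel-Softmax sample of binary routes from keep/drop probabilities.

    y = softmax((log r + g)/tau) with g ~ Gumbel(0,1) i.i.d. In hard mode the
    forward value is the one-hot argmax with the relaxed sample as the
    straight-through gradient surrogate. Returns the keep component R.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    data = r.data if isinstance(r, Tensor) else np.asarray(r, dtype=np.float64)
    g = rng.gumbel(size=data.shape)
    logits = (ad.log(r + 1e-20) + g) * (1.0 / tau)
    y = ad.softmax(logits, axis=-1)
    if not hard:
        return y[..., 0]
    y_data = y.data if isinstance(y, Tensor) else y
    onehot = (y_data >= y_data.max(axis=-1, keepdims=True)).astype(np.float64)
    # guard against exact ties: keep only the first argmax
    onehot = np.eye(data.shape[-1])[np.argmax(y_data, axis=-1)]
    if isinstance(y, Tensor):
        hard_st = (onehot - y.data) + y  # straight-through estimator
        return hard_st[..., 0]
    return onehot[..., 0]


def routed_attention(tokens, R, params: dict, queries=None):
    """Scaled dot-product self-attention with dropped queries masked out.

    ``params`` holds Wq, Wk, Wv (d x d). ``queries`` defaults to ``tokens``;
    the query-router passes its modified query here. The output row of a
    dropped token (R=0) is zero, so the result is invariant to that token's
    query; keys and values keep all tokens.
    """
    if queries is None:
        queries = tokens
    tok_data = tokens.data if isinstance(tokens, Tensor) else np.asarray(tokens)
    R_data = R.data if isinstance(R, Tensor) else np.asarray(R, dtype=np.float64)
    if R_data.shape != tok_data.shape[:-1]:
        raise ValueError("route mask shape must match token layout")
    d = tok_data.shape[-1]
    Q = queries @ params["Wq"]
    K = tokens @ params["Wk"]
    V = tokens @ params["Wv"]
    if isinstance(Q, Tensor) or isinstance(K, Tensor):
        scores = _matmul_t(Q, K) * (1.0 / np.sqrt(d))
    else:
        scores = np.einsum("...ld,...md->...lm", Q, K) / np.sqrt(d)
    A = ad.softmax(scores, axis=-1)
    if isinstance(A, Tensor) or isinstance(V, Tensor):
        out = A @ V
        out = out * R[..., None] if isinstance(R, Tensor) else out * R_data[..., None]
    else:
        out = np.einsum("...lm,...md->...ld", A, V) * R_data[..., None]
    return out


def _matmul_t(Q, K):
    """Q @ K^T for Tensors, batched over leading dims."""
    Kt = _transpose_last(K)
    return Q @ Kt


def _transpose_last(x):
    if isinstance(x, Tensor):
        data = np.swapaxes(x.data, -1, -2)
        axes = list(range(x.data.ndim))
        axes[-1], axes[-2] = axes[-2], axes[-1]

        def back(g):
            return [(x, np.swapaxes(g, -1, -2))]

        return Tensor(data, requires_grad=x.requires_grad,
                      _parents=(x,) if x.requires_grad else (),
                      _backward=back if x.requires_grad else None)
    return np.swapaxes(np.asarray(x), -1, -2)


def fuse(latents: dict) -> np.ndarray:
    """Concatenate modality latents in the fixed documented order."""
    missing = [m for m in MODALITY_ORDER if m not in latents]
    if missing:
        raise ValueError(f"missing modality latents: {missing}")
    return ad.concatenate([latents[m] for m in MODALITY_ORDER], axis=-1)


def risk_head(fused, params: dict) -> RiskOutput:
    """Linear head: two status logits and one time-based risk level.

    risk_score = max(status_probs) * time_risk (the composite score used for
    patient ranking).
    """
    logits = fused @ params["Ws"] + params["bs"]
    probs = ad.softmax(logits, axis=-1)
    t = fused @ params["wt"] + params["bt"]
    probs_np = probs.data if isinstance(probs, Tensor) else np.asarray(probs)
    t_np = float(t.data) if isinstance(t, Tensor) else float(np.asarray(t))
    return RiskOutput(status_probs=probs_np, time_risk=t_np)


@dataclass
class PGMTrainConfig:
    folds: int = 5
    epochs: int = 250
    lr: float = 5e-3
    weight_decay: float = 1e-3
    patience: int = 20       # evaluations without improvement before stopping
    eval_every: int = 5      # epochs between early-stopping evaluations
    stop_frac: float = 0.2   # inner fraction of the training split used for early stopping
    batch_size: int = 64     # mini-batch size; Cox risk sets are formed within batch
    seed: int = 0
    token_dim: int = 16
    hidden: int = 32
    n_blocks: int = 2
    tau: float = 1.0
    tokens_per_modality: tuple = (4, 2, 2, 1)
    val_frac: float = 0.2
    loss_weights: tuple = (1.0, 1.0)  # (status BCE, Cox partial likelihood)


class MultimodalRiskModel:
    """Token encoders + hierarchical query-router blocks + fusion + risk head."""

    def __init__(self, dims: dict, cfg: PGMTrainConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        d, h = cfg.token_dim, cfg.hidden
        self.cfg = cfg
        self.dims = dict(dims)
        self.n_tokens = dict(zip(MODALITY_ORDER, cfg.tokens_per_modality))
        self.L = sum(self.n_tokens.values())

        def lin(m, n):
            return Tensor.param(rng.normal(0, 1.0 / np.sqrt(m), (m, n)))

        self.encoders = {}
        for m in MODALITY_ORDER:
            nt = self.n_tokens[m]
            self.encoders[m] = (lin(dims[m], nt * d), Tensor.param(np.zeros(nt * d)))
        self.routers = []
        for _ in range(cfg.n_blocks):
            rp = RouterParams.random(d, h, rng)
            self.routers.append(RouterParams(*[Tensor.param(x) for x in
                                               (rp.W1, rp.b1, rp.W2, rp.b2,
                                                rp.W3, rp.b3, rp.W4, rp.b4)]))
        self.attn = [{"Wq": lin(d, d), "Wk": lin(d, d), "Wv": lin(d, d)}
                     for _ in range(cfg.n_blocks)]
        fused_dim = 4 * d
        self.head = {"Ws": lin(fused_dim, 2), "bs": Tensor.param(np.zeros(2)),
                     "wt": lin(fused_dim, 1), "bt": Tensor.param(np.zeros(1))}

    def parameters(self):
        ps = []
        for W, b in self.encoders.values():
            ps += [W, b]
        for rp in self.routers:
            ps += [rp.W1, rp.b1, rp.W2, rp.b2, rp.W3, rp.b3, rp.W4, rp.b4]
        for blk in self.attn:
            ps += list(blk.values())
        ps += [self.head["Ws"], self.head["bs"], self.head["wt"], self.head["bt"]]
        return ps

    def _maybe_np(self, t, train):
        return t if train else t.data

    def encode(self, X: dict, train: bool):
        """X: modality name -> (B, dim) arrays. Returns (B, L, d) tokens."""
        d = self.cfg.token_dim
        toks = []
        for m in MODALITY_ORDER:
            W, b = self.encoders[m]
            W = self._maybe_np(W, train)
            b = self._maybe_np(b, train)
            t = ad.elu(X[m] @ W + b)
            B = t.shape[0]
            toks.append(t.reshape(B, self.n_tokens[m], d) if isinstance(t, Tensor)
                        else t.reshape(B, self.n_tokens[m], d))
        return ad.concatenate(toks, axis=1)

    def forward(self, X: dict, rng: np.random.Generator | None, train: bool):
        """Full forward pass; rng=None keeps all routes at their all-ones
        initialization (deterministic inference reproduces plain attention)."""
        tokens = self.encode(X, train)
        B = tokens.shape[0]
        mask_np = np.ones((B, self.L))
        route_states = []
        for blk in range(self.cfg.n_blocks):
            rp = self.routers[blk]
            rp_use = rp if train else RouterParams(*[p.data for p in
                                                     (rp.W1, rp.b1, rp.W2, rp.b2,
                                                      rp.W3, rp.b3, rp.W4, rp.b4)])
            tok_np = np.asarray(tokens.data if isinstance(tokens, Tensor) else tokens)
            Q_mod, r = route_logits(tokens, mask_np, rp_use)
            if rng is not None:
                R = sample_route(r, self.cfg.tau, rng, hard=True)
                R_np = R.data if isinstance(R, Tensor) else np.asarray(R)
            else:
                R = mask_np.copy()
                R_np = R
            # hierarchical persistence: once dropped, always dropped; a patient
            # whose route would drop every remaining token keeps its mask
            new_mask = mask_np * R_np
            dead = ~new_mask.any(axis=1)
            if dead.any():
                new_mask[dead] = mask_np[dead]
            if isinstance(R, Tensor):
                alive = (~dead).astype(np.float64)[:, None]
                R_eff = R * (mask_np * alive) + mask_np * dead.astype(np.float64)[:, None]
            else:
                R_eff = new_mask
            attn_p = ({k: v for k, v in self.attn[blk].items()} if train
                      else {k: v.data for k, v in self.attn[blk].items()})
            # residual connection around the routed attention block
            tokens = tokens + routed_attention(tokens, R_eff, attn_p, queries=Q_mod)
            route_states.append(RouteState(
                Q_in=tok_np,
                Q_emb_out=np.asarray(Q_mod.data if isinstance(Q_mod, Tensor) else Q_mod),
                r=np.asarray(r.data if isinstance(r, Tensor) else r),
                R=new_mask.copy(), tau=self.cfg.tau))
            mask_np = new_mask
        # mean-pool each modality's token latents, then concatenate
        latents, start = {}, 0
        for m in MODALITY_ORDER:
            nt = self.n_tokens[m]
            seg = tokens[:, start : start + nt, :]
            latents[m] = seg.mean(axis=1) if isinstance(seg, Tensor) else seg.mean(axis=1)
            start += nt
        fused = fuse(latents)
        head = (self.head if train
                else {k: v.data for k, v in self.head.items()})
        logits = fused @ head["Ws"] + head["bs"]
        probs = ad.softmax(logits, axis=-1)
        t_risk = fused @ head["wt"] + head["bt"]
        return probs, t_risk, route_states

    def predict(self, X: dict) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic risk scores (all routes kept). Returns
        (risk_score, time_risk) arrays."""
        probs, t_risk, _ = self.forward(X, rng=None, train=False)
        probs = np.asarray(probs)
        t = np.asarray(t_risk).ravel()
        return probs.max(axis=1) * t, t


def _cox_loss(eta, time: np.ndarray, event: np.ndarray):
    """Negative Cox partial log-likelihood (Breslow ties) of risk ``eta``."""
    n_events = int(event.sum())
    if n_events == 0:
        return eta.sum() * 0.0
    at_risk = (time[None, :] >= time[:, None]).astype(np.float64)  # row i: risk set
    e = ad.exp(eta)
    denom = ad.log((at_risk @ e) + 1e-300)
    contrib = (eta - denom) * event
    return -(contrib.sum() * (1.0 / n_events))


@dataclass
class PGMFoldResult:
    fold: int
    cindex_test: float
    test_idx: np.ndarray = field(repr=False, default=None)


@dataclass
class PGMTrainResult:
    model: MultimodalRiskModel
    folds: list
    best_fold: int

    @property
    def mean_cindex(self) -> float:
        return float(np.mean([f.cindex_test for f in self.folds]))


def train_pgm(cohort, cfg: PGMTrainConfig | None = None) -> PGMTrainResult:
    """Monte Carlo cross-validated training of the multimodal risk model.

    ``cohort`` needs attributes pathology/lncrna/immune/clinical (n x dim
    arrays), time (>0) and event (0/1). Splits are stratified by event
    status; the loss is status cross-entropy + Cox partial likelihood on the
    training split; the held-out C-index uses the composite risk score.
    """
    from .survival import SurvivalData, concordance_index

    cfg = cfg or PGMTrainConfig()
    missing = [m for m in MODALITY_ORDER if getattr(cohort, m, None) is None]
    if missing:
        raise ValueError(f"cohort is missing modalities {missing}; "
                         "all four modalities are required (no imputation)")
    X_all = {m: np.asarray(getattr(cohort, m), dtype=np.float64) for m in MODALITY_ORDER}
    time = np.asarray(cohort.time, dtype=np.float64)
    event = np.asarray(cohort.event, dtype=np.int64)
    if (time <= 0).any():
        raise ValueError("survival times must be > 0")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    # standardize each modality on the full cohort scale
    stats = {m: (X_all[m].mean(0), X_all[m].std(0) + 1e-8) for m in MODALITY_ORDER}
    X_all = {m: (X_all[m] - mu) / sd for m, (mu, sd) in stats.items()}
    dims = {m: X_all[m].shape[1] for m in MODALITY_ORDER}

    splitter = StratifiedShuffleSplit(n_splits=cfg.folds, test_size=cfg.val_frac,
                                      random_state=cfg.seed)
    folds, models = [], []
    w_bce, w_cox = cfg.loss_weights
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(time)), event)):
        rng = np.random.default_rng(cfg.seed + 7919 * fold + 13)
        model = MultimodalRiskModel(dims, cfg, seed=cfg.seed + fold)
        opt = ad.Adam(model.parameters(), lr=cfg.lr)
        # inner split of the training portion for early stopping
        if cfg.stop_frac and cfg.patience:
            inner = StratifiedShuffleSplit(n_splits=1, test_size=cfg.stop_frac,
                                           random_state=cfg.seed + fold)
            fit_i, stop_i = next(inner.split(np.zeros(len(tr)), event[tr]))
            fit_idx, stop_idx = tr[fit_i], tr[stop_i]
        else:
            fit_idx, stop_idx = tr, None
        if stop_idx is not None:
            Xst = {m: X_all[m][stop_idx] for m in MODALITY_ORDER}
        best_ci, best_state, since_best = -np.inf, None, 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(fit_idx)
            for s in range(0, len(order), cfg.batch_size):
                bidx = order[s : s + cfg.batch_size]
                if len(bidx) < 8:
                    continue  # too few for a stable risk set
                Xb = {m: X_all[m][bidx] for m in MODALITY_ORDER}
                probs, t_risk, _ = model.forward(Xb, rng=rng, train=True)
                logp = ad.log(probs + 1e-12)
                bce = -(logp[np.arange(len(bidx)), event[bidx]]).mean()
                eta = t_risk.reshape(len(bidx))
                cox = _cox_loss(eta, time[bidx], event[bidx].astype(np.float64))
                loss = w_bce * bce + w_cox * cox
                opt.zero_grad()
                loss.backward()
                if cfg.weight_decay:
                    for p in model.parameters():
                        p.grad = (p.grad if p.grad is not None else 0.0) \
                            + 2.0 * cfg.weight_decay * p.data
                opt.step()
            if stop_idx is not None and (epoch + 1) % cfg.eval_every == 0:
                # monitor held-out ranking (C-index of the composite risk)
                risk_st, _ = model.predict(Xst)
                try:
                    ci = concordance_index(SurvivalData(
                        time=time[stop_idx], event=event[stop_idx], risk=risk_st))
                except ValueError:
                    ci = 0.5
                if ci > best_ci + 1e-6:
                    best_ci, since_best = ci, 0
                    best_state = [p.data.copy() for p in model.parameters()]
                else:
                    since_best += 1
                    if cfg.patience and since_best >= cfg.patience:
                        break
        if best_state is not None:
            for p, s in zip(model.parameters(), best_state):
                p.data = s
        Xte = {m: X_all[m][te] for m in MODALITY_ORDER}
        risk, _ = model.predict(Xte)
        ci = concordance_index(SurvivalData(time=time[te], event=event[te], risk=risk))
        folds.append(PGMFoldResult(fold=fold, cindex_test=float(ci), test_idx=te))
        models.append(model)
    best = int(np.argmax([f.cindex_test for f in folds]))
    return PGMTrainResult(model=models[best], folds=folds, best_fold=best)
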