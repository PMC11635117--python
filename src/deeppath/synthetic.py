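"""Synthetic cohorts with planted ground truth for every pipeline stage.

Every generator is a pure function of its parameters and seed and returns the
ground truth alongside the data, so downstream recovery can be scored
exactly. The defaults encode the study conditions the pipeline is meant to
operate under: slides as saturated tissue blobs on a white background,
multiple-instance bags where a 10% minority of instances carries a
class-specific mean shift of 2 embedding standard deviations, expression
cohorts with a planted 3 (lncRNA) x 2 (immune) cluster structure, and
survival times from an exponential proportional-hazards model whose linear
predictor follows the planted subtype risk code with independent exponential
censoring calibrated to a 30% rate.

These are deliberately idealized: instance embeddings are Gaussian (real
pathology embeddings are not), expression is Gaussian rather than
count-distributed, and censoring is independent of covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage.draw import ellipse as _draw_ellipse

from .embedding import FeatureBag
from .slide_prep import SlideRaster
from .subtyping import SUBTYPE_MAP, assign_subtype

__all__ = [
    "IMMUNE_CELL_TYPES",
    "SlideSpec",
    "BagSpec",
    "ExpressionSpec",
    "CohortSpec",
    "make_slide",
    "make_bags",
    "make_expression_cohort",
    "make_multimodal_cohort",
    "SUBTYPE_RISK_CODE",
]

# the 28 immune-cell populations scored by ssGSEA
IMMUNE_CELL_TYPES = (
    "Activated B cell", "Activated CD4 T cell", "Activated CD8 T cell",
    "Activated dendritic cell", "CD56bright natural killer cell",
    "CD56dim natural killer cell", "Central memory CD4 T cell",
    "Central memory CD8 T cell", "Effector memory CD4 T cell",
    "Effector memory CD8 T cell", "Eosinophil", "Gamma delta T cell",
    "Immature B cell", "Immature dendritic cell", "MDSC", "Macrophage",
    "Mast cell", "Memory B cell", "Monocyte", "Natural killer T cell",
    "Neutrophil", "Plasmacytoid dendritic cell", "Regulatory T cell",
    "T follicular helper cell", "Type 1 T helper cell",
    "Type 17 T helper cell", "Type 2 T helper cell",
    "Natural killer cell",
)

# prognostic ordering of the four subtypes: immune-active tumors fare best,
# immune-dysfunctional (glucose) worst
SUBTYPE_RISK_CODE = {"iFA": 0, "iAA": 1, "iFolate": 2, "iGlu": 3}


@dataclass
class SlideSpec:
    height: int = 1024
    width: int = 1024
    n_blobs: int = 3
    blob_radius: tuple = (80, 160)  # semi-axis range, px
    seed: int = 0


def make_slide(spec: SlideSpec | None = None) -> tuple[SlideRaster, np.ndarray]:
    """White background with saturated elliptical tissue blobs.

    Returns the raster and the exact foreground mask (level 0) used to draw
    the blobs, for scoring segmentation.
    """
    spec = spec or SlideSpec()
    rng = np.random.default_rng(spec.seed)
    img = np.full((spec.height, spec.width, 3), 255, dtype=np.uint8)
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for _ in range(spec.n_blobs):
        a = rng.uniform(*spec.blob_radius)
        b = rng.uniform(*spec.blob_radius)
        cy = rng.uniform(a, spec.height - a)
        cx = rng.uniform(b, spec.width - b)
        rr, cc = _draw_ellipse(cy, cx, a, b, shape=mask.shape)
        # saturated pink/purple tissue tones
        color = np.array([rng.integers(150, 220), rng.integers(30, 90),
                          rng.integers(120, 200)], dtype=np.uint8)
        img[rr, cc] = color
        mask[rr, cc] = True
    return SlideRaster(pixels=img, slide_id=f"synthetic-{spec.seed}"), mask


@dataclass
class BagSpec:
    n_bags: int = 200
    n_instances: int = 50
    dim: int = 32
    signal_frac: float = 0.1
    delta: float = 2.0
    seed: int = 0


def make_bags(spec: BagSpec | None = None) -> list[FeatureBag]:
    """Labeled multiple-instance bags with a planted minority signal.

    Instances are standard normal in ``dim`` dimensions; in each bag a
    ``signal_frac`` fraction is shifted by ``delta`` along the bag's
    class-specific orthonormal axis. Bags carry their subtype label and the
    ground-truth signal instance indices (``bag.signal_idx``).
    """
    spec = spec or BagSpec()
    rng = np.random.default_rng(spec.seed)
    subtypes = sorted(set(SUBTYPE_RISK_CODE), key=SUBTYPE_RISK_CODE.get)
    # orthonormal class axes via QR of a fixed random matrix
    A = rng.standard_normal((spec.dim, len(subtypes)))
    Q, _ = np.linalg.qr(A)
    axes = Q.T  # 4 x dim
    n_signal = max(1, int(round(spec.signal_frac * spec.n_instances)))
    bags = []
    for b in range(spec.n_bags):
        cls = b % len(subtypes)
        H = rng.standard_normal((spec.n_instances, spec.dim))
        sig_idx = rng.choice(spec.n_instances, size=n_signal, replace=False)
        H[sig_idx] += spec.delta * axes[cls]
        coords = np.column_stack([
            256 * (np.arange(spec.n_instances) % 16),
            256 * (np.arange(spec.n_instances) // 16),
        ])
        bags.append(FeatureBag(slide_id=f"bag-{b}", H=H.astype(np.float32),
                               coords=coords, label=subtypes[cls],
                               backbone="synthetic", signal_idx=np.sort(sig_idx)))
    return bags


@dataclass
class ExpressionSpec:
    n_samples: int = 150
    n_lnc_panel: int = 60
    n_background: int = 150
    genes_per_set: int = 15
    lnc_delta: float = 2.0
    imm_delta: float = 1.5
    seed: int = 0
    cluster_weights_lnc: tuple = (1 / 3, 1 / 3, 1 / 3)
    cluster_weights_imm: tuple = (0.5, 0.5)


@dataclass
class ExpressionCohort:
    expr: pd.DataFrame               # genes x samples
    panel: list                      # lncRNA panel gene ids
    immune_sets: dict                # 28 synthetic signatures
    truth: pd.DataFrame              # lnc_cluster, imm_cluster, subtype per sample


def make_expression_cohort(spec: ExpressionSpec | None = None) -> ExpressionCohort:
    """Expression cohort with planted 3 lncRNA x 2 immune cluster structure.

    Panel genes receive cluster mean shifts ordered so that planted lncRNA
    cluster 1 has the highest panel expression (matching the canonical
    renumbering); immune-signature genes are shifted up in planted immune
    cluster 1. The planted subtype follows the standard 2-D mapping.
    """
    spec = spec or ExpressionSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    lnc_clusters = rng.choice([1, 2, 3], size=n, p=spec.cluster_weights_lnc)
    imm_clusters = rng.choice([1, 2], size=n, p=spec.cluster_weights_imm)

    panel = [f"LNC{i:04d}" for i in range(spec.n_lnc_panel)]
    imm_sets = {
        name: [f"IMM{si:02d}_{g:03d}" for g in range(spec.genes_per_set)]
        for si, name in enumerate(IMMUNE_CELL_TYPES)
    }
    imm_genes = [g for genes in imm_sets.values() for g in genes]
    background = [f"BG{i:04d}" for i in range(spec.n_background)]
    genes = panel + imm_genes + background
    X = rng.standard_normal((len(genes), n))

    # lncRNA panel: cluster 1 high, 2 middle, 3 low
    lnc_shift = {1: spec.lnc_delta, 2: 0.0, 3: -spec.lnc_delta}
    for j in range(n):
        X[: len(panel), j] += lnc_shift[lnc_clusters[j]]
    # immune signature genes: cluster 1 enriched, cluster 2 depleted
    imm_slice = slice(len(panel), len(panel) + len(imm_genes))
    imm_shift = {1: spec.imm_delta, 2: -spec.imm_delta}
    for j in range(n):
        X[imm_slice, j] += imm_shift[imm_clusters[j]]

    samples = [f"S{j:04d}" for j in range(n)]
    truth = pd.DataFrame(
        {
            "lnc_cluster": lnc_clusters,
            "imm_cluster": imm_clusters,
            "subtype": [assign_subtype(l, i) for l, i in zip(lnc_clusters, imm_clusters)],
        },
        index=samples,
    )
    expr = pd.DataFrame(X, index=genes, columns=samples)
    return ExpressionCohort(expr=expr, panel=panel, immune_sets=imm_sets, truth=truth)


@dataclass
class CohortSpec:
    n_samples: int = 400
    beta: float = 1.5
    censoring_rate: float = 0.3
    frailty_sd: float = 0.75
    noise_sd: float = 0.1
    path_dim: int = 32
    # the pathology vector emulates an attention-pooled bag representation:
    # pooling over ~n_instances patches shrinks residual noise by ~1/sqrt(n)
    # and concentrates the class shift, hence the low noise and larger delta
    path_delta: float = 3.0
    path_frailty_scale: float = 2.0
    path_noise_sd: float = 0.3
    n_lnc_panel: int = 60
    lnc_delta: float = 2.0
    imm_delta: float = 1.5
    baseline_median_months: float = 24.0
    seed: int = 0


@dataclass
class MultimodalCohort:
    pathology: np.ndarray   # n x path_dim
    lncrna: np.ndarray      # n x n_lnc_panel
    immune: np.ndarray      # n x 28
    clinical: np.ndarray    # n x 5 (age, T, N, stage, PAM50 code)
    time: np.ndarray
    event: np.ndarray
    eta_true: np.ndarray
    subtype: np.ndarray
    truth: pd.DataFrame = field(default=None)


def make_multimodal_cohort(spec: CohortSpec | None = None) -> MultimodalCohort:
    """Four-modality cohort with survival linked to the planted subtype.

    The linear predictor is eta = beta * (centered subtype risk code) +
    frailty + noise. Frailty is a per-patient continuous severity term that
    is also expressed in the pathology modality (image features reflect
    tumor aggressiveness beyond the discrete subtype), so it is learnable;
    the residual noise is not observable anywhere. Event times are
    exponential with hazard proportional to exp(eta), the baseline scaled so
    median survival at eta = 0 is ``baseline_median_months``; independent
    exponential censoring is calibrated analytically to the target rate.
    Each modality carries subtype-linked structure: pathology vectors shifted
    along a class axis (plus the frailty direction), lncRNA/immune features
    shifted by planted cluster, clinical stage correlated with the risk code.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    pairs = list(SUBTYPE_MAP.keys())
    pick = rng.integers(0, len(pairs), size=n)
    lnc_c = np.array([pairs[i][0] for i in pick])
    imm_c = np.array([pairs[i][1] for i in pick])
    subtype = np.array([SUBTYPE_MAP[pairs[i]] for i in pick])
    code = np.array([SUBTYPE_RISK_CODE[s] for s in subtype], dtype=np.float64)

    frailty = rng.normal(0, spec.frailty_sd, n)
    eta = (spec.beta * (code - code.mean()) + frailty
           + rng.normal(0, spec.noise_sd, n))

    lam0 = np.log(2.0) / spec.baseline_median_months
    rate = lam0 * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)

    # censoring rate for exponential censoring at rate c: mean_i c/(c + rate_i)
    target = spec.censoring_rate
    if target > 0:
        f = lambda c: np.mean(c / (c + rate)) - target
        c_rate = brentq(f, 1e-8, 1e4)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(np.int64)
    time = np.maximum(time, 1e-3)

    # pathology: Gaussian vector shifted along an orthonormal subtype axis,
    # plus the frailty along a fifth orthonormal direction
    A = rng.standard_normal((spec.path_dim, 5))
    axes = np.linalg.qr(A)[0].T
    pathology = spec.path_noise_sd * rng.standard_normal((n, spec.path_dim))
    pathology += spec.path_delta * axes[code.astype(int)]
    pathology += (spec.path_frailty_scale * frailty
                  / max(spec.frailty_sd, 1e-12))[:, None] * axes[4]

    lnc_shift = {1: spec.lnc_delta, 2: 0.0, 3: -spec.lnc_delta}
    lncrna = rng.standard_normal((n, spec.n_lnc_panel))
    lncrna += np.array([lnc_shift[c] for c in lnc_c])[:, None]

    imm_shift = {1: spec.imm_delta, 2: -spec.imm_delta}
    immune = rng.standard_normal((n, len(IMMUNE_CELL_TYPES)))
    immune += np.array([imm_shift[c] for c in imm_c])[:, None]

    age = rng.normal(55, 10, n)
    t_stage = np.clip(np.round(1 + code * 0.6 + rng.normal(0, 0.7, n)), 1, 4)
    n_stage = np.clip(np.round(code * 0.5 + rng.normal(0, 0.7, n)), 0, 3)
    stage = np.clip(np.round(1 + code * 0.5 + rng.normal(0, 0.6, n)), 1, 3)
    pam50 = rng.integers(0, 5, n).astype(np.float64)
    clinical = np.column_stack([age, t_stage, n_stage, stage, pam50])

    truth = pd.DataFrame({"lnc_cluster": lnc_c, "imm_cluster": imm_c,
                          "subtype": subtype, "eta": eta})
    return MultimodalCohort(pathology=pathology, lncrna=lncrna, immune=immune,
                            clinical=clinical, time=time, event=event,
                            eta_true=eta, subtype=subtype, truth=truth)
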