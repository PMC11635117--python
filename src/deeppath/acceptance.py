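"""End-to-end study computations used by the acceptance script.

Each function runs one headline analysis from scratch at the package's
standard synthetic study conditions and returns the measured quantity plus
the problem size. They are deliberately thin compositions of the public API
so that the numbers they report are the numbers the pipeline produces.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import abmil, router, subtyping, survival, synthetic

__all__ = [
    "im_classifier_study",
    "null_classifier_study",
    "consensus_recovery_study",
    "subtype_recovery_study",
    "pgm_study",
    "null_pgm_study",
    "cox_recovery_study",
    "gumbel_law_study",
]


def im_classifier_study(seed: int = 0):
    """Train the MIL subtype classifier on planted-signal bags.

    Returns (mean one-vs-rest validation AUC, mean attention mass on the
    planted signal instances, n_bags).
    """
    bags = synthetic.make_bags(synthetic.BagSpec(seed=seed + 1))
    res = abmil.train_subtype_model(bags, abmil.TrainConfig(
        folds=5, embed_dim=32, att_dim=16, seed=seed))
    att = [float(abmil.bag_attention(b, res.model).a[b.signal_idx].sum())
           for b in bags]
    return res.mean_auc, float(np.mean(att)), len(bags)


def null_classifier_study(seed: int = 0):
    """Same conditions with permuted labels: AUC should collapse to chance."""
    bags = synthetic.make_bags(synthetic.BagSpec(seed=seed + 1))
    rng = np.random.default_rng(seed + 2)
    labels = [b.label for b in bags]
    perm = rng.permutation(len(labels))
    res = abmil.train_subtype_model(bags, abmil.TrainConfig(
        folds=5, embed_dim=32, att_dim=16, seed=seed),
        labels=[labels[i] for i in perm])
    return res.mean_auc, len(bags)


def consensus_recovery_study(seed: int = 0):
    """Consensus clustering of a well-separated 3-cluster expression cohort;
    returns (adjusted Rand index vs planted labels, n_samples)."""
    cohort = synthetic.make_expression_cohort(synthetic.ExpressionSpec(
        n_samples=150, seed=seed + 3))
    X = cohort.expr.loc[cohort.panel].to_numpy().T
    Xz = (X - X.mean(0)) / (X.std(0) + 1e-12)
    res = subtyping.consensus_cluster(Xz, k_range=[3], n_iter=1000,
                                      resample_frac=0.8, seed=seed)
    ari = adjusted_rand_score(cohort.truth["lnc_cluster"], res.assignments[3])
    return float(ari), len(X)


def subtype_recovery_study(seed: int = 0):
    """Full subtyping pipeline accuracy against the planted 3x2 structure."""
    cohort = synthetic.make_expression_cohort(synthetic.ExpressionSpec(
        n_samples=150, seed=seed + 4))
    out = subtyping.subtype_cohort(cohort.expr, cohort.panel,
                                   cohort.immune_sets,
                                   subtyping.SubtypeConfig(seed=seed))
    acc = (out["subtype"].to_numpy() == cohort.truth["subtype"].to_numpy()).mean()
    return float(acc), len(out)


def _pgm_config(seed: int) -> router.PGMTrainConfig:
    return router.PGMTrainConfig(folds=5, epochs=250, batch_size=32,
                                 patience=30, seed=seed)


def pgm_study(seed: int = 0):
    """Multimodal risk model on the standard synthetic cohort; returns
    (mean held-out C-index across MC folds, n_patients)."""
    mm = synthetic.make_multimodal_cohort(synthetic.CohortSpec(seed=seed + 5))
    res = router.train_pgm(mm, _pgm_config(seed))
    return res.mean_cindex, len(mm.time)


def null_pgm_study(seed: int = 0, folds: int = 3):
    """Event/time permutation null: C-index should collapse to chance."""
    mm = synthetic.make_multimodal_cohort(synthetic.CohortSpec(seed=seed + 5))
    rng = np.random.default_rng(seed + 6)
    perm = rng.permutation(len(mm.time))
    mm.time, mm.event = mm.time[perm], mm.event[perm]
    cfg = _pgm_config(seed)
    cfg.folds = folds
    res = router.train_pgm(mm, cfg)
    return res.mean_cindex, len(mm.time)


def cox_recovery_study(seed: int = 0, true_hr: float = 2.0, n: int = 500):
    """Two-group Cox fit on simulated data with a known hazard ratio."""
    rng = np.random.default_rng(seed + 7)
    group = rng.integers(0, 2, n)
    lam = 0.04 * true_hr**group
    t = rng.exponential(1 / lam)
    c = rng.exponential(45.0, n)
    d = survival.SurvivalData(np.minimum(t, c) + 1e-9, (t <= c).astype(int))
    res = survival.cox_hr(d, group)
    return float(res.hr), n


def cox_null_coverage_study(seed: int = 0, reps: int = 200, n: int = 80):
    """Fraction of null replicates whose 95% CI covers HR = 1."""
    rng = np.random.default_rng(seed + 8)
    cover = 0
    for _ in range(reps):
        group = rng.integers(0, 2, n)
        t = rng.exponential(20.0, n)
        c = rng.exponential(40.0, n)
        d = survival.SurvivalData(np.minimum(t, c) + 1e-9, (t <= c).astype(int))
        res = survival.cox_hr(d, group)
        cover += res.ci95[0] <= 1.0 <= res.ci95[1]
    return cover / reps, reps


def gumbel_law_study(seed: int = 0, alpha: float = 0.7, n: int = 10_000):
    """Empirical keep frequency of hard Gumbel-Softmax routes at keep
    probability alpha."""
    r = np.tile([alpha, 1.0 - alpha], (n, 1))
    R = router.sample_route(r, tau=0.5, rng=np.random.default_rng(seed + 9))
    return float(np.mean(R)), n
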