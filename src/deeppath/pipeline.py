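"""End-to-end demo pipeline on synthetic data.

Runs every stage once — simulate, segment, patch, embed, train the MIL
subtype classifier, subtype an expression cohort, train the multimodal risk
model, and evaluate survival stratification — and collects all metrics into a
single JSON-serializable report keyed by stage, together with the
configuration hash. Every source of randomness is derived from the config
seed, so a fixed seed reproduces the report bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time as _time

import numpy as np

from . import abmil, router, slide_prep, subtyping, survival, synthetic
from .config import RunConfig
from .embedding import FixtureBackbone, embed_patches

logger = logging.getLogger("deeppath")

STAGES = ("simulate", "segment", "patch", "embed", "train_im", "subtype",
          "train_pgm", "evaluate")


def run_demo(config: RunConfig | None = None) -> dict:
    """Run the full synthetic demo; returns the report dict."""
    cfg = config or RunConfig()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    report = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}
    t0 = _time.time()
    stage = "simulate"
    try:
        slide, true_mask = synthetic.make_slide(synthetic.SlideSpec(
            height=cfg.slide.height, width=cfg.slide.width,
            n_blobs=cfg.slide.n_blobs, seed=cfg.seed))
        report["stages"][stage] = {
            "slide_shape": list(slide.shape),
            "true_foreground_frac": float(true_mask.mean()),
        }

        stage = "segment"
        seg = slide_prep.segment_tissue(slide, slide_prep.SegmentationParams(
            downsample=cfg.segmentation.downsample,
            sat_threshold=cfg.segmentation.sat_threshold,
            median_kernel=cfg.segmentation.median_kernel,
            close_kernel=cfg.segmentation.close_kernel,
            min_area=cfg.segmentation.min_area))
        report["stages"][stage] = {
            "foreground_frac": float(seg.mask.mean()),
            "n_contours": seg.n_contours,
        }

        stage = "patch"
        ps = slide_prep.extract_patches(slide, seg, patch_size=cfg.patching.patch_size,
                                        min_foreground_frac=cfg.patching.min_foreground_frac)
        report["stages"][stage] = {"n_patches": len(ps)}

        stage = "embed"
        backbone = FixtureBackbone(out_dim=cfg.embedding.out_dim)
        bag = embed_patches(ps, backbone, batch_size=cfg.embedding.batch_size)
        report["stages"][stage] = {"bag_shape": list(bag.H.shape)}

        stage = "train_im"
        bags = synthetic.make_bags(synthetic.BagSpec(
            n_bags=cfg.im.n_bags, n_instances=cfg.im.n_instances, dim=cfg.im.dim,
            delta=cfg.im.delta, signal_frac=cfg.im.signal_frac, seed=cfg.seed + 1))
        res = abmil.train_subtype_model(bags, abmil.TrainConfig(
            folds=cfg.im.folds, epochs=cfg.im.epochs, lr=cfg.im.lr,
            embed_dim=cfg.im.embed_dim, att_dim=cfg.im.att_dim, seed=cfg.seed))
        report["stages"][stage] = {
            "mean_auc": round(res.mean_auc, 6),
            "best_fold": res.best_fold,
            "per_fold_auc": [round(f.mean_auc, 6) for f in res.folds],
        }

        stage = "subtype"
        cohort = synthetic.make_expression_cohort(synthetic.ExpressionSpec(
            n_samples=cfg.subtyping.n_samples, seed=cfg.seed + 2))
        assigned = subtyping.subtype_cohort(cohort.expr, cohort.panel,
                                            cohort.immune_sets,
                                            subtyping.SubtypeConfig(
                                                n_iter=cfg.subtyping.n_iter,
                                                resample_frac=cfg.subtyping.resample_frac,
                                                seed=cfg.seed))
        acc = float((assigned["subtype"].to_numpy()
                     == cohort.truth["subtype"].to_numpy()).mean())
        report["stages"][stage] = {
            "subtype_accuracy": round(acc, 6),
            "counts": assigned["subtype"].value_counts().to_dict(),
        }

        stage = "train_pgm"
        mm = synthetic.make_multimodal_cohort(synthetic.CohortSpec(
            n_samples=cfg.pgm.n_samples, beta=cfg.pgm.beta,
            censoring_rate=cfg.pgm.censoring_rate, seed=cfg.seed + 3))
        pg = router.train_pgm(mm, router.PGMTrainConfig(
            folds=cfg.pgm.folds, epochs=cfg.pgm.epochs, lr=cfg.pgm.lr,
            tau=cfg.pgm.tau, seed=cfg.seed))
        report["stages"][stage] = {
            "mean_cindex": round(pg.mean_cindex, 6),
            "per_fold_cindex": [round(f.cindex_test, 6) for f in pg.folds],
        }

        stage = "evaluate"
        X = {m: np.asarray(getattr(mm, m)) for m in router.MODALITY_ORDER}
        stats = {m: (X[m].mean(0), X[m].std(0) + 1e-8) for m in X}
        Xz = {m: (X[m] - mu) / sd for m, (mu, sd) in stats.items()}
        risk, _ = pg.model.predict(Xz)
        d = survival.SurvivalData(time=mm.time, event=mm.event, risk=risk)
        cut = survival.optimal_cutoff(d)
        hr = survival.cox_hr(d, cut.high_mask.astype(int))
        cindex = survival.concordance_index(d)
        aucs = {}
        for t in cfg.evaluate.horizons:
            try:
                aucs[str(t)] = round(survival.time_dependent_auc(d, [t])[t], 6)
            except ValueError:
                aucs[str(t)] = None
        report["stages"][stage] = {
            "cindex_full_cohort": round(cindex, 6),
            "logrank_chi2": round(cut.statistic, 6),
            "hazard_ratio": round(hr.hr, 6) if np.isfinite(hr.hr) else "inf",
            "hr_ci95": [round(x, 6) if np.isfinite(x) else "inf" for x in hr.ci95],
            "auc_by_horizon": aucs,
        }
    except Exception as exc:
        raise RuntimeError(f"demo pipeline failed at stage '{stage}': {exc}") from exc
    report["runtime_s"] = round(_time.time() - t0, 2)
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
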