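# deeppath

Attention-based multiple-instance classification of breast-cancer
immune-metabolic subtypes from pathology slides, and query-routed multimodal
fusion for survival risk prediction — with the upstream transcriptomic
subtyping pipeline (ssGSEA + consensus clustering) and the time-to-event
evaluation statistics, all runnable end-to-end on synthetic cohorts with
known ground truth.

## Who this is for

Computational-pathology and cancer-genomics researchers who want a
self-contained, testable implementation of:

- **Tissue segmentation and patching** of whole-slide rasters (HSV saturation
  thresholding, median blur, morphological closing, contour area filtering,
  256×256 grid patches stored in HDF5);
- **Gated-attention MIL**: a slide is a bag of patch embeddings `h_i`; the
  attention logit of instance *i* is

  ```
  e_i = w^T ( tanh(U h_i) ⊙ sigmoid(V h_i) ),   a = softmax(e),   z = Σ_i a_i h_i
  ```

  with a linear head on the bag representation `z` producing probabilities
  over the four immune-metabolic subtypes (iFA, iAA, iGlu, iFolate), and
  per-patch attention heatmaps (navy → crimson);
- **Query-routed multimodal fusion**: pathology, lncRNA-panel expression,
  28 immune-cell enrichment scores and clinical covariates are encoded into
  tokens; a router computes `Q_out = Q_in + Q_in ⊙ MLP(mean of active tokens)`
  and keep/drop probabilities `r = softmax(MLP(Q_out)) ∈ R^{L×2}`, samples
  binary routes with the hard Gumbel-Softmax straight-through estimator
  (routes start at all-ones and once dropped a token stays dropped), masks
  routed queries in scaled dot-product attention, concatenates modality
  latents and emits event-status probabilities plus a time-based risk level;
  the composite risk score is `max(status_probs) × time_risk`;
- **Immune-metabolic subtyping**: per-sample rank-based gene-set enrichment
  (Barbie-style running-sum integration, exponent α = 0.25), consensus
  clustering (1000 resampling iterations at 80%, hierarchical average
  linkage, CDF delta-area model selection), and the 2-D index crossing three
  lncRNA clusters with two immune clusters:
  (1,1)→iFA, (2,1)/(1,2)→iAA, (2,2)/(3,1)→iGlu, (3,2)→iFolate;
- **Survival evaluation**: Kaplan-Meier, log-rank, univariable Cox hazard
  ratios (Efron ties), Harrell's C, IPCW cumulative/dynamic AUC(t), and the
  maximally selected log-rank cutoff.

The neural components run on a small vectorized reverse-mode autodiff engine
included in the package, so the whole artifact needs only the scientific
Python stack (numpy/scipy/pandas/scikit-learn/scikit-image/h5py/lifelines/
scikit-survival).

## Worked example

```bash
deeppath demo --seed 5 --out report.json
```

runs simulate → segment → patch → embed → train-IM → subtype → train-PGM →
evaluate on synthetic data (about 10 s) and prints the report. With seed 5 it
prints, among others:

```
"segment":   {"foreground_frac": 0.3166, "n_contours": 3}
"patch":     {"n_patches": 30}
"train_im":  {"mean_auc": 0.7101, ...}
"subtype":   {"subtype_accuracy": 1.0, ...}
"train_pgm": {"mean_cindex": 0.8189, ...}
"evaluate":  {"cindex_full_cohort": 0.8721, "hazard_ratio": 25.14,
              "auc_by_horizon": {"12.0": 0.9434, "36.0": 0.9600, "60.0": 0.9631}}
```

Reading: the segmenter recovers the simulated tissue blobs (32% foreground,
3 contours); the demo-sized MIL classifier (80 bags) reaches mean one-vs-rest
AUC 0.71 — the full study conditions (200 bags, 50 instances) reach ≥ 0.9,
see below; the subtyping pipeline recovers every planted subtype; the
multimodal risk model reaches a held-out C-index of 0.82, and thresholding
its risk score at the maximally selected cutoff separates patients with
hazard ratio ≈ 25 on this strongly structured synthetic cohort.

Individual stages are also exposed (`deeppath segment/patch/embed/train-im/
subtype/train-pgm-style workflows/evaluate/simulate`); run
`deeppath --help`.

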