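# pitnet-ith

Imaging intratumor heterogeneity (ITH) and hormone-remission analysis for
growth-hormone-secreting pituitary neuroendocrine tumors (GH-secreting
PitNETs).

Surgical resection of GH-secreting PitNETs frequently leaves residual
tumor, yet a substantial fraction of patients with residuals still reach
biochemical remission — suggesting that hormone secretion is spatially
heterogeneous, so the tissue left behind may be the weakly-secreting part.
This package implements, as a tested library, the analysis chain used to
study that hypothesis on contrast-enhanced T1 MRI and clinical data:

1. **Heterogeneity radiomics** — 42 signed features (9 first-order + 33
   texture from GLCM / GLRLM / GLSZM / NGTDM / GLDM matrices) computed in
   3D over a tumor ROI, each tagged +1 (heterogeneity) or −1 (homogeneity).
2. **ITH score** — features z-scored over a cohort and summed with their
   signs: `ITH_i = Σ_j s_j · z_ij`. Higher = more heterogeneous on imaging.
3. **Tumor habitats** — each voxel gets the 42 features over its 3×3×3
   neighborhood; voxels are pooled across the population, standardized and
   clustered with seeded K-means, with the number of clusters k ∈ 3..8
   chosen by the Calinski-Harabasz score; a patient's habitat count is the
   number of distinct clusters present in their ROI.
4. **Cohort statistics** — remission classification rules, GH/IGF-1
   discordance, Shapiro-Wilk-gated univariate tests, chi-square/Fisher
   contingency tests, Enter-method multivariate logistic regression
   (OR with Wald 95% CIs), and seeded quasi-Bayesian mediation analysis
   (ACME / ADE).
5. **Single-cell QC** — the count-matrix filtering rules (≥100 detected
   genes, ≤10% mitochondrial counts, genes in ≥3 cells) and per-sample GH1
   expression dispersion among POU1F1⁺ tumor cells.
6. **Synthetic data** — seeded generators for textured tumor phantoms with
   planted habitats, clinical cohorts with planted log-odds effects and a
   mediation path, and sparse count matrices with planted QC violations,
   so every stage is testable without any private data.

The intended audience is researchers reproducing or extending
radiomics-based heterogeneity analyses of pituitary (or other solid)
tumors who need a fully deterministic, oracle-tested reference
implementation rather than a GUI pipeline.

See `docs/methods.md` for the model conventions, numerical choices and
known limitations.

## Worked example

```python
import numpy as np
import pitnet_ith as pi
from pitnet_ith.ith import cohort_feature_matrix
from pitnet_ith.radiomics import default_registry

registry = default_registry()

# 1. a small synthetic cohort: ten 2-habitat and ten 3-habitat tumors
vectors, planted = {}, {}
for pid in range(20):
    n_hab = 2 if pid < 10 else 3
    spec = pi.PhantomSpec(shape=(24, 24, 24), n_habitats=n_hab, seed=pid)
    volume, mask, _ = pi.simulate_tumor_phantom(spec)
    vectors[pid] = pi.extract_registry_features(volume, mask, registry, bin_width=8.0)
    planted[pid] = n_hab

z = pi.zscore_columns(cohort_feature_matrix(vectors, registry))
scores = {r.patient_id: r.ith_score for r in pi.ith_scores(z, registry)}
lo = np.mean([scores[p] for p in scores if planted[p] == 2])
hi = np.mean([scores[p] for p in scores if planted[p] == 3])
print(f"mean ITH score: 2 habitats {lo:+.2f}, 3 habitats {hi:+.2f}")

# 2. voxel-level habitat clustering on three of the 3-habitat tumors
maps = []
for pid in (10, 11, 12):
    spec = pi.PhantomSpec(shape=(16, 16, 16), n_habitats=3, seed=pid)
    volume, mask, truth = pi.simulate_tumor_phantom(spec)
    maps.append(pi.local_feature_maps(volume, mask, patient_id=pid))
model = pi.fit_population_kmeans(maps, seed=0)
counts = [pi.subcluster_count(pi.assign_habitats(m, model)) for m in maps]
print(f"Calinski-Harabasz selected k={model.k}; habitats per patient: {counts}")

# 3. remission modelling on a planted-effect cohort
from pitnet_ith.cohort_stats import records_to_frame
records, truth = pi.simulate_cohort(pi.CohortSpec(n_patients=2000, seed=1))
cohort = records_to_frame(records)
cohort["remission"] = truth["remission"]
fit = pi.fit_multivariate_logistic(
    cohort, "remission", ["gh_preop_bin", "resection_rate", "ith_score"],
    reference_levels={"gh_preop_bin": "<=10"},
)
for t in fit.terms:
    print(f"{t.term:28s} OR {t.odds_ratio:6.2f}  95% CI [{t.ci_low:.2f}, {t.ci_high:.2f}]  p={t.p_value:.3g}")
```

Output (≈15 s on one CPU):

```
mean ITH score: 2 habitats -22.50, 3 habitats +22.50
Calinski-Harabasz selected k=3; habitats per patient: [3, 3, 3]
gh_preop_bin[10-30]          OR   0.47  95% CI [0.37, 0.60]  p=3.95e-10
gh_preop_bin[>30]            OR   0.19  95% CI [0.14, 0.24]  p=3.16e-38
resection_rate               OR  25.08  95% CI [14.25, 44.14]  p=5.42e-29
ith_score                    OR   1.06  95% CI [1.05, 1.08]  p=9.05e-20
```

Reading the numbers: tumors with three planted habitats score higher on
the ITH axis than two-habitat tumors (the cohort mean is 0 by
construction); the population K-means correctly selects k = 3 and reads
out 3 habitats per phantom; and the logistic fit recovers the cohort
generator's planted effects — remission odds fall with higher preoperative
GH (OR 0.47 and 0.19 vs the ≤10 ng/mL reference; planted 0.48 / 0.13),
rise steeply with resection rate (planted 18.3), and rise ~6% per ITH
point (planted 1.06).

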