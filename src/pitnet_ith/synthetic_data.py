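"""Synthetic inputs for every pipeline stage.

Three generators, all pure functions of (spec, seed):

* textured 3D tumor phantoms — an ellipsoidal ROI partitioned into planted
  intensity "habitats" (seeded Voronoi cells by default, nested shells as an
  alternative), with per-habitat texture noise plus global Gaussian noise;
* clinical cohorts with planted log-odds effect structure for the remission
  outcome, including an exposure -> mediator (resection rate) -> outcome
  mediation path;
* sparse gene x cell count matrices with planted QC violations and
  per-sample GH1 dispersion.

Default parameter values emulate the study conditions of the cohort the
method was developed on (n = 144 residual-tumor patients; covariate
marginals matching the published cohort tables; habitat contrast of five
texture scales).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse

from .cohort_stats import PatientRecord
from .imaging_io import ROIMask, VolumeImage, write_volume

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "CountMatrix",
    "simulate_tumor_phantom",
    "simulate_cohort",
    "simulate_count_matrix",
    "write_phantom_nifti",
    "write_count_matrix",
]

LN = math.log


@dataclass(frozen=True)
class PhantomSpec:
    """Planted-habitat tumor phantom.

    ``habitat_means`` default to ``base_intensity + i * contrast`` with the
    contrast set to five texture scales, the separation regime under which
    habitat clustering is expected to recover the planted partition.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_habitats: int = 3
    geometry: str = "voronoi"  # "voronoi" | "shells"
    base_intensity: float = 100.0
    habitat_contrast: float = 40.0
    texture_scale: float = 8.0
    texture_ratio: float = 3.0  # habitat h has texture SD scale * ratio**h
    noise_sd: float = 4.0
    habitat_means: Optional[tuple[float, ...]] = None
    texture_scales: Optional[tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_habitats < 1:
            raise ValueError("n_habitats must be >= 1")
        if self.noise_sd < 0 or self.texture_scale < 0:
            raise ValueError("noise/texture scales must be >= 0")
        if self.geometry not in ("voronoi", "shells"):
            raise ValueError(f"unknown geometry {self.geometry!r}")

    @property
    def means(self) -> np.ndarray:
        if self.habitat_means is not None:
            if len(self.habitat_means) != self.n_habitats:
                raise ValueError("habitat_means length must equal n_habitats")
            return np.asarray(self.habitat_means, dtype=float)
        return self.base_intensity + self.habitat_contrast * np.arange(self.n_habitats)

    @property
    def scales(self) -> np.ndarray:
        """Per-habitat texture SDs, geometric by default.

        Habitats are planted to differ in local texture, not only in mean
        intensity: the heterogeneity feature set is location-invariant by
        construction, so a purely mean-shifted compartment would be largely
        invisible to it.
        """
        if self.texture_scales is not None:
            if len(self.texture_scales) != self.n_habitats:
                raise ValueError("texture_scales length must equal n_habitats")
            return np.asarray(self.texture_scales, dtype=float)
        return self.texture_scale * self.texture_ratio ** np.arange(self.n_habitats)


def _ellipsoid_mask(shape) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.42
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    r2 = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    return r2 <= 1.0


def simulate_tumor_phantom(
    spec: PhantomSpec,
) -> tuple[VolumeImage, ROIMask, np.ndarray]:
    """Generate (volume, mask, truth labels); labels are -1 outside the ROI.

    Voxel intensity = N(habitat mean, texture_scale) + N(0, noise_sd),
    i.i.d. per voxel; background stays at 0.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec.shape)
    idx = np.argwhere(mask)
    if len(idx) < spec.n_habitats:
        raise ValueError("grid too small for the requested habitats")
    labels = np.full(spec.shape, -1, dtype=np.int64)
    if spec.geometry == "voronoi":
        # farthest-point seed placement -> compact, well-separated cells
        seeds = [idx[rng.integers(len(idx))]]
        while len(seeds) < spec.n_habitats:
            d2min = np.min(
                ((idx[:, None, :] - np.array(seeds)[None, :, :]) ** 2).sum(axis=2), axis=1
            )
            seeds.append(idx[int(np.argmax(d2min))])
        seeds = np.array(seeds)
        d2 = ((idx[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        labels[tuple(idx.T)] = np.argmin(d2, axis=1)
    else:  # nested shells with equal-count radial bands
        center = (np.asarray(spec.shape) - 1) / 2.0
        semi = np.asarray(spec.shape) * 0.42
        r = np.sqrt((((idx - center) / semi) ** 2).sum(axis=1))
        qs = np.quantile(r, np.linspace(0, 1, spec.n_habitats + 1)[1:-1]) if spec.n_habitats > 1 else []
        labels[tuple(idx.T)] = np.searchsorted(qs, r)
    present = np.unique(labels[mask])
    if len(present) != spec.n_habitats:
        raise ValueError("at least one habitat is empty at this grid size")
    means = spec.means
    scales = spec.scales
    vol = np.zeros(spec.shape, dtype=float)
    inside = labels[mask]
    vol[mask] = (
        means[inside]
        + scales[inside] * rng.standard_normal(inside.shape)
        + rng.normal(0.0, spec.noise_sd, size=inside.shape)
    )
    return VolumeImage(vol, spec.spacing), ROIMask(mask.astype(np.int8)), labels


def write_phantom_nifti(spec: PhantomSpec, prefix) -> None:
    """Write <prefix>_volume/_mask/_truth.nii.gz for one phantom."""
    vol, mask, labels = simulate_tumor_phantom(spec)
    write_volume(f"{prefix}_volume.nii.gz", vol.data, spec.spacing)
    write_volume(f"{prefix}_mask.nii.gz", mask.data.astype(np.int8), spec.spacing)
    write_volume(f"{prefix}_truth.nii.gz", (labels + 1).astype(np.int16), spec.spacing)


# ---------------------------------------------------------------------------
# clinical cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Planted-effect clinical cohort.

    Effect sizes are log-odds on the remission outcome; defaults are the
    published multivariate estimates (OR 0.48 / 0.13 for the GH bins, 18.29
    for resection rate, 1.06 per ITH unit) with covariate marginals matching
    the residual-tumor cohort tables.  The mediation path is
    intrasellar residual -> resection rate -> remission with no direct
    effect by default.
    """

    n_patients: int = 144
    intercept: float = -1.1
    beta_gh_10_30: float = LN(0.48)
    beta_gh_gt30: float = LN(0.13)
    beta_resection: float = LN(18.29)
    beta_ith: float = LN(1.06)
    beta_intrasellar_direct: float = 0.0
    p_intrasellar: float = 19 / 144
    p_suprasellar: float = 54 / 144
    p_parasellar: float = 127 / 144
    mediator_intercept: float = 0.78
    mediator_slope: float = -0.25
    mediator_noise_sd: float = 0.18
    ith_mean: float = -2.9
    ith_sd: float = 8.0
    gh_log_mu: float = 2.83
    gh_log_sigma: float = 1.1
    gh_upper_normal: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 20:
            raise ValueError("n_patients must be >= 20")
        for p in (self.p_intrasellar, self.p_suprasellar, self.p_parasellar):
            if not 0 <= p <= 1:
                raise ValueError("prevalences must be probabilities")


def simulate_cohort(spec: CohortSpec) -> tuple[list[PatientRecord], dict]:
    """Draw a cohort with the planted structure; returns (records, truth).

    The mediator (resection rate) is linear in the intrasellar-residual
    exposure plus Gaussian noise, clipped to [0, 1] (clipped fraction is
    reported in the truth dict); the remission outcome is Bernoulli with a
    logit linear in GH bin, resection rate, ITH score and the direct
    exposure term.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    gh = np.exp(rng.normal(spec.gh_log_mu, spec.gh_log_sigma, n))
    gh_bin_mid = (gh > 10) & (gh <= 30)
    gh_bin_high = gh > 30
    intrasellar = rng.random(n) < spec.p_intrasellar
    suprasellar = rng.random(n) < spec.p_suprasellar
    parasellar = rng.random(n) < spec.p_parasellar
    ith = rng.normal(spec.ith_mean, spec.ith_sd, n)
    resection_raw = (
        spec.mediator_intercept
        + spec.mediator_slope * intrasellar
        + rng.normal(0.0, spec.mediator_noise_sd, n)
    )
    resection = np.clip(resection_raw, 0.0, 1.0)
    clipped_fraction = float(np.mean(resection != resection_raw))
    logit = (
        spec.intercept
        + spec.beta_gh_10_30 * gh_bin_mid
        + spec.beta_gh_gt30 * gh_bin_high
        + spec.beta_resection * resection
        + spec.beta_ith * ith
        + spec.beta_intrasellar_direct * intrasellar
    )
    p = 1.0 / (1.0 + np.exp(-logit))
    if np.all(p < 1e-10) or np.all(p > 1 - 1e-10):
        raise ValueError("spec produces a numerically degenerate outcome")
    remission = rng.random(n) < p

    tumor_volume = np.exp(rng.normal(1.6, 1.0, n))
    residual_volume = tumor_volume * (1.0 - resection)
    gh_post = np.where(
        remission,
        rng.uniform(0.1, spec.gh_upper_normal * 0.95, n),
        spec.gh_upper_normal + np.exp(rng.normal(0.5, 1.0, n)),
    )
    igf1_norm = np.where(remission, rng.random(n) < 49 / 251, False)
    approaches = rng.choice(["MTS", "ETS", "TCS"], size=n, p=[178 / 458, 256 / 458, 24 / 458])
    ihc = rng.choice(
        ["GH-only", "SL-multiple", "ML-multiple"], size=n, p=[66 / 458, 340 / 458, 52 / 458]
    )
    sexes = rng.choice(["M", "F"], size=n, p=[234 / 458, 224 / 458])
    ages = np.clip(rng.normal(41.15, 11.22, n), 18, 80)
    enc = np.where(
        rng.random(n) < 15 / 144, 0.0, np.clip(rng.normal(35, 18, n), 0.1, 100.0)
    )
    knosp = rng.integers(0, 5, n)
    hardy_g = rng.choice(["I", "II", "III", "IV"], size=n)
    hardy_s = rng.choice(["0", "A", "B", "C", "D", "E"], size=n)
    subclusters = rng.integers(3, 6, n)

    records = [
        PatientRecord(
            patient_id=f"P{i:04d}",
            age=float(ages[i]),
            sex=str(sexes[i]),
            surgery_approach=str(approaches[i]),
            ihc_class=str(ihc[i]),
            gh_preop=float(gh[i]),
            gh_post24h=float(gh_post[i]),
            tumor_volume=float(tumor_volume[i]),
            residual_volume=float(residual_volume[i]),
            residual_present=bool(residual_volume[i] > 1e-9),
            residual_suprasellar=bool(suprasellar[i]),
            residual_intrasellar=bool(intrasellar[i]),
            residual_parasellar=bool(parasellar[i]),
            ica_encasement_pct=float(enc[i]),
            knosp_grade=int(knosp[i]),
            hardy_grade=str(hardy_g[i]),
            hardy_stage=str(hardy_s[i]),
            ith_score=float(ith[i]),
            subclusters=int(subclusters[i]),
            igf1_normalized=bool(igf1_norm[i]),
        )
        for i in range(n)
    ]
    truth = {
        "remission": remission,
        "p_remission": p,
        "betas": {
            "intercept": spec.intercept,
            "gh_10_30": spec.beta_gh_10_30,
            "gh_gt30": spec.beta_gh_gt30,
            "resection": spec.beta_resection,
            "ith": spec.beta_ith,
            "intrasellar_direct": spec.beta_intrasellar_direct,
        },
        "mediator": {
            "intercept": spec.mediator_intercept,
            "slope": spec.mediator_slope,
            "noise_sd": spec.mediator_noise_sd,
            "clipped_fraction": clipped_fraction,
        },
        "gh_upper_normal": spec.gh_upper_normal,
    }
    return records, truth


def cohort_to_csv(records, truth, prefix) -> None:
    from .cohort_stats import records_to_frame

    df = records_to_frame(records)
    df["remission"] = truth["remission"]
    df.to_csv(f"{prefix}_cohort.csv", index=False)
    serializable = {
        k: v
        for k, v in truth.items()
        if k not in ("remission", "p_remission")
    }
    with open(f"{prefix}_truth.json", "w") as fh:
        json.dump(serializable, fh, indent=1)


# ---------------------------------------------------------------------------
# count matrices


@dataclass(frozen=True)
class CountMatrix:
    """Sparse genes x cells count matrix with per-cell sample labels."""

    counts: sparse.csr_matrix  # genes x cells
    gene_names: tuple
    cell_ids: tuple
    sample_labels: tuple
    mito_prefix: str = "MT-"

    def __post_init__(self):
        c = sparse.csr_matrix(self.counts)
        if c.shape != (len(self.gene_names), len(self.cell_ids)):
            raise ValueError("counts shape inconsistent with names")
        if len(self.sample_labels) != len(self.cell_ids):
            raise ValueError("every cell needs a sample label")
        if c.nnz and c.data.min() < 0:
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        object.__setattr__(self, "cell_ids", tuple(self.cell_ids))
        object.__setattr__(self, "sample_labels", tuple(self.sample_labels))

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def mito_gene_mask(self) -> np.ndarray:
        return np.array([g.startswith(self.mito_prefix) for g in self.gene_names])


def simulate_count_matrix(
    n_genes: int = 1500,
    n_cells: int = 400,
    n_samples: int = 4,
    n_low_gene_cells: int = 0,
    n_high_mito_cells: int = 0,
    gh1_dispersion: Optional[tuple[float, ...]] = None,
    n_mito_genes: int = 13,
    seed: int = 0,
) -> tuple[CountMatrix, dict]:
    """Negative-binomial count matrix with planted QC violations.

    Designated cells are forced below 100 detected genes or above 10%
    mitochondrial content; GH1 is drawn per sample with the requested
    negative-binomial dispersion (Gamma-Poisson ``1/size`` parameter).
    Returns (matrix, truth) where truth lists the planted rosters.
    """
    if n_low_gene_cells + n_high_mito_cells > n_cells:
        raise ValueError("planted violations exceed cell count")
    if gh1_dispersion is not None and len(gh1_dispersion) != n_samples:
        raise ValueError("need one GH1 dispersion per sample")
    rng = np.random.default_rng(seed)
    genes = [f"MT-G{i}" for i in range(n_mito_genes)]
    genes += ["GH1", "POU1F1"]
    genes += [f"GENE{i}" for i in range(n_genes - len(genes))]
    gene_names = tuple(genes)
    gh1_idx = genes.index("GH1")
    pou_idx = genes.index("POU1F1")
    mito_idx = np.arange(n_mito_genes)

    base = np.exp(rng.normal(-0.3, 1.0, n_genes))
    base[mito_idx] = np.exp(rng.normal(1.2, 0.3, n_mito_genes))  # ~5% mito content
    depth = np.exp(rng.normal(0.0, 0.25, n_cells))
    lam = base[:, None] * depth[None, :]
    counts = rng.poisson(rng.gamma(shape=2.0, scale=lam / 2.0)).astype(np.int64)

    samples = np.array([f"S{i % n_samples}" for i in range(n_cells)])
    # tumor marker: ~96% of cells POU1F1-positive
    tumor = rng.random(n_cells) < 0.96
    counts[pou_idx, :] = np.where(tumor, rng.poisson(5.0, n_cells) + 1, 0)
    # per-sample GH1 with planted dispersion
    disp = gh1_dispersion if gh1_dispersion is not None else tuple([0.5] * n_samples)
    gh1_mean = 20.0
    for si in range(n_samples):
        cells = np.where(samples == f"S{si}")[0]
        d = max(disp[si], 1e-9)
        lam_gh1 = rng.gamma(shape=1.0 / d, scale=gh1_mean * d, size=len(cells))
        counts[gh1_idx, cells] = rng.poisson(lam_gh1 * depth[cells])

    order = rng.permutation(n_cells)
    low_gene = order[:n_low_gene_cells]
    high_mito = order[n_low_gene_cells : n_low_gene_cells + n_high_mito_cells]
    for c in low_gene:
        keep = rng.choice(n_genes, size=50, replace=False)
        col = np.zeros(n_genes, dtype=np.int64)
        col[keep] = counts[keep, c]
        col[keep[col[keep] == 0]] = 1  # ensure ~50 detected genes, never >= 100
        counts[:, c] = col
    for c in high_mito:
        non_mito_total = counts[:, c].sum() - counts[mito_idx, c].sum()
        # force mito fraction ~30%
        target = max(int(0.45 * non_mito_total), 10)
        counts[mito_idx, c] = rng.multinomial(target, np.ones(n_mito_genes) / n_mito_genes)

    cm = CountMatrix(
        sparse.csr_matrix(counts),
        gene_names,
        tuple(f"C{i:05d}" for i in range(n_cells)),
        tuple(samples),
    )
    truth = {
        "planted_low_gene_cells": tuple(f"C{i:05d}" for i in sorted(low_gene)),
        "planted_high_mito_cells": tuple(f"C{i:05d}" for i in sorted(high_mito)),
        "tumor_cells": tuple(np.array(cm.cell_ids)[tumor]),
        "gh1_dispersion": tuple(disp),
    }
    return cm, truth


def write_count_matrix(cm: CountMatrix, prefix) -> None:
    """MatrixMarket bundle: <prefix>.mtx + _genes/_barcodes/_samples.tsv."""
    from scipy.io import mmwrite

    mmwrite(f"{prefix}.mtx", cm.counts)
    pd.Series(cm.gene_names).to_csv(f"{prefix}_genes.tsv", sep="\t", index=False, header=False)
    pd.Series(cm.cell_ids).to_csv(f"{prefix}_barcodes.tsv", sep="\t", index=False, header=False)
    pd.DataFrame({"cell": cm.cell_ids, "sample": cm.sample_labels}).to_csv(
        f"{prefix}_samples.tsv", sep="\t", index=False
    )
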