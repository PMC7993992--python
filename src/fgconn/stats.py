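"""Inference and descriptive statistics around prediction results.

Covers: multi-level block permutation for family-structured cohorts, the
permutation p-value convention (k+1)/(n+1), test-set-only bootstrap CIs for
contrasts between cross-validated R² values, the region-size-corrected
topographic idiosyncrasy index, Dice overlap of vertex sets, top-k region
selection, and cortical-system overlap percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .cohort import FamilyStructure, Parcellation
from .predict import cv_r2

__all__ = [
    "IdiosyncrasyResult",
    "ContrastCI",
    "idiosyncrasy_index",
    "block_permutation",
    "permutation_pvalue",
    "bootstrap_contrast",
    "dice",
    "top_k_regions",
    "system_overlap",
    "dominant_system",
    "pearson_r",
]


@dataclass(frozen=True)
class IdiosyncrasyResult:
    """Per-region transform dissimilarity, raw and size-corrected.

    ``raw`` is the mean over subject pairs of ‖T_i − T_j‖_F; because that
    norm grows like sqrt(region size), ``residual`` is the residual of an OLS
    regression of ``raw`` on sqrt(region size) and is the usable
    idiosyncrasy index.
    """

    raw: np.ndarray
    sqrt_region_size: np.ndarray
    residual: np.ndarray
    slope: float
    intercept: float


@dataclass(frozen=True)
class ContrastCI:
    """Percentile bootstrap CI for a contrast between two VAF values."""

    kind: str                 # "difference" | "ratio"
    point: float
    lower: float
    upper: float
    n_boot: int
    seed: int
    n_redrawn: int = 0        # degenerate resamples that were redrawn


def idiosyncrasy_index(
    transforms_by_region: dict[int, list[np.ndarray]],
    region_sizes: np.ndarray | None = None,
) -> IdiosyncrasyResult:
    """Mean pairwise Frobenius transform distance per region, size-corrected.

    ``transforms_by_region`` maps region id → list of per-subject orthogonal
    matrices. Requires ≥ 2 subjects and ≥ 3 regions (for the regression).
    """
    regions = sorted(transforms_by_region)
    if len(regions) < 3:
        raise ValueError("need >= 3 regions for the size regression")
    raw = np.empty(len(regions))
    sizes = np.empty(len(regions))
    for k, r in enumerate(regions):
        mats = transforms_by_region[r]
        if len(mats) < 2:
            raise ValueError("need >= 2 subjects")
        stack = np.stack(mats)  # (n_sub, n_r, n_r)
        n_sub = len(mats)
        # pairwise Frobenius distances without an explicit double loop:
        # ‖Ti − Tj‖² = ‖Ti‖² + ‖Tj‖² − 2<Ti, Tj>
        flat = stack.reshape(n_sub, -1)
        sq = np.sum(flat**2, axis=1)
        inner = flat @ flat.T
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * inner, 0.0)
        iu = np.triu_indices(n_sub, k=1)
        raw[k] = np.sqrt(d2[iu]).mean()
        sizes[k] = mats[0].shape[0]
    x = np.sqrt(sizes)
    if np.ptp(x) == 0:  # all regions the same size: nothing to correct
        slope, intercept = 0.0, float(raw.mean())
    else:
        slope, intercept = np.polyfit(x, raw, 1)
    resid = raw - (slope * x + intercept)
    return IdiosyncrasyResult(
        raw=raw, sqrt_region_size=x, residual=resid,
        slope=float(slope), intercept=float(intercept),
    )


def block_permutation(
    scores: np.ndarray,
    families: FamilyStructure,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Multi-level block permutations respecting family structure.

    Each permutation (a) shuffles members within every family and (b)
    exchanges whole families only among families of identical size, so the
    family composition of every position is preserved. Singleton families
    form their own stratum and permute freely among singleton positions.
    Returns an (n_perm, n_subjects) array of permuted scores.
    """
    scores = np.asarray(scores, float)
    rng = np.random.default_rng(seed)
    fam_members = [families.members_of(f) for f in range(families.n_families)]
    sizes = np.array([len(m) for m in fam_members])
    out = np.empty((n_perm, families.n_subjects))
    for p in range(n_perm):
        perm = np.empty(families.n_subjects)
        for size in np.unique(sizes):
            stratum = np.nonzero(sizes == size)[0]
            source = rng.permutation(stratum)  # which family's scores go where
            for dest, src in zip(stratum, source):
                vals = scores[fam_members[src]]
                perm[fam_members[dest]] = rng.permutation(vals)
        out[p] = perm
    return out


def permutation_pvalue(observed: float, permuted: np.ndarray) -> float:
    """p = (1 + #{perm ≥ observed}) / (1 + n_perm)."""
    permuted = np.asarray(permuted, float)
    if permuted.size == 0:
        raise ValueError("need at least one permutation")
    return float((1 + np.sum(permuted >= observed)) / (1 + permuted.size))


def bootstrap_contrast(
    y: np.ndarray,
    predictions_a: np.ndarray,
    predictions_b: np.ndarray,
    train_means: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[ContrastCI, ContrastCI]:
    """Test-set-only bootstrap of the VAF difference and ratio.

    Subjects are resampled with replacement; both cross-validated R² values
    are recomputed per resample from the fixed, already-trained predictions
    (models are never refit — the per-subject null prediction ȳᵢ,train is
    resampled alongside). Returns 95% percentile CIs for VAF_A − VAF_B and
    VAF_A / VAF_B. Resamples with a zero null-model sum of squares are
    redrawn and counted.
    """
    y = np.asarray(y, float)
    a = np.asarray(predictions_a, float)
    b = np.asarray(predictions_b, float)
    tm = np.asarray(train_means, float)
    n = len(y)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    ratios = np.empty(n_boot)
    redrawn = 0
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, n)
        denom = np.sum((y[idx] - tm[idx]) ** 2)
        if denom == 0:
            redrawn += 1
            if redrawn > 100 * max(n_boot, 1):
                raise RuntimeError("bootstrap stuck on degenerate resamples")
            continue
        vaf_a = cv_r2(y[idx], a[idx], tm[idx])
        vaf_b = cv_r2(y[idx], b[idx], tm[idx])
        diffs[i] = vaf_a - vaf_b
        ratios[i] = vaf_a / vaf_b if vaf_b != 0 else np.nan
        i += 1
    vaf_a0 = cv_r2(y, a, tm)
    vaf_b0 = cv_r2(y, b, tm)
    d_lo, d_hi = np.percentile(diffs, [2.5, 97.5])
    finite = ratios[np.isfinite(ratios)]
    r_lo, r_hi = (np.percentile(finite, [2.5, 97.5]) if finite.size
                  else (np.nan, np.nan))
    diff_ci = ContrastCI("difference", float(vaf_a0 - vaf_b0),
                         float(d_lo), float(d_hi), n_boot, seed, redrawn)
    ratio_point = vaf_a0 / vaf_b0 if vaf_b0 != 0 else np.nan
    ratio_ci = ContrastCI("ratio", float(ratio_point),
                          float(r_lo), float(r_hi), n_boot, seed, redrawn)
    return diff_ci, ratio_ci


def dice(set_a: set | np.ndarray, set_b: set | np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) of two vertex sets."""
    a, b = set(np.asarray(list(set_a)).tolist()), set(np.asarray(list(set_b)).tolist())
    if not a and not b:
        raise ValueError("Dice undefined for two empty sets")
    return 2.0 * len(a & b) / (len(a) + len(b))


def top_k_regions(r2_by_region: np.ndarray, k: int = 30) -> np.ndarray:
    """Ids of the k regions with largest R²; boundary ties go to the lower id."""
    r2 = np.asarray(r2_by_region, float)
    if k > len(r2):
        raise ValueError(f"k={k} exceeds {len(r2)} regions")
    order = np.lexsort((np.arange(len(r2)), -r2))  # r2 desc, then id asc
    return np.sort(order[:k])


def system_overlap(
    region_set: np.ndarray,
    system_label: np.ndarray,
    parcellation: Parcellation,
) -> dict[int, float]:
    """Percent of the regions' pooled vertices in each cortical system."""
    system_label = np.asarray(system_label)
    if len(system_label) != parcellation.n_vertices:
        raise ValueError("system labels do not cover all vertices")
    vertices = np.concatenate(
        [parcellation.vertices_of(r) for r in np.asarray(region_set)]
    )
    labels, counts = np.unique(system_label[vertices], return_counts=True)
    return {int(s): 100.0 * c / len(vertices) for s, c in zip(labels, counts)}


def dominant_system(
    region: int, system_label: np.ndarray, parcellation: Parcellation
) -> int:
    """The system holding the most of the region's vertices (ties → lower id)."""
    v = parcellation.vertices_of(region)
    labels, counts = np.unique(np.asarray(system_label)[v], return_counts=True)
    return int(labels[np.argmax(counts)])


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    return float(sps.pearsonr(x, y).statistic)
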