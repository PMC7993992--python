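"""Connectivity hyperalignment (CHA).

Each subject's vertices within a region are remixed by an orthogonal matrix
(an improper rotation — reflections allowed, no scaling) so that vertex-wise
connectivity-target profiles align across subjects in a shared space. The
connectivity targets are the region-mean time series of the parcellation, so
each vertex's seed profile is a vector of R correlation coefficients.

Because the transforms are orthogonal, the information content of a region's
data is untouched: Frobenius norms and pairwise timepoint geometry are
preserved exactly; only the cortical topography of the information changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Parcellation, SubjectTimeSeries

__all__ = [
    "Transform",
    "CommonModel",
    "region_mean_timeseries",
    "cha_seed_profiles",
    "fit_procrustes",
    "build_common_model",
    "apply_transform",
    "fit_cha",
    "apply_cha",
    "identity_transforms",
]


@dataclass(frozen=True)
class Transform:
    """Orthogonal vertex-remixing matrix for one subject × region.

    Aligned data are ``matrix.T @ block``; ``matrix.T @ matrix = I`` and
    ``|det| = 1`` (reflections permitted, never any scaling).
    """

    matrix: np.ndarray
    subject_id: int
    region_id: int

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("transform must be square")
        if not np.allclose(m.T @ m, np.eye(m.shape[0]), atol=1e-8):
            raise ValueError("transform is not orthogonal within 1e-8")


@dataclass
class CommonModel:
    """Per-region common-space template of vertex × target connectivity."""

    templates: dict[int, np.ndarray]  # region_id -> (n_r, R)
    n_passes: int = 2
    subject_order: tuple[int, ...] = field(default_factory=tuple)


def region_mean_timeseries(
    ts: SubjectTimeSeries, parcellation: Parcellation
) -> np.ndarray:
    """Unweighted mean time series per region, shape (R, T)."""
    if parcellation.n_vertices != ts.n_vertices:
        raise ValueError("parcellation does not match time series")
    sizes = parcellation.region_sizes()
    if np.any(sizes == 0):
        raise ValueError("empty region in parcellation")
    sums = np.zeros((parcellation.n_regions, ts.n_timepoints))
    np.add.at(sums, parcellation.region_label, ts.values)
    return sums / sizes[:, None]


def _corr_rows(a: np.ndarray, b: np.ndarray, what: str = "series") -> np.ndarray:
    """Pearson correlation between every row of a and every row of b."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.linalg.norm(a, axis=1)
    sb = np.linalg.norm(b, axis=1)
    for name, s in (("row", sa), ("target", sb)):
        bad = np.nonzero(s == 0)[0]
        if bad.size:
            raise ValueError(f"zero-variance {what} ({name} {bad[0]})")
    return np.clip((a @ b.T) / np.outer(sa, sb), -1.0, 1.0)


def cha_seed_profiles(ts: SubjectTimeSeries, targets: np.ndarray) -> np.ndarray:
    """Correlation of each vertex's series with each target series, (V, R).

    Runs are treated as already concatenated (preprocessing leaves each run
    mean ~0, so concatenated-run correlation is well defined).
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlations")
    if targets.shape[1] != ts.n_timepoints:
        raise ValueError("target length does not match time series")
    return _corr_rows(ts.values, targets)


def fit_procrustes(source: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Orthogonal T minimizing ``‖T.T @ source − template‖_F`` — no scaling.

    Solved in closed form from the SVD of ``source @ template.T``; the full
    orthogonal group is searched, so T may include a reflection. Degenerate
    singular subspaces are disambiguated by a deterministic sign convention
    (largest-magnitude element of each left singular vector made positive).

    When the cross-product is rank deficient (fewer targets than vertices)
    the optimum is not unique; the unconstrained subspace is completed with
    the minimal rotation (T as close to the identity as the constrained part
    allows), so a transform never scrambles directions the data do not pin
    down.
    """
    if source.shape != template.shape:
        raise ValueError("source and template shapes differ")
    m = source @ template.T
    if not np.any(m):
        raise ValueError("rank-0 cross-product; cannot fit a rotation")
    u, s, vt = np.linalg.svd(m)
    # sign convention on singular vector pairs (stabilizes exact ties)
    signs = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    u = u * signs
    vt = vt * signs[:, None]
    k = int(np.sum(s > s[0] * 1e-10))
    n = m.shape[0]
    if k == n:
        return u @ vt
    t = u[:, :k] @ vt[:k]
    u2, v2 = u[:, k:], vt[k:].T
    # minimal-rotation completion: maximize tr(T) over the free block
    p, _, qt = np.linalg.svd(v2.T @ u2)
    return t + u2 @ (qt.T @ p.T) @ v2.T


def apply_transform(block: np.ndarray, transform: Transform | np.ndarray) -> np.ndarray:
    """Map a region's (n_r, T) data block into the common space: ``T.T @ block``."""
    t = transform.matrix if isinstance(transform, Transform) else transform
    if t.shape[1] != block.shape[0]:
        raise ValueError(
            f"transform of size {t.shape} does not match block with "
            f"{block.shape[0]} vertices"
        )
    return t.T @ block


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    c = x - x.mean(axis=1, keepdims=True)
    sd = c.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return c / sd


def build_common_model(
    seed_profiles: list[np.ndarray],
    region_id: int,
    subject_ids: list[int] | None = None,
    normalize: bool = True,
) -> tuple[np.ndarray, list[Transform]]:
    """Iterative common template for one region, plus per-subject transforms.

    Two-pass sequential-average algorithm: pass 1 aligns subjects one at a
    time to a running average seeded by the first subject; pass 2 re-aligns
    every subject to the pass-1 mean and averages the results into the final
    template; transforms are then re-fit to that final template. Deterministic
    given the subject order.

    Seed profiles are z-scored per vertex before fitting (removes per-vertex
    scale leverage; the transform itself still contains no scaling).
    """
    n_sub = len(seed_profiles)
    if n_sub < 2:
        raise ValueError("need at least 2 subjects to build a common model")
    if subject_ids is None:
        subject_ids = list(range(n_sub))
    profiles = [_zscore_rows(p) if normalize else np.asarray(p, float)
                for p in seed_profiles]

    # pass 1: running average
    template = profiles[0].copy()
    for i in range(1, n_sub):
        t = fit_procrustes(profiles[i], template)
        aligned = t.T @ profiles[i]
        template = (template * i + aligned) / (i + 1)

    # pass 2: re-align everyone to the pass-1 mean, average
    aligned_sum = np.zeros_like(template)
    for p in profiles:
        t = fit_procrustes(p, template)
        aligned_sum += t.T @ p
    final_template = aligned_sum / n_sub

    transforms = [
        Transform(matrix=fit_procrustes(p, final_template),
                  subject_id=sid, region_id=region_id)
        for p, sid in zip(profiles, subject_ids)
    ]
    return final_template, transforms


def fit_cha(
    subjects: list[SubjectTimeSeries], parcellation: Parcellation
) -> tuple[CommonModel, dict[tuple[int, int], Transform]]:
    """Fit connectivity hyperalignment for every region of a cohort.

    Returns the common model and transforms keyed by (subject, region).
    Transforms fit on one dataset must not be applied to another unless
    cross-dataset alignment is explicitly intended.
    """
    profiles = [
        cha_seed_profiles(ts, region_mean_timeseries(ts, parcellation))
        for ts in subjects
    ]
    templates: dict[int, np.ndarray] = {}
    transforms: dict[tuple[int, int], Transform] = {}
    for r in range(parcellation.n_regions):
        idx = parcellation.vertices_of(r)
        region_profiles = [p[idx] for p in profiles]
        template, region_transforms = build_common_model(
            region_profiles, region_id=r,
            subject_ids=list(range(len(subjects))),
        )
        templates[r] = template
        for t in region_transforms:
            transforms[(t.subject_id, r)] = t
    model = CommonModel(templates=templates,
                        subject_order=tuple(range(len(subjects))))
    return model, transforms


def identity_transforms(
    subjects: list[SubjectTimeSeries], parcellation: Parcellation
) -> dict[tuple[int, int], Transform]:
    """Identity transforms for every subject × region (the anatomical-alignment
    baseline: the pipeline runs unchanged but no vertex remixing occurs)."""
    out: dict[tuple[int, int], Transform] = {}
    for r in range(parcellation.n_regions):
        n_r = len(parcellation.vertices_of(r))
        eye = np.eye(n_r)
        for i in range(len(subjects)):
            out[(i, r)] = Transform(matrix=eye, subject_id=i, region_id=r)
    return out


def apply_cha(
    ts: SubjectTimeSeries,
    parcellation: Parcellation,
    transforms: dict[tuple[int, int], Transform],
    subject_id: int,
) -> SubjectTimeSeries:
    """Apply a subject's per-region transforms to their full time series."""
    out = np.empty_like(ts.values, dtype=float)
    for r in range(parcellation.n_regions):
        idx = parcellation.vertices_of(r)
        out[idx] = apply_transform(ts.values[idx], transforms[(subject_id, r)])
    return SubjectTimeSeries(values=out, run_boundaries=ts.run_boundaries)
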