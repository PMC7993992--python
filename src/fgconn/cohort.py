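"""Synthetic multi-subject cohorts with a planted latent trait.

This module generates desk-scale stand-ins for a large resting/task fMRI
cohort: per-subject vertex x time arrays on a shared parcellation, a family
structure with a realistic family-size histogram, ten cognitive test scores
generated from a bifactor model, and per-subject, per-region orthogonal
"topographic scrambling" matrices.

The generative model plants an individual-difference signal (``g``) at a
controlled spatial scale:

* ``fine_effect`` moves vertex-level source weights (column-centered, so
  region-mean time series — and hence coarse, region-pair connectivity — are
  untouched);
* ``coarse_effect`` modulates inter-region source coupling (moves only
  region-pair block means of connectivity);
* ``rotation_dispersion`` controls how far each subject's per-region
  orthogonal matrix strays from the identity (reflections allowed), emulating
  idiosyncratic functional topographies that survive anatomical alignment.

Because the two effects act on orthogonal parts of the connectivity profile,
downstream analyses can test cleanly whether fine-grained (residual) or
coarse-grained connectivity carries the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FamilyStructure",
    "Parcellation",
    "CohortConfig",
    "SubjectTimeSeries",
    "TraitScores",
    "PAPER_FAMILY_HISTOGRAM",
    "DESK_FAMILY_HISTOGRAM",
    "DEFAULT_G_LOADINGS",
    "DEFAULT_GROUP_ASSIGNMENT",
    "make_family_structure",
    "make_parcellation",
    "simulate_cohort",
    "simulate_test_scores",
    "random_orthogonal",
    "dispersed_orthogonal",
    "mean_preserving_orthogonal",
]

#: Family-size histogram of the HCP-like prediction cohort: 103 singletons and
#: 177/107/22/2 families of sizes 2-5 → 411 families, 876 subjects.
PAPER_FAMILY_HISTOGRAM: dict[int, int] = {1: 103, 2: 177, 3: 107, 4: 22, 5: 2}

#: Desk-scale histogram with the same 1-5 family-size range, scaled to
#: 120 subjects in 53 families.
DESK_FAMILY_HISTOGRAM: dict[int, int] = {1: 10, 2: 24, 3: 15, 4: 3, 5: 1}

#: Default general-factor loadings for the ten synthetic cognitive tests,
#: chosen so regression g scores recover the planted g with r ≈ 0.92 at
#: large n, matching the determinacy of well-constructed test batteries.
DEFAULT_G_LOADINGS: tuple[float, ...] = (
    0.80, 0.78, 0.75, 0.72, 0.70, 0.68, 0.65, 0.62, 0.60, 0.55,
)

#: Default assignment of the ten tests to three group factors
#: (memory / speed / reasoning-like).
DEFAULT_GROUP_ASSIGNMENT: tuple[int, ...] = (0, 0, 0, 1, 1, 1, 2, 2, 2, 2)


class InvalidConfigError(ValueError):
    """Raised when a generator configuration is inconsistent."""


@dataclass(frozen=True)
class FamilyStructure:
    """Subject → family assignment.

    ``family_id`` is an integer label per subject; ids are contiguous from 0.
    """

    subject_id: np.ndarray
    family_id: np.ndarray

    def __post_init__(self) -> None:
        if len(self.subject_id) != len(self.family_id):
            raise InvalidConfigError("subject_id and family_id lengths differ")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_id)

    @property
    def n_families(self) -> int:
        return len(np.unique(self.family_id))

    def family_sizes(self) -> np.ndarray:
        """Size of each family, indexed by family id."""
        return np.bincount(self.family_id, minlength=self.n_families)

    def histogram(self) -> dict[int, int]:
        """Family-size histogram, ``{size: count}``."""
        sizes, counts = np.unique(self.family_sizes(), return_counts=True)
        return {int(s): int(c) for s, c in zip(sizes, counts)}

    def members_of(self, fam: int) -> np.ndarray:
        return self.subject_id[self.family_id == fam]


@dataclass(frozen=True)
class Parcellation:
    """Vertex → region labeling (R regions over V vertices)."""

    region_label: np.ndarray  # (V,), values in 0..R-1

    @property
    def n_vertices(self) -> int:
        return len(self.region_label)

    @property
    def n_regions(self) -> int:
        return int(self.region_label.max()) + 1

    def vertices_of(self, region: int) -> np.ndarray:
        return np.nonzero(self.region_label == region)[0]

    def region_sizes(self) -> np.ndarray:
        return np.bincount(self.region_label, minlength=self.n_regions)


@dataclass(frozen=True)
class SubjectTimeSeries:
    """Vertex × timepoint signal array plus run boundaries.

    ``run_boundaries`` lists the starting offset of each run; run ``k`` spans
    ``run_boundaries[k]:run_boundaries[k+1]`` (the last run ends at T).
    """

    values: np.ndarray  # (V, T)
    run_boundaries: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.run_boundaries[0] != 0:
            raise ValueError("first run must start at 0")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def run_slices(self) -> list[slice]:
        edges = list(self.run_boundaries) + [self.n_timepoints]
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class TraitScores:
    """Planted trait, observed test scores, and (later) the estimated trait."""

    g_true: np.ndarray
    test_scores: pd.DataFrame  # columns test_01..test_10
    g_estimated: np.ndarray | None = None

    def to_frame(self, families: FamilyStructure) -> pd.DataFrame:
        df = pd.DataFrame(
            {"subject_id": families.subject_id, "family_id": families.family_id}
        )
        df["g_true"] = self.g_true
        for c in self.test_scores.columns:
            df[c] = self.test_scores[c].to_numpy()
        if self.g_estimated is not None:
            df["g_estimated"] = self.g_estimated
        return df


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults are the desk-scale study conditions: 120 subjects in 53 families,
    24 regions of ~30 vertices, 2 runs × 300 timepoints.
    """

    family_histogram: Mapping[int, int] = field(
        default_factory=lambda: dict(DESK_FAMILY_HISTOGRAM)
    )
    n_vertices: int = 720
    n_regions: int = 24
    n_runs: int = 2
    n_timepoints_per_run: int = 300
    n_latent_sources: int = 30
    n_global_sources: int = 36
    n_coupling_sources: int = 3
    coupling_strength: float = 0.5
    fine_effect: float = 0.35
    coarse_effect: float = 0.07
    weight_noise: float = 0.35
    coupling_noise: float = 0.35
    rotation_dispersion: float = 0.5
    noise_sd: float = 0.5
    family_g_correlation: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_vertices, self.n_regions, self.n_runs,
            self.n_timepoints_per_run, self.n_latent_sources,
            self.n_global_sources, self.n_coupling_sources,
        ]
        if any(c <= 0 for c in counts):
            raise InvalidConfigError("all counts must be positive")
        effects = [self.fine_effect, self.coarse_effect, self.weight_noise,
                   self.coupling_noise, self.rotation_dispersion, self.noise_sd]
        if not all(np.isfinite(effects)):
            raise InvalidConfigError("non-finite generator parameter")
        if any(e < 0 for e in effects):
            raise InvalidConfigError("effects must be >= 0")
        if not 0.0 <= self.family_g_correlation < 1.0:
            raise InvalidConfigError("family_g_correlation must be in [0, 1)")

    @property
    def n_subjects(self) -> int:
        return sum(s * c for s, c in self.family_histogram.items())

    @property
    def n_timepoints(self) -> int:
        return self.n_runs * self.n_timepoints_per_run


def make_family_structure(
    histogram: Mapping[int, int], seed: int | np.random.Generator = 0
) -> FamilyStructure:
    """Build a family structure realizing a family-size histogram.

    Family ids are contiguous integers; the subject → family assignment is
    shuffled by ``seed`` so family members are not contiguous in subject order.
    """
    if not histogram:
        raise InvalidConfigError("empty family histogram")
    for size, count in histogram.items():
        if size <= 0 or count < 0:
            raise InvalidConfigError(f"bad histogram entry {size}:{count}")
    rng = np.random.default_rng(seed)
    fam_sizes: list[int] = []
    for size in sorted(histogram):
        fam_sizes.extend([size] * histogram[size])
    family_of_subject = np.repeat(np.arange(len(fam_sizes)), fam_sizes)
    rng.shuffle(family_of_subject)
    n = len(family_of_subject)
    return FamilyStructure(subject_id=np.arange(n), family_id=family_of_subject)


def make_parcellation(
    n_vertices: int, n_regions: int, seed: int | np.random.Generator = 0
) -> Parcellation:
    """Partition ``n_vertices`` into ``n_regions`` contiguous blocks.

    Block boundaries are near-equal with seed-controlled jitter, so region
    sizes vary the way cortical parcel sizes do. Every region is non-empty.
    """
    if n_regions > n_vertices:
        raise InvalidConfigError("more regions than vertices")
    rng = np.random.default_rng(seed)
    base = np.linspace(0, n_vertices, n_regions + 1)
    jitter_scale = max((n_vertices / n_regions) * 0.15, 0.0)
    inner = base[1:-1] + rng.normal(0, jitter_scale, n_regions - 1)
    edges = np.concatenate([[0], np.sort(inner), [n_vertices]])
    edges = np.round(edges).astype(int)
    # enforce strictly increasing edges → every region >= 1 vertex
    for i in range(1, len(edges)):
        if edges[i] <= edges[i - 1]:
            edges[i] = edges[i - 1] + 1
    overflow = edges[-1] - n_vertices
    if overflow > 0:
        for i in range(len(edges) - 1, 0, -1):
            edges[i] -= overflow
            if edges[i] > edges[i - 1]:
                break
            overflow = edges[i - 1] - edges[i] + 1
            edges[i] = edges[i - 1] + 1
    edges[-1] = n_vertices
    labels = np.empty(n_vertices, dtype=int)
    for r in range(n_regions):
        labels[edges[r]: edges[r + 1]] = r
    return Parcellation(region_label=labels)


def random_orthogonal(n: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform orthogonal matrix via QR of a Gaussian with sign fix."""
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def dispersed_orthogonal(
    n: int, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Orthogonal matrix interpolated geodesically from identity.

    ``dispersion=0`` gives the identity; ``dispersion=1`` gives a Haar-uniform
    rotation. Interpolation is along the geodesic in SO(n): the matrix
    logarithm of a uniform rotation is scaled by ``dispersion`` and
    re-exponentiated. A reflection (det −1) is composed in with probability
    ``dispersion / 2``.
    """
    if not 0.0 <= dispersion <= 1.0:
        raise InvalidConfigError("rotation_dispersion must be in [0, 1]")
    if dispersion == 0.0:
        return np.eye(n)
    if n == 1:
        return np.array([[-1.0 if rng.random() < dispersion / 2.0 else 1.0]])
    from scipy.linalg import expm, logm

    q = random_orthogonal(n, rng)
    if np.linalg.det(q) < 0:  # stay in SO(n) for the geodesic
        q[:, [0, 1]] = q[:, [1, 0]]
    log_q = np.real(logm(q))
    out = np.real(expm(dispersion * log_q))
    if rng.random() < dispersion / 2.0:
        out[:, [0, 1]] = out[:, [1, 0]]  # compose a reflection
    return out


def mean_preserving_orthogonal(
    n: int, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Dispersed orthogonal matrix that fixes the uniform-mean direction.

    The rotation acts only in the (n−1)-dim subspace orthogonal to the
    all-ones vector, so ``Q @ 1 = 1``: vertex patterns are scrambled but the
    region's mean time series is untouched. This models topographic
    idiosyncrasy as a rearrangement of the fine pattern that leaves the
    coarse (regional-mean) signal anatomically stable — which is also what
    makes regional means usable as shared connectivity-alignment targets.
    """
    if n == 1:
        return np.eye(1)
    ones = np.ones((n, 1)) / np.sqrt(n)
    basis = np.linalg.svd(np.eye(n) - ones @ ones.T)[0][:, : n - 1]
    q_sub = dispersed_orthogonal(n - 1, dispersion, rng)
    return ones @ ones.T + basis @ q_sub @ basis.T


def _draw_g(config: CohortConfig, families: FamilyStructure,
            rng: np.random.Generator) -> np.ndarray:
    """Planted trait with within-family correlation, standardized cohort-wide."""
    rho = config.family_g_correlation
    fam_effect = rng.standard_normal(families.n_families)
    g = (np.sqrt(rho) * fam_effect[families.family_id]
         + np.sqrt(1.0 - rho) * rng.standard_normal(families.n_subjects))
    if families.n_subjects == 1:  # single-subject cohort: no trait variation
        return np.zeros(1)
    g = g - g.mean()
    sd = g.std()
    if sd == 0:
        raise InvalidConfigError("degenerate g draw (zero variance)")
    return g / sd


def simulate_test_scores(
    g_true: np.ndarray,
    loadings_g: Sequence[float] = DEFAULT_G_LOADINGS,
    group_assignment: Sequence[int] = DEFAULT_GROUP_ASSIGNMENT,
    loadings_group: Sequence[float] | float = 0.45,
    noise_sd: Sequence[float] | float = 0.5,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Ten test scores from a bifactor model.

    score_t = loadings_g[t]·g + loadings_group[t]·f_{group(t)} + ε_t with
    orthogonal standard-normal group factors f and ε_t ~ N(0, noise_sd[t]²).
    """
    g_true = np.asarray(g_true, dtype=float)
    loadings_g = np.asarray(loadings_g, dtype=float)
    group_assignment = np.asarray(group_assignment, dtype=int)
    if loadings_g.shape != (10,) or group_assignment.shape != (10,):
        raise InvalidConfigError("exactly 10 tests are required")
    loadings_group = np.broadcast_to(
        np.asarray(loadings_group, dtype=float), (10,)
    ).copy()
    noise_sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (10,)).copy()
    rng = np.random.default_rng(seed)
    n = len(g_true)
    n_groups = int(group_assignment.max()) + 1
    group_factors = rng.standard_normal((n, n_groups))
    eps = rng.standard_normal((n, 10)) * noise_sd
    scores = (
        g_true[:, None] * loadings_g[None, :]
        + group_factors[:, group_assignment] * loadings_group[None, :]
        + eps
    )
    cols = [f"test_{t + 1:02d}" for t in range(10)]
    return pd.DataFrame(scores, columns=cols)


def simulate_cohort(
    config: CohortConfig,
    families: FamilyStructure | None = None,
    parcellation: Parcellation | None = None,
) -> tuple[list[SubjectTimeSeries], TraitScores, dict[tuple[int, int], np.ndarray]]:
    """Generate a cohort with a planted trait at a controlled spatial scale.

    Generative model (all randomness from ``config.seed``):

    1. draw ``g_i`` per subject with within-family correlation
       ``family_g_correlation``, standardized cohort-wide;
    2. per region ``r``, fix mixing ``A_r`` (latent sources ← shared global
       sources ``U``) and vertex weights ``W_r``, whose rows are normalized
       so every vertex has unit signal variance, plus a trait-direction
       matrix ``D_r``;
    3. fine scale: subject weights
       ``W_{i,r} = W_r + fine_effect·g_i·D_r + weight_noise·E_{i,r}``, with
       ``D_r`` doubly constrained — zero column means (the fine effect never
       moves region-mean time series) and rows orthogonal to ``Σ_r w_v``
       (it never moves per-vertex variances to first order, so correlation
       block means stay trait-free);
    4. coarse scale: dedicated coupling sources ``z`` enter every vertex of
       region ``r`` with the *same* loading vector ``γ_{i,r}``, rotated in
       coupling space by an angle ``coarse_effect·g_i`` (constant norm, so
       per-vertex variances never depend on the trait); the region-uniform
       component shifts region-pair connectivity block means while
       block-demeaning removes it from residual profiles exactly;
    5. apply a subject- and region-specific mean-preserving orthogonal
       ``Q_{i,r}`` (dispersion ``rotation_dispersion``, reflections allowed)
       to the vertex dimension — fine patterns scramble, regional means and
       the region-uniform coupling component are untouched;
    6. add white noise with sd ``noise_sd``.

    Returns the subjects' time series, the trait scores (with observed test
    scores), and the true ``Q`` matrices keyed by ``(subject, region)`` for
    recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    if families is None:
        families = make_family_structure(
            config.family_histogram, rng.integers(2**31)
        )
    if parcellation is None:
        parcellation = make_parcellation(
            config.n_vertices, config.n_regions, rng.integers(2**31)
        )
    if families.n_subjects != config.n_subjects:
        raise InvalidConfigError("family structure does not match config")
    if parcellation.n_vertices != config.n_vertices:
        raise InvalidConfigError("parcellation does not match config")
    if parcellation.n_regions != config.n_regions:
        raise InvalidConfigError("parcellation region count does not match config")

    n_sub = config.n_subjects
    R, L, K = config.n_regions, config.n_latent_sources, config.n_global_sources
    T = config.n_timepoints

    g = _draw_g(config, families, rng)
    test_scores = simulate_test_scores(g, seed=rng.integers(2**31))

    # Fixed group-level structure.
    Kc = config.n_coupling_sources
    if Kc < 2 and config.coarse_effect > 0:
        raise InvalidConfigError(
            "coarse_effect requires at least 2 coupling sources"
        )
    if T <= K + Kc:
        raise InvalidConfigError("need more timepoints than sources")
    A = rng.standard_normal((R, L, K)) / np.sqrt(K)   # source mixing
    h = rng.standard_normal((R, Kc))                  # base coupling loadings
    b = rng.standard_normal((R, Kc))                  # trait rotation plane

    # source series shared by the whole cohort: individuals differ only
    # through weights, coupling loadings, topography, and noise, so the
    # all-effects-zero generator degenerates to identical subjects
    u = rng.standard_normal((K, T))
    z = rng.standard_normal((Kc, T))                  # coupling sources
    # make the coupling sources exactly sample-orthogonal to the global
    # sources and sample-orthonormal, so the region-uniform coupling
    # component is uncorrelated with vertex patterns in-sample, not just in
    # expectation — the fine/coarse scale separation holds at finite T
    z = z - (z @ u.T) @ np.linalg.solve(u @ u.T, u)
    z = np.linalg.qr(z.T)[0].T * np.sqrt(T)
    sample_cov_u = (u @ u.T) / T

    region_vertices = [parcellation.vertices_of(r) for r in range(R)]
    # pass 1: group weights, rows normalized to unit signal variance per
    # vertex (correlation and covariance block means then coincide, keeping
    # the scale separation exact); sample source covariance used throughout
    # so the constraints hold for this realization, not just in expectation
    W, sigmas = [], []
    for r in range(R):
        n_r = len(region_vertices[r])
        sigma = A[r] @ sample_cov_u @ A[r].T
        w = rng.standard_normal((n_r, L)) / np.sqrt(L)
        w /= np.sqrt(np.einsum("vl,lm,vm->v", w, sigma, w))[:, None]
        W.append(w)
        sigmas.append(sigma)
    w_bar = np.stack([w.mean(axis=0) for w in W])  # region-mean weights

    # pass 2: trait directions, triply constrained:
    #   (a) zero column means — the fine effect never moves region means;
    #   (b) rows ⊥ Σ w_v — per-vertex variances fixed to first order, so
    #       correlation block means stay trait-free;
    #   (c) rows ⊥ the R seed directions (covariance with every region-mean
    #       time series) — the fine effect is invisible to the connectivity
    #       targets used for hyperalignment, so fitted transforms are
    #       trait-free and alignment cannot absorb the planted signal.
    # (c) needs n_latent_sources > n_regions + 1; otherwise it is skipped
    # and only (a)/(b) hold.
    D = []
    for r in range(R):
        w, sigma = W[r], sigmas[r]
        d = rng.standard_normal((w.shape[0], L)) / np.sqrt(L)
        target_mix = np.einsum("slk,sl->sk", A, w_bar)  # A_s' w̄_s per region
        seed_dirs = A[r] @ sample_cov_u @ target_mix.T  # (L, R)
        proj_shared = np.zeros((L, L))
        if L > R + 1:
            basis, _ = np.linalg.qr(seed_dirs)
            proj_shared = basis @ basis.T
        sw = w @ sigma  # row v is Σ w_v
        sw = sw - sw @ proj_shared
        sw_norm2 = np.sum(sw * sw, axis=1, keepdims=True)
        sw_norm2[sw_norm2 == 0] = 1.0
        for _ in range(50):
            d -= d @ proj_shared
            d -= (np.sum(d * sw, axis=1, keepdims=True) / sw_norm2) * sw
            d -= d.mean(axis=0, keepdims=True)
        scale = np.sqrt(np.mean(np.einsum("vl,lm,vm->v", d, sigma, d)))
        D.append(d / scale if scale > 0 else d)

    run_boundaries = tuple(
        config.n_timepoints_per_run * k for k in range(config.n_runs)
    )
    subjects: list[SubjectTimeSeries] = []
    transforms: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n_sub):
        x = np.empty((config.n_vertices, T))
        for r in range(R):
            s = A[r] @ u
            w = (W[r] + config.fine_effect * g[i] * D[r]
                 + config.weight_noise
                 * rng.standard_normal(W[r].shape) / np.sqrt(L))
            # rotate h_r toward the orthogonalized b_r by an angle that mixes
            # the trait effect with idiosyncratic coupling variation: the
            # loading norm (hence vertex variance) is trait-independent,
            # while inter-region coupling γ_r'·γ_s' varies across subjects
            e1 = h[r] / np.linalg.norm(h[r])
            p = b[r] - (b[r] @ e1) * e1
            p_norm = np.linalg.norm(p)
            angle = (config.coarse_effect * g[i]
                     + config.coupling_noise * rng.standard_normal())
            if p_norm > 0:
                p = p / p_norm
                direction = np.cos(angle) * e1 + np.sin(angle) * p
            else:
                direction = e1
            gamma = config.coupling_strength * np.linalg.norm(h[r]) * direction
            q = mean_preserving_orthogonal(len(region_vertices[r]),
                                           config.rotation_dispersion, rng)
            transforms[(i, r)] = q
            x[region_vertices[r]] = q @ (w @ s) + (gamma @ z)[None, :]
        if config.noise_sd > 0:
            x += config.noise_sd * rng.standard_normal(x.shape)
        # offset so percent-signal-change normalization is well defined
        subjects.append(SubjectTimeSeries(values=x + 100.0,
                                          run_boundaries=run_boundaries))
    traits = TraitScores(g_true=g, test_scores=test_scores)
    return subjects, traits, transforms
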