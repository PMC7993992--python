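"""The three connectivity-profile types: full fine, coarse, residual fine.

For a seed region with n_r vertices on a cortex of V vertices partitioned
into R regions:

* the *full fine-grained* profile is the n_r × V matrix of Pearson
  correlations between the region's vertices and every cortical vertex;
* the *coarse-grained* profile is the R-vector of region-pair block means of
  that matrix — one mean correlation per target region;
* the *residual fine-grained* profile subtracts each block's mean from the
  block, leaving purely fine-scale pattern information. By construction
  fine = residual + expanded coarse, every residual block has mean zero, and
  an OLS regression of the vectorized fine profile on the expanded coarse
  profile has slope exactly 1.

Raw correlations are used throughout (no Fisher z). The seed region's own
block — including the exact 1.0 self-correlations — is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Parcellation, SubjectTimeSeries
from .hyperalign import _corr_rows

__all__ = [
    "FineProfile",
    "CoarseProfile",
    "ResidualProfile",
    "full_fine_profile",
    "coarse_profile",
    "residual_profile",
    "expand_coarse",
    "vectorize_profile",
    "subject_profiles",
]


@dataclass(frozen=True)
class FineProfile:
    region_id: int
    matrix: np.ndarray  # (n_r, V) correlations


@dataclass(frozen=True)
class CoarseProfile:
    region_id: int
    vector: np.ndarray  # (R,) block means


@dataclass(frozen=True)
class ResidualProfile:
    region_id: int
    matrix: np.ndarray  # (n_r, V) block-demeaned correlations


def full_fine_profile(
    ts: SubjectTimeSeries, parcellation: Parcellation, region_id: int
) -> FineProfile:
    """Correlations between a region's vertices and all cortical vertices."""
    idx = parcellation.vertices_of(region_id)
    if idx.size == 0:
        raise ValueError(f"region {region_id} is empty")
    mat = _corr_rows(ts.values[idx], ts.values, what="vertex")
    return FineProfile(region_id=region_id, matrix=mat)


def coarse_profile(fine: FineProfile, parcellation: Parcellation) -> CoarseProfile:
    """Region-pair block means of a fine profile: one value per target region.

    The seed region's own block (with its internal 1.0 diagonal) is averaged
    like any other block, keeping the assembled R × R coarse matrix symmetric.
    """
    labels = parcellation.region_label
    r_count = parcellation.n_regions
    sums = np.zeros(r_count)
    np.add.at(sums, labels, fine.matrix.sum(axis=0))
    counts = fine.matrix.shape[0] * parcellation.region_sizes()
    return CoarseProfile(region_id=fine.region_id, vector=sums / counts)


def expand_coarse(
    coarse: CoarseProfile, parcellation: Parcellation, n_rows: int
) -> np.ndarray:
    """Broadcast a coarse profile back to fine shape (each block constant)."""
    return np.broadcast_to(
        coarse.vector[parcellation.region_label][None, :],
        (n_rows, parcellation.n_vertices),
    ).copy()


def residual_profile(
    fine: FineProfile, coarse: CoarseProfile, parcellation: Parcellation
) -> ResidualProfile:
    """Fine profile minus each block's scalar mean; block means become 0."""
    expanded = expand_coarse(coarse, parcellation, fine.matrix.shape[0])
    return ResidualProfile(region_id=fine.region_id,
                           matrix=fine.matrix - expanded)


def vectorize_profile(
    profile: FineProfile | CoarseProfile | ResidualProfile,
) -> np.ndarray:
    """Flatten a profile into a feature vector.

    Fine/residual profiles use C order (vertex-in-region major, cortical
    vertex minor) — with contiguous-block parcellations this is region-major,
    vertex-minor within each row. Coarse profiles are already vectors.
    """
    if isinstance(profile, CoarseProfile):
        return profile.vector.copy()
    return profile.matrix.ravel().copy()


def subject_profiles(
    ts: SubjectTimeSeries,
    parcellation: Parcellation,
    region_id: int,
) -> tuple[FineProfile, CoarseProfile, ResidualProfile]:
    """All three profile types for one subject and region."""
    fine = full_fine_profile(ts, parcellation, region_id)
    coarse = coarse_profile(fine, parcellation)
    resid = residual_profile(fine, coarse, parcellation)
    return fine, coarse, resid
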