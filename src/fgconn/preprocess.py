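"""Nuisance regression and temporal filtering for vertex-wise time series.

The pipeline order is fixed: percent-signal-change normalization, Gaussian
low-pass filtering of both data and nuisance regressors, then linear
regression of the nuisance design from the data. All steps operate per run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .cohort import SubjectTimeSeries

__all__ = [
    "NuisanceDesign",
    "DegenerateInputError",
    "to_percent_signal_change",
    "gaussian_lowpass",
    "build_nuisance_design",
    "regress_out",
    "preprocess_subject",
]


class DegenerateInputError(ValueError):
    """A vertex/run/column makes the requested operation undefined."""


@dataclass(frozen=True)
class NuisanceDesign:
    """Timepoint × regressor matrix with per-column labels."""

    columns: np.ndarray  # (T, n_regressors)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.columns.shape[1] != len(self.labels):
            raise ValueError("label count does not match column count")


def to_percent_signal_change(ts: SubjectTimeSeries) -> SubjectTimeSeries:
    """Normalize each vertex, per run, to percent signal change.

    x → 100·(x / mean − 1), where the mean is the vertex's temporal mean in
    that run. Output has per-run temporal mean 0 at every vertex.
    """
    out = np.empty_like(ts.values, dtype=float)
    for k, sl in enumerate(ts.run_slices()):
        block = ts.values[:, sl]
        mean = block.mean(axis=1, keepdims=True)
        bad = np.nonzero(mean.ravel() == 0)[0]
        if bad.size:
            raise DegenerateInputError(
                f"zero temporal mean at vertex {bad[0]} in run {k}"
            )
        out[:, sl] = 100.0 * (block / mean - 1.0)
    return SubjectTimeSeries(values=out, run_boundaries=ts.run_boundaries)


def _gaussian_kernel(sd: float, truncate: float = 4.0) -> np.ndarray:
    """Truncated, renormalized Gaussian kernel (unit sum → exact DC gain 1)."""
    radius = int(np.ceil(truncate * sd))
    t = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (t / sd) ** 2)
    return k / k.sum()


def _lowpass_matrix(x: np.ndarray, sd: float) -> np.ndarray:
    """Filter each row of (n, T) along time; reflect boundary handling."""
    kernel = _gaussian_kernel(sd)
    radius = len(kernel) // 2
    if x.shape[1] <= radius:
        raise DegenerateInputError(
            f"run of {x.shape[1]} timepoints shorter than kernel radius {radius}"
        )
    padded = np.pad(x, [(0, 0), (radius, radius)], mode="reflect")
    return _signal.fftconvolve(padded, kernel[None, :], mode="valid", axes=1)


def gaussian_lowpass(
    ts: SubjectTimeSeries, sd_in_timepoints: float = 1.0
) -> SubjectTimeSeries:
    """Per-run Gaussian low-pass filter along time (sd in timepoints).

    The kernel is truncated at ±4 sd and renormalized to unit sum, so a
    constant series passes through unchanged.
    """
    out = np.empty_like(ts.values, dtype=float)
    for sl in ts.run_slices():
        out[:, sl] = _lowpass_matrix(np.asarray(ts.values[:, sl], float),
                                     sd_in_timepoints)
    return SubjectTimeSeries(values=out, run_boundaries=ts.run_boundaries)


def _legendre_polys(n_timepoints: int, order: int) -> np.ndarray:
    """Per-run Legendre-style polynomial trends, degree 0..order, on [-1, 1]."""
    t = np.linspace(-1.0, 1.0, n_timepoints)
    return np.polynomial.legendre.legvander(t, order)


def build_nuisance_design(
    n_timepoints: int,
    run_boundaries: tuple[int, ...] = (0,),
    motion: np.ndarray | None = None,
    tissue_signals: np.ndarray | None = None,
    global_signal: np.ndarray | None = None,
    poly_order: int = 3,
    n_tissue_pcs: int = 5,
    filter_sd: float = 1.0,
) -> NuisanceDesign:
    """Assemble the nuisance design matrix.

    Parts, in order: the 6 motion parameters and their backward-difference
    derivatives (first row of each run zero); the ``n_tissue_pcs`` leading
    principal components of ``tissue_signals`` (white-matter/CSF voxels,
    column-centered per run); the global signal; and per-run polynomial trends
    of degree 0..``poly_order``. All columns are then low-pass filtered with
    the same Gaussian kernel as the data.
    """
    parts: list[np.ndarray] = []
    labels: list[str] = []
    edges = list(run_boundaries) + [n_timepoints]
    run_slices = [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_timepoints, 6):
            raise ValueError(
                f"motion must be ({n_timepoints}, 6), got {motion.shape}"
            )
        deriv = np.zeros_like(motion)
        for sl in run_slices:
            deriv[sl][1:] = np.diff(motion[sl], axis=0)
        parts.extend([motion, deriv])
        labels += [f"motion_{j}" for j in range(6)]
        labels += [f"motion_deriv_{j}" for j in range(6)]

    if tissue_signals is not None:
        tissue_signals = np.asarray(tissue_signals, dtype=float)
        if tissue_signals.shape[0] != n_timepoints:
            raise ValueError("tissue_signals timepoint count mismatch")
        pcs = np.empty((n_timepoints, n_tissue_pcs))
        for sl in run_slices:
            block = tissue_signals[sl] - tissue_signals[sl].mean(axis=0)
            u, s, _ = np.linalg.svd(block, full_matrices=False)
            if len(s) < n_tissue_pcs:
                raise ValueError("too few tissue signals for requested PCs")
            pcs[sl] = u[:, :n_tissue_pcs] * s[:n_tissue_pcs]
        parts.append(pcs)
        labels += [f"tissue_pc_{j}" for j in range(n_tissue_pcs)]

    if global_signal is not None:
        global_signal = np.asarray(global_signal, dtype=float).reshape(-1, 1)
        if global_signal.shape[0] != n_timepoints:
            raise ValueError("global_signal timepoint count mismatch")
        parts.append(global_signal)
        labels.append("global_signal")

    # per-run polynomials; zero outside their run so trends stay run-local
    for k, sl in enumerate(run_slices):
        block = np.zeros((n_timepoints, poly_order + 1))
        block[sl] = _legendre_polys(sl.stop - sl.start, poly_order)
        parts.append(block)
        labels += [f"poly_run{k}_deg{d}" for d in range(poly_order + 1)]

    columns = np.hstack(parts)
    filtered = np.empty_like(columns)
    for sl in run_slices:
        filtered[sl] = _lowpass_matrix(columns[sl].T, filter_sd).T
    return NuisanceDesign(columns=filtered, labels=tuple(labels))


def regress_out(ts: SubjectTimeSeries, design: NuisanceDesign) -> SubjectTimeSeries:
    """Remove the nuisance design from every vertex by least squares.

    Residuals are orthogonal to every design column. Raises if the design is
    rank deficient (after exact-duplicate columns are dropped upstream).
    """
    x = design.columns
    if x.shape[0] != ts.n_timepoints:
        raise ValueError("design timepoint count does not match data")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify a minimal set of collinear columns for the error message
        q, r = np.linalg.qr(x)
        dep = [design.labels[j] for j in range(x.shape[1])
               if abs(r[j, j]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"rank-deficient nuisance design; collinear: {dep}")
    beta, *_ = np.linalg.lstsq(x, ts.values.T, rcond=None)
    resid = ts.values - (x @ beta).T
    return SubjectTimeSeries(values=resid, run_boundaries=ts.run_boundaries)


def preprocess_subject(
    ts: SubjectTimeSeries,
    motion: np.ndarray | None = None,
    tissue_signals: np.ndarray | None = None,
    use_global_signal: bool = True,
    poly_order: int = 3,
    filter_sd: float = 1.0,
) -> SubjectTimeSeries:
    """Full preprocessing: PSC → low-pass (data and regressors) → regression.

    The global signal, when requested, is the mean over vertices of the
    percent-signal-change data (computed after PSC).
    """
    psc = to_percent_signal_change(ts)
    global_signal = psc.values.mean(axis=0) if use_global_signal else None
    filtered = gaussian_lowpass(psc, filter_sd)
    design = build_nuisance_design(
        ts.n_timepoints,
        run_boundaries=ts.run_boundaries,
        motion=motion,
        tissue_signals=tissue_signals,
        global_signal=global_signal,
        poly_order=poly_order,
        filter_sd=filter_sd,
    )
    return regress_out(filtered, design)
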