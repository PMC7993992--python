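"""Family-aware cross-validated principal-component ridge regression.

Regional connectivity features predict the general-intelligence score with a
two-level scheme: an outer leave-one-family-out (or repeated family-grouped
k-fold) loop, and an inner 3-sub-fold nested loop that picks the number of
principal components and the ridge penalty. No family ever straddles a
train/test boundary at either level.

Model evaluation uses the cross-validated coefficient of determination

    R² = 100 · (1 − Σᵢ(yᵢ − ŷᵢ)² / Σᵢ(yᵢ − ȳᵢ,train)²)

where ȳᵢ,train is the null model: the mean outcome of the training set of
the fold that predicted subject i. R² is capped at 100 and can be negative.

Feature matrices for fine-grained profiles are tall (features ≫ subjects),
so the cross-validation engine works entirely through the n × n Gram matrix:
PCA of the centered training block via its eigendecomposition, and ridge on
PC scores in closed form (PC scores have diagonal covariance, so the full
penalty grid is evaluated at negligible cost).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import FamilyStructure

__all__ = [
    "FoldPlan",
    "ModelSpec",
    "PredictionResult",
    "PCRRidgeModel",
    "DEFAULT_PC_GRID",
    "default_alpha_grid",
    "lofo_folds",
    "repeated_grouped_kfold",
    "fit_pcr_ridge",
    "nested_select",
    "run_features",
    "run_region",
    "cv_r2",
]

#: Principal-component counts considered during nested selection; "all" means
#: no dimensionality reduction (every PC the training set supports).
DEFAULT_PC_GRID: tuple[int | str, ...] = (10, 20, 40, 80, 160, 320, "all")


def default_alpha_grid() -> np.ndarray:
    """81 ridge penalties, log-spaced from 1e-20 to 1e20."""
    return np.logspace(-20.0, 20.0, 81)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: PC count (int or "all") and ridge penalty."""

    n_pcs: int | str
    alpha: float

    def __post_init__(self) -> None:
        if isinstance(self.n_pcs, str) and self.n_pcs != "all":
            raise ValueError("n_pcs must be a positive integer or 'all'")
        if not isinstance(self.n_pcs, str) and self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass(frozen=True)
class FoldPlan:
    """Outer cross-validation folds with family bookkeeping.

    ``folds`` maps each fold to (test subject indices, train subject indices);
    test sets partition the cohort and no family straddles the boundary.
    """

    folds: tuple[tuple[np.ndarray, np.ndarray], ...]
    family_id: np.ndarray

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def n_subjects(self) -> int:
        return len(self.family_id)

    def validate(self) -> None:
        """Audit the family-integrity and partition invariants."""
        seen = np.concatenate([test for test, _ in self.folds])
        if len(seen) != self.n_subjects or len(np.unique(seen)) != len(seen):
            raise ValueError("test sets do not partition the cohort")
        for test, train in self.folds:
            if np.intersect1d(self.family_id[test], self.family_id[train]).size:
                raise ValueError("a family straddles a train/test boundary")
            if len(test) + len(train) != self.n_subjects:
                raise ValueError("train ∪ test does not cover the cohort")


def lofo_folds(families: FamilyStructure) -> FoldPlan:
    """Leave-one-family-out: one fold per family."""
    if families.n_subjects == 0:
        raise ValueError("empty cohort")
    all_idx = np.arange(families.n_subjects)
    folds = []
    for fam in range(families.n_families):
        test = all_idx[families.family_id == fam]
        train = all_idx[families.family_id != fam]
        folds.append((test, train))
    return FoldPlan(folds=tuple(folds), family_id=families.family_id.copy())


def repeated_grouped_kfold(
    families: FamilyStructure, k: int = 10, repeats: int = 50,
    seed: int | np.random.Generator = 0,
) -> list[FoldPlan]:
    """Repeated k-fold over families: whole families stay in one chunk."""
    n_fam = families.n_families
    if n_fam < k:
        raise ValueError(f"need at least k={k} families, have {n_fam}")
    rng = np.random.default_rng(seed)
    all_idx = np.arange(families.n_subjects)
    plans = []
    for _ in range(repeats):
        fam_order = rng.permutation(n_fam)
        chunks = np.array_split(fam_order, k)
        folds = []
        for chunk in chunks:
            mask = np.isin(families.family_id, chunk)
            folds.append((all_idx[mask], all_idx[~mask]))
        plans.append(FoldPlan(folds=tuple(folds),
                              family_id=families.family_id.copy()))
    return plans


def cv_r2(
    y: np.ndarray, y_hat: np.ndarray, fold_train_means: np.ndarray
) -> float:
    """Cross-validated R² in percent; negative when worse than the null model."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    fold_train_means = np.asarray(fold_train_means, float)
    denom = np.sum((y - fold_train_means) ** 2)
    if denom == 0:
        raise ZeroDivisionError("null-model sum of squares is zero")
    return 100.0 * (1.0 - np.sum((y - y_hat) ** 2) / denom)


# ---------------------------------------------------------------------------
# Gram-matrix PCA + closed-form ridge


def _centered_train_gram(gram: np.ndarray, tr: np.ndarray) -> np.ndarray:
    g = gram[np.ix_(tr, tr)]
    rm = g.mean(axis=1, keepdims=True)
    return g - rm - rm.T + g.mean()

def _train_eig(gram: np.ndarray, tr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the centered training Gram, descending, trimmed
    to numerically positive eigenvalues. Returns (eigenvalues, eigenvectors)."""
    k = _centered_train_gram(gram, tr)
    lam, u = np.linalg.eigh(k)
    lam, u = lam[::-1], u[:, ::-1]
    keep = lam > max(lam[0], 0) * 1e-10
    keep[0] = lam[0] > 0
    return lam[keep], u[:, keep]


def _test_scores(
    gram: np.ndarray, tr: np.ndarray, te: np.ndarray,
    lam: np.ndarray, u: np.ndarray,
) -> np.ndarray:
    """PC scores of test rows in the training PCA basis."""
    gtt = gram[np.ix_(tr, tr)]
    gte = gram[np.ix_(te, tr)]
    c = (gte - gte.mean(axis=1, keepdims=True)
         - (gtt.mean(axis=0) - gtt.mean()))
    return (c @ u) / np.sqrt(lam)


def _resolve_n_pcs(n_pcs: int | str, rank: int, warn: bool = False) -> int:
    if n_pcs == "all":
        return rank
    if n_pcs > rank:
        if warn:
            warnings.warn(
                f"n_pcs={n_pcs} exceeds available rank {rank}; clipped",
                stacklevel=2,
            )
        return rank
    return int(n_pcs)


def _ridge_grid_predictions(
    z_tr_proj: np.ndarray,   # Zᵀ y_c, length rank
    lam: np.ndarray,
    z_te: np.ndarray,        # (n_te, rank)
    y_bar: float,
    pc_counts: Sequence[int],
    alphas: np.ndarray,
) -> np.ndarray:
    """Predictions for every (pc count, alpha) pair, shape (n_k, n_a, n_te)."""
    coef = z_tr_proj[:, None] / (lam[:, None] + alphas[None, :])  # (rank, n_a)
    out = np.empty((len(pc_counts), len(alphas), z_te.shape[0]))
    for i, k in enumerate(pc_counts):
        out[i] = y_bar + (z_te[:, :k] @ coef[:k]).T
    return out


def nested_select(
    x_or_gram: np.ndarray,
    y: np.ndarray,
    families_train: np.ndarray,
    pc_grid: Sequence[int | str] = DEFAULT_PC_GRID,
    alphas: np.ndarray | None = None,
    n_subfolds: int = 3,
    seed: int | np.random.Generator = 0,
    is_gram: bool = False,
) -> ModelSpec:
    """Choose (n_pcs, alpha) by nested family-aware cross-validation.

    The training families are shuffled (by ``seed``) into ``n_subfolds``
    chunks; each candidate is scored by the pooled inner cross-validated R²
    and the maximizer is returned, ties broken toward fewer PCs, then larger
    alpha (parsimony).
    """
    if len(pc_grid) == 0:
        raise ValueError("empty PC grid")
    alphas = default_alpha_grid() if alphas is None else np.asarray(alphas, float)
    if alphas.size == 0:
        raise ValueError("empty alpha grid")
    y = np.asarray(y, float)
    gram = x_or_gram if is_gram else x_or_gram @ x_or_gram.T
    n = len(y)
    rng = np.random.default_rng(seed)

    fams = np.unique(families_train)
    if len(fams) < n_subfolds:
        raise ValueError("fewer training families than sub-folds")
    fam_order = rng.permutation(fams)
    chunks = np.array_split(fam_order, n_subfolds)

    sse = np.zeros((len(pc_grid), len(alphas)))
    ss_null = 0.0
    all_idx = np.arange(n)
    for chunk in chunks:
        te = all_idx[np.isin(families_train, chunk)]
        tr = all_idx[~np.isin(families_train, chunk)]
        lam, u = _train_eig(gram, tr)
        rank = len(lam)
        z_te = _test_scores(gram, tr, te, lam, u)
        y_bar = y[tr].mean()
        y_c = y[tr] - y_bar
        proj = (u.T @ y_c) * np.sqrt(lam)
        pc_counts = [_resolve_n_pcs(p, rank) for p in pc_grid]
        preds = _ridge_grid_predictions(proj, lam, z_te, y_bar, pc_counts, alphas)
        sse += np.sum((preds - y[te][None, None, :]) ** 2, axis=2)
        ss_null += np.sum((y[te] - y_bar) ** 2)

    score = 1.0 - sse / ss_null  # inner cross-validated R² per candidate
    # parsimony tie-break: iterate PCs ascending, alphas descending
    best = (-np.inf, None)
    for i, p in enumerate(pc_grid):
        for j in range(len(alphas) - 1, -1, -1):
            if score[i, j] > best[0] + 1e-12:
                best = (score[i, j], ModelSpec(n_pcs=p, alpha=float(alphas[j])))
    return best[1]


@dataclass
class PCRRidgeModel:
    """Fitted PCA + ridge model (explicit basis form)."""

    mean_: np.ndarray          # feature center, (p,)
    components_: np.ndarray    # (p, k) PC basis
    coef_: np.ndarray          # (k,) ridge coefficients on PC scores
    intercept_: float
    spec: ModelSpec

    def predict(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, float) - self.mean_) @ self.components_
        return self.intercept_ + z @ self.coef_


def fit_pcr_ridge(
    x_train: np.ndarray, y_train: np.ndarray, spec: ModelSpec
) -> PCRRidgeModel:
    """Fit PCA (centering only, no scaling) then ridge on the PC scores.

    ``n_pcs`` larger than the training rank is clipped with a warning (the
    "all PCs" ceiling). ``alpha=0`` with full PCs reduces to OLS.
    """
    x_train = np.asarray(x_train, float)
    y_train = np.asarray(y_train, float)
    mean = x_train.mean(axis=0)
    xc = x_train - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    keep = s > max(s[0], 0) * 1e-12 if s.size else np.zeros(0, bool)
    u, s, vt = u[:, keep], s[keep], vt[keep]
    k = _resolve_n_pcs(spec.n_pcs, len(s), warn=True)
    z = u[:, :k] * s[:k]
    y_bar = y_train.mean()
    lam = s[:k] ** 2
    coef = (z.T @ (y_train - y_bar)) / (lam + spec.alpha)
    return PCRRidgeModel(
        mean_=mean, components_=vt[:k].T, coef_=coef,
        intercept_=float(y_bar), spec=spec,
    )


@dataclass
class PredictionResult:
    """Pooled cross-validated predictions for one region × condition."""

    region_id: int
    condition: str
    y: np.ndarray
    y_pred: np.ndarray
    train_means: np.ndarray       # per-subject null-model prediction
    fold_id: np.ndarray
    chosen_specs: tuple[ModelSpec, ...]
    r2: float = field(init=False)

    def __post_init__(self) -> None:
        self.r2 = cv_r2(self.y, self.y_pred, self.train_means)


def run_features(
    x: np.ndarray,
    y: np.ndarray,
    fold_plan: FoldPlan,
    pc_grid: Sequence[int | str] = DEFAULT_PC_GRID,
    alphas: np.ndarray | None = None,
    seed: int = 0,
    region_id: int = -1,
    condition: str = "",
    gram: np.ndarray | None = None,
) -> PredictionResult:
    """Full outer loop on a subjects × features matrix.

    Per fold: nested selection on the training set, refit on the full
    training set with the chosen spec, predict the held-out family. All
    linear algebra runs through the subjects × subjects Gram matrix.
    """
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite outcome values")
    alphas = default_alpha_grid() if alphas is None else np.asarray(alphas, float)
    if gram is None:
        x = np.asarray(x, float)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite feature values")
        gram = x @ x.T
    n = len(y)
    y_pred = np.full(n, np.nan)
    train_means = np.full(n, np.nan)
    fold_of = np.full(n, -1)
    specs = []
    for f, (te, tr) in enumerate(fold_plan.folds):
        spec = nested_select(
            gram[np.ix_(tr, tr)], y[tr], fold_plan.family_id[tr],
            pc_grid=pc_grid, alphas=alphas, seed=seed + f, is_gram=True,
        )
        lam, u = _train_eig(gram, tr)
        k = _resolve_n_pcs(spec.n_pcs, len(lam))
        z_te = _test_scores(gram, tr, te, lam, u)
        y_bar = y[tr].mean()
        proj = (u.T @ (y[tr] - y_bar)) * np.sqrt(lam)
        coef = proj[:k] / (lam[:k] + spec.alpha)
        y_pred[te] = y_bar + z_te[:, :k] @ coef
        train_means[te] = y_bar
        fold_of[te] = f
        specs.append(spec)
    return PredictionResult(
        region_id=region_id, condition=condition, y=y, y_pred=y_pred,
        train_means=train_means, fold_id=fold_of, chosen_specs=tuple(specs),
    )


def run_region(
    profile_features: np.ndarray,
    g_estimated: np.ndarray,
    fold_plan: FoldPlan,
    pc_grid: Sequence[int | str] = DEFAULT_PC_GRID,
    alphas: np.ndarray | None = None,
    seed: int = 0,
    region_id: int = -1,
    condition: str = "",
) -> PredictionResult:
    """Predict the trait from one region's vectorized profiles (subjects × features)."""
    return run_features(
        profile_features, g_estimated, fold_plan, pc_grid=pc_grid,
        alphas=alphas, seed=seed, region_id=region_id, condition=condition,
    )
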