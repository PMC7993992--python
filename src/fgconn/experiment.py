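"""End-to-end orchestration of the fine- vs coarse-grained prediction study.

``run_all`` simulates a cohort, extracts the g factor from its test scores,
preprocesses the time series, hyperaligns them (and keeps an
identity-aligned baseline), builds the requested connectivity-profile types,
and runs family-aware cross-validated PC-ridge prediction per region and
condition. ``compare_conditions`` contrasts two conditions region by region
and on the across-region mean, with test-set bootstrap CIs.

A condition is named ``<alignment>_<kind>`` with alignment ∈ {cha, identity}
and kind ∈ {residual, fine, coarse}; e.g. ``cha_residual`` is hyperaligned
residual fine-grained connectivity, the analysis's headline condition.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CohortConfig,
    FamilyStructure,
    Parcellation,
    SubjectTimeSeries,
    TraitScores,
    make_family_structure,
    make_parcellation,
    simulate_cohort,
)
from .connectivity import (
    CoarseProfile,
    FineProfile,
    coarse_profile,
    residual_profile,
)
from .gfactor import fit_bifactor
from .hyperalign import Transform, apply_cha, fit_cha, identity_transforms
from .predict import (
    DEFAULT_PC_GRID,
    FoldPlan,
    PredictionResult,
    cv_r2,
    default_alpha_grid,
    lofo_folds,
    repeated_grouped_kfold,
    run_features,
)
from .preprocess import preprocess_subject
from .stats import ContrastCI, block_permutation, bootstrap_contrast, permutation_pvalue

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "DEFAULT_CONDITIONS",
    "run_all",
    "compare_conditions",
    "permutation_test_features",
]

#: The three conditions of the planted-effect contrast: hyperaligned residual
#: fine-grained, coarse-grained (on the same hyperaligned data), and
#: identity-aligned (anatomical baseline) residual fine-grained.
DEFAULT_CONDITIONS: tuple[tuple[str, str], ...] = (
    ("cha", "residual"),
    ("cha", "coarse"),
    ("identity", "residual"),
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved configuration of one experiment run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    conditions: tuple[tuple[str, str], ...] = DEFAULT_CONDITIONS
    cv_scheme: str = "lofo"            # "lofo" | "repeated-kfold"
    kfold_k: int = 10
    kfold_repeats: int = 5
    pc_grid: tuple[int | str, ...] = (10, 20, 40, "all")
    n_alphas: int = 81
    group_assignment: tuple[int, ...] = (0, 0, 0, 1, 1, 1, 2, 2, 2, 2)
    trait_source: str = "bifactor"     # "bifactor" | "g_true" (diagnostics)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trait_source not in ("bifactor", "g_true"):
            raise ValueError(f"unknown trait source {self.trait_source!r}")
        for alignment, kind in self.conditions:
            if alignment not in ("cha", "identity"):
                raise ValueError(f"unknown alignment {alignment!r}")
            if kind not in ("residual", "fine", "coarse"):
                raise ValueError(f"unknown profile kind {kind!r}")
        if self.cv_scheme not in ("lofo", "repeated-kfold"):
            raise ValueError(f"unknown cv scheme {self.cv_scheme!r}")

    def alphas(self) -> np.ndarray:
        return np.logspace(-20.0, 20.0, self.n_alphas)


@dataclass
class ExperimentReport:
    """Everything ``run_all`` computed, ready for contrasts and export."""

    config: ExperimentConfig
    families: FamilyStructure
    parcellation: Parcellation
    traits: TraitScores
    fold_plan: FoldPlan
    results: dict[str, list[PredictionResult]]
    cha_transforms: dict[tuple[int, int], Transform]
    preprocessed: list[SubjectTimeSeries] | None = None
    runtime_seconds: float = 0.0

    def conditions(self) -> list[str]:
        return list(self.results)

    def r2_by_region(self, condition: str) -> np.ndarray:
        return np.array([res.r2 for res in self.results[condition]])

    def mean_r2(self, condition: str) -> float:
        return float(self.r2_by_region(condition).mean())

    def r2_table(self) -> pd.DataFrame:
        rows = []
        for cond, results in self.results.items():
            for res in results:
                rows.append({
                    "region_id": res.region_id,
                    "condition": cond,
                    "r2": res.r2,
                    "n_folds": len(res.chosen_specs),
                })
        return pd.DataFrame(rows)

    def predictions_table(self) -> pd.DataFrame:
        rows = []
        for cond, results in self.results.items():
            for res in results:
                for i in range(len(res.y)):
                    rows.append({
                        "condition": cond,
                        "region_id": res.region_id,
                        "subject_id": i,
                        "y": res.y[i],
                        "y_hat": res.y_pred[i],
                        "fold_id": res.fold_id[i],
                    })
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.r2_table().to_csv(out / "r2_by_region.tsv", sep="\t", index=False)
        self.predictions_table().to_csv(
            out / "predictions.tsv", sep="\t", index=False
        )
        summary = {
            "seed": self.config.seed,
            "n_subjects": self.families.n_subjects,
            "n_regions": self.parcellation.n_regions,
            "mean_r2": {c: self.mean_r2(c) for c in self.conditions()},
            "runtime_seconds": self.runtime_seconds,
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2))


def _standardized_rows(ts: SubjectTimeSeries) -> np.ndarray:
    """Rows centered and scaled to unit norm, so X @ X.T is the correlation."""
    x = ts.values - ts.values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-variance vertex after preprocessing")
    return x / norms


def _region_feature_matrix(
    standardized: list[np.ndarray],
    parcellation: Parcellation,
    region_id: int,
    kind: str,
) -> np.ndarray:
    """Subjects × features matrix of vectorized profiles for one region."""
    idx = parcellation.vertices_of(region_id)
    rows = []
    for z in standardized:
        fine_mat = np.clip(z[idx] @ z.T, -1.0, 1.0)
        fine = FineProfile(region_id=region_id, matrix=fine_mat)
        if kind == "fine":
            rows.append(fine.matrix.ravel())
            continue
        coarse = coarse_profile(fine, parcellation)
        if kind == "coarse":
            rows.append(coarse.vector)
        else:
            rows.append(residual_profile(fine, coarse, parcellation).matrix.ravel())
    return np.asarray(rows)


def run_all(config: ExperimentConfig) -> ExperimentReport:
    """Run the full pipeline; deterministic given ``config.seed``."""
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    cohort_cfg = replace(config.cohort, seed=int(rng.integers(2**31)))
    families = make_family_structure(
        cohort_cfg.family_histogram, int(rng.integers(2**31))
    )
    parcellation = make_parcellation(
        cohort_cfg.n_vertices, cohort_cfg.n_regions, int(rng.integers(2**31))
    )
    subjects, traits, _true_q = simulate_cohort(
        cohort_cfg, families, parcellation
    )

    gfactor_seed = int(rng.integers(2**31))
    if config.trait_source == "bifactor":
        fit = fit_bifactor(
            traits.test_scores.to_numpy(),
            np.asarray(config.group_assignment),
            seed=gfactor_seed,
        )
        traits.g_estimated = fit.g_scores
    else:
        traits.g_estimated = traits.g_true.copy()

    preprocessed = [preprocess_subject(ts) for ts in subjects]

    need_cha = any(a == "cha" for a, _ in config.conditions)
    cha_transforms: dict[tuple[int, int], Transform] = {}
    aligned: dict[str, list[SubjectTimeSeries]] = {}
    if need_cha:
        _model, cha_transforms = fit_cha(preprocessed, parcellation)
        aligned["cha"] = [
            apply_cha(ts, parcellation, cha_transforms, i)
            for i, ts in enumerate(preprocessed)
        ]
    if any(a == "identity" for a, _ in config.conditions):
        aligned["identity"] = preprocessed

    if config.cv_scheme == "lofo":
        fold_plan = lofo_folds(families)
    else:
        fold_plan = repeated_grouped_kfold(
            families, k=config.kfold_k, repeats=1,
            seed=int(rng.integers(2**31)),
        )[0]
    fold_plan.validate()

    alphas = config.alphas()
    pred_seed = int(rng.integers(2**31))
    results: dict[str, list[PredictionResult]] = {}
    standardized_cache: dict[str, list[np.ndarray]] = {}
    for alignment, kind in config.conditions:
        cond = f"{alignment}_{kind}"
        if alignment not in standardized_cache:
            standardized_cache[alignment] = [
                _standardized_rows(ts) for ts in aligned[alignment]
            ]
        z_list = standardized_cache[alignment]
        region_results = []
        for r in range(parcellation.n_regions):
            x = _region_feature_matrix(z_list, parcellation, r, kind)
            region_results.append(run_features(
                x, traits.g_estimated, fold_plan,
                pc_grid=config.pc_grid, alphas=alphas,
                seed=pred_seed + r, region_id=r, condition=cond,
            ))
        results[cond] = region_results

    return ExperimentReport(
        config=config, families=families, parcellation=parcellation,
        traits=traits, fold_plan=fold_plan, results=results,
        cha_transforms=cha_transforms, preprocessed=preprocessed,
        runtime_seconds=time.time() - t0,
    )


def compare_conditions(
    report: ExperimentReport,
    condition_a: str,
    condition_b: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-region and mean contrasts of cross-validated R² (A vs B).

    Returns one row per region plus a summary row ("mean") whose difference
    and ratio CIs come from a test-set-only bootstrap of the across-region
    mean VAF.
    """
    for cond in (condition_a, condition_b):
        if cond not in report.results:
            raise KeyError(f"condition {cond!r} not in report")
    res_a = report.results[condition_a]
    res_b = report.results[condition_b]
    rows = []
    for ra, rb in zip(res_a, res_b):
        ratio = ra.r2 / rb.r2 if rb.r2 != 0 else np.nan
        rows.append({
            "region_id": ra.region_id, "r2_a": ra.r2, "r2_b": rb.r2,
            "difference": ra.r2 - rb.r2, "ratio": ratio,
            "a_greater": ra.r2 > rb.r2,
        })

    y = res_a[0].y
    tm = res_a[0].train_means
    preds_a = np.stack([r.y_pred for r in res_a])
    preds_b = np.stack([r.y_pred for r in res_b])
    rng = np.random.default_rng(seed)
    n = len(y)
    diffs = np.empty(n_boot)
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        denom = np.sum((y[idx] - tm[idx]) ** 2)
        if denom == 0:
            diffs[b] = np.nan
            ratios[b] = np.nan
            continue
        sse_a = np.sum((y[idx][None, :] - preds_a[:, idx]) ** 2, axis=1)
        sse_b = np.sum((y[idx][None, :] - preds_b[:, idx]) ** 2, axis=1)
        mean_a = np.mean(100.0 * (1.0 - sse_a / denom))
        mean_b = np.mean(100.0 * (1.0 - sse_b / denom))
        diffs[b] = mean_a - mean_b
        ratios[b] = mean_a / mean_b if mean_b != 0 else np.nan
    mean_a0 = report.mean_r2(condition_a)
    mean_b0 = report.mean_r2(condition_b)
    d = diffs[np.isfinite(diffs)]
    r = ratios[np.isfinite(ratios)]
    rows.append({
        "region_id": -1, "r2_a": mean_a0, "r2_b": mean_b0,
        "difference": mean_a0 - mean_b0,
        "ratio": mean_a0 / mean_b0 if mean_b0 != 0 else np.nan,
        "a_greater": mean_a0 > mean_b0,
        "diff_ci_low": float(np.percentile(d, 2.5)),
        "diff_ci_high": float(np.percentile(d, 97.5)),
        "ratio_ci_low": float(np.percentile(r, 2.5)) if r.size else np.nan,
        "ratio_ci_high": float(np.percentile(r, 97.5)) if r.size else np.nan,
    })
    return pd.DataFrame(rows)


def permutation_test_features(
    x: np.ndarray,
    y: np.ndarray,
    fold_plan: FoldPlan,
    families: FamilyStructure,
    n_perm: int = 100,
    pc_grid: Sequence[int | str] = DEFAULT_PC_GRID,
    alphas: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Permutation test of one feature matrix's predictive R².

    The trait is permuted with family-respecting multi-level block
    permutations and the *entire* prediction pipeline — nested parameter
    selection included — is re-run per permutation. Returns
    (observed R², p-value, permuted R² distribution). The feature Gram
    matrix is shared across permutations (features never change).
    """
    alphas = default_alpha_grid() if alphas is None else alphas
    x = np.asarray(x, float)
    gram = x @ x.T
    observed = run_features(
        x, y, fold_plan, pc_grid=pc_grid, alphas=alphas,
        seed=seed, gram=gram,
    ).r2
    permuted_y = block_permutation(y, families, n_perm=n_perm, seed=seed)
    permuted_r2 = np.array([
        run_features(x, permuted_y[p], fold_plan, pc_grid=pc_grid,
                     alphas=alphas, seed=seed, gram=gram).r2
        for p in range(n_perm)
    ])
    return observed, permutation_pvalue(observed, permuted_r2), permuted_r2
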