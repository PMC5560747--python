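"""Nested cross-validation for KronRLS under leakage-controlled scenarios.

Three prediction scenarios are supported, each with its own fold design:

* **Bioactivity imputation** (leave-one-out, LOO): one observed
  compound-protein entry is held out at a time; the drug and protein of the
  query pair are both present in training.
* **New drug** (leave-drug-out, LDO): all affinities of one compound are
  held out; its row and column are removed from the drug kernel before
  training and interaction-profile drug kernels are disallowed (a new
  compound has no bioactivity profile).
* **New target** (leave-target-out, LTO): symmetric to LDO on the protein
  axis.

Model selection is nested: for every outer fold, an inner cross-validation
of the same design scores each grid point (lambda plus kernel parameters)
by RMSE, the best point (ties broken toward stronger regularization) is
refit on the outer-training data, and the held-out unit is predicted.

Leakage rules, applied per fold before any kernel or imputation touches the
data: the held-out entries are masked; similarity-weighted imputation runs
on the masked matrix only; interaction-profile (GIP) kernels are rebuilt
per fold with the test pair's partner axis excluded from the profiles
(for a drug-side GIP the protein column of the test pair is dropped, and
symmetrically for the protein side); and under LDO/LTO the held-out unit's
kernel row and column are removed entirely before training.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .compound_kernels import KernelMatrix
from .io_formats import BioactivityMatrix
from .kronrls_core import eigh_kernel, fit_from_eigh, impute_missing, predict_matrix

__all__ = [
    "ScenarioError",
    "GridSpec",
    "CVPlan",
    "CVResult",
    "StaticKernel",
    "GIPKernel",
    "nested_loo_cv",
    "nested_ldo_cv",
    "nested_lto_cv",
    "select_and_refit",
]

SCENARIOS = ("bioactivity_imputation", "new_drug", "new_target", "new_pair")


class ScenarioError(ValueError):
    """A kernel or fold design is incompatible with the requested scenario."""


def default_lambda_grid() -> np.ndarray:
    """13 log-spaced regularization values from 2^-15 to 2^10."""
    return np.logspace(-15, 10, 13, base=2.0)


@dataclass
class GridSpec:
    """Search grid: lambda values; kernel-parameter candidates are supplied
    by the kernel builders themselves."""

    lambda_values: Sequence[float] = field(default_factory=default_lambda_grid)

    def __post_init__(self) -> None:
        self.lambda_values = [float(v) for v in self.lambda_values]
        if not self.lambda_values:
            raise ValueError("lambda grid must be non-empty")
        if any(v <= 0 for v in self.lambda_values):
            raise ValueError("lambda values must be positive")


@dataclass
class CVPlan:
    """Scenario-specific fold structure (outer folds partition the observed
    entries for LOO, or one axis for LDO/LTO)."""

    scenario: str
    outer_folds: list
    inner_spec: str
    seed: int

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        flat: list = []
        for fold in self.outer_folds:
            flat.extend(fold if isinstance(fold, (list, tuple, set)) else [fold])
        if len(flat) != len(set(flat)):
            raise ValueError("outer folds must be disjoint")


@dataclass
class CVResult:
    """Per-fold predictions with their true values and selected parameters."""

    scenario: str
    drug_ids: list[str]
    protein_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    selected: list[dict]

    @property
    def n(self) -> int:
        return len(self.y_true)

    @property
    def pearson_r(self) -> float:
        from .evaluation import pearson

        return pearson(self.y_true, self.y_pred)

    @property
    def rmse(self) -> float:
        from .evaluation import rmse

        return rmse(self.y_true, self.y_pred)


class StaticKernel:
    """A kernel that does not depend on the label matrix (fingerprint,
    sequence, structure or identity kernels): computed once, subset per fold."""

    profile_based = False

    def __init__(self, kernel: KernelMatrix):
        self.kernel = kernel

    def candidates(self) -> list[dict]:
        return [{}]

    def build(
        self,
        values: np.ndarray,
        observed: np.ndarray,
        axis: int,
        indices: np.ndarray,
        exclude_partner: int | None,
    ) -> np.ndarray:
        return self.kernel.values[np.ix_(indices, indices)]

    def query_vector(self, query: int, indices: np.ndarray, params: dict) -> np.ndarray:
        return self.kernel.values[query, indices]


class GIPKernel:
    """Gaussian interaction-profile kernel builder.

    Profiles are rows (drug side, ``axis=0``) or columns (protein side,
    ``axis=1``) of the fold's imputed label matrix.  The Gaussian width is a
    grid parameter expressed as a quantile of the off-diagonal pairwise
    profile distances, recomputed from each fold's own training profiles
    (the candidate-width rule: 0.1 / 0.5 / 0.9 quantiles).
    """

    profile_based = True

    def __init__(self, sigma_quantiles: Sequence[float] = (0.1, 0.5, 0.9)):
        self.sigma_quantiles = tuple(sigma_quantiles)

    def candidates(self) -> list[dict]:
        return [{"sigma_quantile": q} for q in self.sigma_quantiles]

    def build(
        self,
        values: np.ndarray,
        observed: np.ndarray,
        axis: int,
        indices: np.ndarray,
        exclude_partner: int | None,
        sigma_quantile: float = 0.5,
    ) -> np.ndarray:
        profiles = values if axis == 0 else values.T
        profiles = profiles[indices]
        if exclude_partner is not None:
            profiles = np.delete(profiles, exclude_partner, axis=1)
        from scipy.spatial.distance import pdist, squareform

        d2 = squareform(pdist(profiles, metric="sqeuclidean"))
        dists = np.sqrt(d2[np.triu_indices_from(d2, k=1)])
        sigma = float(np.quantile(dists, sigma_quantile)) if dists.size else 0.0
        if sigma <= 0:
            positive = dists[dists > 0]
            sigma = float(positive.min()) if positive.size else 1.0
        K = np.exp(-d2 / (2.0 * sigma**2))
        np.fill_diagonal(K, 1.0)
        return K

    def query_vector(self, query: int, indices: np.ndarray, params: dict) -> np.ndarray:
        raise ScenarioError(
            "interaction-profile kernels cannot produce a query vector for a "
            "unit outside the training data"
        )


def _grid_points(grid: GridSpec, drug_kernel, protein_kernel) -> list[dict]:
    points = []
    for dk, pk, lam in itertools.product(
        drug_kernel.candidates(), protein_kernel.candidates(), grid.lambda_values
    ):
        points.append({"drug": dk, "protein": pk, "lam": lam})
    return points


def _select_best(scores: list[tuple[float, dict]]) -> dict:
    """Lowest RMSE; ties broken toward larger lambda."""
    best = None
    for rmse_val, point in scores:
        if (
            best is None
            or rmse_val < best[0] - 1e-12
            or (abs(rmse_val - best[0]) <= 1e-12 and point["lam"] > best[1]["lam"])
        ):
            best = (rmse_val, point)
    return best[1]


class _FoldEngine:
    """Shared per-fold machinery: imputation, kernel construction with
    leakage exclusions, eigendecomposition caching, fitting."""

    def __init__(self, drug_kernel, protein_kernel, protein_similarity):
        self.drug_kernel = drug_kernel
        self.protein_kernel = protein_kernel
        self.S_P = np.asarray(protein_similarity, dtype=float)
        self._eigh_cache: dict = {}

    def _eigh(self, values: np.ndarray, cache_key):
        if cache_key is None:
            return eigh_kernel(values)
        if cache_key not in self._eigh_cache:
            self._eigh_cache[cache_key] = eigh_kernel(values)
        return self._eigh_cache[cache_key]

    def fit_models(
        self,
        Y_fold: BioactivityMatrix,
        drug_idx: np.ndarray,
        prot_idx: np.ndarray,
        point_kernels: dict,
        lambdas: Sequence[float],
        exclude_drug: int | None = None,
        exclude_protein: int | None = None,
    ):
        """Impute the fold's masked matrix, build both kernels with the
        leakage exclusions, and fit one model per lambda (single
        eigendecomposition)."""
        S_sub = self.S_P[np.ix_(prot_idx, prot_idx)]
        values, _ = impute_missing(Y_fold, S_sub)
        kernels = {}
        for side, builder, axis, idx, excl in (
            ("drug", self.drug_kernel, 0, drug_idx, exclude_protein),
            ("protein", self.protein_kernel, 1, prot_idx, exclude_drug),
        ):
            params = point_kernels[side]
            full = np.arange(values.shape[axis])
            K = builder.build(values, Y_fold.observed, axis, full, excl, **params)
            cache_key = None
            if not builder.profile_based:
                cache_key = (side, len(full))
            kernels[side] = (K, cache_key)
        eig_D = self._eigh(*kernels["drug"])
        eig_P = self._eigh(*kernels["protein"])
        models = {
            lam: fit_from_eigh(eig_D, eig_P, values, lam) for lam in lambdas
        }
        return models, kernels["drug"][0], kernels["protein"][0]


def _observed_entries(Y: BioactivityMatrix) -> list[tuple[int, int]]:
    return [tuple(idx) for idx in np.argwhere(Y.observed)]


def nested_loo_cv(
    Y: BioactivityMatrix,
    drug_kernel,
    protein_kernel,
    grid: GridSpec,
    protein_similarity: np.ndarray,
    seed: int = 0,
) -> CVResult:
    """Nested leave-one-out CV (bioactivity-imputation scenario).

    Every observed entry is an outer fold.  When the grid has more than one
    point, an inner LOO over the remaining entries scores each point by
    RMSE; with a single grid point the inner loop is skipped (its selection
    is determined).  Interaction-profile kernels and imputation are
    recomputed for every fold with the fold's test entry masked first, and
    the test pair's partner axis excluded from GIP profiles.
    """
    entries = _observed_entries(Y)
    if len(entries) < 2:
        raise ValueError("need at least two observed entries for LOO-CV")
    engine = _FoldEngine(drug_kernel, protein_kernel, protein_similarity)
    points = _grid_points(grid, drug_kernel, protein_kernel)
    if not points:
        raise ValueError("empty parameter grid")
    drug_idx = np.arange(Y.n_drugs)
    prot_idx = np.arange(Y.n_proteins)
    y_true, y_pred, selected = [], [], []
    dids, pids = [], []
    for d, p in entries:
        Y_out = Y.mask_entries([(d, p)])
        if len(points) == 1:
            best = points[0]
        else:
            best = _inner_loo_select(engine, Y_out, drug_idx, prot_idx, points, grid)
        models, K_D, K_P = engine.fit_models(
            Y_out,
            drug_idx,
            prot_idx,
            {"drug": best["drug"], "protein": best["protein"]},
            [best["lam"]],
            exclude_drug=d,
            exclude_protein=p,
        )
        model = models[best["lam"]]
        pred = float(predict_matrix(model, K_D[d], K_P[p])[0, 0])
        y_true.append(Y.values[d, p])
        y_pred.append(pred)
        selected.append(best)
        dids.append(Y.drug_ids[d])
        pids.append(Y.protein_ids[p])
    return CVResult(
        "bioactivity_imputation",
        dids,
        pids,
        np.array(y_true),
        np.array(y_pred),
        selected,
    )


def _inner_loo_select(engine, Y_out, drug_idx, prot_idx, points, grid) -> dict:
    inner_entries = _observed_entries(Y_out)
    kernel_combos = {}
    for pt in points:
        key = (tuple(sorted(pt["drug"].items())), tuple(sorted(pt["protein"].items())))
        kernel_combos.setdefault(key, {"drug": pt["drug"], "protein": pt["protein"]})
    lambdas = sorted({pt["lam"] for pt in points})
    sq_err: dict = {
        (key, lam): [] for key in kernel_combos for lam in lambdas
    }
    for d2, p2 in inner_entries:
        Y_in = Y_out.mask_entries([(d2, p2)])
        for key, combo in kernel_combos.items():
            models, K_D, K_P = engine.fit_models(
                Y_in,
                drug_idx,
                prot_idx,
                combo,
                lambdas,
                exclude_drug=d2,
                exclude_protein=p2,
            )
            for lam in lambdas:
                pred = float(predict_matrix(models[lam], K_D[d2], K_P[p2])[0, 0])
                sq_err[(key, lam)].append((pred - Y_out.values[d2, p2]) ** 2)
    scores = []
    for key, combo in kernel_combos.items():
        for lam in lambdas:
            rmse_val = math.sqrt(float(np.mean(sq_err[(key, lam)])))
            scores.append(
                (rmse_val, {"drug": combo["drug"], "protein": combo["protein"], "lam": lam})
            )
    return _select_best(scores)


def _nested_leave_unit_out(
    Y: BioactivityMatrix,
    drug_kernel,
    protein_kernel,
    grid: GridSpec,
    protein_similarity: np.ndarray,
    seed: int,
    axis: int,
    inner_fold_size: int = 5,
) -> CVResult:
    """Shared LDO (axis=0) / LTO (axis=1) driver.

    The outer loop leaves each unit on ``axis`` out; the inner loop removes
    ``inner_fold_size`` random units at a time from the outer-training set
    (disjoint seeded folds) to score grid points by RMSE.  The held-out
    unit's row and column are removed from its side's kernel before training,
    and a profile-based kernel on the left-out axis is a scenario violation.
    """
    n_units = Y.n_drugs if axis == 0 else Y.n_proteins
    scenario = "new_drug" if axis == 0 else "new_target"
    left_out_builder = drug_kernel if axis == 0 else protein_kernel
    if left_out_builder.profile_based:
        raise ScenarioError(
            f"interaction-profile kernel on the left-out axis is unavailable "
            f"under the {scenario} scenario: a new unit has no bioactivity profile"
        )
    if n_units < inner_fold_size + 2:
        raise ValueError(
            f"need at least {inner_fold_size + 2} units on the left-out axis"
        )
    engine = _FoldEngine(drug_kernel, protein_kernel, protein_similarity)
    points = _grid_points(grid, drug_kernel, protein_kernel)
    if not points:
        raise ValueError("empty parameter grid")
    y_true_all, y_pred_all, selected = [], [], []
    dids, pids = [], []

    def _subproblem(unit_indices: np.ndarray):
        """Restrict Y to the given units on the left-out axis."""
        if axis == 0:
            bm = BioactivityMatrix(
                [Y.drug_ids[i] for i in unit_indices],
                list(Y.protein_ids),
                Y.values[unit_indices],
                Y.observed[unit_indices],
            )
            d_idx = unit_indices
            p_idx = np.arange(Y.n_proteins)
        else:
            bm = BioactivityMatrix(
                list(Y.drug_ids),
                [Y.protein_ids[i] for i in unit_indices],
                Y.values[:, unit_indices],
                Y.observed[:, unit_indices],
            )
            d_idx = np.arange(Y.n_drugs)
            p_idx = unit_indices
        return bm, d_idx, p_idx

    def _fit_on(unit_indices: np.ndarray, combo: dict, lambdas):
        bm, d_idx, p_idx = _subproblem(unit_indices)
        # builders receive the restricted matrix; static kernels are subset
        sub_engine_Y = bm
        S_sub = (
            protein_similarity
            if axis == 0
            else np.asarray(protein_similarity)[np.ix_(unit_indices, unit_indices)]
        )
        values, _ = impute_missing(sub_engine_Y, np.asarray(S_sub))
        if axis == 0:
            K_D = drug_kernel.kernel.values[np.ix_(unit_indices, unit_indices)]
            K_P = protein_kernel.build(
                values, bm.observed, 1, np.arange(bm.n_proteins), None, **combo["protein"]
            )
        else:
            K_D = drug_kernel.build(
                values, bm.observed, 0, np.arange(bm.n_drugs), None, **combo["drug"]
            )
            K_P = protein_kernel.kernel.values[np.ix_(unit_indices, unit_indices)]
        eig_D = eigh_kernel(K_D)
        eig_P = eigh_kernel(K_P)
        models = {lam: fit_from_eigh(eig_D, eig_P, values, lam) for lam in lambdas}
        return models, K_D, K_P

    kernel_combos: dict = {}
    for pt in points:
        key = (tuple(sorted(pt["drug"].items())), tuple(sorted(pt["protein"].items())))
        kernel_combos.setdefault(key, {"drug": pt["drug"], "protein": pt["protein"]})
    lambdas = sorted({pt["lam"] for pt in points})

    static_side = drug_kernel if axis == 0 else protein_kernel

    for unit in range(n_units):
        train_units = np.array([u for u in range(n_units) if u != unit])
        # unit's observed entries to predict
        obs = Y.observed[unit] if axis == 0 else Y.observed[:, unit]
        if not obs.any():
            continue
        if len(points) == 1:
            best = points[0]
        else:
            rng = np.random.default_rng([seed, unit])
            perm = rng.permutation(train_units)
            n_folds = math.ceil(len(train_units) / inner_fold_size)
            folds = [perm[k::n_folds] for k in range(n_folds)]
            sq_err = {(key, lam): [] for key in kernel_combos for lam in lambdas}
            for fold in folds:
                inner_train = np.array(
                    sorted(set(train_units) - set(fold.tolist()))
                )
                for key, combo in kernel_combos.items():
                    models, K_D, K_P = _fit_on(inner_train, combo, lambdas)
                    for lam in lambdas:
                        errs = _predict_units(
                            Y, models[lam], static_side, inner_train, fold,
                            K_D, K_P, axis,
                        )
                        sq_err[(key, lam)].extend(errs)
            scores = []
            for key, combo in kernel_combos.items():
                for lam in lambdas:
                    rmse_val = math.sqrt(float(np.mean(sq_err[(key, lam)])))
                    scores.append(
                        (rmse_val, {**combo, "lam": lam})
                    )
            best = _select_best(scores)
        models, K_D, K_P = _fit_on(
            train_units, {"drug": best["drug"], "protein": best["protein"]},
            [best["lam"]],
        )
        model = models[best["lam"]]
        k_unit = static_side.kernel.values[unit, train_units]
        if axis == 0:
            preds = predict_matrix(model, k_unit, K_P)[0]
            cols = np.flatnonzero(obs)
            for c in cols:
                y_true_all.append(Y.values[unit, c])
                y_pred_all.append(preds[c])
                dids.append(Y.drug_ids[unit])
                pids.append(Y.protein_ids[c])
                selected.append(best)
        else:
            preds = predict_matrix(model, K_D, k_unit)[:, 0]
            rows = np.flatnonzero(obs)
            for r in rows:
                y_true_all.append(Y.values[r, unit])
                y_pred_all.append(preds[r])
                dids.append(Y.drug_ids[r])
                pids.append(Y.protein_ids[unit])
                selected.append(best)
    return CVResult(
        scenario, dids, pids, np.array(y_true_all), np.array(y_pred_all), selected
    )


def _predict_units(Y, model, static_side, inner_train, fold, K_D, K_P, axis):
    """Squared errors for the observed entries of the inner-test units."""
    errs = []
    for u in fold:
        k_u = static_side.kernel.values[u, inner_train]
        if axis == 0:
            preds = predict_matrix(model, k_u, K_P)[0]
            for c in np.flatnonzero(Y.observed[u]):
                errs.append((preds[c] - Y.values[u, c]) ** 2)
        else:
            preds = predict_matrix(model, K_D, k_u)[:, 0]
            for r in np.flatnonzero(Y.observed[:, u]):
                errs.append((preds[r] - Y.values[r, u]) ** 2)
    return errs


def nested_ldo_cv(
    Y: BioactivityMatrix,
    drug_kernel,
    protein_kernel,
    grid: GridSpec,
    protein_similarity: np.ndarray,
    seed: int = 0,
    inner_fold_size: int = 5,
) -> CVResult:
    """Nested leave-drug-out CV (new-drug scenario)."""
    return _nested_leave_unit_out(
        Y, drug_kernel, protein_kernel, grid, protein_similarity, seed,
        axis=0, inner_fold_size=inner_fold_size,
    )


def nested_lto_cv(
    Y: BioactivityMatrix,
    drug_kernel,
    protein_kernel,
    grid: GridSpec,
    protein_similarity: np.ndarray,
    seed: int = 0,
    inner_fold_size: int = 5,
) -> CVResult:
    """Nested leave-target-out CV (new-target scenario)."""
    return _nested_leave_unit_out(
        Y, drug_kernel, protein_kernel, grid, protein_similarity, seed,
        axis=1, inner_fold_size=inner_fold_size,
    )


def new_pair_plan(Y: BioactivityMatrix, seed: int = 0) -> CVPlan:
    """Fold plan for the (experimental) new-pair scenario: each fold holds
    out one drug and one target jointly.  Plan construction only."""
    n = min(Y.n_drugs, Y.n_proteins)
    rng = np.random.default_rng(seed)
    drugs = rng.permutation(Y.n_drugs)[:n]
    prots = rng.permutation(Y.n_proteins)[:n]
    folds = [[(int(d), int(p))] for d, p in zip(drugs, prots)]
    return CVPlan("new_pair", folds, inner_spec="leave-drug-and-target-out", seed=seed)


def select_and_refit(
    Y: BioactivityMatrix,
    drug_kernel,
    protein_kernel,
    grid: GridSpec,
    scenario: str,
    protein_similarity: np.ndarray,
    seed: int = 0,
):
    """Pick the grid point minimizing scenario-CV RMSE on the full training
    data, then refit on all observed entries (after imputation).

    Returns ``(model, best_point, cv_rmse)``.
    """
    if scenario not in ("bioactivity_imputation", "new_drug", "new_target"):
        raise ScenarioError(f"unsupported scenario for refit: {scenario!r}")
    points = _grid_points(grid, drug_kernel, protein_kernel)
    if len(points) == 1:
        best, best_rmse = points[0], float("nan")
    else:
        scores = []
        for pt in points:
            sub_grid = GridSpec([pt["lam"]])
            dk = _fixed_candidates(drug_kernel, pt["drug"])
            pk = _fixed_candidates(protein_kernel, pt["protein"])
            if scenario == "bioactivity_imputation":
                res = nested_loo_cv(Y, dk, pk, sub_grid, protein_similarity, seed)
            elif scenario == "new_drug":
                res = nested_ldo_cv(Y, dk, pk, sub_grid, protein_similarity, seed)
            else:
                res = nested_lto_cv(Y, dk, pk, sub_grid, protein_similarity, seed)
            scores.append((res.rmse, pt))
        best = _select_best(scores)
        best_rmse = min(s for s, _ in scores)
    engine = _FoldEngine(drug_kernel, protein_kernel, protein_similarity)
    models, _, _ = engine.fit_models(
        Y,
        np.arange(Y.n_drugs),
        np.arange(Y.n_proteins),
        {"drug": best["drug"], "protein": best["protein"]},
        [best["lam"]],
    )
    model = models[best["lam"]]
    model.drug_ids = list(Y.drug_ids)
    model.protein_ids = list(Y.protein_ids)
    return model, best, best_rmse


class _fixed_candidates:
    """Wrap a builder so its candidate list is pinned to one param dict."""

    def __init__(self, builder, params: dict):
        self._builder = builder
        self._params = params
        self.profile_based = builder.profile_based
        if hasattr(builder, "kernel"):
            self.kernel = builder.kernel

    def candidates(self):
        return [self._params]

    def build(self, *args, **kwargs):
        return self._builder.build(*args, **kwargs)

    def query_vector(self, *args, **kwargs):
        return self._builder.query_vector(*args, **kwargs)
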