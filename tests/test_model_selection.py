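import numpy as np
import pytest

from kronaff.compound_kernels import KernelMatrix
from kronaff.io_formats import BioactivityMatrix
from kronaff.kronrls_core import impute_missing, solve_explicit
from kronaff.model_selection import (
    CVPlan,
    GIPKernel,
    GridSpec,
    ScenarioError,
    StaticKernel,
    _select_best,
    nested_ldo_cv,
    nested_loo_cv,
    nested_lto_cv,
    new_pair_plan,
    select_and_refit,
)


def _bm(values):
    values = np.asarray(values, dtype=float)
    return BioactivityMatrix(
        [f"d{i}" for i in range(values.shape[0])],
        [f"p{j}" for j in range(values.shape[1])],
        values,
        np.isfinite(values),
    )


def _psd_kernel(rng, ids):
    n = len(ids)
    A = rng.normal(size=(n, n + 3))
    K = A @ A.T
    d = np.sqrt(np.diag(K))
    K = K / np.outer(d, d)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(list(ids), K, normalized=True)


class TestNestedLOO:
    def test_matches_brute_force_oracle_identity_kernels(self, rng):
        """Each held-out prediction equals a from-scratch fit on the
        remaining entries (mask, impute, dense Kronecker solve)."""
        Y = _bm(rng.normal(7, 1, (3, 3)))
        ids_d, ids_p = Y.drug_ids, Y.protein_ids
        KD = KernelMatrix(ids_d, np.eye(3), normalized=True)
        KP = KernelMatrix(ids_p, np.eye(3), normalized=True)
        res = nested_loo_cv(
            Y, StaticKernel(KD), StaticKernel(KP), GridSpec([1.0]), np.eye(3), seed=0
        )
        # independent double loop
        for did, pid, pred in zip(res.drug_ids, res.protein_ids, res.y_pred):
            d, p = ids_d.index(did), ids_p.index(pid)
            Y_out = Y.mask_entries([(d, p)])
            values, _ = impute_missing(Y_out, np.eye(3))
            alpha = solve_explicit(np.eye(3), np.eye(3), values, 1.0)
            expected = float(np.kron(np.eye(3)[d], np.eye(3)[p]) @ alpha)
            assert pred == pytest.approx(expected, abs=1e-10)

    def test_matches_oracle_with_general_kernels(self, rng):
        Y = _bm(np.where(rng.random((4, 3)) < 0.85, rng.normal(7, 1, (4, 3)), np.nan))
        KD = _psd_kernel(rng, Y.drug_ids)
        KP = _psd_kernel(rng, Y.protein_ids)
        S_P = np.abs(KP.values)
        res = nested_loo_cv(
            Y, StaticKernel(KD), StaticKernel(KP), GridSpec([0.5]), S_P, seed=0
        )
        for did, pid, pred in zip(res.drug_ids, res.protein_ids, res.y_pred):
            d, p = Y.drug_ids.index(did), Y.protein_ids.index(pid)
            values, _ = impute_missing(Y.mask_entries([(d, p)]), S_P)
            alpha = solve_explicit(KD.values, KP.values, values, 0.5)
            expected = float(np.kron(KD.values[d], KP.values[p]) @ alpha)
            assert pred == pytest.approx(expected, abs=1e-8)

    def test_single_grid_point_always_selected(self, rng):
        Y = _bm(rng.normal(7, 1, (3, 3)))
        KP = KernelMatrix(Y.protein_ids, np.eye(3), normalized=True)
        res = nested_loo_cv(
            Y, GIPKernel(sigma_quantiles=(0.5,)), StaticKernel(KP),
            GridSpec([2.0]), np.eye(3), seed=0,
        )
        assert all(sel["lam"] == 2.0 for sel in res.selected)

    def test_inner_selection_runs_with_multi_point_grid(self, rng):
        Y = _bm(rng.normal(7, 1, (3, 3)))
        KD = _psd_kernel(rng, Y.drug_ids)
        KP = _psd_kernel(rng, Y.protein_ids)
        res = nested_loo_cv(
            Y, StaticKernel(KD), StaticKernel(KP), GridSpec([0.1, 10.0]),
            np.abs(KP.values), seed=0,
        )
        assert {sel["lam"] for sel in res.selected} <= {0.1, 10.0}
        assert res.n == 9

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec([])


class TestLeakageControl:
    def test_loo_prediction_independent_of_held_out_value(self, rng):
        """Sentinel perturbation: changing the held-out entry's value must
        not change its fold's GIP kernel, imputation, or model."""
        vals = rng.normal(7, 1, (6, 5))
        Y1 = _bm(vals)
        vals2 = vals.copy()
        vals2[2, 3] += 50.0  # sentinel
        Y2 = _bm(vals2)
        KP = _psd_kernel(rng, Y1.protein_ids)
        kw = dict(grid=GridSpec([1.0]), protein_similarity=np.abs(KP.values), seed=0)
        r1 = nested_loo_cv(Y1, GIPKernel((0.5,)), StaticKernel(KP), **kw)
        r2 = nested_loo_cv(Y2, GIPKernel((0.5,)), StaticKernel(KP), **kw)
        i = [
            k for k, (d, p) in enumerate(zip(r1.drug_ids, r1.protein_ids))
            if (d, p) == ("d2", "p3")
        ][0]
        assert r1.y_pred[i] == pytest.approx(r2.y_pred[i], abs=1e-10)

    def test_ldo_predictions_independent_of_held_out_drug_row(self, rng):
        vals = rng.normal(7, 1, (8, 4))
        Y1 = _bm(vals)
        vals2 = vals.copy()
        vals2[5, :] += 100.0
        Y2 = _bm(vals2)
        KD = _psd_kernel(rng, Y1.drug_ids)
        KP = _psd_kernel(rng, Y1.protein_ids)
        kw = dict(grid=GridSpec([1.0]), protein_similarity=np.abs(KP.values), seed=3)
        r1 = nested_ldo_cv(Y1, StaticKernel(KD), StaticKernel(KP), **kw)
        r2 = nested_ldo_cv(Y2, StaticKernel(KD), StaticKernel(KP), **kw)
        for k, (d, p) in enumerate(zip(r1.drug_ids, r1.protein_ids)):
            if d == "d5":
                assert r1.y_pred[k] == pytest.approx(r2.y_pred[k], abs=1e-10)

    def test_gip_drug_kernel_rejected_under_new_drug_scenario(self, rng):
        Y = _bm(rng.normal(7, 1, (8, 4)))
        KP = _psd_kernel(rng, Y.protein_ids)
        with pytest.raises(ScenarioError, match="profile"):
            nested_ldo_cv(
                Y, GIPKernel(), StaticKernel(KP), GridSpec([1.0]),
                np.abs(KP.values), seed=0,
            )

    def test_gip_protein_kernel_rejected_under_new_target_scenario(self, rng):
        Y = _bm(rng.normal(7, 1, (4, 8)))
        KD = _psd_kernel(rng, Y.drug_ids)
        with pytest.raises(ScenarioError, match="profile"):
            nested_lto_cv(
                Y, StaticKernel(KD), GIPKernel(), GridSpec([1.0]),
                np.eye(8), seed=0,
            )


class TestNestedLDO:
    def test_matches_brute_force_oracle(self, rng):
        Y = _bm(np.where(rng.random((8, 4)) < 0.9, rng.normal(7, 1, (8, 4)), np.nan))
        KD = _psd_kernel(rng, Y.drug_ids)
        KP = _psd_kernel(rng, Y.protein_ids)
        S_P = np.abs(KP.values)
        res = nested_ldo_cv(
            Y, StaticKernel(KD), StaticKernel(KP), GridSpec([0.7]), S_P, seed=0
        )
        for did, pid, pred in zip(res.drug_ids, res.protein_ids, res.y_pred):
            d = Y.drug_ids.index(did)
            p = Y.protein_ids.index(pid)
            T = [i for i in range(8) if i != d]
            sub = BioactivityMatrix(
                [Y.drug_ids[i] for i in T], Y.protein_ids,
                Y.values[T], Y.observed[T],
            )
            values, _ = impute_missing(sub, S_P)
            KD_sub = KD.values[np.ix_(T, T)]
            alpha = solve_explicit(KD_sub, KP.values, values, 0.7)
            k_d = KD.values[d, T]
            expected = float(np.kron(k_d, KP.values[p]) @ alpha)
            assert pred == pytest.approx(expected, abs=1e-8)

    def test_deterministic_under_fixed_seed(self, rng):
        Y = _bm(rng.normal(7, 1, (9, 4)))
        KD = _psd_kernel(rng, Y.drug_ids)
        KP = _psd_kernel(rng, Y.protein_ids)
        kw = dict(grid=GridSpec([0.25, 4.0]), protein_similarity=np.abs(KP.values))
        r1 = nested_ldo_cv(Y, StaticKernel(KD), StaticKernel(KP), seed=5, **kw)
        r2 = nested_ldo_cv(Y, StaticKernel(KD), StaticKernel(KP), seed=5, **kw)
        assert np.array_equal(r1.y_pred, r2.y_pred)
        assert r1.selected == r2.selected

    def test_too_few_compounds_rejected(self, rng):
        Y = _bm(rng.normal(7, 1, (4, 4)))
        K = _psd_kernel(rng, Y.drug_ids)
        with pytest.raises(ValueError, match="at least"):
            nested_ldo_cv(
                Y, StaticKernel(K), StaticKernel(_psd_kernel(rng, Y.protein_ids)),
                GridSpec([1.0, 2.0]), np.eye(4), seed=0,
            )

    def test_lto_is_ldo_on_transposed_axis(self, rng):
        vals = rng.normal(7, 1, (4, 8))
        Y = _bm(vals)
        KD = _psd_kernel(rng, Y.drug_ids)
        KP = _psd_kernel(rng, Y.protein_ids)
        res = nested_lto_cv(
            Y, StaticKernel(KD), StaticKernel(KP), GridSpec([1.0]),
            np.abs(KP.values), seed=0,
        )
        assert res.scenario == "new_target"
        assert res.n == 32


class TestSelection:
    def test_ties_break_toward_stronger_regularization(self):
        scores = [
            (0.5, {"drug": {}, "protein": {}, "lam": 0.1}),
            (0.5, {"drug": {}, "protein": {}, "lam": 10.0}),
            (0.7, {"drug": {}, "protein": {}, "lam": 100.0}),
        ]
        assert _select_best(scores)["lam"] == 10.0

    def test_select_and_refit_returns_grid_member(self, rng):
        Y = _bm(rng.normal(7, 1, (4, 3)))
        KD = _psd_kernel(rng, Y.drug_ids)
        KP = _psd_kernel(rng, Y.protein_ids)
        model, best, cv_rmse = select_and_refit(
            Y, StaticKernel(KD), StaticKernel(KP), GridSpec([0.1, 1.0]),
            "bioactivity_imputation", np.abs(KP.values), seed=0,
        )
        assert best["lam"] in (0.1, 1.0)
        assert model.lam == best["lam"]
        assert model.drug_ids == Y.drug_ids
        assert np.isfinite(cv_rmse)


def test_cv_plan_requires_disjoint_folds():
    with pytest.raises(ValueError, match="disjoint"):
        CVPlan("new_drug", [[0, 1], [1, 2]], inner_spec="ldo5", seed=0)


def test_new_pair_plan_holds_out_drug_and_target_jointly(rng):
    Y = _bm(rng.normal(7, 1, (5, 4)))
    plan = new_pair_plan(Y, seed=1)
    assert plan.scenario == "new_pair"
    drugs = [d for fold in plan.outer_folds for d, _ in fold]
    assert len(drugs) == len(set(drugs))
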