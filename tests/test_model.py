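"""Mixed-model engine against independent GLS / direct-likelihood oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla

import ssgwas as sg
from ssgwas.io import DataError, PedigreeTable
from ssgwas.model import (RepeatabilityModel, VarianceComponents, build_design,
                          _theta_to_vc, _vc_to_theta)
from conftest import make_phenotypes


def _ped(animals, sires=None, dams=None):
    n = len(animals)
    bf = pd.DataFrame(index=pd.Index(animals, name="animal"))
    return PedigreeTable(animals, sires or ["0"] * n, dams or ["0"] * n, bf)


def gls_blup_oracle(model, vc):
    """Direct V-form generalized least squares + BLUP, assembled per
    (record, trait) observation: independent of the MME path."""
    eng = model.engine
    des = model.design
    A_like = np.linalg.inv(eng.Hinv)         # the H actually used
    obs = [(i, t) for i in range(eng.n) for t in range(eng.T) if des.mask[i, t]]
    N = len(obs)
    ri = np.array([i for i, _ in obs])
    rt = np.array([t for _, t in obs])
    V = (vc.Va[np.ix_(rt, rt)] * A_like[np.ix_(eng.anim[ri], eng.anim[ri])]
         + vc.Vp[np.ix_(rt, rt)] * (eng.pe[ri][:, None] == eng.pe[ri][None, :])
         + vc.Ve[np.ix_(rt, rt)] * (ri[:, None] == ri[None, :]))
    X = np.zeros((N, eng.T * eng.f))
    y = np.empty(N)
    for r, (i, t) in enumerate(obs):
        y[r] = des.y[i, t]
        X[r, t * eng.f:(t + 1) * eng.f] = des.F[i]
    Vinv = np.linalg.inv(V)
    XtVi = X.T @ Vinv
    b = np.linalg.solve(XtVi @ X, XtVi @ y)
    resid = y - X @ b
    # Cov(a_(t,k), y_(j,u)) = Va[t,u] * H[k, anim_j]
    gebv = np.zeros((eng.T, eng.q))
    w = Vinv @ resid
    for r, (j, u) in enumerate(obs):
        for t in range(eng.T):
            gebv[t] += vc.Va[t, u] * A_like[:, eng.anim[j]] * w[r]
    # restricted log-likelihood (V-form), up to the same additive constant
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtVi @ X)
    ll = -0.5 * (ldV + ldX + resid @ w)
    return b.reshape(eng.T, eng.f), gebv, ll


def small_model(seed=0, n_bulls=8, records=2, traits=3, missing=False):
    rng = np.random.default_rng(seed)
    sires = ["s1", "s2"]
    animals = sires + [f"b{i}" for i in range(n_bulls)]
    ped = _ped(animals,
               ["0", "0"] + [sires[i % 2] for i in range(n_bulls)],
               ["0"] * (2 + n_bulls))
    rows = np.repeat([f"b{i}" for i in range(n_bulls)], records)
    vals = rng.standard_normal((len(rows), 3))
    if missing:
        vals[rng.random(vals.shape) < 0.25] = np.nan
        empty = np.isnan(vals).all(axis=1)
        vals[empty, 0] = rng.standard_normal(empty.sum())
    phen = make_phenotypes(vals, rows)
    # add some covariate variation so the design is interesting
    phen.df["age_months"] = rng.uniform(24, 60, len(rows))
    phen.df["contemporary_group"] = [f"cg{i % 2}" for i in range(len(rows))]
    return RepeatabilityModel(phen, pedigree=ped)


def example_vc(traits=("T1", "T2", "T3")):
    base = np.array([[0.4, 0.1, 0.05], [0.1, 0.5, 0.1], [0.05, 0.1, 0.6]])
    return VarianceComponents(0.5 * base, 0.3 * base, base, list(traits))


class TestDesign:
    def test_single_level_collapses_to_intercept(self):
        phen = make_phenotypes(np.ones((2, 3)), ["b", "b"])
        des = build_design(phen)
        assert des.columns == ["intercept"]

    def test_reference_coding(self):
        phen = make_phenotypes(np.ones((4, 3)), ["b"] * 4)
        phen.df["contemporary_group"] = ["c1", "c2", "c1", "c2"]
        des = build_design(phen)
        cg_cols = [c for c in des.columns if c.startswith("contemporary_group")]
        assert len(cg_cols) == 1

    def test_rank_deficiency_names_aliased_column(self):
        phen = make_phenotypes(np.ones((4, 3)), ["b"] * 4)
        phen.df["contemporary_group"] = ["c1", "c2", "c1", "c2"]
        phen.df["ejaculate_order"] = ["1", "2", "1", "2"]  # aliased with CG
        with pytest.raises(DataError, match="aliased"):
            build_design(phen)


class TestSolve:
    def test_matches_gls_oracle(self):
        model = small_model(seed=1)
        vc = example_vc()
        sol = model.solve(vc)
        b, gebv, ll = gls_blup_oracle(model, vc)
        np.testing.assert_allclose(sol.fixed_effects.to_numpy(), b.T, atol=1e-8)
        np.testing.assert_allclose(sol.gebv.to_numpy(), gebv.T, atol=1e-8)

    def test_matches_gls_oracle_with_missing_traits(self):
        model = small_model(seed=2, missing=True)
        vc = example_vc()
        sol = model.solve(vc)
        b, gebv, ll = gls_blup_oracle(model, vc)
        np.testing.assert_allclose(sol.fixed_effects.to_numpy(), b.T, atol=1e-8)
        np.testing.assert_allclose(sol.gebv.to_numpy(), gebv.T, atol=1e-8)

    def test_loglik_matches_direct_form(self):
        # MME-based restricted likelihood equals the V-form one (same constant)
        model = small_model(seed=3, missing=True)
        for s in (4, 5):
            vc = example_vc()
            scale = 1.0 + 0.3 * s
            vc2 = VarianceComponents(vc.Va * scale, vc.Vp, vc.Ve, vc.traits)
            _, _, ll_oracle = gls_blup_oracle(model, vc2)
            assert model.loglik(vc2) == pytest.approx(ll_oracle, abs=1e-8)

    def test_gebv_shrink_to_zero_when_va_vanishes(self):
        model = small_model(seed=4)
        vc = example_vc()
        tiny = VarianceComponents(1e-12 * np.eye(3), vc.Vp, vc.Ve, vc.traits)
        sol = model.solve(tiny)
        assert np.abs(sol.gebv.to_numpy()).max() < 1e-6

    def test_duplicating_records_and_doubling_ve_keeps_solutions(self):
        # exact weighting identity: each duplicated record at 2*Ve carries
        # half the weight, so the assembled MME (and hence all BLUE/BLUP
        # solutions) is unchanged
        model = small_model(seed=5)
        vc = example_vc()
        sol1 = model.solve(vc)
        phen2 = sg.PhenotypeTable(
            pd.concat([model.phenotypes.df] * 2, ignore_index=True),
            model.phenotypes.traits)
        model2 = RepeatabilityModel(phen2, relationships=model.relationships)
        vc2 = VarianceComponents(vc.Va, vc.Vp, vc.Ve * 2.0, vc.traits)
        sol2 = model2.solve(vc2)
        np.testing.assert_allclose(sol1.fixed_effects.to_numpy(),
                                   sol2.fixed_effects.to_numpy(), atol=1e-8)
        np.testing.assert_allclose(sol1.gebv.to_numpy(),
                                   sol2.gebv.to_numpy(), atol=1e-8)

    def test_record_order_invariance(self):
        model = small_model(seed=6, missing=True)
        vc = example_vc()
        sol1 = model.solve(vc)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(model.phenotypes.df))
        phen2 = sg.PhenotypeTable(
            model.phenotypes.df.iloc[perm].reset_index(drop=True),
            model.phenotypes.traits)
        sol2 = RepeatabilityModel(phen2, relationships=model.relationships).solve(vc)
        np.testing.assert_allclose(sol1.gebv.to_numpy(), sol2.gebv.to_numpy(),
                                   atol=1e-8)
        np.testing.assert_allclose(sol1.fixed_effects.to_numpy(),
                                   sol2.fixed_effects.to_numpy(), atol=1e-8)


class TestREML:
    def test_em_is_monotone(self):
        model = small_model(seed=7, n_bulls=12, records=3)
        res = model.fit(method="em", max_iter=25, tol=1e-12)
        assert np.all(np.diff(res.loglik_path) >= -1e-8)

    def test_ai_path_is_monotone_and_faster(self):
        model = small_model(seed=8, n_bulls=12, records=3)
        res = model.fit(method="ai", max_iter=60, tol=1e-8)
        assert np.all(np.diff(res.loglik_path) >= -1e-7)

    def test_reml_estimate_is_a_stationary_interior_maximum(self):
        # on a problem large enough for an interior optimum, the fitted
        # components must zero the restricted-likelihood gradient (finite
        # differences of the likelihood, whose value is itself validated
        # against the independent V-form in test_loglik_matches_direct_form)
        spec = sg.SimulationSpec(
            n_sires=20, n_dams=40, n_bulls_phenotyped=200, records_per_bull=8,
            n_genotyped_bulls=0, n_genotyped_dams=0, n_chromosomes=1,
            markers_per_chromosome=10, n_contemporary_groups=6, seed=77)
        data = sg.simulate_dataset(spec)
        model = RepeatabilityModel(data.phenotypes, pedigree=data.pedigree)
        res = model.fit(max_iter=60, tol=1e-8)
        assert res.converged
        mins = [np.linalg.eigvalsh(m).min() for m in (res.vc.Va, res.vc.Vp, res.vc.Ve)]
        assert min(mins) > 1e-3, "optimum unexpectedly on the PSD boundary"
        th = _vc_to_theta(res.vc)
        h = 1e-4
        grad = np.zeros(len(th))
        for k in range(len(th)):
            tp, tm = th.copy(), th.copy()
            tp[k] += h
            tm[k] -= h
            grad[k] = (model.loglik(_theta_to_vc(tp, res.vc.traits))
                       - model.loglik(_theta_to_vc(tm, res.vc.traits))) / (2 * h)
        assert np.abs(grad).max() < 0.5

    def test_pure_noise_boundary(self):
        # true Va = Vp = 0: additive and permanent-environment variances
        # must collapse relative to the residual
        ratios = []
        for seed in range(3):
            spec = sg.SimulationSpec(
                n_sires=15, n_dams=30, n_bulls_phenotyped=100, records_per_bull=5,
                n_genotyped_bulls=0, n_genotyped_dams=0, n_chromosomes=1,
                markers_per_chromosome=10, n_contemporary_groups=5,
                Va=np.zeros((3, 3)), Vp=np.zeros((3, 3)),
                Ve=np.eye(3), cg_sd=0.2, seed=100 + seed)
            data = sg.simulate_dataset(spec)
            model = RepeatabilityModel(data.phenotypes, pedigree=data.pedigree)
            res = model.fit(max_iter=30, tol=1e-6)
            ratios.append((np.diag(res.vc.Va) + np.diag(res.vc.Vp))
                          / np.diag(res.vc.Ve))
        assert np.mean(ratios) < 0.10

    def test_summary_mentions_components(self):
        model = small_model(seed=10)
        res = model.fit(max_iter=10, tol=1e-4)
        text = res.summary()
        assert "Va (additive)" in text and "repeatability" in text
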