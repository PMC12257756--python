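import numpy as np
import pandas as pd
import pytest

from pigdamage.mixed_model import (MMEWorkspace, ModelSpec,
                                   RankDeficientDesign, VarianceComponents,
                                   build_design, compute_pev, heritability,
                                   model_accuracy, reml_bivariate, reml_fit,
                                   solve_blup)
from pigdamage.pedigree import Pedigree, relationship_matrix
from pigdamage.simulate import simulate_dataset

from conftest import small_config
from oracles import dense_gls, dense_neg2_restricted


class TestBuildDesign:
    def test_two_level_factor_rank(self, small_ds):
        spec = ModelSpec(traits=["ear"], fixed_factors=["sex"],
                         covariates=[])
        d = build_design(small_ds.phenotypes, spec, small_ds.pedigree)
        assert d.p == 2     # intercept + one dummy
        assert d.x_names[0] == "intercept"

    def test_animal_incidence_one_per_row(self, small_ds):
        spec = ModelSpec(traits=["ear"])
        d = build_design(small_ds.phenotypes, spec, small_ds.pedigree)
        Za = d.Z["animal"]
        assert Za.shape == (len(small_ds.phenotypes), len(small_ds.pedigree))
        assert np.all(Za.sum(axis=1) == 1)
        assert np.all(Za.data == 1)

    def test_confounded_design_rejected(self, small_ds):
        tab = small_ds.phenotypes.copy()
        tab["sex_copy"] = tab["sex"]
        spec = ModelSpec(traits=["ear"], fixed_factors=["sex", "sex_copy"],
                         covariates=[])
        with pytest.raises(RankDeficientDesign, match="sex_copy"):
            build_design(tab, spec, small_ds.pedigree)

    def test_centred_age_same_loglik(self, small_ds):
        tab = small_ds.phenotypes.copy()
        spec = ModelSpec(traits=["ear"])
        _, fit_raw = reml_fit(tab, spec, small_ds.pedigree)
        tab["age_days"] = tab["age_days"] - tab["age_days"].mean()
        _, fit_ctr = reml_fit(tab, spec, small_ds.pedigree)
        assert fit_raw.loglik == pytest.approx(fit_ctr.loglik, abs=1e-8)

    def test_missing_values_rejected(self, small_ds):
        tab = small_ds.phenotypes.copy()
        tab.loc[tab.index[3], "ear"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_design(tab, ModelSpec(traits=["ear"]), small_ds.pedigree)


class TestLikelihoodOracles:
    def comps(self):
        return {"animal": 0.07, "litter": 0.12, "pen": 0.15,
                "hys_scoring": 0.08, "residual": 0.5}

    def test_mme_loglik_equals_dense(self, small_ds):
        spec = ModelSpec(traits=["ear"])
        d = build_design(small_ds.phenotypes, spec, small_ds.pedigree)
        ws = MMEWorkspace(d)
        A = relationship_matrix(small_ds.pedigree).values
        comps = self.comps()
        mme = ws.neg2_restricted_loglik(comps, comps["residual"])
        dense = dense_neg2_restricted(d, A, comps)
        assert mme == pytest.approx(dense, abs=1e-6)

    def test_sparse_blup_equals_dense_gls(self, small_ds):
        # <=200 records so the dense GLS route is exact and cheap
        tab = small_ds.phenotypes.iloc[:180]
        spec = ModelSpec(traits=["ear"])
        d = build_design(tab, spec, small_ds.pedigree)
        comps = self.comps()
        vc = VarianceComponents(components=comps)
        fit = solve_blup(d, vc)
        A = relationship_matrix(small_ds.pedigree).values
        b, u = dense_gls(d, A, comps)
        assert np.allclose(fit.b.to_numpy(), b, atol=1e-6)
        for term in d.Z:
            assert np.allclose(fit.u[term].to_numpy(), u[term], atol=1e-6)
        assert fit.mme_residual < 1e-6

    def test_pev_matches_dense_inverse(self, small_ds):
        tab = small_ds.phenotypes.iloc[:150]
        spec = ModelSpec(traits=["ear"])
        vc, fit = reml_fit(tab, spec, small_ds.pedigree)
        pev = compute_pev(fit)
        ws = fit._workspace
        gamma = {t: float(vc.components[t])
                 / float(vc.components["residual"]) for t in ws.terms}
        Minv = np.linalg.inv(ws.coefficient_matrix(gamma).toarray())
        sl = ws.slices["animal"]
        ped = small_ds.pedigree
        for a in pev.index[:20]:
            j = sl.start + ped.index_of(a)
            expect = float(vc.components["residual"]) * Minv[j, j]
            assert pev.loc[a] == pytest.approx(expect, rel=1e-8)


class TestRemlFit:
    def test_half_sib_anova_oracle(self):
        # balanced paternal half-sib design: REML additive variance equals
        # 4x the ANOVA sire component for balanced data
        rng = np.random.default_rng(12)
        n_sires, n_off = 100, 20
        sire_eff = rng.normal(0, np.sqrt(0.1), n_sires)
        recs, rows = [], []
        for s in range(n_sires):
            recs.append((f"s{s}", None, None))
            for k in range(n_off):
                a = f"o{s}_{k}"
                recs.append((a, f"s{s}", None))
                rows.append({"animal": a,
                             "y": sire_eff[s] + rng.normal(0, 1.0)})
        ped = Pedigree.from_records(recs)
        tab = pd.DataFrame(rows)
        spec = ModelSpec(traits=["y"], fixed_factors=[], covariates=[],
                         random_terms={"animal": "animal"})
        vc, fit = reml_fit(tab, spec, ped)
        y = tab["y"].to_numpy().reshape(n_sires, n_off)
        ms_sire = n_off * np.var(y.mean(axis=1), ddof=1)
        ms_within = np.mean(np.var(y, axis=1, ddof=1))
        anova_va = 4.0 * (ms_sire - ms_within) / n_off
        assert float(vc.components["animal"]) == pytest.approx(
            anova_va, rel=5e-3, abs=5e-4)

    def test_null_additive_variance_at_floor(self):
        cfg = small_config(var_a=0.0, dams_per_generation=40, seed=61)
        ds = simulate_dataset(cfg)
        vc, fit = reml_fit(ds.phenotypes, ModelSpec(traits=["ear"]),
                           ds.pedigree)
        assert float(vc.components["animal"]) < 0.02 * vc.total_variance()

    def test_optimum_beats_grid(self, small_ds):
        # 30-record toy with animal + litter + residual; the returned
        # likelihood must dominate a 21^3 grid of component values
        tab = small_ds.phenotypes.iloc[:30]
        spec = ModelSpec(traits=["ear"], fixed_factors=["sex"],
                         covariates=[],
                         random_terms={"animal": "animal",
                                       "litter": "litter"})
        vc, fit = reml_fit(tab, spec, small_ds.pedigree)
        d = build_design(tab, spec, small_ds.pedigree)
        ws = MMEWorkspace(d)
        vy = float(np.var(d.y))
        grid = vy * np.geomspace(0.01, 2.0, 21)
        best = -np.inf
        for va in grid:
            for vl in grid:
                for ve in grid:
                    val = -0.5 * ws.neg2_restricted_loglik(
                        {"animal": va, "litter": vl, "residual": ve}, ve)
                    best = max(best, val)
        assert fit.loglik >= best - 1e-6

    def test_loglik_invariant_to_record_order_and_reference(self, small_ds):
        spec = ModelSpec(traits=["ear"])
        _, fit0 = reml_fit(small_ds.phenotypes, spec, small_ds.pedigree)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(small_ds.phenotypes))
        shuffled = small_ds.phenotypes.iloc[perm].reset_index(drop=True)
        _, fit1 = reml_fit(shuffled, spec, small_ds.pedigree)
        relabelled = small_ds.phenotypes.copy()
        relabelled["sex"] = relabelled["sex"].map(
            {"boar": "z_boar", "gilt": "a_gilt"})   # flips reference level
        _, fit2 = reml_fit(relabelled, spec, small_ds.pedigree)
        assert fit1.loglik == pytest.approx(fit0.loglik, abs=1e-6)
        assert fit2.loglik == pytest.approx(fit0.loglik, abs=1e-6)


class TestBivariate:
    def test_biv_loglik_equals_dense(self, small_ds):
        spec = ModelSpec(traits=["ear", "tail"])
        d = build_design(small_ds.phenotypes.iloc[:120], spec,
                         small_ds.pedigree)
        ws = MMEWorkspace(d)
        comps = {t: np.array([[v, 0.3 * v], [0.3 * v, v]]) for t, v in
                 [("animal", 0.06), ("litter", 0.1), ("pen", 0.18),
                  ("hys_scoring", 0.09)]}
        comps["residual"] = np.array([[0.5, 0.12], [0.12, 0.55]])
        mme = ws.neg2_restricted_loglik_biv(comps)
        A = relationship_matrix(small_ds.pedigree).values
        n = d.n
        y = d.y.T.ravel()
        V = np.kron(comps["residual"], np.eye(n))
        for term, Z in d.Z.items():
            Zd = Z.toarray()
            K = Zd @ A @ Zd.T if term == "animal" else Zd @ Zd.T
            V += np.kron(comps[term], K)
        X = np.kron(np.eye(2), d.X)
        Vi = np.linalg.inv(V)
        XVX = X.T @ Vi @ X
        b = np.linalg.solve(XVX, X.T @ Vi @ y)
        quad = (y - X @ b) @ Vi @ y
        dense = (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XVX)[1] + quad
                 + (2 * n - X.shape[1]) * np.log(2 * np.pi))
        assert mme == pytest.approx(dense, abs=1e-6)

    def test_duplicate_traits_fixed_litter_correlation(self, small_ds):
        tab = small_ds.phenotypes.copy()
        tab["ear2"] = tab["ear"]
        vc, fit = reml_bivariate(tab, ModelSpec(traits=["ear", "ear2"]),
                                 small_ds.pedigree, fix={"litter": 0.99})
        rg, _ = vc.genetic_correlation()
        assert rg >= 0.99
        S = np.asarray(vc.components["litter"])
        assert S[0, 1] / np.sqrt(S[0, 0] * S[1, 1]) == pytest.approx(0.99)


class TestDerivedQuantities:
    def vc(self, va=0.05, vl=0.05, vg=0.20, vh=0.10, ve=0.60):
        return VarianceComponents(components={
            "animal": va, "litter": vl, "pen": vg, "hys_scoring": vh,
            "residual": ve})

    def test_heritability_arithmetic(self):
        h2, _ = heritability(self.vc())
        assert h2 == pytest.approx(0.05)
        h2x, _ = heritability(self.vc(), include_hys=False)
        assert h2x == pytest.approx(0.05 / 0.90)

    def test_heritability_pure_genetic(self):
        h2, _ = heritability(self.vc(va=1.0, vl=0, vg=0, vh=0, ve=0))
        assert h2 == 1.0

    def test_heritability_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            heritability(self.vc(va=0, vl=0, vg=0, vh=0, ve=0))

    def test_model_accuracy_formula_and_monotonicity(self, small_fit):
        vc, fit = small_fit
        va = float(vc.components["animal"])
        fit.pev = pd.Series([va, 0.0, 0.75 * va, 0.5 * va],
                            index=["w", "x", "y", "z"])
        acc = model_accuracy(fit, vc, animals=["w", "x", "y", "z"])
        assert acc.loc["w"] == pytest.approx(0.0)
        assert acc.loc["x"] == pytest.approx(1.0)
        assert acc.loc["y"] == pytest.approx(0.5)
        # monotone decreasing in PEV
        assert acc.loc["x"] > acc.loc["z"] > acc.loc["y"] > acc.loc["w"]

    def test_accuracy_clamps_out_of_range_pev(self, small_fit, caplog):
        vc, fit = small_fit
        va = float(vc.components["animal"])
        fit.pev = pd.Series([1.5 * va, -0.1 * va], index=["u", "v"])
        with caplog.at_level("WARNING"):
            acc = model_accuracy(fit, vc, animals=["u", "v"])
        assert acc.loc["u"] == 0.0 and acc.loc["v"] == 1.0
        assert "clamped" in caplog.text
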