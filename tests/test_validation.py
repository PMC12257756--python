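import numpy as np
import pandas as pd
import pytest

from pigdamage.mixed_model import ModelSpec, VarianceComponents, reml_fit
from pigdamage.pedigree import Pedigree
from pigdamage.simulate import simulate_dataset
from pigdamage.validation import (CvScheme, adjust_phenotypes, lr_metrics,
                                  lr_split, make_folds, run_cv,
                                  run_lr_validation)

from conftest import small_config


class TestAdjustPhenotypes:
    def test_constant_shift_absorbed_by_intercept(self, small_ds,
                                                  small_fit):
        # at fixed variance components the shift moves only the intercept
        # estimate, so the adjusted phenotypes are unchanged exactly
        from pigdamage.mixed_model import build_design, solve_blup

        vc, fit0 = small_fit
        spec = ModelSpec(traits=["ear"])
        ya0 = adjust_phenotypes(small_ds.phenotypes, fit0)
        shifted = small_ds.phenotypes.copy()
        shifted["ear"] = shifted["ear"] + 7.5
        d1 = build_design(shifted, spec, small_ds.pedigree)
        fit1 = solve_blup(d1, vc)
        ya1 = adjust_phenotypes(shifted, fit1)
        assert np.allclose(ya0, ya1, atol=1e-8)
        # and a full REML refit reproduces it within optimiser precision
        _, fit2 = reml_fit(shifted, spec, small_ds.pedigree)
        ya2 = adjust_phenotypes(shifted, fit2)
        assert np.allclose(ya0, ya2, atol=1e-4)

    def test_true_effect_adjustment_leaves_animal_plus_residual(self,
                                                                small_ds):
        # subtracting the *true* fixed and group effects must leave exactly
        # a + e, by construction of the generator
        ds = small_ds
        pheno = ds.phenotypes.set_index("animal")
        liab = ds.liabilities["ear"]
        removed = (
            ds.true_effects["litter"].loc[pheno["litter"], "ear"].to_numpy()
            + ds.true_effects["pen"].loc[pheno["pen"], "ear"].to_numpy()
            + ds.true_effects["hys_scoring"].loc[pheno["hys_scoring"],
                                                 "ear"].to_numpy())
        a_plus_e_noise = liab.to_numpy() - removed
        tbv = ds.true_bv.loc[pheno.index, "ear"].to_numpy()
        resid = a_plus_e_noise - tbv
        # the leftover (fixed part + e) is uncorrelated with the BV
        assert abs(np.corrcoef(resid, tbv)[0, 1]) < 0.1

    def test_zero_estimates_mean_no_adjustment(self, small_fit, small_ds):
        vc, fit = small_fit
        import copy
        f = copy.copy(fit)
        f.b = fit.b * 0.0
        f.u = {t: u * 0.0 for t, u in fit.u.items()}
        ya = adjust_phenotypes(small_ds.phenotypes, f)
        assert np.allclose(ya, small_ds.phenotypes["ear"])


class TestFolds:
    def unrelated(self, n=10):
        return Pedigree.from_records([(f"a{i}", None, None)
                                      for i in range(n)])

    def test_random_partition_balanced(self):
        ped = self.unrelated(10)
        tab = pd.DataFrame({"animal": ped.ids})
        folds = make_folds(tab, ped, CvScheme(k=5, replicates=3, seed=1))
        for assign in folds:
            sizes = np.bincount(assign, minlength=5)
            assert sizes.tolist() == [2] * 5

    def test_partition_is_exact(self, medium_ds):
        tab = medium_ds.phenotypes
        for g in ("random", "full-sib", "half-sib"):
            assign = make_folds(tab, medium_ds.pedigree,
                                CvScheme(k=5, grouping=g, seed=3))[0]
            assert len(assign) == len(tab)
            assert set(assign) <= set(range(5))

    def test_full_sibs_never_split(self, medium_ds):
        tab = medium_ds.phenotypes
        ped = medium_ds.pedigree
        assign = make_folds(tab, ped,
                            CvScheme(k=5, grouping="full-sib", seed=2))[0]
        key = [(ped.sire[ped.index_of(a)], ped.dam[ped.index_of(a)])
               for a in tab["animal"]]
        df = pd.DataFrame({"key": key, "fold": assign})
        assert (df.groupby("key")["fold"].nunique() == 1).all()

    def test_half_sibs_never_split_and_match_networkx(self, medium_ds):
        import networkx as nx

        tab = medium_ds.phenotypes
        ped = medium_ds.pedigree
        assign = make_folds(tab, ped,
                            CvScheme(k=5, grouping="half-sib", seed=2))[0]
        G = nx.Graph()
        animals = tab["animal"].to_list()
        G.add_nodes_from(animals)
        for a in animals:
            i = ped.index_of(a)
            for p in (ped.sire[i], ped.dam[i]):
                if p >= 0:
                    G.add_edge(a, f"parent{p}")
        fold_of = dict(zip(animals, assign))
        for comp in nx.connected_components(G):
            members = [a for a in comp if not str(a).startswith("parent")]
            assert len({fold_of[a] for a in members}) <= 1

    def test_single_sire_block_stays_intact(self):
        recs = [("S", None, None)]
        rows = []
        for d in range(40):
            recs.append((f"D{d}", None, None))
            recs.append((f"o{d}", "S", f"D{d}"))
            rows.append({"animal": f"o{d}"})
        for i in range(40):   # unrelated filler records
            recs.append((f"u{i}", None, None))
            rows.append({"animal": f"u{i}"})
        ped = Pedigree.from_records(recs)
        tab = pd.DataFrame(rows)
        assign = make_folds(tab, ped,
                            CvScheme(k=5, grouping="half-sib", seed=0))[0]
        block = assign[:40]
        assert len(set(block)) == 1


class TestRunCv:
    def test_null_genetics_gives_null_accuracy(self):
        ds = simulate_dataset(small_config(var_a=0.0, var_e=0.6,
                                           dams_per_generation=40, seed=55))
        spec = ModelSpec(traits=["ear"])
        vc, fit = reml_fit(ds.phenotypes, spec, ds.pedigree)
        # rescale by a nominal h so division is defined even at the floor
        vc.components["animal"] = max(float(vc.components["animal"]),
                                      1e-4)
        rep = run_cv(ds.phenotypes, ds.pedigree, spec,
                     CvScheme(k=5, replicates=2, seed=1),
                     vc=vc, full_fit=fit)
        se = np.std(rep.fold_accuracies, ddof=1) / np.sqrt(
            len(rep.fold_accuracies))
        assert abs(rep.accuracy) < 3 * se + 0.05

    def test_report_shape_and_seed_stability(self, medium_ds):
        spec = ModelSpec(traits=["ear"])
        vc, fit = reml_fit(medium_ds.phenotypes, spec, medium_ds.pedigree)
        reps = [run_cv(medium_ds.phenotypes, medium_ds.pedigree, spec,
                       CvScheme(k=5, replicates=2, seed=s),
                       vc=vc, full_fit=fit) for s in (1, 2)]
        assert len(reps[0].fold_accuracies) == 10
        # replicate means agree across seeds within Monte-Carlo scatter
        pooled_se = np.hypot(reps[0].accuracy_se, reps[1].accuracy_se)
        assert abs(reps[0].accuracy - reps[1].accuracy) < 4 * pooled_se


class TestLrSplit:
    def test_cutoff_before_all_births_errors(self, medium_ds):
        with pytest.raises(ValueError, match="training"):
            lr_split(medium_ds.phenotypes, "1990-01-01")

    def test_partition_sums(self, medium_ds):
        t, v = lr_split(medium_ds.phenotypes, "2021-12-31")
        assert t.sum() + v.sum() == len(medium_ds.phenotypes)
        assert t.sum() > 0 and v.sum() > 0

    def test_generation_cutoff_selects_last_generation(self, medium_ds):
        t, v = lr_split(medium_ds.phenotypes, "2021-12-31")
        gens = medium_ds.phenotypes["generation"].to_numpy()
        assert np.all(gens[v] == 2)
        assert np.all(gens[t] == 1)


class TestLrMetrics:
    def vc(self, va=0.05):
        return VarianceComponents(components={"animal": va, "residual": 0.5})

    def test_identical_ebv_bias_zero_dispersion_one(self):
        rng = np.random.default_rng(0)
        e = pd.Series(rng.normal(0, 0.1, 200))
        rep = lr_metrics(e, e.copy(), self.vc(), fbar=0.0)
        assert rep.bias_sd_units == pytest.approx(0.0, abs=1e-12)
        assert rep.dispersion == pytest.approx(1.0)

    def test_accuracy_one_when_variance_matches(self):
        rng = np.random.default_rng(1)
        va, fbar = 0.05, 0.1
        e = pd.Series(rng.normal(0, 1.0, 5000))
        e = e / e.std(ddof=1) * np.sqrt((1 - fbar) * va)
        rep = lr_metrics(e, e.copy(), self.vc(va), fbar=fbar)
        assert rep.accuracy == pytest.approx(1.0, abs=1e-9)

    def test_negative_covariance_flags_nan(self):
        e1 = pd.Series([1.0, 2.0, 3.0, 4.0])
        e2 = pd.Series([4.0, 3.0, 2.0, 1.0])
        rep = lr_metrics(e1, e2, self.vc(), fbar=0.0)
        assert np.isnan(rep.accuracy) and not rep.accuracy_valid
        assert np.isfinite(rep.dispersion)

    def test_dispersion_equals_ols_slope(self):
        rng = np.random.default_rng(2)
        p = pd.Series(rng.normal(0, 1, 300))
        c = 0.8 * p + pd.Series(rng.normal(0, 0.3, 300))
        rep = lr_metrics(p, c, self.vc(), fbar=0.0)
        slope = np.polyfit(p, c, 1)[0]
        assert rep.dispersion == pytest.approx(slope, rel=1e-10)


def test_lr_validation_end_to_end(medium_ds):
    spec = ModelSpec(traits=["ear"])
    vc, fit = reml_fit(medium_ds.phenotypes, spec, medium_ds.pedigree)
    rep = run_lr_validation(medium_ds.phenotypes, medium_ds.pedigree, spec,
                            "2021-12-31", vc=vc, full_fit=fit)
    assert 0.0 <= rep.accuracy <= 1.0
    assert abs(rep.bias_sd_units) < 0.5
    assert 0.3 < rep.dispersion < 2.0
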