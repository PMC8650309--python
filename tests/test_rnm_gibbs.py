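"""Mixed-model assembly, Gibbs sampling, summaries and diagnostics."""
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from heatnorm import relmat, rnm_gibbs, simdata
from heatnorm.envgrad import build_gradient


def _toy_data(n_animals=3, records_per_animal=2, seed=0):
    rng = np.random.default_rng(seed)
    ped = pd.DataFrame({"animal": range(1, n_animals + 1),
                        "sire": 0, "dam": 0})
    rows = []
    rid = 0
    for a in ped["animal"]:
        for _ in range(records_per_animal):
            rid += 1
            rows.append({"record_id": rid, "animal": a, "litter": a,
                         "cg": "c1" if a % 2 else "c2",
                         "env_value": float(rng.uniform(0, 10)),
                         "value": float(rng.normal(5, 1))})
    return ped, pd.DataFrame(rows)


class TestAssembly:
    def test_tiny_blup_matches_dense_normal_equations(self):
        ped, data = _toy_data()
        rel = relmat.build_relationships(ped)
        spec = rnm_gibbs.ModelSpec(fixed=("cg",), random=("a",))
        system = rnm_gibbs.assemble_mme(data, spec, None, rel.Hinv, rel.animals)
        g0 = {"a": np.array([[1.0, 0.2], [0.2, 0.5]])}
        s2e = 1.3
        # hand-assembled dense normal equations
        W = system.W.toarray()
        C = W.T @ W / s2e
        prior = np.zeros((system.n_coef, system.n_coef))
        block = np.kron(rel.Ainv.toarray(), np.linalg.inv(g0["a"]))
        prior[system.n_fixed:, system.n_fixed:] = block
        sol = np.linalg.solve(C + prior, W.T @ system.y / s2e)
        np.testing.assert_allclose(system.solve(g0, s2e), sol, atol=1e-10)
        gs = rnm_gibbs.solve_blup(system, g0, s2e, n_sweeps=500)
        np.testing.assert_allclose(gs, sol, atol=1e-8)

    def test_duplicate_records_double_rhs(self):
        ped, data = _toy_data()
        rel = relmat.build_relationships(ped)
        spec = rnm_gibbs.ModelSpec(fixed=("cg",), random=("a",))
        one = rnm_gibbs.assemble_mme(data, spec, None, rel.Hinv, rel.animals)
        basis = one.basis
        doubled = rnm_gibbs.assemble_mme(
            pd.concat([data, data]), spec, basis, rel.Hinv, rel.animals)
        np.testing.assert_allclose(doubled.rhs(), 2 * one.rhs())

    def test_single_record_additive_only(self):
        ped = pd.DataFrame({"animal": [1], "sire": [0], "dam": [0]})
        rel = relmat.build_relationships(ped)
        data = pd.DataFrame([{"record_id": 1, "animal": 1, "litter": 1,
                              "env_value": 5.0, "value": 3.0}])
        spec = rnm_gibbs.ModelSpec(fixed=(), random=("a",))
        basis = build_gradient([0.0, 10.0])
        system = rnm_gibbs.assemble_mme(data, spec, basis, rel.Hinv, rel.animals)
        # intercept, fixed regression, plus one (a0, a1) pair
        assert system.n_coef == 4 and system.n_fixed == 2

    def test_rank_deficiency_names_columns(self):
        ped, data = _toy_data(n_animals=4)
        data["dup"] = data["cg"]   # perfectly confounded factor
        rel = relmat.build_relationships(ped)
        spec = rnm_gibbs.ModelSpec(fixed=("cg", "dup"), random=("a",))
        with pytest.raises(ValueError, match="confounded columns.*(dup|cg)"):
            rnm_gibbs.assemble_mme(data, spec, None, rel.Hinv, rel.animals)

    def test_record_order_does_not_change_system(self):
        ped, data = _toy_data(n_animals=6, records_per_animal=3)
        rel = relmat.build_relationships(ped)
        spec = rnm_gibbs.ModelSpec(fixed=("cg",), random=("a", "pe", "ce"))
        a = rnm_gibbs.assemble_mme(data, spec, None, rel.Hinv, rel.animals)
        shuffled = data.sample(frac=1.0, random_state=3)
        b = rnm_gibbs.assemble_mme(shuffled, spec, None, rel.Hinv, rel.animals)
        assert (a.W != b.W).nnz == 0
        np.testing.assert_array_equal(a.y, b.y)


class TestChainConfig:
    def test_retained_count(self):
        chain = rnm_gibbs.ChainConfig(n_iter=5000, burn_in=2000, thin=10)
        assert chain.n_retained == 300

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            rnm_gibbs.ChainConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            rnm_gibbs.ChainConfig(thin=0)

    def test_presets(self):
        full = rnm_gibbs.ChainConfig.preset("full")
        assert (full.n_iter, full.burn_in, full.thin) == (600_000, 300_000, 60)
        assert rnm_gibbs.ChainConfig.preset("full-ibf").n_iter == 900_000


def _fit_small(seed=1, g0a=None, n_iter=1500, burn=500, random=("a",)):
    g0a = np.array([[1.0, 0.3], [0.3, 0.5]]) if g0a is None else g0a
    cfg = simdata.SimConfig(
        n_founders=200, n_generations=2, dams_per_generation=100,
        litter_size_mean=1.5, records_per_sow=3, seed=seed,
        true_G0_a=g0a, true_G0_pe=np.zeros((2, 2)), true_G0_ce=np.zeros((2, 2)),
        sigma2_e=1.0)
    ped = simdata.simulate_pedigree(cfg)
    records = simdata.make_records(ped, cfg, record_all_females=True)
    rng = np.random.default_rng(seed + 99)
    env = pd.DataFrame({"record_id": records["record_id"], "env": "MaxT",
                        "value": rng.uniform(5, 30, len(records))})
    pheno, _ = simdata.simulate_phenotypes(ped, env, cfg, records=records)
    rel = relmat.build_relationships(ped)
    spec = rnm_gibbs.ModelSpec(fixed=("cg", "parity"), random=random)
    system = rnm_gibbs.assemble_mme(pheno, spec, None, rel.Hinv, rel.animals)
    chain = rnm_gibbs.ChainConfig(n_iter=n_iter, burn_in=burn, thin=5, seed=seed)
    return rnm_gibbs.gibbs_sample(system, chain)


class TestGibbs:
    def test_same_seed_identical_chains(self):
        a = _fit_small(seed=4, n_iter=400, burn=100)
        b = _fit_small(seed=4, n_iter=400, burn=100)
        np.testing.assert_array_equal(a.sigma2_e, b.sigma2_e)
        np.testing.assert_array_equal(a.g0["a"], b.g0["a"])
        np.testing.assert_array_equal(a.coef_mean, b.coef_mean)

    def test_retained_count_when_thin_does_not_divide(self):
        # (400 - 150) / 4 is not integral: exactly floor() draws are kept
        s = _fit_small(seed=3, n_iter=400, burn=150)
        assert s.n_retained == s.chain.n_retained == (400 - 150) // 5

    def test_sampled_covariances_positive_definite(self):
        s = _fit_small(seed=5, n_iter=600, burn=200)
        for g in s.g0["a"]:
            assert np.linalg.eigvalsh(g).min() > 0
        assert (s.sigma2_e > 0).all()
        assert s.n_retained == s.chain.n_retained

    def test_zero_slope_variance_shrinks_posterior_slope(self):
        g0a = np.array([[1.0, 0.0], [0.0, 0.0]])
        s = _fit_small(seed=6, g0a=g0a, n_iter=2000, burn=800)
        tab = s.component_table()
        assert tab["var_a1"].mean() < 0.1 * tab["var_a0"].mean()

    def test_intercept_only_sigma2e_matches_reml(self):
        # no random effects: REML of sigma2_e is RSS / (n - p)
        rng = np.random.default_rng(11)
        n = 200
        data = pd.DataFrame({
            "record_id": range(n), "animal": 1, "litter": 1,
            "cg": np.repeat(["a", "b"], n // 2),
            "env_value": rng.uniform(0, 1, n),
            "value": rng.normal(10, 2, n),
        })
        ped = pd.DataFrame({"animal": [1], "sire": [0], "dam": [0]})
        rel = relmat.build_relationships(ped)
        spec = rnm_gibbs.ModelSpec(fixed=("cg",), random=())
        system = rnm_gibbs.assemble_mme(data, spec, None, rel.Hinv, rel.animals)
        chain = rnm_gibbs.ChainConfig(n_iter=4000, burn_in=500, thin=1, seed=2)
        s = rnm_gibbs.gibbs_sample(system, chain)
        X = system.W.toarray()[:, :system.n_fixed]
        beta = np.linalg.lstsq(X, system.y, rcond=None)[0]
        rss = float(np.sum((system.y - X @ beta) ** 2))
        reml = rss / (n - system.n_fixed)
        mc_se = s.sigma2_e.std(ddof=1) / np.sqrt(50)  # generous ESS discount
        assert abs(s.sigma2_e.mean() - reml) < 3 * max(mc_se, 0.02)


class TestSummaries:
    def _samples(self):
        g0 = {"a": np.array([np.diag([1.0, 1.0]), np.diag([2.0, 2.0]),
                             np.diag([3.0, 3.0])])}
        ped = pd.DataFrame({"animal": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2]})
        rel = relmat.build_relationships(ped)
        data = pd.DataFrame({
            "record_id": [1, 2, 3], "animal": [1, 2, 3], "litter": [1, 2, 3],
            "env_value": [0.0, 5.0, 10.0], "value": [1.0, 2.0, 3.0],
        })
        spec = rnm_gibbs.ModelSpec(fixed=(), random=("a",))
        system = rnm_gibbs.assemble_mme(data, spec, None, rel.Hinv, rel.animals)
        chain = rnm_gibbs.ChainConfig(n_iter=40, burn_in=10, thin=1, seed=1)
        return rnm_gibbs.PosteriorSamples(
            g0=g0, sigma2_e=np.array([1.0, 2.0, 3.0]),
            coef_mean=np.zeros(system.n_coef), coef_sd=np.zeros(system.n_coef),
            system=system, chain=chain), ped

    def test_hand_arithmetic_mean_and_sd(self):
        samples, ped = self._samples()
        vc, gebv = rnm_gibbs.summarize_posterior(samples, min_retained=3)
        assert vc.sigma2_e == pytest.approx(2.0)
        assert vc.sigma2_e_sd == pytest.approx(1.0)
        assert vc.mean["a"][0, 0] == pytest.approx(2.0)
        assert len(gebv) == 3   # one row per pedigree animal

    def test_constant_chain_gives_zero_sd(self):
        samples, _ = self._samples()
        samples = rnm_gibbs.PosteriorSamples(
            g0={"a": np.repeat(samples.g0["a"][:1], 3, axis=0)},
            sigma2_e=np.full(3, 1.5), coef_mean=samples.coef_mean,
            coef_sd=samples.coef_sd, system=samples.system, chain=samples.chain)
        vc, _ = rnm_gibbs.summarize_posterior(samples, min_retained=3)
        assert vc.sigma2_e_sd == 0.0 and vc.sd["a"][0, 0] == 0.0

    def test_summary_matches_independent_two_pass(self):
        s = _fit_small(seed=9, n_iter=500, burn=200)
        vc, _ = rnm_gibbs.summarize_posterior(s, min_retained=10)
        tab = s.component_table()
        assert vc.mean["a"][1, 1] == pytest.approx(tab["var_a1"].mean())
        assert vc.sd["a"][0, 0] == pytest.approx(tab["var_a0"].std(ddof=1))

    def test_offspring_counts_from_pedigree(self):
        samples, ped = self._samples()
        _, gebv = rnm_gibbs.summarize_posterior(samples, pedigree=ped, min_retained=3)
        counts = gebv.set_index("animal")["n_offspring"]
        assert counts.loc[1] == 1 and counts.loc[2] == 1 and counts.loc[3] == 0

    def test_too_few_samples_is_error(self):
        samples, _ = self._samples()
        with pytest.raises(ValueError, match="retained"):
            rnm_gibbs.summarize_posterior(samples, min_retained=50)


class TestConvergenceDiagnostics:
    def test_iid_chain_rarely_flagged(self):
        rng = np.random.default_rng(31)
        flags = 0
        for _ in range(100):
            z = rng.standard_normal(1000)
            rep = rnm_gibbs.convergence_check(pd.DataFrame({"x": z}))
            flags += int(abs(rep["geweke_z"].iloc[0]) > 2)
        assert flags <= 5

    def test_trending_chain_flagged(self):
        chain = np.linspace(0.0, 5.0, 1000) + np.random.default_rng(1).normal(0, 0.1, 1000)
        rep = rnm_gibbs.convergence_check(pd.DataFrame({"x": chain}))
        assert bool(rep["flagged"].iloc[0])

    def test_iid_ess_close_to_length(self):
        rng = np.random.default_rng(7)
        rep = rnm_gibbs.convergence_check(pd.DataFrame({"x": rng.standard_normal(1000)}))
        assert rep["ess"].iloc[0] == pytest.approx(1000, rel=0.2)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match="retained"):
            rnm_gibbs.convergence_check(pd.DataFrame({"x": np.arange(10.0)}))
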