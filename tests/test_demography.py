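"""Joint AFS container, Monte-Carlo expected spectra, composite likelihood,
model selection, unit conversion and the ABC cross-check."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

from spinypop.demography import (
    MODEL_SPECS,
    STUDY_MODELS,
    ConversionSpec,
    FitResult,
    JointAFS,
    abc_model_choice,
    afs_from_matrix,
    branch_joint_afs,
    build_demography,
    expected_afs,
    from_biological_units,
    loglik,
    model_select,
    residual_spectrum,
    summary_stats,
    to_biological_units,
)
from spinypop.genotype_io import GenotypeMatrix
from spinypop.synthetic_data import panmictic_demography, simulate_genotypes


class TestJointAfs:
    def test_corners_always_masked(self):
        afs = JointAFS(np.ones((5, 5)), (4, 4))
        assert afs.mask[0, 0] and afs.mask[4, 4]
        assert afs.total() == 25 - 2

    def test_fold_conserves_total(self, rng):
        data = rng.uniform(0, 10, (9, 7))
        afs = JointAFS(data, (8, 6))
        folded = afs.fold()
        assert folded.folded
        assert folded.total() == pytest.approx(afs.total())

    def test_fold_idempotent(self, rng):
        afs = JointAFS(rng.uniform(0, 1, (5, 5)), (4, 4)).fold()
        assert afs.fold() is afs

    def test_projection_identity(self, rng):
        afs = JointAFS(rng.uniform(0, 1, (7, 7)), (6, 6))
        proj = afs.project((6, 6))
        assert proj.data[proj.unmasked] == pytest.approx(afs.data[afs.unmasked])

    def test_projection_conserves_interior_mass(self, rng):
        # projection moves mass to the masked corners only
        data = np.zeros((9, 9))
        data[3, 4] = 100.0
        afs = JointAFS(data, (8, 8))
        proj = afs.project((4, 4))
        assert proj.data.sum() == pytest.approx(100.0)

    def test_text_round_trip(self, tmp_path, rng):
        afs = JointAFS(rng.uniform(0, 5, (5, 7)), (4, 6)).fold()
        path = tmp_path / "afs.txt"
        afs.to_text(path)
        back = JointAFS.from_text(path)
        assert back.sample_sizes == afs.sample_sizes
        assert back.folded
        assert back.data == pytest.approx(afs.data)
        assert (back.mask == afs.mask).all()


class TestAfsFromMatrix:
    def test_fixed_difference_lands_in_corner_cell(self):
        calls = np.vstack([np.zeros((4, 1)), np.full((4, 1), 2)]).astype(np.int16)
        ids = [f"i{k}" for k in range(8)]
        m = GenotypeMatrix(ids, ["L"], calls,
                           {ids[k]: ("a" if k < 4 else "b") for k in range(8)})
        afs = afs_from_matrix(m, "a", "b", (4, 4))
        # folded: all mass at (4,0)/(0,4); the fold splits the diagonal pair
        assert afs.data[4, 0] + afs.data[0, 4] == pytest.approx(1.0)
        assert afs.total() == pytest.approx(1.0)

    def test_projection_matches_subsample_enumeration(self, rng):
        # brute-force oracle: average the folded spectrum over every way of
        # choosing 2 of 3 individuals per population (gene-copy subsets
        # follow the same hypergeometric law locus-by-locus)
        from itertools import combinations
        n = 3
        calls = rng.binomial(2, rng.uniform(0.2, 0.8, 50), size=(2 * n, 50)).astype(np.int16)
        ids = [f"i{k}" for k in range(2 * n)]
        pops = {ids[k]: ("a" if k < n else "b") for k in range(2 * n)}
        m = GenotypeMatrix(ids, [f"L{j}" for j in range(50)], calls, pops)
        target = afs_from_matrix(m, "a", "b", (4, 4))
        # oracle at the gene-copy level: enumerate C(6,4) subsets per pop
        import itertools
        acc = np.zeros((5, 5))
        for j in range(50):
            copies_a = [c for k in range(n) for c in ([1] * calls[k, j] + [0] * (2 - calls[k, j]))]
            copies_b = [c for k in range(n, 2 * n) for c in ([1] * calls[k, j] + [0] * (2 - calls[k, j]))]
            cell = np.zeros((5, 5))
            combos = list(itertools.combinations(range(6), 4))
            for sa in combos:
                for sb in combos:
                    i = sum(copies_a[x] for x in sa)
                    jj = sum(copies_b[x] for x in sb)
                    cell[i, jj] += 1
            acc += cell / len(combos) ** 2
        oracle = JointAFS(acc, (4, 4)).fold()
        assert target.data[target.unmasked] == pytest.approx(
            oracle.data[oracle.unmasked], abs=1e-10)

    def test_insufficient_copies_dropped_and_counted(self):
        from spinypop.genotype_io import MISSING
        calls = np.array([[1, MISSING], [1, MISSING], [0, 1], [2, 1]],
                         dtype=np.int16)
        ids = list("abcd")
        m = GenotypeMatrix(ids, ["L1", "L2"], calls,
                           {"a": "x", "b": "x", "c": "y", "d": "y"})
        afs = afs_from_matrix(m, "x", "y", (4, 4))
        assert afs.n_dropped == 1
        assert afs.total() == pytest.approx(1.0)


class TestExpectedAfs:
    def test_constant_size_sfs_is_watterson(self):
        # unfolded single-population branch SFS: E[xi_i] = (theta/2) * 2/i
        sfs = branch_joint_afs(panmictic_demography(), (16,), 8000, seed=21,
                               population_names=("d0",))
        interior = sfs[1:-1]
        expected = 2.0 / np.arange(1, 16)
        z = (interior - expected) / expected
        assert np.abs(z).max() < 0.10
        assert interior * np.arange(1, 16) == pytest.approx(
            np.full(15, 2.0), rel=0.1)

    def test_vanishing_split_is_panmixia(self):
        # T1 -> 0 with nu1 = nu2 = 0.5: indistinguishable from one population
        afs = expected_afs("S_nomig", dict(nu1=0.5, nu2=0.5, T1=1e-4),
                           (10, 10), n_replicates=4000, seed=22, folded=False)
        pan = branch_joint_afs(panmictic_demography(1.0), (20,), 4000, seed=23,
                               population_names=("d0",))
        # marginal over both populations should match the pooled SFS
        joint = afs.data
        marg = np.array([joint.diagonal(offset=k - 10).sum()
                         if False else 0 for k in range(21)])
        marg = np.zeros(21)
        for i in range(11):
            for j in range(11):
                marg[i + j] += joint[i, j]
        ratio = marg[1:-1] / pan[1:-1]
        assert np.abs(ratio - 1).mean() < 0.1

    def test_deep_isolation_mass_is_private(self):
        afs = expected_afs("S_nomig", dict(nu1=1, nu2=1, T1=5.0), (10, 10),
                           n_replicates=3000, seed=24, folded=False)
        d = afs.data.copy()
        total = d[afs.unmasked].sum()
        private = d[1:, 0].sum() + d[0, 1:].sum() + d[10, :-1].sum() + d[:-1, 10].sum()
        assert private / total > 0.95

    def test_t1_le_t2_rejected(self):
        with pytest.raises(ValueError, match="T1 > T2"):
            build_demography("S_nomig_secont",
                             dict(nu1=1, nu2=1, m12=1, m21=1, T1=0.5, T2=0.6))

    def test_simulated_genotypes_match_expected_spectrum(self):
        # the two engines cross-validate: data AFS from the genotype
        # simulator vs branch-mode expectation, chi-square on coarse groups
        params = dict(nu1=1.0, nu2=0.5, T1=1.0)
        m = simulate_genotypes("S_nomig", params, n_per_pop=8, n_loci=2500,
                               seed=25)
        data = afs_from_matrix(m, "p1", "p2", (16, 16))
        model = expected_afs("S_nomig", params, (16, 16),
                             n_replicates=12000, seed=26)
        ll_fit, theta = loglik(data, model, coarsen=True)
        um = data.unmasked & model.unmasked
        exp = theta * model.data
        obs = data.data
        from spinypop.demography import _group_cells
        gids = _group_cells(data)
        gids[~um] = -1
        chisq = 0.0
        dof = 0
        for k in np.unique(gids[gids >= 0]):
            e = exp[gids == k].sum()
            o = obs[gids == k].sum()
            if e > 5:
                chisq += (o - e) ** 2 / e
                dof += 1
        from scipy.stats import chi2
        assert chi2.sf(chisq, dof - 1) > 1e-3


class TestLoglik:
    def test_two_by_two_closed_form(self):
        data = JointAFS(np.array([[0, 3.0], [2.0, 0]]), (1, 1))
        model = JointAFS(np.array([[0, 1.5], [0.5, 0]]), (1, 1))
        ll, theta = loglik(data, model)
        assert theta == pytest.approx(5 / 2)
        mu1, mu2 = theta * 1.5, theta * 0.5
        expected = (3 * math.log(mu1) - mu1 - math.lgamma(4)
                    + 2 * math.log(mu2) - mu2 - math.lgamma(3))
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_proportional_model_maximizes_over_rescaling(self, rng):
        d = rng.uniform(0.5, 5, (6, 6))
        data = JointAFS(d, (5, 5))
        model = JointAFS(d * 3.7, (5, 5))
        ll_star, theta = loglik(data, model)
        assert theta == pytest.approx(1 / 3.7)
        for scale in (0.5, 0.9, 1.1, 2.0):
            scaled = JointAFS(d * 3.7 * scale, (5, 5))
            mu = (1 / 3.7 / scale) * scaled.data[scaled.unmasked] * scale
            ll = float((data.data[data.unmasked] * np.log(mu) - mu
                        - gammaln(data.data[data.unmasked] + 1)).sum())
            assert ll <= ll_star + 1e-9

    def test_masked_cells_ignored(self, rng):
        d = rng.uniform(0.5, 5, (5, 5))
        data = JointAFS(d.copy(), (4, 4))
        model = JointAFS(rng.uniform(0.5, 5, (5, 5)), (4, 4))
        ll1, _ = loglik(data, model)
        d2 = d.copy()
        d2[0, 0] = 999.0
        d2[4, 4] = 123.0
        ll2, _ = loglik(JointAFS(d2, (4, 4)), model)
        assert ll1 == pytest.approx(ll2)

    def test_incompatible_shapes_rejected(self):
        a = JointAFS(np.ones((3, 3)), (2, 2))
        b = JointAFS(np.ones((4, 4)), (3, 3))
        with pytest.raises(ValueError):
            loglik(a, b)


class TestFitModel:
    def test_single_parameter_split_time_recovered(self):
        # SNM_split has one free parameter, so the fit is cheap and sharp
        from spinypop.demography import fit_model
        m = simulate_genotypes("SNM_split", dict(T1=1.0), n_per_pop=12,
                               n_loci=1500, seed=61)
        data = afs_from_matrix(m, "p1", "p2", (16, 16))
        fit = fit_model(data, "SNM_split", seed=62, n_grid=10, n_starts=2,
                        n_polish=1, maxiter=30, n_replicates=200,
                        polish_replicates=600, report_replicates=2500)
        assert fit.params["T1"] == pytest.approx(1.0, rel=0.25)
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik)

    def test_aic_prefers_generating_model(self):
        # isolation data: the nested migration model gains < 2 units of
        # log-likelihood, so its 2-parameter penalty loses the AIC race
        from spinypop.demography import fit_model, model_select
        m = simulate_genotypes("S_nomig", dict(nu1=1.0, nu2=0.6, T1=1.2),
                               n_per_pop=10, n_loci=1200, seed=63)
        data = afs_from_matrix(m, "p1", "p2", (16, 16))
        fits = [fit_model(data, name, seed=64, n_grid=12, n_starts=2,
                          n_polish=1, maxiter=35, n_replicates=200,
                          polish_replicates=600, report_replicates=2500)
                for name in ("S_nomig", "S_asymig")]
        ranked = model_select(fits)
        assert ranked[0]["fit"].model == "S_nomig"


class TestModelSelect:
    def _fit(self, name, k_params, ll, fp="abc"):
        spec = MODEL_SPECS[name]
        return FitResult(model=name, params={}, loglik=ll,
                         aic=2 * k_params - 2 * ll, theta_hat=1.0,
                         converged=True, data_fingerprint=fp)

    def test_equal_loglik_smaller_k_wins(self):
        a = self._fit("S_nomig_secont", 6, -100.0)
        b = self._fit("secont_asymig_size", 8, -100.0)
        ranked = model_select([a, b])
        assert ranked[0]["fit"].model == "S_nomig_secont"
        assert ranked[1]["delta_aic"] == pytest.approx(4.0)

    def test_small_loglik_gain_does_not_justify_k(self):
        a = self._fit("S_nomig", 3, -100.0)        # aic = 206
        b = self._fit("S_asymig_size", 7, -98.0)   # aic = 210
        ranked = model_select([a, b])
        assert ranked[0]["fit"].model == "S_nomig"
        assert ranked[1]["delta_aic"] == pytest.approx(4.0)

    def test_single_fit_weight_one(self):
        ranked = model_select([self._fit("SNM_split", 1, -5.0)])
        assert ranked[0]["akaike_weight"] == pytest.approx(1.0)

    def test_mixed_data_fingerprints_rejected(self):
        with pytest.raises(ValueError):
            model_select([self._fit("S_nomig", 3, -1.0, fp="a"),
                          self._fit("S_asymig", 5, -1.0, fp="b")])

    def test_residual_spectrum_masks_nan(self, rng):
        d = rng.uniform(1, 10, (5, 5))
        data = JointAFS(d, (4, 4))
        model = JointAFS(d * 2, (4, 4))
        res = residual_spectrum(data, model)
        assert np.isnan(res[0, 0]) and np.isnan(res[4, 4])
        assert np.nanmax(np.abs(res)) < 1e-6  # proportional model: no residual


class TestUnits:
    def test_nref_unit_check(self):
        conv = ConversionSpec(mu=8e-8, generation_time=5.0, L=1000.0)
        out = to_biological_units({"theta": 4 * 8e-8 * 1000.0}, conv)
        assert out["N_ref"] == pytest.approx(1.0)

    def test_round_trip_inverse(self):
        conv = ConversionSpec(mu=8e-8, generation_time=7.0, L=5e5)
        params = dict(theta=481.0, nu1=0.26, nu2=0.10, m12=2.15, m21=22.39,
                      T1=14.91, T2=0.148)
        rep = to_biological_units(params, conv)
        back = from_biological_units(rep, conv)
        for k in ("theta", "T1", "T2", "m12", "m21"):
            assert back[k] == pytest.approx(params[k], abs=1e-10)

    def test_default_mutation_rate(self):
        assert ConversionSpec().mu == 8e-8

    def test_migrants_per_generation(self):
        conv = ConversionSpec(mu=1e-8, generation_time=1.0, L=1e4)
        out = to_biological_units(dict(theta=4.0, nu1=0.5, m12=3.0), conv)
        assert out["m12_migrants_per_generation"] == pytest.approx(3.0 * 0.5 / 2)


class TestAbc:
    def test_identical_candidates_split_posterior(self):
        m = simulate_genotypes("S_nomig", dict(nu1=1, nu2=1, T1=0.8),
                               n_per_pop=8, n_loci=150, seed=31)
        obs = summary_stats(m, "p1", "p2")
        priors = {"nu": (0.3, 3.0), "T": (0.1, 3.0), "m": (0.1, 10.0)}
        res = abc_model_choice(obs, ["S_nomig", "S_nomig"], priors,
                               n_sims_per_model=120, tolerance=0.2, seed=32,
                               n_loci=80, n_per_pop=6)
        assert res["posterior"]["S_nomig"] == 1.0  # same name pools both

    def test_generating_model_preferred(self):
        # secondary contact vs strict isolation: strong recent migration
        # leaves shared polymorphism isolation cannot mimic
        gen = dict(nu1=1.0, nu2=1.0, m12=5.0, m21=5.0, T1=2.0, T2=0.4)
        m = simulate_genotypes("S_nomig_secont", gen, n_per_pop=8,
                               n_loci=200, seed=33)
        obs = summary_stats(m, "p1", "p2")
        priors = {"nu": (0.3, 3.0), "T": (0.3, 8.0), "m": (0.5, 20.0)}
        wins = 0
        for rep in range(3):
            res = abc_model_choice(obs, ["S_nomig", "S_nomig_secont"], priors,
                                   n_sims_per_model=100, tolerance=0.1,
                                   seed=100 + rep, n_loci=60, n_per_pop=5)
            wins += res["posterior"]["S_nomig_secont"] > 0.5
        assert wins >= 2

    def test_default_sims_match_protocol(self):
        import inspect
        sig = inspect.signature(abc_model_choice)
        assert sig.parameters["n_sims_per_model"].default == 1_000_000
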