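import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, spearmanr

import segmorph as sm
from segmorph.exceptions import DataError, InvalidArgumentError
from segmorph.phylo import (
    Priors,
    SegmentEvolutionModel,
    bm_loglik,
    branch_changes,
    marginal_likelihood,
    segment_rate_correlations,
)
from segmorph.ratemodel import BranchRateModel
from segmorph.trees import Phylogeny

from conftest import spawn_seeds


def _brute_force_loglik(tree, x, sigma2, rates, root):
    C = tree.shared_path_matrix(rates=rates)
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    p = x.shape[1]
    sigma2 = np.atleast_2d(sigma2)
    V = np.kron(C, sigma2)
    if isinstance(root, str):
        # flat-prior root integration of the full MVN
        Z = np.kron(np.ones((tree.n_tips, 1)), np.eye(p))
        Vi = np.linalg.inv(V)
        A = Z.T @ Vi @ Z
        mu = np.linalg.solve(A, Z.T @ Vi @ x.ravel())
        r = x.ravel() - Z @ mu
        n = x.size
        return -0.5 * ((n - p) * np.log(2 * np.pi) + np.linalg.slogdet(V)[1]
                       + np.linalg.slogdet(A)[1] + r @ Vi @ r)
    mean = np.tile(np.atleast_1d(root), tree.n_tips)
    return multivariate_normal.logpdf(x.ravel(), mean=mean, cov=V)


class TestBmLoglik:
    def test_single_tip_standard_normal(self):
        # one tip below a unary root, sigma2 * t * r = 1, data at the root value
        tree = Phylogeny([1, -1], [1.0, 0.0], ["a"])
        ll = bm_loglik(tree, np.array([0.5]), 1.0, rates=np.array([1.0]), root=np.array([0.5]))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_rate_sigma_confounding_identity(self, tree12):
        rng = np.random.default_rng(0)
        x = rng.normal(0.5, 0.1, (12, 8))
        S = np.diag(rng.uniform(0.005, 0.02, 8))
        a = bm_loglik(tree12, x, S, rates=np.full(22, 2.0))
        b = bm_loglik(tree12, x, 2 * S, rates=None)
        assert a == pytest.approx(b, abs=1e-10)

    @pytest.mark.parametrize("root_mode", ["integrated", "fixed"])
    def test_pruning_equals_brute_force(self, root_mode):
        rng = np.random.default_rng(31)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            while True:
                tree = sm.simulate_tree(n, seed=int(rng.integers(2**31)))
                if tree.branch_length[tree.branch_nodes].min() >= 1e-3:
                    break
            rates = np.exp(rng.normal(0, 0.6, tree.n_branches))
            s2 = float(np.exp(rng.normal(np.log(0.01), 0.7)))
            x = rng.normal(0.5, 0.1, n)
            root = "integrated" if root_mode == "integrated" else np.array([0.5])
            ll_p = bm_loglik(tree, x, s2, rates=rates, root=root)
            ll_b = _brute_force_loglik(tree, x, s2, rates, root)
            assert ll_p == pytest.approx(ll_b, abs=1e-8)

    def test_missing_species_listed(self, tree12):
        df = pd.DataFrame(np.full((10, 2), 0.5), index=tree12.tip_labels[:10], columns=["A1", "A2"])
        with pytest.raises(DataError, match=tree12.tip_labels[11]):
            bm_loglik(tree12, df, np.eye(2) * 0.01)


class TestFit:
    def test_single_iteration_posterior(self, tree12):
        rng = np.random.default_rng(0)
        x = rng.normal(0.5, 0.05, (12, 2))
        res = SegmentEvolutionModel(tree12, x, rate_model=BranchRateModel("strict")).fit(n_iter=1, thin=1, seed=0)
        assert res.n_samples == 1
        assert (res.samples["sigma2"] > 0).all()
        assert res.samples["node_states"].shape == (1, 23, 2)

    def test_rates_positive_and_centred(self, tree12):
        hist = sm.evolve_traits(tree12, np.eye(2) * 0.01, sm.BranchRateModel("ucln", s_r=0.6),
                                root_state=[0.4, 0.6], seed=1)
        res = SegmentEvolutionModel(tree12, hist.tip_states, rate_model=BranchRateModel("ucln")).fit(
            n_iter=800, thin=4, seed=2
        )
        r = res.samples["rates"]
        assert (r > 0).all()
        # the UCLN identifiability constraint: mean log-rate is exactly zero
        assert np.abs(np.log(r).mean(axis=1)).max() < 1e-9

    def test_low_ess_warned(self, tree12):
        rng = np.random.default_rng(0)
        x = rng.normal(0.5, 0.05, (12, 1))
        res = SegmentEvolutionModel(tree12, x, rate_model=BranchRateModel("ucln")).fit(n_iter=200, thin=2, seed=0)
        assert any("effective sample size" in w for w in res.warnings)

    def test_summary_table_shape(self, tree12):
        rng = np.random.default_rng(0)
        x = rng.normal(0.5, 0.05, (12, 2))
        res = SegmentEvolutionModel(tree12, x, rate_model=BranchRateModel("ucln")).fit(n_iter=400, thin=4, seed=0)
        s = res.summary()
        assert {"mean", "sd", "ci95_low", "ci95_high", "ess"} <= set(s.columns)
        assert "sigma2[trait1]" in s.index
        assert "s_r" in s.index


class TestAncestralStates:
    def test_near_zero_rate_collapses_to_tip_value(self, tree12):
        x = np.full((12, 1), 0.47)
        model = SegmentEvolutionModel(tree12, x, rate_model=BranchRateModel("strict"),
                                      priors=Priors(sigma2_log10_median=-8.0, sigma2_log10_sd=0.3))
        res = model.fit(n_iter=600, thin=3, seed=0)
        anc = res.ancestral_states()
        assert np.abs(anc["mean"] - 0.47).max() < 1e-3

    def test_two_tip_root_is_midpoint(self):
        tree = sm.simulate_tree(2, seed=0)
        x = np.array([[0.40], [0.60]])
        res = SegmentEvolutionModel(tree, x, rate_model=BranchRateModel("strict")).fit(
            n_iter=6000, thin=3, seed=1
        )
        anc = res.ancestral_states()
        root_mean = anc[(anc.label == "root")]["mean"].iloc[0]
        assert root_mean == pytest.approx(0.50, abs=0.02)

    def test_ci_widens_away_from_tips(self, tree12):
        hist = sm.evolve_traits(tree12, np.array([[0.01]]), root_state=[0.5], seed=3)
        res = SegmentEvolutionModel(tree12, hist.tip_states, rate_model=BranchRateModel("strict")).fit(
            n_iter=2000, thin=4, seed=4
        )
        anc = res.ancestral_states()
        width = (anc["ci95_high"] - anc["ci95_low"]).to_numpy()
        depths = tree12.node_depths()
        internal = ~anc["is_tip"].to_numpy()
        # deeper nodes (farther from the tips) should on average carry wider CIs
        d = 1 - depths[anc["node"].to_numpy()[internal]]
        r = spearmanr(d, width[internal]).statistic
        assert r > 0


class TestBranchChanges:
    def test_definition_identities(self, tree12):
        hist = sm.evolve_traits(tree12, np.array([[0.01]]), root_state=[0.5], seed=5)
        res = SegmentEvolutionModel(tree12, hist.tip_states, rate_model=BranchRateModel("strict")).fit(
            n_iter=400, thin=4, seed=0
        )
        bc = res.branch_changes()
        assert (bc.per_branch["mean"] >= 0).all()
        assert (bc.pooled >= 0).all()
        # recompute one branch by hand from the samples
        v = int(res.model.branch_nodes[0])
        t_b = tree12.branch_length[v]
        manual = np.abs(res.samples["node_states"][:, v, 0]
                        - res.samples["node_states"][:, tree12.parent[v], 0]) / t_b
        got = bc.per_branch[(bc.per_branch.branch == v)]["mean"].iloc[0]
        assert got == pytest.approx(manual.mean())

    def test_child_equal_parent_gives_zero_and_length_scaling(self):
        tree = sm.simulate_tree(3, seed=0)
        x = np.full((3, 1), 0.5)
        res = SegmentEvolutionModel(tree, x, rate_model=BranchRateModel("strict"),
                                    priors=Priors(sigma2_log10_median=-9.0, sigma2_log10_sd=0.2)).fit(
            n_iter=300, thin=3, seed=0
        )
        # constant states: every normalised change is ~0
        assert res.branch_changes().pooled.max() < 1e-3
        # halving branch lengths doubles c_b for the same states
        half = Phylogeny(tree.parent, np.where(tree.parent >= 0, tree.branch_length / 2, 0.0), tree.tip_labels)
        doubled = branch_changes(res, half)
        orig = branch_changes(res, tree)
        assert np.allclose(doubled.pooled, 2 * orig.pooled)

    def test_hot_branch_detected(self):
        # normalised change scales like sqrt(rate / branch length), so the
        # rate signal is only comparable across branches of similar length:
        # use a balanced tree with near-equal branches
        nwk = ("(((a:0.34,b:0.34):0.33,(c:0.34,d:0.34):0.33):0.33,"
               "((e:0.34,f:0.34):0.33,(g:0.34,h:0.34):0.33):0.33);")
        tree = Phylogeny.from_newick(nwk)
        B = tree.n_branches
        hits = 0
        for k, s in enumerate(spawn_seeds(99, 10)):
            rates = np.ones(B)
            hot = k % B
            rates[hot] = 20.0
            # eight segments share the branch rates, as in the study; the
            # per-branch change averages over segments, beating the
            # realisation noise of any single trait
            hist = sm.evolve_traits(tree, np.eye(8) * 0.005, root_state=np.linspace(0.3, 0.8, 8),
                                    seed=s, branch_rates=rates)
            res = SegmentEvolutionModel(tree, hist.tip_states, rate_model=BranchRateModel("ucln")).fit(
                n_iter=1500, thin=5, burnin=0.2, seed=s
            )
            per = res.branch_changes().per_branch.groupby("branch")["mean"].mean()
            top2 = per.sort_values(ascending=False).index[:2]
            hits += int(res.model.branch_nodes[hot]) in list(top2)
        assert hits >= 9


class TestSegmentRateCorrelations:
    @pytest.fixture(scope="class")
    def two_fits(self, tree12):
        hist = sm.evolve_traits(tree12, np.array([[0.01]]), sm.BranchRateModel("ucln", s_r=0.8), seed=0)
        m = SegmentEvolutionModel(tree12, hist.tip_states, rate_model=BranchRateModel("ucln"))
        r1 = m.fit(n_iter=400, thin=4, seed=0)
        r2 = m.fit(n_iter=400, thin=4, seed=0)
        return r1, r2

    def test_identical_rate_vectors_give_unit_correlation(self, two_fits):
        r1, r2 = two_fits
        df = segment_rate_correlations([r1, r2], mean_positions=[0.3, 0.5])
        assert df["r"].iloc[0] == pytest.approx(1.0)
        assert df["distance"].iloc[0] == pytest.approx(0.2)

    def test_negated_log_rates_give_minus_one(self, two_fits):
        r1, r2 = two_fits
        import copy

        r3 = copy.copy(r2)
        r3.samples = dict(r2.samples)
        r3.samples["rates"] = 1.0 / r2.samples["rates"]  # negates the log
        df = segment_rate_correlations([r1, r3], mean_positions=[0.3, 0.5])
        assert df["r"].iloc[0] == pytest.approx(-1.0)

    def test_requires_two_posteriors(self, two_fits):
        with pytest.raises(InvalidArgumentError):
            segment_rate_correlations([two_fits[0]], mean_positions=[0.3])


class TestTraitCorrelations:
    def test_strong_pairwise_correlation_recovered(self, tree12):
        Sig = 0.02 * np.array([[1.0, 0.9], [0.9, 1.0]])
        hist = sm.evolve_traits(tree12, Sig, sm.BranchRateModel("strict"), root_state=[0.4, 0.6], seed=3)
        res = SegmentEvolutionModel(tree12, hist.tip_states, rate_model=BranchRateModel("strict"),
                                    correlations=True).fit(n_iter=4000, thin=4, burnin=0.2, seed=0)
        tc = res.trait_correlations()
        assert tc["mean_r"].iloc[0] > 0.6
        assert tc["ci95_low"].iloc[0] > 0.2

    def test_correlation_matrix_samples_valid(self, tree12):
        hist = sm.evolve_traits(tree12, np.eye(3) * 0.01, root_state=[0.3, 0.5, 0.7], seed=4)
        res = SegmentEvolutionModel(tree12, hist.tip_states, rate_model=BranchRateModel("ucln"),
                                    correlations=True).fit(n_iter=600, thin=3, burnin=0.2, seed=1)
        R = res.samples["correlations"]
        assert np.allclose(R, np.swapaxes(R, 1, 2))
        assert np.allclose(R[:, np.arange(3), np.arange(3)], 1.0)
        for k in range(0, len(R), 20):
            assert np.linalg.eigvalsh(R[k]).min() > 0

    def test_diagonal_fit_has_no_correlation_samples(self, tree12):
        rng = np.random.default_rng(0)
        res = SegmentEvolutionModel(tree12, rng.normal(0.5, 0.05, (12, 2)),
                                    rate_model=BranchRateModel("strict")).fit(n_iter=50, thin=5, seed=0)
        with pytest.raises(InvalidArgumentError):
            res.trait_correlations()

    def test_scalar_trait_rejected(self, tree12):
        rng = np.random.default_rng(0)
        with pytest.raises(InvalidArgumentError):
            SegmentEvolutionModel(tree12, rng.normal(0.5, 0.05, 12),
                                  rate_model=BranchRateModel("strict"), correlations=True)


class TestMarginalLikelihood:
    def test_two_seeds_agree_within_error(self, tree12):
        hist = sm.evolve_traits(tree12, np.array([[0.01]]), root_state=[0.5], seed=9)
        m1 = marginal_likelihood(tree12, hist.tip_states, model=BranchRateModel("strict"),
                                 n_stones=8, n_iter_per_stone=400, seed=1)
        m2 = marginal_likelihood(tree12, hist.tip_states, model=BranchRateModel("strict"),
                                 n_stones=8, n_iter_per_stone=400, seed=2)
        tol = 3 * np.hypot(m1.mc_error, m2.mc_error)
        assert abs(m1.log_marginal - m2.log_marginal) <= max(tol, 0.5)

    def test_single_stone_flagged_unreliable(self, tree12):
        hist = sm.evolve_traits(tree12, np.array([[0.01]]), root_state=[0.5], seed=9)
        ml = marginal_likelihood(tree12, hist.tip_states, model=BranchRateModel("strict"),
                                 n_stones=1, n_iter_per_stone=150, seed=0)
        assert any("unreliable" in f for f in ml.flags)
        assert np.isfinite(ml.log_marginal)

    def test_strict_data_prefers_strict_model(self, tree12):
        wins = 0
        for k, s in enumerate(spawn_seeds(55, 6)):
            hist = sm.evolve_traits(tree12, np.array([[0.01]]), root_state=[0.5], seed=s)
            ms = marginal_likelihood(tree12, hist.tip_states, model=BranchRateModel("strict"),
                                     n_stones=8, n_iter_per_stone=350, seed=k)
            mu = marginal_likelihood(tree12, hist.tip_states, model=BranchRateModel("ucln"),
                                     n_stones=8, n_iter_per_stone=350, seed=k)
            wins += ms.log_marginal > mu.log_marginal
        assert wins >= 3
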