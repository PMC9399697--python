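import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from locomorph import comparative as cp
from locomorph import synthetic, treeops


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the pruning implementation)

def brute_mk(tree, states, q, levels, marginal_node=None):
    """Sum over all internal-state assignments with explicit expm."""
    k = len(levels)
    Q = np.full((k, k), q)
    np.fill_diagonal(Q, -(k - 1) * q)
    nodes = list(tree.preorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    total = 0.0
    marg = np.zeros(k)
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        p = 1.0 / k  # flat root prior
        for n in nodes:
            if n.parent_node is None:
                continue
            P = expm(Q * (n.edge.length or 0.0))
            s_par = amap[n.parent_node]
            s_ch = amap[n] if n in amap else levels.index(states[n.taxon.label])
            p *= P[s_par, s_ch]
        total += p
        if marginal_node is not None:
            marg[assign[marginal_node]] += p
    if marginal_node is not None:
        return marg / marg.sum()
    return np.log(total)


SMALL_TREES = [
    "((A:1.2,B:0.7):0.5,(C:2.0,D:0.3):1.1);",
    "(((A:0.4,B:0.9):0.6,C:1.5):0.8,D:2.0);",
    "((A:1,B:1):1,(C:1,(D:1,E:1):0.5):0.7);",
]


class TestMkLikelihood:
    @pytest.mark.parametrize("newick", SMALL_TREES)
    @pytest.mark.parametrize("q", [0.05, 0.4, 1.5])
    def test_matches_enumeration_oracle(self, newick, q):
        tree = treeops.tree_from_newick(newick)
        tips = treeops.tip_labels(tree)
        levels = ["x", "y", "z"]
        states = pd.Series(
            {t: levels[i % 3] for i, t in enumerate(sorted(tips))}
        )
        mine = cp.mk_loglik(tree, states, q, levels)
        oracle = brute_mk(tree, states, q, levels)
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_stationary_limit_long_branches(self):
        k = 3
        tree = treeops.tree_from_newick("(A:1e6,B:1e6,C:1e6);")
        states = pd.Series({"A": "x", "B": "y", "C": "z"})
        lnL = cp.mk_loglik(tree, states, 1.0, ["x", "y", "z"])
        assert lnL == pytest.approx(3 * np.log(1 / k), abs=1e-6)

    def test_q_zero_monomorphic_gives_root_prior_only(self):
        tree = treeops.tree_from_newick("((A:1,B:1):1,C:2);")
        states = pd.Series({"A": "x", "B": "x", "C": "x"})
        lnL = cp.mk_loglik(tree, states, 1e-12, ["x", "y"])
        assert lnL == pytest.approx(np.log(0.5), abs=1e-6)

    def test_unknown_state_rejected(self):
        tree = treeops.tree_from_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="unknown state"):
            cp.mk_loglik(tree, pd.Series({"A": "x", "B": "w"}), 0.1, ["x", "y"])


class TestFitMk:
    def test_branch_length_rescaling_halves_rate(self):
        tree, _ = synthetic.sim_tree(n_species=60, seed=41)
        states = synthetic.sim_locomotion(tree, q=0.08, classes=("u", "v", "w"), seed=2)
        fit1 = cp.fit_mk(tree, states)
        doubled = tree.clone(depth=1)
        for e in doubled.preorder_edge_iter():
            if e.length is not None:
                e.length *= 2.0
        fit2 = cp.fit_mk(doubled, states)
        assert fit2.q == pytest.approx(fit1.q / 2.0, rel=1e-3)

    def test_estimate_is_a_local_optimum(self):
        tree, _ = synthetic.sim_tree(n_species=40, seed=42)
        states = synthetic.sim_locomotion(tree, q=0.05, classes=("u", "v"), seed=3)
        fit = cp.fit_mk(tree, states)
        lnL = lambda q: cp.mk_loglik(tree, states, q, fit.states)
        assert fit.loglik >= lnL(fit.q / 2) - 1e-8
        assert fit.loglik >= lnL(fit.q * 2) - 1e-8

    def test_monomorphic_tips_warn_and_pin_rate(self):
        tree = treeops.tree_from_newick("((A:1,B:1):1,C:2);")
        states = pd.Series({"A": "x", "B": "x", "C": "x"})
        with pytest.warns(UserWarning, match="share one state"):
            fit = cp.fit_mk(tree, states, ["x", "y"])
        assert fit.q <= 1e-8


class TestMarginalStates:
    @pytest.mark.parametrize("newick", SMALL_TREES[:2])
    def test_match_enumeration_oracle(self, newick):
        tree = treeops.tree_from_newick(newick)
        tips = treeops.tip_labels(tree)
        levels = ["x", "y"]
        states = pd.Series({t: levels[i % 2] for i, t in enumerate(sorted(tips))})
        model = cp.MkModel(levels, 0.3, 0.0, True)
        anc = cp.marginal_states(tree, states, model)
        internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        for idx in range(len(internals)):
            oracle = brute_mk(tree, states, 0.3, levels, marginal_node=idx)
            mine = anc.probabilities.iloc[idx].to_numpy()
            assert np.allclose(mine, oracle, atol=1e-10)

    def test_rows_sum_to_one(self):
        tree, _ = synthetic.sim_tree(n_species=25, seed=44)
        states = synthetic.sim_locomotion(tree, 0.05, ("u", "v", "w"), seed=5)
        model = cp.fit_mk(tree, states)
        anc = cp.marginal_states(tree, states, model)
        assert np.allclose(anc.probabilities.sum(axis=1), 1.0, atol=1e-12)

    def test_q_to_zero_with_monomorphic_tips_fixes_ancestors(self):
        tree = treeops.tree_from_newick("((A:1,B:1):1,C:2);")
        states = pd.Series({"A": "x", "B": "x", "C": "x"})
        model = cp.MkModel(["x", "y"], 1e-10, 0.0, True)
        anc = cp.marginal_states(tree, states, model)
        assert np.allclose(anc.probabilities["x"], 1.0, atol=1e-6)


class TestModelCov:
    def test_ou_limit_reproduces_bm(self):
        tree, _ = synthetic.sim_tree(n_species=12, seed=5)
        _, Vbm = cp.model_cov(tree, "BM", {"sigma2": 0.5, "z0": 0})
        _, Vou = cp.model_cov(tree, "OU", {"sigma2": 0.5, "z0": 0, "alpha": 1e-12})
        assert np.max(np.abs(Vou.values - Vbm.values)) / np.max(Vbm.values) < 1e-6

    def test_eb_limit_reproduces_bm(self):
        tree, _ = synthetic.sim_tree(n_species=12, seed=5)
        _, Vbm = cp.model_cov(tree, "BM", {"sigma2": 0.5, "z0": 0})
        _, Veb = cp.model_cov(tree, "EB", {"sigma2": 0.5, "z0": 0, "a": -1e-12})
        assert np.max(np.abs(Veb.values - Vbm.values)) / np.max(Vbm.values) < 1e-6

    def test_drift_shifts_means_by_depth(self):
        tree = treeops.tree_from_newick("((A:1,B:1):1,C:2);")
        mu, _ = cp.model_cov(tree, "drift", {"sigma2": 1, "z0": 3.0, "h": 0.5})
        assert np.allclose(mu, 3.0 + 0.5 * 2.0)

    def test_trend_positivity_enforced(self):
        tree = treeops.tree_from_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="positive"):
            cp.model_cov(tree, "trend", {"sigma2": 0.1, "z0": 0, "b": -0.2})

    @pytest.mark.parametrize(
        "model,params",
        [
            ("BM", {"sigma2": 0.3, "z0": 0}),
            ("OU", {"sigma2": 0.3, "z0": 0, "alpha": 0.2}),
            ("EB", {"sigma2": 0.3, "z0": 0, "a": -0.1}),
            ("trend", {"sigma2": 0.3, "z0": 0, "b": 0.05}),
            ("drift", {"sigma2": 0.3, "z0": 0, "h": 0.1}),
        ],
    )
    def test_covariances_positive_semidefinite(self, model, params):
        tree, _ = synthetic.sim_tree(n_species=20, seed=47, death=0.03)
        _, V = cp.model_cov(tree, model, params)
        assert np.linalg.eigvalsh(V.to_numpy()).min() > -1e-9

    def test_drift_unidentifiable_on_ultrametric_tree(self):
        """On an ultrametric tree all tips share the same depth, so the
        drift term is absorbed by the ancestral state: the profile
        likelihood is flat in h."""
        tree, _ = synthetic.sim_tree(n_species=16, seed=9, death=0.0)
        y = synthetic.sim_continuous(tree, "BM", {"sigma2": 0.02, "z0": 1.0}, seed=3)
        C = treeops.vcv_matrix(tree)
        depths = np.diag(C.to_numpy())
        lls = []
        for h in (-0.05, 0.0, 0.05):
            yv = y[C.index].to_numpy() - h * depths
            ll, _, _ = cp._gls_profile(C.to_numpy(), np.ones((16, 1)), yv)
            lls.append(ll)
        assert np.ptp(lls) < 1e-6


class TestFitContinuous:
    @pytest.fixture(scope="class")
    def fossil_tree(self):
        tree, _ = synthetic.sim_tree(n_species=16, seed=50, death=0.04)
        return tree

    def test_nested_models_dominate_bm_at_optimum(self, fossil_tree):
        y = synthetic.sim_continuous(fossil_tree, "BM", {"sigma2": 0.01, "z0": 1}, seed=8)
        fits = {m: cp.fit_continuous(fossil_tree, y, m) for m in cp.CONTINUOUS_MODELS}
        eps = 1e-6
        for m in ("OU", "EB", "trend", "drift"):
            assert fits[m].loglik >= fits["BM"].loglik - eps

    def test_drift_sign_recovery_on_fossil_trees(self):
        hits = 0
        reps = 20
        for rep in range(reps):
            tree, _ = synthetic.sim_tree(n_species=16, seed=700 + rep, death=0.04)
            y = synthetic.sim_continuous(
                tree, "drift", {"sigma2": 0.005, "z0": 1.0, "h": 0.02}, seed=rep
            )
            fit = cp.fit_continuous(tree, y, "drift")
            hits += fit.params["h"] > 0
        assert hits >= int(0.8 * reps)

    def test_missing_tip_value_rejected(self, fossil_tree):
        y = synthetic.sim_continuous(fossil_tree, "BM", {"sigma2": 0.01, "z0": 1}, seed=8)
        with pytest.raises(ValueError, match="without trait"):
            cp.fit_continuous(fossil_tree, y.iloc[:-1], "BM")


class TestAkaikeWeights:
    def _fit(self, model, aicc, h="abc"):
        return cp.TraitModelFit(model, {}, 0.0, 3, 16, aicc, aicc, data_hash=h)

    def test_equal_aicc_split_evenly(self):
        fits = cp.akaike_weights([self._fit("BM", 10.0), self._fit("OU", 10.0)])
        assert fits[0].weight == pytest.approx(0.5)

    def test_delta_two_closed_form(self):
        fits = cp.akaike_weights([self._fit("BM", 10.0), self._fit("OU", 12.0)])
        assert fits[0].weight == pytest.approx(1 / (1 + np.exp(-1)), abs=5e-4)
        assert fits[0].weight == pytest.approx(0.731, abs=1e-3)
        assert fits[1].weight == pytest.approx(0.269, abs=1e-3)

    def test_weights_sum_to_one(self):
        fits = cp.akaike_weights(
            [self._fit(m, 10.0 + i) for i, m in enumerate(cp.CONTINUOUS_MODELS)]
        )
        assert sum(f.weight for f in fits) == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError, match="different data"):
            cp.akaike_weights([self._fit("BM", 1.0, "aaa"), self._fit("OU", 2.0, "bbb")])


class TestAncestralContinuous:
    def test_two_tip_root_is_midpoint(self):
        tree = treeops.tree_from_newick("(A:1,B:1);")
        rec = cp.ancestral_continuous(tree, pd.Series({"A": 2.0, "B": 6.0}))
        assert rec.z0 == pytest.approx(4.0)
        assert rec.estimates.iloc[0] == pytest.approx(4.0)

    def test_constant_tips_reconstruct_constant(self):
        tree, _ = synthetic.sim_tree(n_species=10, seed=55)
        tips = treeops.tip_labels(tree)
        rec = cp.ancestral_continuous(tree, pd.Series(7.5, index=tips))
        assert np.allclose(rec.estimates, 7.5, atol=1e-8)

    def test_matches_direct_gls_oracle(self):
        """Conditional expectations agree with an explicit matrix-inversion
        computation done independently here."""
        tree, _ = synthetic.sim_tree(n_species=20, seed=56, death=0.05)
        tips = treeops.tip_labels(tree)
        y = synthetic.sim_continuous(tree, "BM", {"sigma2": 0.3, "z0": 2.0}, seed=1)
        rec = cp.ancestral_continuous(tree, y)

        depths = treeops.node_depths(tree)
        Ctt = treeops.vcv_matrix(tree, tips).to_numpy()
        Cinv = np.linalg.inv(Ctt)
        ones = np.ones(len(tips))
        yv = y[tips].to_numpy()
        z0 = (ones @ Cinv @ yv) / (ones @ Cinv @ ones)
        assert rec.z0 == pytest.approx(z0, abs=1e-8)

        tipsets = {}
        for node in tree.postorder_node_iter():
            tipsets[node] = (
                {node.taxon.label}
                if node.is_leaf()
                else set().union(*(tipsets[c] for c in node.child_nodes()))
            )
        internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        for i, node in enumerate(internals):
            cov = []
            for t in tips:
                anc = node
                while t not in tipsets[anc]:
                    anc = anc.parent_node
                cov.append(depths[anc])
            expect = z0 + np.array(cov) @ Cinv @ (yv - z0)
            assert rec.estimates.iloc[i] == pytest.approx(expect, abs=1e-8)

    def test_root_estimate_equals_gls_grand_mean(self, small_bundle):
        rec = cp.ancestral_continuous(small_bundle.tree, small_bundle.trait)
        assert rec.estimates.iloc[0] == pytest.approx(rec.z0, abs=1e-10)
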