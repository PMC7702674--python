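"""Tree handling, BM machinery, Mk/simmap, parsimony."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from skullroof.phylogeny import (BMParams, MkModel, NewickError,
                                 asr_continuous, branch_posterior,
                                 estimate_bm_ml, fit_lambda_ml, fit_mk,
                                 fitch_steps, lambda_transform, mk_loglik,
                                 parse_newick, phylo_vcv, prune_tree,
                                 retention_index, simmap_sample, simulate_bm,
                                 write_newick)

from conftest import random_tree, shared_path_bruteforce


def aligned_patristic(tree, labels):
    idx = tree.tip_index(labels)
    return tree.patristic()[np.ix_(idx, idx)]


class TestNewick:
    def test_parse_basic(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert sorted(t.tip_labels) == ["A", "B", "C"]
        ia = t.tip_index(["A"])[0]
        assert t.node_depths[ia] == pytest.approx(2.0)

    def test_roundtrip_preserves_patristic(self, rng):
        t = random_tree(99, rng)
        t2 = parse_newick(write_newick(t))
        labels = sorted(t.tip_labels)
        assert np.allclose(aligned_patristic(t, labels),
                           aligned_patristic(t2, labels), atol=1e-9)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(NewickError):
            parse_newick("((A:1,A:1):1,B:1);")

    def test_malformed_rejected(self):
        with pytest.raises(NewickError):
            parse_newick("((A:1,B:1):1;")

    def test_quoted_labels(self):
        t = parse_newick("('Homo sapiens':1,'B. tridactylus':2);")
        assert "Homo sapiens" in t.tip_labels
        t2 = parse_newick(write_newick(t))
        assert sorted(t2.tip_labels) == sorted(t.tip_labels)


class TestPrune:
    def test_patristic_preserved_small(self):
        t = parse_newick("(((A:1,B:1):1,(C:1,D:2):0.5):1,E:3);")
        pr = prune_tree(t, ["A", "D"])
        assert aligned_patristic(pr, ["A", "D"])[0, 1] == \
            pytest.approx(aligned_patristic(t, ["A", "D"])[0, 1])

    def test_prune_to_all_is_identity(self, rng):
        t = random_tree(12, rng)
        pr = prune_tree(t, t.tip_labels)
        labels = sorted(t.tip_labels)
        assert np.allclose(aligned_patristic(t, labels),
                           aligned_patristic(pr, labels))

    def test_random_battery_matches_path_sums(self, rng):
        for _ in range(20):
            t = random_tree(50, rng)
            keep = list(rng.choice(t.tip_labels, size=10, replace=False))
            pr = prune_tree(t, keep)
            assert pr.n_tips == 10
            assert np.allclose(aligned_patristic(t, sorted(keep)),
                               aligned_patristic(pr, sorted(keep)), atol=1e-9)

    def test_unknown_taxon_listed(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(KeyError, match="ZZ"):
            prune_tree(t, ["A", "ZZ"])


class TestVcv:
    def test_three_tip_example(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        V = phylo_vcv(t)
        i = {lab: k for k, lab in enumerate(t.tip_labels)}
        assert V[i["A"], i["B"]] == pytest.approx(1.0)
        assert V[i["A"], i["A"]] == pytest.approx(2.0)
        assert V[i["A"], i["C"]] == pytest.approx(0.0)

    def test_star_tree_is_diagonal(self):
        t = parse_newick("(A:1,B:2,C:3);")
        V = phylo_vcv(t)
        assert np.allclose(V, np.diag(np.diag(V)))

    def test_ultrametric_constant_diagonal(self, rng):
        from skullroof.synthetic import gen_tree

        t = gen_tree(20, 1.0, 7)
        assert np.ptp(np.diag(phylo_vcv(t))) < 1e-9

    def test_random_battery_matches_bruteforce(self, rng):
        for _ in range(25):
            t = random_tree(int(rng.integers(4, 13)), rng)
            assert np.allclose(phylo_vcv(t), shared_path_bruteforce(t),
                               atol=1e-10)


class TestLambdaTransform:
    def test_identity_at_one(self, rng):
        V = phylo_vcv(random_tree(8, rng))
        assert np.allclose(lambda_transform(V, 1.0), V)

    def test_star_at_zero(self, rng):
        V = phylo_vcv(random_tree(8, rng))
        assert np.allclose(lambda_transform(V, 0.0), np.diag(np.diag(V)))

    def test_half_scales_offdiagonal(self):
        V = phylo_vcv(parse_newick("((A:1,B:1):1,C:2);"))
        W = lambda_transform(V, 0.5)
        i = np.eye(3, dtype=bool)
        assert np.allclose(W[~i], 0.5 * V[~i])
        assert np.allclose(np.diag(W), np.diag(V))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lambda_transform(np.eye(3), 1.5)


class TestLambdaFit:
    def test_optimum_beats_endpoints(self, rng):
        t = random_tree(40, rng)
        y = simulate_bm(t, BMParams(1.0), 1, seed=3)[0]
        fit = fit_lambda_ml(t, y)
        from skullroof.phylogeny import _gls_profile_loglik

        V = phylo_vcv(t)
        X = np.ones((40, 1))
        for lam in (0.0, 1.0):
            ll, _, _ = _gls_profile_loglik(y, X, lambda_transform(V, lam))
            assert fit.logL >= ll - 1e-6

    def test_constant_trait_rejected(self, rng):
        t = random_tree(10, rng)
        with pytest.raises(ValueError):
            fit_lambda_ml(t, np.ones(10))


class TestSimulateBM:
    def test_tip_moments_match_covariance(self, rng):
        t = random_tree(12, rng)
        V = phylo_vcv(t)
        sims = simulate_bm(t, BMParams(2.0, root_state=1.0), 20_000, seed=5)
        var = sims.var(axis=0)
        assert np.allclose(var, 2.0 * np.diag(V), rtol=0.05)
        C = np.cov(sims, rowvar=False)
        off = ~np.eye(12, dtype=bool)
        big = np.abs(2.0 * V[off]) > 0.3  # avoid tiny shared paths
        assert np.allclose(C[off][big], 2.0 * V[off][big], rtol=0.12)

    def test_zero_length_branch_copies_parent(self):
        t = parse_newick("((A:0,B:1):1,C:2);")
        sims = simulate_bm(t, BMParams(1.0), 200, seed=0, return_nodes=True)
        ia = t.tip_index(["A"])[0]
        parent = t.parent[ia]
        assert np.allclose(sims[:, ia], sims[:, parent])

    def test_reproducible_under_seed(self, rng):
        t = random_tree(10, rng)
        a = simulate_bm(t, BMParams(1.0), 5, seed=42)
        b = simulate_bm(t, BMParams(1.0), 5, seed=42)
        assert np.array_equal(a, b)


class TestAsrContinuous:
    def test_star_tree_root_is_mean(self):
        t = parse_newick("(A:1,B:1,C:1);")
        vals = asr_continuous(t, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert vals[t.root] == pytest.approx(2.0)

    def test_two_tip_inverse_length_weighting(self):
        t = parse_newick("(A:1,B:3);")
        vals = asr_continuous(t, {"A": 0.0, "B": 4.0})
        assert vals[t.root] == pytest.approx(1.0)

    def test_constant_tips_constant_nodes(self, rng):
        t = random_tree(9, rng)
        vals = asr_continuous(t, np.full(9, 3.7))
        assert np.allclose(vals, 3.7)

    def test_root_equals_gls_mean(self, rng):
        t = random_tree(25, rng)
        y = simulate_bm(t, BMParams(1.0), 1, seed=8)[0]
        vals = asr_continuous(t, y)
        assert vals[t.root] == pytest.approx(estimate_bm_ml(t, y).root_state)


FIVE_TIP = "((A:1,B:1):0.5,((C:0.7,D:0.7):0.6,E:1.3):0.2);"
FIVE_STATES = {"A": "0", "B": "1", "C": "0", "D": "1", "E": "0"}


def brute_force_mk_loglik(tree, states, model):
    P = {u: expm(model.Q * tree.blen[u])
         for u in range(tree.n_nodes) if tree.parent[u] >= 0}
    pi = model.stationary()
    sidx = {s: i for i, s in enumerate(model.states)}
    obs = {i: sidx[states[lab]] for i, lab in enumerate(tree.tip_labels)}
    internals = [u for u in range(tree.n_nodes) if u >= tree.n_tips]
    total = 0.0
    for assign in itertools.product(range(model.k), repeat=len(internals)):
        st = dict(zip(internals, assign))
        st.update(obs)
        p = pi[st[tree.root]]
        for u in range(tree.n_nodes):
            if tree.parent[u] >= 0:
                p *= P[u][st[tree.parent[u]], st[u]]
        total += p
    return np.log(total)


class TestMk:
    def test_pruning_matches_enumeration(self):
        t = parse_newick(FIVE_TIP)
        m = MkModel(["0", "1"], np.array([[-0.3, 0.3], [0.4, -0.4]]))
        assert mk_loglik(t, FIVE_STATES, m) == \
            pytest.approx(brute_force_mk_loglik(t, FIVE_STATES, m))

    def test_pruning_matches_enumeration_three_states(self, rng):
        t = random_tree(5, rng)
        states = dict(zip(t.tip_labels, ["0", "1", "2", "1", "0"]))
        Q = np.array([[-0.5, 0.3, 0.2], [0.1, -0.4, 0.3], [0.2, 0.2, -0.4]])
        m = MkModel(["0", "1", "2"], Q)
        assert mk_loglik(t, states, m) == \
            pytest.approx(brute_force_mk_loglik(t, states, m))

    def test_ml_beats_perturbed_rates(self):
        t = parse_newick(FIVE_TIP)
        fit = fit_mk(t, FIVE_STATES)
        base = mk_loglik(t, FIVE_STATES, fit)
        for f in (0.5, 2.0):
            m2 = MkModel(fit.states, fit.Q * f)
            assert base >= mk_loglik(t, FIVE_STATES, m2) - 1e-6

    def test_single_state_rejected(self):
        t = parse_newick(FIVE_TIP)
        with pytest.raises(ValueError):
            fit_mk(t, {k: "0" for k in FIVE_STATES})


class TestSimmap:
    def test_tip_segments_match_observations(self):
        t = parse_newick(FIVE_TIP)
        m = MkModel(["0", "1"], np.array([[-0.3, 0.3], [0.4, -0.4]]))
        maps = simmap_sample(t, FIVE_STATES, m, n_maps=100, seed=0)
        for h in maps:
            for i, lab in enumerate(t.tip_labels):
                assert h.segments[i][-1][0] == FIVE_STATES[lab]

    def test_durations_sum_and_adjacent_differ(self):
        t = parse_newick(FIVE_TIP)
        m = MkModel(["0", "1"], np.array([[-0.8, 0.8], [0.6, -0.6]]))
        for h in simmap_sample(t, FIVE_STATES, m, n_maps=50, seed=1):
            for u, segs in h.segments.items():
                assert sum(d for _, d in segs) == pytest.approx(t.blen[u])
                assert all(a != b for (a, _), (b, _) in zip(segs, segs[1:]))

    def test_node_marginals_match_pruning(self):
        from skullroof.phylogeny import _pruning_partials, _tip_state_matrix

        t = parse_newick(FIVE_TIP)
        m = MkModel(["0", "1"], np.array([[-0.3, 0.3], [0.4, -0.4]]))
        maps = simmap_sample(t, FIVE_STATES, m, n_maps=10_000, seed=2)
        D = _pruning_partials(t, m.Q, _tip_state_matrix(t, FIVE_STATES,
                                                        ["0", "1"]))
        pi = m.stationary()
        # exact root marginal; conditional marginals at other nodes via
        # brute-force enumeration of all internal assignments
        P = {u: expm(m.Q * t.blen[u])
             for u in range(t.n_nodes) if t.parent[u] >= 0}
        sidx = {s: i for i, s in enumerate(m.states)}
        obs = {i: sidx[FIVE_STATES[lab]] for i, lab in enumerate(t.tip_labels)}
        internals = [u for u in range(t.n_nodes) if u >= t.n_tips]
        marg = {u: np.zeros(2) for u in internals}
        for assign in itertools.product(range(2), repeat=len(internals)):
            st = dict(zip(internals, assign))
            st.update(obs)
            p = pi[st[t.root]]
            for u in range(t.n_nodes):
                if t.parent[u] >= 0:
                    p *= P[u][st[t.parent[u]], st[u]]
            for u in internals:
                marg[u][st[u]] += p
        for u in internals:
            marg[u] /= marg[u].sum()
            emp = np.mean([h.node_states[u] == "1" for h in maps])
            assert emp == pytest.approx(marg[u][1], abs=0.02)

    def test_zero_rate_identical_tips_no_transitions(self):
        t = parse_newick(FIVE_TIP)
        m = MkModel(["0", "1"], np.array([[-1e-9, 1e-9], [1e-9, -1e-9]]))
        states = {k: "0" for k in FIVE_STATES}
        maps = simmap_sample(t, states, m, n_maps=50, seed=3)
        assert all(h.n_changes() == 0 for h in maps)

    def test_expected_changes_match_rejection_sampling(self, rng):
        # independent oracle: unconditional forward simulation kept only
        # when the realised tips match the data
        t = parse_newick(FIVE_TIP)
        r = 0.25
        m = MkModel(["0", "1"], np.array([[-r, r], [r, -r]]))
        from skullroof.synthetic import gen_lifestyle

        target = tuple(FIVE_STATES[lab] for lab in t.tip_labels)
        pi = m.stationary()
        accepted = []
        trials = 0
        rng2 = np.random.default_rng(99)
        while len(accepted) < 1500 and trials < 400_000:
            trials += 1
            # forward Gillespie from a stationary root
            node_state = {t.root: int(rng2.random() < pi[1])}
            changes = 0
            for u in t.preorder:
                if u == t.root:
                    continue
                s = node_state[t.parent[u]]
                tau = 0.0
                while True:
                    tau += rng2.exponential(1.0 / r)
                    if tau >= t.blen[u]:
                        break
                    s = 1 - s
                    changes += 1
                node_state[u] = s
            tips = tuple("01"[node_state[i]] for i in range(t.n_tips))
            if tips == target:
                accepted.append(changes)
        assert len(accepted) >= 1000
        maps = simmap_sample(t, FIVE_STATES, m, n_maps=4000, seed=4)
        mean_maps = np.mean([h.n_changes() for h in maps])
        assert mean_maps == pytest.approx(np.mean(accepted), rel=0.15)


class TestBranchPosterior:
    def test_single_history_profile_binary(self):
        t = parse_newick(FIVE_TIP)
        m = MkModel(["0", "1"], np.array([[-0.3, 0.3], [0.4, -0.4]]))
        maps = simmap_sample(t, FIVE_STATES, m, n_maps=1, seed=5)
        profiles, _ = branch_posterior(t, maps, "1")
        for prof in profiles.values():
            assert set(np.unique(prof)) <= {0.0, 1.0}

    def test_acquisitions_recover_planted_regimes(self):
        # two clean focal clades against a clearly state-0 background, so
        # gains (not losses) are the parsimonious reading
        t = parse_newick("(((A:1,B:1):3,(C:1,D:1):3):1,((E:1,F:1):3,"
                         "((G:1,H:1):1,(I:1,J:1):1):2):1);")
        states = {"A": "1", "B": "1", "C": "0", "D": "0", "E": "1",
                  "F": "1", "G": "0", "H": "0", "I": "0", "J": "0"}
        m = fit_mk(t, states)
        maps = simmap_sample(t, states, m, n_maps=400, seed=6)
        _, acq = branch_posterior(t, maps, "1")
        assert len(acq) == 2

    def test_empty_history_rejected(self):
        t = parse_newick(FIVE_TIP)
        with pytest.raises(ValueError):
            branch_posterior(t, [], "1")


def brute_force_fitch(tree, states_by_label):
    """Minimum steps over all internal labelings (trees <= 6 tips)."""
    k_states = sorted(set(states_by_label.values()))
    obs = {i: states_by_label[lab] for i, lab in enumerate(tree.tip_labels)}
    internals = [u for u in range(tree.n_nodes) if u >= tree.n_tips]
    best = None
    for assign in itertools.product(k_states, repeat=len(internals)):
        st = dict(zip(internals, assign))
        st.update(obs)
        steps = sum(st[u] != st[tree.parent[u]]
                    for u in range(tree.n_nodes) if tree.parent[u] >= 0)
        best = steps if best is None else min(best, steps)
    return best


class TestParsimony:
    def test_clade_character_has_retention_one(self):
        t = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        char = {"A": "x", "B": "x", "C": "y", "D": "y", "E": "y"}
        assert fitch_steps(t, char) == 1
        assert retention_index(t, char) == pytest.approx(1.0)

    def test_alternating_ladder_has_retention_zero(self):
        t = parse_newick("(A:1,(B:1,(C:1,(D:1,(E:1,F:1):1):1):1):1);")
        char = dict(zip("ABCDEF", "010101"))
        s = fitch_steps(t, char)
        g = 6 - 3
        assert s == g
        assert retention_index(t, char) == pytest.approx(0.0)

    def test_fitch_matches_bruteforce_battery(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 7))
            t = random_tree(n, rng)
            labels = {lab: str(rng.integers(0, 2)) for lab in t.tip_labels}
            if len(set(labels.values())) < 2:
                labels[t.tip_labels[0]] = "1"
                labels[t.tip_labels[1]] = "0"
            assert fitch_steps(t, labels) == brute_force_fitch(t, labels)

    def test_invariant_character_rejected(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError):
            retention_index(t, {"A": "x", "B": "x", "C": "x"})
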