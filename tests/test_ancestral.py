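import math

import numpy as np
import pytest

import mitoscolia as m
from mitoscolia.ancestral import MISSING, _default_prior, _tree_index, node_signature
from mitoscolia.simulate import simulate_character, simulate_tree

from _oracles import brute_force_likelihood, exhaustive_parsimony_minimum


class TestFitch:
    def test_cherry_disagreement(self):
        tree = m.read_newick("(A:1,B:1);")
        fr = m.fitch(tree, {"A": "0", "B": "1"}, alphabet=("0", "1"))
        assert fr.root_set == frozenset({"0", "1"})
        assert fr.changes == 1

    def test_monomorphic_no_changes(self):
        tree = m.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        fr = m.fitch(tree, {t: "0" for t in "ABCD"}, alphabet=("0", "1"))
        assert fr.changes == 0
        assert all(s == frozenset({"0"}) for s in fr.node_sets.values())

    def test_missing_tips_carry_full_set(self):
        tree = m.read_newick("((A:1,B:1):1,C:1);")
        fr = m.fitch(tree, {"A": "0", "B": None, "C": "?"}, alphabet=("0", "1"))
        assert fr.changes == 0
        assert fr.node_sets[node_signature(tree.seed_node)] == frozenset({"0"})

    def test_all_missing_errors(self):
        tree = m.read_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            m.fitch(tree, {"A": None, "B": MISSING}, alphabet=("0", "1"))

    def test_matches_exhaustive_minimum_on_random_characters(self, rng):
        for _ in range(60):
            tree = simulate_tree(5, seed=int(rng.integers(2**31)))
            states = {f"t{i+1}": str(rng.integers(2)) for i in range(5)}
            fr = m.fitch(tree, states, alphabet=("0", "1"))
            assert fr.changes == exhaustive_parsimony_minimum(tree, states, ["0", "1"])

    def test_trifurcating_root_handled(self):
        tree = m.read_newick("(A:1,B:1,C:1);")
        fr = m.fitch(tree, {"A": "0", "B": "0", "C": "1"}, alphabet=("0", "1"))
        assert fr.changes == 1
        assert fr.root_set == frozenset({"0"})


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        for family, rates in [("Mk1", (0.7,)), ("AsymmMk", (0.7, 0.2))]:
            P = m.mk_transition_matrix(family, rates, 0.0)
            assert np.allclose(P, np.eye(2))

    def test_long_time_reaches_stationarity(self):
        P = m.mk_transition_matrix("Mk1", (1.0,), 1e6)
        assert np.allclose(P, 0.5)
        P2 = m.mk_transition_matrix("AsymmMk", (0.4, 0.1), 1e6)
        assert np.allclose(P2, [[0.2, 0.8], [0.2, 0.8]])

    def test_mk1_closed_form(self):
        P = m.mk_transition_matrix("Mk1", (1.0,), 1.0)
        assert P[0, 0] == pytest.approx(0.5 + 0.5 * math.exp(-2))

    def test_rows_sum_to_one(self):
        for family, rates in [("Mk1", (0.3,)), ("AsymmMk", (0.9, 0.2))]:
            P = m.mk_transition_matrix(family, rates, 0.37)
            assert np.allclose(P.sum(axis=1), 1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            m.mk_transition_matrix("Mk1", (1.0,), -0.1)


class TestPruningLoglik:
    def test_single_tip_equal_prior(self):
        tree = m.read_newick("(A:1);")
        ll = m.pruning_loglik(tree, {"A": "0"}, "Mk1", (1.0,), alphabet=("0", "1"))
        assert ll == pytest.approx(math.log(0.5))

    def test_all_missing_likelihood_one(self):
        tree = m.read_newick("((A:1,B:1):1,C:1);")
        ll = m.pruning_loglik(tree, {t: None for t in "ABC"}, "Mk1", (1.0,),
                              alphabet=("0", "1"))
        assert ll == pytest.approx(0.0)

    def test_zero_length_conflict_gives_neg_inf(self):
        tree = m.read_newick("(A:0,B:0);")
        ll = m.pruning_loglik(tree, {"A": "0", "B": "1"}, "Mk1", (1.0,),
                              alphabet=("0", "1"))
        assert ll == -np.inf

    @pytest.mark.parametrize("family", ["Mk1", "AsymmMk"])
    def test_matches_enumeration_oracle(self, family, rng):
        for _ in range(10):
            n = int(rng.integers(3, 7))
            tree = simulate_tree(n, seed=int(rng.integers(2**31)))
            states = {f"t{i+1}": (None if rng.random() < 0.2 else str(rng.integers(2)))
                      for i in range(n)}
            if all(v is None for v in states.values()):
                states["t1"] = "0"
            rates = ((float(rng.uniform(0.05, 2.0)),) if family == "Mk1"
                     else tuple(rng.uniform(0.05, 2.0, size=2)))
            prior = _default_prior(family, rates, 2)
            lik, _ = brute_force_likelihood(tree, states, family, rates, prior, ["0", "1"])
            ll = m.pruning_loglik(tree, states, family, rates, alphabet=("0", "1"))
            assert abs(math.log(lik) - ll) < 1e-9

    def test_invariance_to_child_order_and_rerooting(self, rng):
        """Mk1 with uniform prior is reversible: lnL must not depend on how
        the rooted tree is drawn."""
        newicks = [
            "((A:0.3,B:0.2):0.4,(C:0.1,D:0.7):0.2);",
            "(((C:0.1,D:0.7):0.6,A:0.3):0.1,B:0.1);",  # re-rooted along A-B edge
            "((B:0.2,A:0.3):0.4,(D:0.7,C:0.1):0.2);",  # children swapped
        ]
        states = {"A": "0", "B": "1", "C": "1", "D": "0"}
        lls = [m.pruning_loglik(m.read_newick(nw), states, "Mk1", (0.6,),
                                alphabet=("0", "1")) for nw in newicks]
        assert max(lls) - min(lls) < 1e-9


class TestFitAndSelect:
    def test_monomorphic_hits_lower_bound_flagged(self):
        tree = simulate_tree(8, seed=3)
        states = {f"t{i+1}": "0" for i in range(8)}
        fit = m.fit_model(tree, states, "Mk1", alphabet=("0", "1"))
        assert fit.at_boundary
        assert fit.rates[0] == pytest.approx(1e-8, rel=1e-2)

    def test_asymm_nests_mk1(self):
        tree = simulate_tree(20, seed=9)
        states = simulate_character(tree, "Mk1", (0.8,), seed=2)
        f1 = m.fit_model(tree, states, "Mk1", alphabet=("0", "1"))
        f2 = m.fit_model(tree, states, "AsymmMk", alphabet=("0", "1"))
        assert f2.llf >= f1.llf - 1e-6

    def test_aic_arithmetic_and_tie_break(self):
        tree = simulate_tree(4, seed=1)
        states = {"t1": "0", "t2": "1", "t3": "0", "t4": "1"}
        model1 = m.MkModel(tree, states, "Mk1", alphabet=("0", "1"))
        model2 = m.MkModel(tree, states, "AsymmMk", alphabet=("0", "1"))
        a = m.MkResults(model=model1, rates=(1.0,), llf=-10.0, n_params=1)
        b = m.MkResults(model=model2, rates=(1.0, 1.0), llf=-10.0, n_params=2)
        assert a.aic == pytest.approx(22.0)
        assert m.select_model([b, a]) is a  # tie on lnL -> fewer parameters wins

    def test_rate_recovery_median(self):
        """Median MLE across characters simulated at q=0.5 lands near 0.5."""
        tree = simulate_tree(60, seed=17)
        chars = simulate_character(tree, "Mk1", (0.5,), seed=23, n_chars=60)
        qs = []
        for j in range(60):
            states = {t: v[j] for t, v in chars.items()}
            qs.append(m.fit_model(tree, states, "Mk1", alphabet=("0", "1")).rates[0])
        assert 0.3 < float(np.median(qs)) < 0.7

    def test_summary_mentions_family_and_aic(self):
        tree = simulate_tree(6, seed=2)
        states = simulate_character(tree, "Mk1", (0.5,), seed=3)
        fit = m.fit_model(tree, states, "Mk1", alphabet=("0", "1"))
        text = fit.summary()
        assert "Mk1" in text and "AIC" in text


class TestMarginals:
    def test_vectors_sum_to_one(self, fig_tree, modes_matrix):
        states = modes_matrix.column("cluster1")
        fit = m.fit_model(fig_tree, states, "Mk1", alphabet=("mode1", "mode2"))
        rec = m.marginal_reconstruction(fig_tree, states, fit)
        for vec in rec.ml_probabilities.values():
            assert np.atleast_1d(vec).sum() == pytest.approx(1.0, abs=1e-9)

    def test_monomorphic_majority(self):
        tree = simulate_tree(10, seed=4)
        states = {f"t{i+1}": "0" for i in range(10)}
        model = m.MkModel(tree, states, "Mk1", alphabet=("0", "1"))
        res = m.MkResults(model=model, rates=(0.2,), llf=model.loglike((0.2,)), n_params=1)
        for vec in res.marginal_probabilities().values():
            assert np.atleast_1d(vec)[0] > 0.5

    def test_long_branches_approach_root_prior(self):
        tree = m.read_newick("((A:500,B:500):500,(C:500,D:500):500);")
        states = {"A": "0", "B": "0", "C": "0", "D": "1"}
        model = m.MkModel(tree, states, "Mk1", alphabet=("0", "1"))
        res = m.MkResults(model=model, rates=(1.0,), llf=0.0, n_params=1)
        for sig, vec in res.marginal_probabilities().items():
            if "|" in sig:  # internal nodes only; tips stay clamped to their data
                assert np.allclose(np.atleast_1d(vec), 0.5, atol=1e-3)

    @pytest.mark.parametrize("family", ["Mk1", "AsymmMk"])
    def test_match_enumeration_posterior(self, family, rng):
        for _ in range(5):
            n = int(rng.integers(3, 6))
            tree = simulate_tree(n, seed=int(rng.integers(2**31)))
            states = {f"t{i+1}": str(rng.integers(2)) for i in range(n)}
            rates = ((float(rng.uniform(0.1, 1.5)),) if family == "Mk1"
                     else tuple(rng.uniform(0.1, 1.5, size=2)))
            prior = _default_prior(family, rates, 2)
            _, marg = brute_force_likelihood(tree, states, family, rates, prior, ["0", "1"])
            model = m.MkModel(tree, states, family, alphabet=("0", "1"))
            res = m.MkResults(model=model, rates=rates, llf=0.0,
                              n_params=model.n_params)
            got = res.marginal_probabilities()
            for sig, vec in marg.items():
                assert np.allclose(np.atleast_1d(got[sig]), vec, atol=1e-9)

    def test_fitch_changes_bound_ml_joint(self, fig_tree, modes_matrix):
        """The MP minimum never exceeds the changes implied by assigning each
        node its ML state."""
        states = modes_matrix.column("cluster2")
        fit = m.fit_model(fig_tree, states, "Mk1", alphabet=("mode3", "mode4"))
        rec = m.marginal_reconstruction(fig_tree, states, fit)
        ti = _tree_index(fig_tree)
        assigned = {}
        for i, sig in enumerate(ti.signatures):
            if ti.is_leaf[i]:
                assigned[i] = states[ti.labels[i]]
            else:
                assigned[i] = rec.ml_state(sig)
        implied = 0
        for i in range(len(ti.nodes)):
            for c in ti.children[i]:
                a, b = assigned[i], assigned[c]
                if a is not None and b is not None and a != b:
                    implied += 1
        assert rec.mp_changes <= implied


class TestCharacterMatrix:
    def test_tsv_round_trip(self, tmp_path, modes_matrix):
        path = tmp_path / "modes.tsv"
        modes_matrix.to_tsv(path)
        again = m.CharacterMatrix.from_tsv(
            path, alphabets={"cluster1": ("mode1", "mode2"),
                             "cluster2": ("mode3", "mode4")})
        assert again.column("cluster1") == modes_matrix.column("cluster1")
        assert again.column("cluster2") == modes_matrix.column("cluster2")

    def test_missing_coded(self, modes_matrix):
        col = modes_matrix.column("cluster1")
        assert col["Campsomeriella_annulata"] is None
        assert col["Liacos_erythrosoma"] is None
        assert col["Colpa_tartara"] == "mode1"

    def test_bad_state_rejected(self):
        with pytest.raises(ValueError):
            m.CharacterMatrix(taxa=["a"], characters={"c": ("x", "y")},
                              states={"a": {"c": "z"}})


class TestScoliidaeFixture:
    """The study reconstruction: Scoliini-type modes dominate the family root."""

    def test_root_reconstruction(self, fig_tree, modes_matrix):
        from mitoscolia.data import scoliidae_root_signature
        root = scoliidae_root_signature()
        for char, anc_mode in [("cluster1", "mode1"), ("cluster2", "mode3")]:
            states = modes_matrix.column(char)
            alphabet = modes_matrix.characters[char]
            fr = m.fitch(fig_tree, states, alphabet=alphabet)
            # one tribe-level switch: the root is within one step of either mode
            assert anc_mode in fr.root_set
            assert fr.changes == 1
            fit = m.fit_model(fig_tree, states, "Mk1", alphabet=alphabet)
            rec = m.marginal_reconstruction(fig_tree, states, fit)
            assert rec.ml_state(root) == anc_mode
            assert rec.ml_at(root)[anc_mode] > 0.5

    def test_campsomerini_crown_reconstructs_derived_modes(self, fig_tree, modes_matrix):
        """The clade of scored Campsomerini (excluding the unscored
        Campsomeriella) reconstructs the derived modes 2 and 4."""
        crown = "|".join(sorted([
            "Phalerimeris_phalerata", "Micromeriella_marginella",
            "Sericocampsomeris_flavomaculata", "Megacampsomeris_prismatica",
            "Megacampsomeris_binghami", "Megacampsomeris_farrenwhitei"]))
        for char, derived in [("cluster1", "mode2"), ("cluster2", "mode4")]:
            states = modes_matrix.column(char)
            fit = m.fit_model(fig_tree, states, "Mk1",
                              alphabet=modes_matrix.characters[char])
            rec = m.marginal_reconstruction(fig_tree, states, fit)
            assert rec.ml_state(crown) == derived
            assert rec.mp_sets[crown] == frozenset({derived})
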