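import math

import dendropy
import numpy as np
import pytest

from plastmark import delimit
from plastmark.delimit import (
    brute_force_ml,
    ml_delimitation,
    null_loglik,
)
from plastmark.errors import DegenerateTreeError, RootingError, SizeError
from plastmark.simulate import simulate_tree

from conftest import random_rooted_tree


def tree_from(nw: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=nw, schema="newick", rooting="force-rooted")


class TestNullLoglik:
    def test_two_unit_edges(self):
        ll, lam = null_loglik(tree_from("(A:1,B:1);"))
        assert lam == pytest.approx(1.0)
        assert ll == pytest.approx(-2.0, abs=1e-12)

    def test_four_half_edges(self):
        ll, lam = null_loglik(tree_from("((A:0.5,B:0.5):0.5,C:0.5);"))
        assert lam == pytest.approx(2.0)
        assert ll == pytest.approx(4 * math.log(2) - 4, abs=1e-12)

    def test_equals_single_entity_delimitation(self, rng):
        for _ in range(10):
            t = random_rooted_tree(rng, int(rng.integers(3, 9)))
            ll, _ = null_loglik(t)
            single = brute_force_ml(t, alpha=0.01)
            if single.n_entities == 1:
                assert single.loglik == pytest.approx(ll, abs=1e-12)
            assert single.null_loglik == pytest.approx(ll, abs=1e-12)

    def test_closed_form_on_random_trees(self, rng):
        for _ in range(25):
            t = random_rooted_tree(rng, int(rng.integers(2, 12)))
            lengths = [
                nd.edge.length
                for nd in t.preorder_node_iter()
                if nd.parent_node and nd.edge.length >= delimit.MIN_BRANCH_LENGTH
            ]
            n, s = len(lengths), sum(lengths)
            ll, lam = null_loglik(t)
            assert ll == pytest.approx(n * math.log(n / s) - n, abs=1e-12)
            assert lam == pytest.approx(n / s, rel=1e-12)

    def test_degenerate_tree_rejected(self):
        with pytest.raises(DegenerateTreeError):
            null_loglik(tree_from("(A:0,B:0);"))


class TestBruteForce:
    def test_quartet_splits_into_cherries(self, quartet_tree):
        d = brute_force_ml(quartet_tree, alpha=None)
        assert d.n_entities == 2
        assert set(d.species_roots) == {
            frozenset({"A", "B"}),
            frozenset({"C", "D"}),
        }
        # coalescent rates far exceed the speciation rate
        assert d.lambda_sp == pytest.approx(1.0)
        assert all(l == pytest.approx(100.0) for l in d.lambda_coal)

    def test_equal_edges_kept_single_after_lrt(self):
        t = tree_from("((A:1,B:1):1,(C:1,D:1):1);")
        d = brute_force_ml(t, alpha=0.01)
        assert d.n_entities == 1

    def test_star_tree_single_entity(self):
        t = tree_from("(A:1,B:1,C:1,D:1,E:1);")
        d = brute_force_ml(t, alpha=None)
        assert d.n_entities == 1

    def test_enumeration_bound(self, rng):
        t = random_rooted_tree(rng, 14)
        with pytest.raises(SizeError):
            brute_force_ml(t)


class TestMlDelimitation:
    def test_matches_oracle_on_random_trees(self, rng):
        for rep in range(40):
            n_sp = int(rng.integers(1, 7))
            tps = int(rng.integers(1, 4))
            if not (2 <= n_sp * tps <= 12):
                continue
            ratio = float(rng.choice([1, 5, 20, 50]))
            truth = simulate_tree(n_sp, tps, 50.0, 50.0 * ratio, seed=900 + rep)
            for model in ("single", "multi"):
                bf = brute_force_ml(truth.tree, model=model, alpha=None)
                ml = ml_delimitation(truth.tree, model=model, alpha=None)
                assert ml.loglik == pytest.approx(bf.loglik, abs=1e-9)
                assert set(ml.species_roots) == set(bf.species_roots)

    def test_lrt_decision_matches_oracle_path(self, rng):
        for rep in range(8):
            truth = simulate_tree(3, 3, 50.0, 1000.0, seed=300 + rep)
            bf = brute_force_ml(truth.tree, alpha=0.01)
            ml = ml_delimitation(truth.tree, alpha=0.01)
            assert ml.p_value == bf.p_value
            assert set(ml.species_roots) == set(bf.species_roots)

    def test_recovers_simulated_species(self):
        # rate ratio 20: a typical replicate recovers >=9 of 10 species exactly
        recovered = []
        for rep in range(20):
            truth = simulate_tree(10, 3, 50.0, 1000.0, seed=40 + rep)
            ml = ml_delimitation(truth.tree, alpha=0.01)
            recovered.append(
                sum(e in set(ml.species_roots) for e in truth.true_entities)
            )
        assert np.median(recovered) >= 9

    def test_loglik_never_below_null(self, rng):
        for _ in range(20):
            t = random_rooted_tree(rng, int(rng.integers(2, 10)))
            ml = ml_delimitation(t, alpha=None)
            assert ml.loglik >= null_loglik(t)[0] - 1e-12

    def test_unrooted_tree_rejected(self):
        t = dendropy.Tree.get(
            data="(A:1,B:1,C:1);", schema="newick", rooting="force-unrooted"
        )
        with pytest.raises(RootingError):
            ml_delimitation(t)

    def test_type_one_error_controlled(self):
        rejections = 0
        for rep in range(60):
            truth = simulate_tree(1, 15, 50.0, 50.0, seed=7000 + rep)
            ml = ml_delimitation(truth.tree, alpha=0.01)
            rejections += ml.n_entities > 1
        assert rejections <= 3

    def test_rate_ratio_recovered_within_factor_two(self):
        ratios = []
        for rep in range(25):
            truth = simulate_tree(10, 4, 50.0, 1000.0, seed=31000 + rep)
            ml = ml_delimitation(truth.tree, alpha=0.01)
            coal = [l for l in ml.lambda_coal if l]
            if ml.lambda_sp and coal:
                ratios.append(np.mean(coal) / ml.lambda_sp)
        med = float(np.median(ratios))
        assert 10.0 <= med <= 40.0  # true ratio 20, within a factor of 2
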