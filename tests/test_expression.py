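import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from lineageml.encoding import ExpressionMatrix
from lineageml.expression import (
    ExpressionPrior,
    ExpressionScorer,
    bhc_log_marginal,
    h1_log_marginal,
)
from lineageml.tree import LineageTree, Node, read_tree

from conftest import random_binary_tree


def em(X, names=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = names or [f"c{i}" for i in range(X.shape[0])]
    return ExpressionMatrix(X, names, [f"g{j}" for j in range(X.shape[1])])


@pytest.fixture
def unit_prior():
    return ExpressionPrior(mean=np.array([0.0]), strength=1.0, shape=2.0, rate=np.array([2.0]), alpha=1.0)


class TestH1Marginal:
    def test_single_cell_equals_leaf_marginal(self, unit_prior):
        t = LineageTree(Node("c0"))
        score, stats = bhc_log_marginal(t, em([[1.3]]), unit_prior)
        assert score == pytest.approx(h1_log_marginal([[1.3]], unit_prior))

    def test_close_pair_beats_distant_pair(self, unit_prior):
        near = h1_log_marginal([[1.0], [1.0]], unit_prior)
        far = h1_log_marginal([[-5.0], [5.0]], unit_prior)
        assert near > far

    def test_matches_numerical_integration(self, unit_prior):
        """Closed form vs direct 2-D quadrature over (mean, precision)
        of the Normal-Gamma model on a one-gene instance."""
        from scipy.integrate import dblquad

        data = np.array([0.4, -0.3, 1.1])
        mu0, k0, a0, b0 = 0.0, 1.0, 2.0, 2.0

        def integrand(mu, tau):
            lik = np.prod([math.sqrt(tau / (2 * math.pi)) * math.exp(-0.5 * tau * (x - mu) ** 2)
                           for x in data])
            prior_tau = b0**a0 / math.gamma(a0) * tau ** (a0 - 1) * math.exp(-b0 * tau)
            prior_mu = math.sqrt(k0 * tau / (2 * math.pi)) * math.exp(-0.5 * k0 * tau * mu**2)
            return lik * prior_tau * prior_mu

        val, _ = dblquad(integrand, 1e-9, 40, lambda t: -12, lambda t: 12)
        assert h1_log_marginal(data[:, None], unit_prior) == pytest.approx(np.log(val), abs=1e-6)

    def test_genes_are_independent(self, unit_prior):
        prior2 = ExpressionPrior(mean=np.zeros(2), strength=1.0, shape=2.0,
                                 rate=np.full(2, 2.0), alpha=1.0)
        X = np.array([[0.5, -1.0], [1.5, 0.3]])
        total = h1_log_marginal(X, prior2)
        per_gene = sum(h1_log_marginal(X[:, [j]], unit_prior) for j in range(2))
        assert total == pytest.approx(per_gene, abs=1e-10)

    def test_empty_subset_rejected(self, unit_prior):
        with pytest.raises(ValueError):
            h1_log_marginal(np.empty((0, 1)), unit_prior)


class TestBhcRecursion:
    def test_cherry_pi_is_half_at_alpha_one(self, unit_prior):
        t = read_tree("(c0,c1);")
        _, stats = bhc_log_marginal(t, em([[0.2], [0.4]], ["c0", "c1"]), unit_prior)
        root_stats = stats[id(t.root)]
        assert math.exp(root_stats.log_pi) == pytest.approx(0.5, abs=1e-12)

    def test_cherry_matches_two_partition_dpm_sum(self, unit_prior):
        """Independent oracle: explicit CRP-weighted sum over the two
        tree-consistent partitions of a pair."""
        X = np.array([[0.7], [-0.4]])
        t = read_tree("(c0,c1);")
        score, _ = bhc_log_marginal(t, em(X, ["c0", "c1"]), unit_prior)
        a = unit_prior.alpha
        w_together = 1.0 / (1.0 + a)
        w_apart = a / (1.0 + a)
        brute = (
            w_together * math.exp(h1_log_marginal(X, unit_prior))
            + w_apart
            * math.exp(h1_log_marginal(X[:1], unit_prior))
            * math.exp(h1_log_marginal(X[1:], unit_prior))
        )
        assert score == pytest.approx(math.log(brute), abs=1e-8)

    def test_four_leaf_balanced_matches_partition_enumeration(self, unit_prior):
        """On ((a,b),(c,d)) the BHC recursion sums exactly the
        tree-consistent partitions with DPM weights; enumerate them."""
        X = np.array([[0.0], [0.3], [2.0], [2.2]])
        names = ["a", "b", "c", "d"]
        t = read_tree("((a,b),(c,d));")
        score, _ = bhc_log_marginal(t, em(X, names), unit_prior)

        def prior_mass(sizes, alpha):
            # unnormalized DPM prior mass alpha^k prod (s-1)!; the BHC
            # recursion normalizes over tree-consistent partitions only
            return alpha ** len(sizes) * math.prod(math.factorial(s - 1) for s in sizes)

        # tree-consistent partitions of {ab|cd} tree:
        # {abcd}, {ab|cd}, {ab|c|d}, {a|b|cd}, {a|b|c|d}
        blocks_list = [
            [[0, 1, 2, 3]],
            [[0, 1], [2, 3]],
            [[0, 1], [2], [3]],
            [[0], [1], [2, 3]],
            [[0], [1], [2], [3]],
        ]
        masses = [prior_mass([len(b) for b in blocks], unit_prior.alpha)
                  for blocks in blocks_list]
        total = 0.0
        for blocks, mass in zip(blocks_list, masses):
            lik = 1.0
            for b in blocks:
                lik *= math.exp(h1_log_marginal(X[b], unit_prior))
            total += mass / sum(masses) * lik
        assert score == pytest.approx(math.log(total), abs=1e-8)

    def test_child_permutation_invariance(self, rng, unit_prior):
        """Swapping the two children of any node leaves every BHC
        quantity unchanged (200 random trees)."""
        for _ in range(200):
            n = int(rng.integers(3, 9))
            names = [f"c{i}" for i in range(n)]
            t = random_binary_tree(names, rng)
            X = rng.normal(size=(n, 1))
            data = em(X, names)
            prior = ExpressionPrior(mean=np.array([0.0]), strength=1.0, shape=2.0,
                                    rate=np.array([2.0]), alpha=1.0)
            s1, _ = bhc_log_marginal(t, data, prior)
            node = t.internal_nodes()[int(rng.integers(len(t.internal_nodes())))]
            node.children.reverse()
            s2, _ = bhc_log_marginal(t, data, prior)
            assert s1 == pytest.approx(s2, abs=1e-12)

    def test_logsumexp_lower_bounds(self, rng, unit_prior):
        names = [f"c{i}" for i in range(8)]
        t = random_binary_tree(names, rng)
        data = em(rng.normal(size=(8, 1)), names)
        _, stats = bhc_log_marginal(t, data, unit_prior)
        index = {id(n): n for n in t.preorder()}
        for node in t.internal_nodes():
            st = stats[id(node)]
            su, sw = (stats[id(c)] for c in node.children)
            assert st.log_L >= st.log_pi + st.log_h1 - 1e-12
            assert st.log_L >= st.log_one_minus_pi + su.log_L + sw.log_L - 1e-12

    def test_pi_monotone_in_alpha_on_cherry(self):
        X = np.array([[0.1], [0.2]])
        t = read_tree("(c0,c1);")
        pis = []
        for alpha in [0.1, 0.5, 1.0, 2.0, 10.0]:
            prior = ExpressionPrior(mean=np.array([0.0]), strength=1.0, shape=2.0,
                                    rate=np.array([2.0]), alpha=alpha)
            _, stats = bhc_log_marginal(t, em(X, ["c0", "c1"]), prior)
            pis.append(math.exp(stats[id(t.root)].log_pi))
        assert all(a > b for a, b in zip(pis, pis[1:]))
        assert pis[2] == pytest.approx(0.5)

    def test_nonbinary_rejected(self, unit_prior):
        root = Node()
        for nm in ["a", "b", "c"]:
            root.add_child(Node(nm))
        with pytest.raises(ValueError, match="binary"):
            bhc_log_marginal(LineageTree(root), em(np.zeros((3, 1)), ["a", "b", "c"]), unit_prior)


class TestAgainstGreedyBhc:
    def test_matches_independent_greedy_implementation(self, rng):
        """An independently coded bottom-up greedy BHC (its own merge
        bookkeeping and formulas) must assign the same root marginal
        to the tree it builds."""
        n = 12
        X = rng.normal(size=(n, 2)) + np.repeat([[0, 0], [4, 4], [-4, 4]], 4, axis=0)
        names = [f"c{i}" for i in range(n)]
        prior = ExpressionPrior(mean=X.mean(axis=0), strength=0.5, shape=1.5,
                                rate=X.var(axis=0), alpha=1.0)

        # --- independent greedy BHC (test-local) ---
        def marg(rows):
            k0, a0 = prior.strength, prior.shape
            out = 0.0
            for j in range(X.shape[1]):
                x = X[rows, j]
                nn = len(x)
                kn, an = k0 + nn, a0 + nn / 2
                xbar = x.mean()
                bn = (prior.rate[j] + 0.5 * ((x - xbar) ** 2).sum()
                      + k0 * nn * (xbar - prior.mean[j]) ** 2 / (2 * kn))
                out += (gammaln(an) - gammaln(a0) + a0 * np.log(prior.rate[j])
                        - an * np.log(bn) + 0.5 * (np.log(k0) - np.log(kn))
                        - nn / 2 * np.log(2 * np.pi))
            return out

        clusters = [{"rows": [i], "d": prior.alpha, "logL": marg([i]), "node": Node(names[i])}
                    for i in range(n)]
        while len(clusters) > 1:
            best = None
            for i, j in itertools.combinations(range(len(clusters)), 2):
                ci, cj = clusters[i], clusters[j]
                rows = ci["rows"] + cj["rows"]
                d = prior.alpha * math.gamma(len(rows)) + ci["d"] * cj["d"]
                pi = prior.alpha * math.gamma(len(rows)) / d
                logL = np.logaddexp(np.log(pi) + marg(rows),
                                    np.log1p(-pi) + ci["logL"] + cj["logL"])
                r = np.exp(np.log(pi) + marg(rows) - logL)
                if best is None or r > best[0]:
                    best = (r, i, j, rows, d, logL)
            r, i, j, rows, d, logL = best
            node = Node()
            node.add_child(clusters[i]["node"])
            node.add_child(clusters[j]["node"])
            merged = {"rows": rows, "d": d, "logL": logL, "node": node}
            clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]

        greedy_tree = LineageTree(clusters[0]["node"])
        greedy_score = clusters[0]["logL"]
        ours, _ = bhc_log_marginal(greedy_tree, em(X, names), prior)
        assert ours == pytest.approx(greedy_score, abs=1e-8)
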