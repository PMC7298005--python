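"""Expression likelihood of a lineage tree via Bayesian hierarchical
clustering (BHC) under a Dirichlet process mixture (DPM).

The tree is viewed as a hierarchical clustering of the cells. At each
internal node v with children u, w two hypotheses are weighed: H1,
all cells below v form one cluster (a single draw of component
parameters), versus H2, the cells split according to the two
subtrees. The recursive marginal likelihood

    L_v = pi_v * P(Y^v | H1) + (1 - pi_v) * L_u * L_w
    pi_v = alpha * Gamma(n_v) / d_v,   d_v = alpha * Gamma(n_v) + d_u * d_w

(leaves: pi = 1, d = alpha, L = P(y | H1)) lower-bounds the DPM
marginal likelihood; the root value is the tree's expression
likelihood. The per-cluster observation model is an independent
Normal-Gamma conjugate model per gene (diagonal covariance), so
P(Y | H1) is available in closed form. All arithmetic is in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .encoding import ExpressionMatrix
from .tree import LineageTree, Node

__all__ = [
    "ExpressionPrior",
    "NodeStats",
    "h1_log_marginal",
    "bhc_log_marginal",
    "ExpressionScorer",
]

_MIN_RATE = 1e-8


@dataclass
class ExpressionPrior:
    """Conjugate Normal-Gamma hyperparameters (per gene) plus DPM alpha.

    mean : prior mean of gene expression (length G)
    strength : pseudo-observation count kappa_0 backing the mean (> 0)
    shape, rate : Gamma prior on the gene precision (> 0); ``rate`` is
        per gene
    alpha : DPM concentration (> 0); larger alpha favors more clusters
    """

    mean: np.ndarray
    strength: float
    shape: float
    rate: np.ndarray
    alpha: float = 1.0

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.rate = np.atleast_1d(np.asarray(self.rate, dtype=float))
        if self.strength <= 0 or self.shape <= 0 or self.alpha <= 0:
            raise ValueError("strength, shape and alpha must be positive")
        if np.any(self.rate <= 0):
            raise ValueError("rate must be positive for every gene")

    @classmethod
    def empirical(
        cls,
        Y: np.ndarray | ExpressionMatrix,
        strength_frac: float = 0.01,
        shape: float = 1.0,
        alpha: float = 1.0,
    ) -> "ExpressionPrior":
        """Empirical-Bayes defaults: prior mean = per-gene grand mean,
        strength = ``strength_frac`` * N, rate = per-gene variance."""
        X = Y.Y if isinstance(Y, ExpressionMatrix) else np.asarray(Y, dtype=float)
        n = X.shape[0]
        return cls(
            mean=X.mean(axis=0),
            strength=max(strength_frac * n, 1e-3),
            shape=shape,
            rate=np.maximum(X.var(axis=0), _MIN_RATE),
            alpha=alpha,
        )


@dataclass
class NodeStats:
    """Per-node BHC quantities, all log-scale except the leaf count."""

    n: int
    log_d: float
    log_pi: float
    log_h1: float
    log_L: float
    log_one_minus_pi: float = -np.inf


def _h1_from_suffstats(
    n: np.ndarray, s1: np.ndarray, s2: np.ndarray, prior: ExpressionPrior
) -> np.ndarray:
    """Closed-form Normal-Gamma log marginal from sufficient statistics.

    ``n`` is (V,), ``s1``/``s2`` are (V, G) sums and sums of squares;
    returns (V,) log marginals summed over genes.
    """
    n = np.asarray(n, dtype=float)[:, None]
    k0, a0 = prior.strength, prior.shape
    mu0, b0 = prior.mean[None, :], prior.rate[None, :]
    kn = k0 + n
    an = a0 + n / 2.0
    xbar = s1 / n
    ss = np.maximum(s2 - n * xbar**2, 0.0)
    bn = b0 + 0.5 * ss + k0 * n * (xbar - mu0) ** 2 / (2.0 * kn)
    lm = (
        gammaln(an)
        - gammaln(a0)
        + a0 * np.log(b0)
        - an * np.log(bn)
        + 0.5 * (np.log(k0) - np.log(kn))
        - (n / 2.0) * np.log(2.0 * np.pi)
    )
    return lm.sum(axis=1)


def h1_log_marginal(data: np.ndarray, prior: ExpressionPrior) -> float:
    """Log marginal of a set of cells as one cluster (hypothesis H1).

    ``data`` is an (n, G) slice of the expression matrix; the model is
    the diagonal Normal-Gamma conjugate model, integrated exactly.
    """
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("h1_log_marginal needs at least one cell")
    return float(
        _h1_from_suffstats(
            np.array([X.shape[0]]), X.sum(axis=0)[None, :], (X**2).sum(axis=0)[None, :], prior
        )[0]
    )


class ExpressionScorer:
    """Reusable BHC scorer binding an expression matrix and a prior.

    Scoring is a full re-evaluation per call: sufficient statistics
    are accumulated bottom-up, the H1 marginals of all nodes are
    computed in one vectorized pass, and the pi/d/L recursion runs as
    a cheap scalar loop.
    """

    def __init__(self, Y: ExpressionMatrix | pd.DataFrame, prior: ExpressionPrior | None = None):
        if isinstance(Y, pd.DataFrame):
            Y = ExpressionMatrix(Y.to_numpy(dtype=float), [str(i) for i in Y.index], [str(c) for c in Y.columns])
        self.Y = Y
        self.prior = prior if prior is not None else ExpressionPrior.empirical(Y.Y)
        self._row = {c: i for i, c in enumerate(Y.cell_ids)}
        self._X = Y.Y
        self._X2 = Y.Y**2

    def score(self, tree: LineageTree) -> tuple[float, dict[int, NodeStats]]:
        nodes = list(tree.postorder())
        V = len(nodes)
        G = self._X.shape[1]
        index = {id(n): i for i, n in enumerate(nodes)}
        cnt = np.zeros(V)
        s1 = np.zeros((V, G))
        s2 = np.zeros((V, G))
        for i, node in enumerate(nodes):
            if node.is_leaf:
                if node.name not in self._row:
                    raise ValueError(f"leaf {node.name!r} has no expression row")
                r = self._row[node.name]
                cnt[i] = 1.0
                s1[i] = self._X[r]
                s2[i] = self._X2[r]
            else:
                if len(node.children) != 2:
                    raise ValueError("BHC scoring requires a strictly binary tree")
                iu, iw = (index[id(c)] for c in node.children)
                cnt[i] = cnt[iu] + cnt[iw]
                s1[i] = s1[iu] + s1[iw]
                s2[i] = s2[iu] + s2[iw]

        log_h1 = _h1_from_suffstats(cnt, s1, s2, self.prior)
        log_alpha = np.log(self.prior.alpha)

        stats: dict[int, NodeStats] = {}
        for i, node in enumerate(nodes):
            if node.is_leaf:
                stats[id(node)] = NodeStats(
                    n=1,
                    log_d=log_alpha,
                    log_pi=0.0,
                    log_h1=log_h1[i],
                    log_L=log_h1[i],
                    log_one_minus_pi=-np.inf,
                )
            else:
                su, sw = (stats[id(c)] for c in node.children)
                n_v = su.n + sw.n
                lg = log_alpha + gammaln(n_v)
                log_d = np.logaddexp(lg, su.log_d + sw.log_d)
                log_pi = lg - log_d
                log_1mpi = su.log_d + sw.log_d - log_d
                log_L = np.logaddexp(log_pi + log_h1[i], log_1mpi + su.log_L + sw.log_L)
                stats[id(node)] = NodeStats(
                    n=n_v,
                    log_d=float(log_d),
                    log_pi=float(log_pi),
                    log_h1=float(log_h1[i]),
                    log_L=float(log_L),
                    log_one_minus_pi=float(log_1mpi),
                )
        return stats[id(tree.root)].log_L, stats


def bhc_log_marginal(
    tree: LineageTree,
    Y: ExpressionMatrix | pd.DataFrame,
    prior: ExpressionPrior | None = None,
) -> tuple[float, dict[int, NodeStats]]:
    """Tree expression log-likelihood (root BHC marginal) and all NodeStats."""
    return ExpressionScorer(Y, prior).score(tree)


def annotate_stats(tree: LineageTree, stats: dict[int, NodeStats]) -> None:
    """Write BHC quantities into each node's annotation dict."""
    for node in tree.preorder():
        st = stats[id(node)]
        node.annot.update(
            n=st.n, log_d=st.log_d, log_pi=st.log_pi, log_h1=st.log_h1, log_L=st.log_L
        )
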