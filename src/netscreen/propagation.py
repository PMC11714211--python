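"""Seed-gene module identification by personalized network propagation.

A personalized PageRank-style walk is run from the seed gene(s): at each
step the walker follows a random interaction with probability ``damping``
and teleports back to the personalization vector with probability
``1 - damping``.  The stationary distribution scores every gene's network
influence from the seed; the top-k genes form the seed-associated module
that the drug screens are run against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from sklearn.metrics import roc_auc_score

from netscreen._linalg import column_stochastic, restart_walk
from netscreen.interactome import GeneSet, InteractomeGraph

__all__ = [
    "PropagationConfig",
    "PropagationScores",
    "GeneModule",
    "personalized_propagation",
    "extract_module",
    "evaluate_module_auc",
]

#: Module size used throughout: the screens take the 200 highest-influence
#: genes as the seed-associated module.
DEFAULT_MODULE_SIZE = 200


@dataclass
class PropagationConfig:
    """Parameters of the personalized propagation.

    ``damping`` is the probability of following an edge (the walk restarts
    to the personalization vector with probability ``1 - damping``);
    0.85 is the conventional default.  ``personalization`` maps genes to
    nonnegative restart weights -- a single seed gene gets weight 1 and every
    other gene 0.  Uniform personalization recovers the classic global
    ranking with a uniform ``(1-d)/n`` teleport.
    """

    personalization: Mapping[str, float]
    damping: float = 0.85
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.damping < 1.0:
            raise ValueError(f"damping must be in (0,1), got {self.damping}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    @classmethod
    def for_seed(cls, seed: str | Iterable[str], **kwargs) -> "PropagationConfig":
        seeds = [seed] if isinstance(seed, str) else list(seed)
        return cls(personalization={g: 1.0 for g in seeds}, **kwargs)


class PropagationScores(dict):
    """Node -> influence score map with convergence metadata."""

    converged: bool = True
    n_iter: int = 0


@dataclass
class GeneModule:
    """Ranked seed-associated gene module.

    ``members`` are the top-k genes by influence score, sorted by descending
    score with lexicographic tie-break; ``scores`` keeps the full score map
    (summing to 1) so the module can be re-ranked or evaluated against
    benchmarks.
    """

    seed: tuple[str, ...]
    scores: dict[str, float]
    members: list[str]
    k: int

    @property
    def gene_set(self) -> GeneSet:
        return GeneSet("module", self.members)


def personalized_propagation(
    graph: InteractomeGraph, config: PropagationConfig
) -> PropagationScores:
    """Stationary influence scores of the personalized walk.

    Scores are nonnegative and sum to 1.  Convergence is declared when the
    L1 change between iterates drops below ``config.tol``; hitting
    ``max_iter`` first raises a warning and sets ``converged=False`` on the
    returned map.  The fixed point is unique for damping < 1, so the result
    is independent of node insertion order.
    """
    weights = np.zeros(graph.number_of_nodes())
    found = False
    for gene, w in config.personalization.items():
        if w < 0:
            raise ValueError(f"negative personalization weight for {gene}")
        if gene in graph and w > 0:
            weights[graph.index_of([gene])[0]] = w
            found = True
    if not found or weights.sum() == 0:
        raise ValueError(
            "personalization is all-zero on the graph: no positive-weight "
            "gene is a graph node"
        )
    p0 = weights / weights.sum()
    W = column_stochastic(graph.adjacency)
    res = restart_walk(
        W, p0, restart=1.0 - config.damping, tol=config.tol, max_iter=config.max_iter
    )
    if not res.converged:
        warnings.warn(
            f"propagation did not converge in {config.max_iter} iterations",
            RuntimeWarning,
        )
    scores = PropagationScores(
        (v, float(res.p[i])) for i, v in enumerate(graph.nodes)
    )
    scores.converged = res.converged
    scores.n_iter = res.n_iter
    return scores


def extract_module(
    scores: Mapping[str, float],
    k: int = DEFAULT_MODULE_SIZE,
    seed: str | Iterable[str] | None = None,
    exclude_seed: bool = True,
) -> GeneModule:
    """Top-k genes by influence score.

    Ties at the boundary break lexicographically on the gene symbol, so the
    module is deterministic.  The seed gene(s) are excluded from membership
    by default (the module is the seed's *associated* genes) but always stay
    in the score map.  ``k`` larger than the number of candidates returns
    all of them with a warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seeds: tuple[str, ...] = ()
    if seed is not None:
        seeds = (seed,) if isinstance(seed, str) else tuple(seed)
    candidates = scores
    if exclude_seed and seeds:
        candidates = {g: s for g, s in scores.items() if g not in seeds}
    if k > len(candidates):
        warnings.warn(
            f"k={k} exceeds the {len(candidates)} scored genes; returning all",
            RuntimeWarning,
        )
    ranked = sorted(candidates.items(), key=lambda kv: (-kv[1], kv[0]))
    members = [g for g, _ in ranked[: min(k, len(ranked))]]
    return GeneModule(seed=seeds, scores=dict(scores), members=members, k=k)


def evaluate_module_auc(scores: Mapping[str, float], benchmark: GeneSet) -> float:
    """AUC of the influence-score ranking against a benchmark gene set.

    Ties are averaged (Mann-Whitney formulation).  The benchmark is first
    restricted to scored genes and must then be a nonempty proper subset.
    """
    genes = sorted(scores)
    labels = np.array([g in benchmark.members for g in genes], dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("benchmark has no overlap with the scored genes")
    if n_pos == len(genes):
        raise ValueError("benchmark covers every scored gene; AUC undefined")
    values = np.array([scores[g] for g in genes], dtype=float)
    return float(roc_auc_score(labels, values))
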