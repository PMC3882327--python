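"""Graph-based (Wang) semantic similarity over an is_a ontology.

Each term's semantic profile is the set of its is_a ancestors with
contribution S-values decaying by a fixed edge weight (0.8) per
step, taking the best (max) path when several exist:

    S_A(A) = 1
    S_A(t) = max{ w * S_A(c) : c is a child of t on a path from A }

The similarity of two terms is the sum of both profiles over their
shared ancestors divided by the sum of the full profiles.  Two
genes' term sets are combined by best-match average (BMA).  The
result is symmetric and equals 1 for identical non-empty term sets.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import networkx as nx

from .datatypes import OntologyBundle

log = logging.getLogger(__name__)

IS_A_WEIGHT = 0.8
DEFAULT_NAMESPACE = "biological_process"


class SemanticSimilarity:
    """Wang-style term and gene similarity with per-instance caching."""

    def __init__(
        self,
        ontology: OntologyBundle,
        namespace: str | None = DEFAULT_NAMESPACE,
        weight: float = IS_A_WEIGHT,
    ) -> None:
        self.ontology = ontology
        self.namespace = namespace
        self.weight = weight
        self._svalues = lru_cache(maxsize=None)(self._compute_svalues)
        self._term_sim = lru_cache(maxsize=None)(self._compute_term_sim)

    # -- term level ---------------------------------------------------------

    def _compute_svalues(self, term: str) -> dict[str, float]:
        """S-value of every ancestor of ``term`` (child->parent DAG walk)."""
        dag = self.ontology.dag
        closure = {term} | nx.descendants(dag, term)
        sub = dag.subgraph(closure)
        s = {term: 1.0}
        # topological order of the closure puts children before parents
        for node in nx.topological_sort(sub):
            if node == term:
                continue
            s[node] = max(
                self.weight * s[child]
                for child in sub.predecessors(node)
                if child in s
            )
        return s

    def _compute_term_sim(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        sa, sb = self._svalues(a), self._svalues(b)
        common = set(sa) & set(sb)
        if not common:
            return 0.0
        num = sum(sa[t] + sb[t] for t in common)
        den = sum(sa.values()) + sum(sb.values())
        return num / den

    def term_similarity(self, a: str, b: str) -> float:
        """Similarity of two terms in [0, 1]; symmetric."""
        key = (a, b) if a <= b else (b, a)
        return self._term_sim(*key)

    # -- gene level ---------------------------------------------------------

    def _gene_terms(self, gene: str) -> frozenset[str]:
        if self.namespace is None:
            return frozenset(self.ontology.gene_terms.get(gene, set()))
        return frozenset(self.ontology.terms_in_namespace(gene, self.namespace))

    def gene_similarity(self, gene_a: str, gene_b: str) -> float:
        """Best-match-average similarity of two genes' term sets.

        Returns 0 (with a warning) when either gene has no term in
        the configured namespace.
        """
        ta, tb = self._gene_terms(gene_a), self._gene_terms(gene_b)
        if not ta or not tb:
            log.debug(
                "no %s terms for %s; similarity 0",
                self.namespace,
                gene_a if not ta else gene_b,
            )
            return 0.0
        best_a = [max(self.term_similarity(t, u) for u in tb) for t in ta]
        best_b = [max(self.term_similarity(t, u) for u in ta) for t in tb]
        return (sum(best_a) + sum(best_b)) / (len(ta) + len(tb))
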