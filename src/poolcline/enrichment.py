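"""GO-term over-representation with the elim algorithm.

Terms are processed from most specific to most general; whenever a term
tests significant its current genes are removed from all its ancestors'
annotation sets before those are tested, decorrelating the is_a DAG.
Each test is a one-sided (over-representation) Fisher exact test, i.e.
the hypergeometric upper tail, against the universe of all genes with at
least one GO annotation.  Terms annotated with three or fewer genes are
not tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import OntologyGraph


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    namespace: str
    annotated: int
    significant: int
    p_elim: float
    p_classic: float
    genes: tuple


def propagate_annotations(direct: dict, ontology: OntologyGraph) -> dict:
    """True-path rule: term -> set of genes annotated to it or any
    descendant.  Idempotent; genes are never duplicated within a term."""
    term_genes: dict[str, set] = {t: set() for t in ontology.graph.nodes}
    for gene, terms in direct.items():
        for t in terms:
            if t not in term_genes:
                continue
            term_genes[t].add(gene)
            for anc in ontology.ancestors(t):
                term_genes[anc].add(gene)
    return term_genes


def _depths(graph: nx.DiGraph) -> dict:
    """Longest-path depth from each node up to a root (edges child->parent)."""
    depth: dict[str, int] = {}
    for node in nx.topological_sort(graph.reverse()):
        parents = list(graph.successors(node))
        depth[node] = 1 + max((depth[p] for p in parents), default=-1)
    return depth


def fisher_enrichment_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric: P(X >= k) drawing n study genes from a
    universe of N containing K term genes."""
    return float(hypergeom.sf(k - 1, N, K, n))


def elim_enrichment(
    ontology: OntologyGraph,
    study: set,
    alpha: float = 0.05,
    min_genes: int = 4,
    direct: dict | None = None,
) -> list[EnrichmentResult]:
    """elim over-representation analysis of ``study`` genes.

    The universe is every gene with >= 1 annotation.  Terms are visited
    in reverse topological order (deepest first, ties broken by term id);
    a term significant at ``alpha`` has its current genes removed from
    its ancestors before those are tested.  Terms with fewer than
    ``min_genes`` annotated genes (i.e. not more than three by default)
    are skipped.  Results are sorted by elim p-value, deterministic given
    graph and sets.
    """
    direct = direct if direct is not None else ontology.annotations
    full = propagate_annotations(direct, ontology)
    universe = set().union(*direct.values()) if direct else set()
    universe = {g for g in direct if direct[g]}
    study = set(study) & universe
    if not study:
        raise ValueError("empty study set (after restricting to the universe)")
    N, n = len(universe), len(study)
    depth = _depths(ontology.graph)
    order = sorted(full, key=lambda t: (-depth[t], t))
    current = {t: set(g) for t, g in full.items()}
    results = []
    for term in order:
        genes_now = current[term]
        classic_genes = full[term]
        p_classic = (
            fisher_enrichment_p(len(classic_genes & study), len(classic_genes), n, N)
            if classic_genes
            else 1.0
        )
        if len(genes_now) < min_genes:
            continue
        k = len(genes_now & study)
        p = fisher_enrichment_p(k, len(genes_now), n, N)
        node = ontology.graph.nodes[term]
        results.append(
            EnrichmentResult(
                term=term,
                name=node.get("name", term),
                namespace=node.get("namespace", ""),
                annotated=len(genes_now),
                significant=k,
                p_elim=p,
                p_classic=p_classic,
                genes=tuple(sorted(genes_now & study)),
            )
        )
        if p < alpha:
            for anc in ontology.ancestors(term):
                current[anc] -= genes_now
    results.sort(key=lambda r: (r.p_elim, r.term))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """TSV-ready table: term, name, annotated, significant, frequency of
    study genes in the term, and log10 elim p."""
    rows = [
        dict(
            term=r.term,
            name=r.name,
            namespace=r.namespace,
            annotated=r.annotated,
            significant=r.significant,
            frequency=round(100.0 * r.significant / r.annotated, 2),
            log10_p=round(float(np.log10(r.p_elim)), 2) if r.p_elim > 0 else -np.inf,
            p_classic=r.p_classic,
        )
        for r in results
    ]
    return pd.DataFrame(rows)
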