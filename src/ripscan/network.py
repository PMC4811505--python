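"""Network enrichment analysis (NEA) by crossing-edge counts.

Connectivity between a query gene set (AGS) and a pathway gene set (FGS) in
a global interaction network is quantified as the number of network edges
with one endpoint in each set. The null expectation under random wiring that
preserves node degrees is

    E[links] = sum_{i in AGS} sum_{j in FGS, j != i} d_i d_j / (2E)

with pairs inside the AGS/FGS overlap counted once, and the score is the
normal deviate z = (observed - expected) / sqrt(expected) with a one-sided
upper-tail p. A permutation mode replaces the analytic p by the empirical
tail over degree-preserving edge rewirings. Batch scoring across pathways
applies Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import norm

from .enrichment import adjust_bh
from .simulate import GeneSet

logger = logging.getLogger(__name__)


@dataclass
class NEAResult:
    pathway: str
    observed_links: int
    expected_links: float
    z: float
    p: float
    adj_p: float = float("nan")
    n_permutations: int = 0


def load_network(
    edges: list[tuple[str, str, float]], confidence_cutoff: float = 0.5
) -> nx.Graph:
    """Build the interaction graph from (nodeA, nodeB, confidence) triples.

    Edges below the cutoff are dropped (the cutoff itself is kept — the rule
    is "cutoff or higher"); self-loops and duplicate edges are removed with
    logged counts. Confidence is stored as an attribute but not used as a
    weight downstream.
    """
    g = nx.Graph()
    n_low = n_self = n_dup = 0
    for u, v, conf in edges:
        if conf < confidence_cutoff:
            n_low += 1
            continue
        if u == v:
            n_self += 1
            continue
        if g.has_edge(u, v):
            n_dup += 1
            continue
        g.add_edge(u, v, confidence=float(conf))
    if n_low or n_self or n_dup:
        logger.info(
            "load_network: dropped %d below-cutoff, %d self-loop, %d duplicate edges",
            n_low, n_self, n_dup,
        )
    return g


def observed_links(ags: GeneSet, fgs: GeneSet, net: nx.Graph) -> int:
    """Edges with one endpoint in each set; both-in-overlap edges count once."""
    a, f = ags.genes, fgs.genes
    n = 0
    for u, v in net.edges:
        if (u in a and v in f) or (v in a and u in f):
            n += 1
    return n


def expected_links(ags: GeneSet, fgs: GeneSet, net: nx.Graph) -> float:
    """Degree-product null expectation of crossing links.

    Genes absent from the network contribute zero degree. Unordered pairs
    are counted once, matching the observed-links convention.
    """
    m = net.number_of_edges()
    if m == 0:
        return 0.0
    deg = dict(net.degree())
    d = lambda x: deg.get(x, 0)
    a, f = ags.genes, fgs.genes
    overlap = a & f
    d_a = sum(d(x) for x in a)
    d_f = sum(d(x) for x in f)
    d_o = sum(d(x) for x in overlap)
    sq_o = sum(d(x) ** 2 for x in overlap)
    # ordered pairs (i in A, j in F, i != j), then collapse the doubly
    # counted both-in-overlap pairs to single counting
    total = d_a * d_f - sq_o - (d_o**2 - sq_o) / 2.0
    return total / (2.0 * m)


def nea_score(
    ags: GeneSet,
    fgs: GeneSet,
    net: nx.Graph,
    n_permutations: int = 0,
    seed: int | None = None,
) -> NEAResult:
    """Score AGS-FGS connectivity against the degree-product null.

    With ``n_permutations`` > 0 the analytic normal p is replaced by the
    empirical upper tail over degree-preserving edge rewirings
    (double-edge swaps), p = (1 + #{perm >= observed}) / (n + 1).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    obs = observed_links(ags, fgs, net)
    exp = expected_links(ags, fgs, net)
    if exp > 0:
        z = (obs - exp) / np.sqrt(exp)
        p = float(norm.sf(z))
    elif obs == 0:
        z, p = 0.0, 0.5
    else:
        z, p = float("inf"), 0.0

    if n_permutations > 0:
        rng = np.random.RandomState(seed)
        hits = 0
        m = net.number_of_edges()
        for _ in range(n_permutations):
            perm = net.copy()
            if m > 1:
                nx.double_edge_swap(perm, nswap=2 * m, max_tries=40 * m, seed=rng)
            if observed_links(ags, fgs, perm) >= obs:
                hits += 1
        p = (1.0 + hits) / (n_permutations + 1.0)
    return NEAResult(
        pathway=fgs.name,
        observed_links=obs,
        expected_links=exp,
        z=float(z),
        p=p,
        n_permutations=n_permutations,
    )


def nea_batch(
    ags: GeneSet,
    pathways: list[GeneSet],
    net: nx.Graph,
    n_permutations: int = 0,
    seed: int | None = None,
) -> list[NEAResult]:
    """Score every pathway and BH-adjust across them; ranked by p then z."""
    if not pathways:
        raise ValueError("need at least one pathway")
    results = [
        nea_score(ags, fgs, net, n_permutations=n_permutations, seed=seed)
        for fgs in pathways
    ]
    adj = adjust_bh([r.p for r in results])
    for r, a in zip(results, adj):
        r.adj_p = float(a)
    results.sort(key=lambda r: (r.p, -r.z, r.pathway))
    return results
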