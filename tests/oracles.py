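"""Independent reference computations used to check the implementation."""

from decimal import Decimal, getcontext
from typing import Dict, List, Sequence, Tuple


def poisson_tail_decimal(k: int, lam: float, digits: int = 50) -> float:
    """P(X >= k) for X ~ Poisson(lam) by forward tail summation in Decimal.

    Sums pmf terms from k upward with a term recurrence until the running
    term is negligible relative to the accumulated sum; independent of any
    library survival function.
    """
    if k < 0 or lam < 0:
        raise ValueError("k and lambda must be non-negative")
    if k == 0:
        return 1.0
    if lam == 0:
        return 0.0
    getcontext().prec = digits
    lam_d = Decimal(repr(lam))
    # log term_k = -lam + k*ln(lam) - ln(k!)
    ln_fact = sum(Decimal(i).ln() for i in range(1, k + 1))
    log_term = -lam_d + Decimal(k) * lam_d.ln() - ln_fact
    term = log_term.exp()
    total = Decimal(0)
    i = k
    while True:
        total += term
        i += 1
        term = term * lam_d / Decimal(i)
        if term < total * Decimal("1e-40"):
            break
    return float(total)


def brute_force_clonal_count(
    records: Sequence[Tuple[str, int, str]], cap: int
) -> int:
    """Sum of min(multiplicity, cap) over distinct (chrom, pos, strand)."""
    from collections import Counter

    counts = Counter(records)
    return sum(min(n, cap) for n in counts.values())


def max_bipartite_matching_size(
    summits_a: Sequence[int], summits_b: Sequence[int], max_dist: int
) -> int:
    """Optimal number of replicate-peak pairs within max_dist (one chromosome).

    Exhaustive maximum bipartite matching via networkx; the oracle for the
    greedy nearest-summit heuristic.
    """
    import networkx as nx

    graph = nx.Graph()
    a_nodes = [("a", i) for i in range(len(summits_a))]
    b_nodes = [("b", j) for j in range(len(summits_b))]
    graph.add_nodes_from(a_nodes, bipartite=0)
    graph.add_nodes_from(b_nodes, bipartite=1)
    for i, sa in enumerate(summits_a):
        for j, sb in enumerate(summits_b):
            if abs(sa - sb) <= max_dist:
                graph.add_edge(("a", i), ("b", j))
    matching = nx.bipartite.maximum_matching(graph, top_nodes=a_nodes)
    return sum(1 for node in matching if node[0] == "a")


def enumerate_pwm_pvalues(
    probs, background, resolution: float
) -> Dict[int, float]:
    """Exact P(score >= s) by enumerating all 4^width words.

    Returns a map from every achievable integer (discretized) score to its
    survival probability under the background.
    """
    import itertools

    import numpy as np

    probs = np.asarray(probs, dtype=float)
    background = np.asarray(background, dtype=float)
    width = probs.shape[0]
    int_scores = np.rint(np.log2(probs / background) / resolution).astype(int)
    weights: Dict[int, float] = {}
    for word in itertools.product(range(4), repeat=width):
        s = int(sum(int_scores[i, b] for i, b in enumerate(word)))
        w = float(np.prod([background[b] for b in word]))
        weights[s] = weights.get(s, 0.0) + w
    out: Dict[int, float] = {}
    running = 0.0
    for s in sorted(weights, reverse=True):
        running += weights[s]
        out[s] = running
    return out


def edit_distance(a: str, b: str) -> int:
    import edlib

    return edlib.align(a, b)["editDistance"]
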