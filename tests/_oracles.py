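"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the motif oracle walks
characters per candidate start and enumerates loop tuples lazily; the
Fisher oracle enumerates the full hypergeometric support with exact
integers; the common-peak oracle builds an explicit interval-overlap graph.
"""
from math import comb
from typing import List, Optional, Tuple

import networkx as nx


def oracle_scan_spans(seq: str, run_len: int, n_runs: int, loop_min: int,
                      loop_max: int) -> List[Tuple[int, int]]:
    """Leftmost lazy non-overlapping PG4 matches on one strand, as spans."""
    L = len(seq)

    def match_at(start: int) -> Optional[int]:
        if start >= L or seq[start] != "G" or (start > 0 and seq[start - 1] == "G"):
            return None

        def rec(i: int, depth: int) -> Optional[int]:
            j = i
            while j < L and seq[j] == "G":
                j += 1
            if j - i < run_len:
                return None
            if depth == n_runs:
                return j
            for loop_len in range(loop_min, loop_max + 1):
                if j + loop_len > L:
                    return None
                loop = seq[j : j + loop_len]
                if "N" in loop:
                    continue
                nxt = j + loop_len
                if nxt >= L or seq[nxt] != "G":
                    continue
                if seq[nxt - 1] == "G":
                    continue  # loop would end inside a G-run: tract not maximal
                end = rec(nxt, depth + 1)
                if end is not None:
                    return end
            return None

        return rec(start, 1)

    spans: List[Tuple[int, int]] = []
    pos = 0
    while pos < L:
        hit = None
        for start in range(pos, L):
            end = match_at(start)
            if end is not None:
                hit = (start, end)
                break
        if hit is None:
            break
        spans.append(hit)
        pos = hit[1]
    return spans


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration.

    Sums probabilities of all tables with the observed margins whose
    probability is <= the observed one, with a 1e-7 relative tolerance on
    the comparison, using exact integer arithmetic.
    """
    r1, r2 = a + b, c + d
    m = a + c
    n = r1 + r2
    n_obs = comb(r1, a) * comb(r2, c)
    total = 0
    for k in range(max(0, m - r2), min(r1, m) + 1):
        n_k = comb(r1, k) * comb(r2, m - k)
        if n_k * 10**7 <= n_obs * (10**7 + 1):  # n_k <= n_obs * (1 + 1e-7)
            total += n_k
    return total / comb(n, m)


def oracle_common_peaks(rep1, rep2) -> List[Tuple[str, int, int]]:
    """Connected-component min/max merge on the interval-overlap graph."""
    graph = nx.Graph()
    nodes = [("r1", p.chrom, p.start, p.end) for p in rep1] + [
        ("r2", p.chrom, p.start, p.end) for p in rep2
    ]
    for i, node in enumerate(nodes):
        graph.add_node((i, *node))
    items = list(graph.nodes)
    for i, u in enumerate(items):
        for v in items[i + 1 :]:
            if u[2] == v[2] and u[3] < v[4] and v[3] < u[4]:
                graph.add_edge(u, v)
    merged = []
    for component in nx.connected_components(graph):
        reps = {node[1] for node in component}
        if reps == {"r1", "r2"}:
            chrom = next(iter(component))[2]
            merged.append(
                (chrom, min(n[3] for n in component), max(n[4] for n in component))
            )
    return sorted(merged)
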