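"""Topological and functional characterisation of synergy networks.

Covers the power-law degree-distribution fit, average clustering
coefficient, characteristic path length, randomised baselines (degree-
preserving rewiring or a duplication growth model), hub calling,
hypergeometric disease enrichment of modules, and Pearson co-expression
classification of synergistic miRNA pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .datatypes import ExpressionMatrix, GeneList


def _as_graph(net) -> nx.Graph:
    if isinstance(net, nx.Graph):
        return net
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edges)
    return g


# ---------------------------------------------------------------------------
# enrichment

def hypergeom_pvalue(N: int, M: int, K: int, x: int) -> float:
    """P(overlap >= x) drawing K from N containing M marked, log-space stable.

    Equals 1 - sum_{i<x} C(M,i) C(N-M,K-i) / C(N,K); the upper tail of the
    hypergeometric distribution.
    """
    if not (0 <= M <= N and 0 <= K <= N):
        raise ValueError(f"need 0 <= M,K <= N, got N={N} M={M} K={K}")
    if not (max(0, K - (N - M)) <= x <= min(M, K)):
        raise ValueError(f"x={x} outside feasible overlap range for "
                         f"N={N} M={M} K={K}")
    return float(stats.hypergeom.sf(x - 1, N, M, K))


@dataclass
class EnrichmentResult:
    module_id: str
    N: int
    M: int
    K: int
    x: int
    p_value: float
    flagged: bool


def enrich_modules(modules, disease_genes: GeneList, background: GeneList,
                   alpha: float = 0.05) -> list[EnrichmentResult]:
    """Hypergeometric disease-gene enrichment per module.

    Background N is the significant miRNAs + mRNAs after selection; module
    genes (miRNAs + mRNAs) must all lie inside the background.
    """
    bg = background.members
    disease_in_bg = disease_genes.members & bg
    N, M = len(bg), len(disease_in_bg)
    out = []
    for i, mod in enumerate(modules):
        genes = set(mod.miRNAs) | set(mod.mRNAs)
        outside = genes - bg
        if outside:
            raise ValueError(f"module genes outside background: {sorted(outside)}")
        K = len(genes)
        x = len(genes & disease_in_bg)
        p = hypergeom_pvalue(N, M, K, x)
        out.append(EnrichmentResult(f"module_{i + 1}", N, M, K, x, p, p < alpha))
    return out


# ---------------------------------------------------------------------------
# topology

def power_law_fit(degree_histogram: dict[int, float]) -> tuple[float, float, float]:
    """Fit y = b x^a by least squares on log10-log10 axes; returns (a, b, R^2)."""
    pts = [(d, c) for d, c in degree_histogram.items() if d > 0 and c > 0]
    if len({d for d, _ in pts}) < 2:
        raise ValueError("need >= 2 distinct positive degrees for a power-law fit")
    if len(pts) == 2:
        warnings.warn("power-law fit on exactly 2 points: R^2 is trivially 1")
    lx = np.log10([d for d, _ in pts])
    ly = np.log10([c for _, c in pts])
    a, intercept = np.polyfit(lx, ly, 1)
    pred = a * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(a), float(10 ** intercept), float(r2)


def degree_histogram(net) -> dict[int, int]:
    g = _as_graph(net)
    hist: dict[int, int] = {}
    for _, d in g.degree():
        hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items()))


def avg_clustering(net) -> float:
    """Mean local clustering over ALL nodes; degree < 2 contributes 0."""
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return float(nx.average_clustering(g, count_zeros=True))


def avg_path_length(net) -> tuple[float, int]:
    """Mean shortest-path length over connected ordered pairs.

    Disconnected pairs are excluded; returns (mean, n_excluded_ordered_pairs).
    """
    g = _as_graph(net)
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    total, count = 0, 0
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            if src != dst:
                total += d
                count += 1
    n = g.number_of_nodes()
    excluded = n * (n - 1) - count
    if count == 0:
        raise ValueError("no connected node pairs")
    return total / count, excluded


def _duplication_graph(n_nodes: int, n_edges: int, rng: np.random.Generator
                       ) -> nx.Graph:
    """Grow a graph by node duplication with partial edge retention.

    Starts from a single edge; each new node copies the edges of a random
    existing node, keeping each with probability tuned on the fly so the
    final edge count approaches the requested one, and always attaches to
    its template so the graph stays connected-ish.
    """
    g = nx.Graph()
    g.add_edge(0, 1)
    while g.number_of_nodes() < n_nodes:
        new = g.number_of_nodes()
        template = int(rng.integers(new))
        remaining_nodes = n_nodes - new
        remaining_edges = max(n_edges - g.number_of_edges(), 1)
        target_per_node = remaining_edges / remaining_nodes
        deg = max(g.degree(template), 1)
        p_keep = min(1.0, max(0.0, (target_per_node - 1) / deg))
        g.add_node(new)
        for nbr in list(g.neighbors(template)):
            if rng.random() < p_keep:
                g.add_edge(new, nbr)
        g.add_edge(new, template)
    return g


def random_baseline(net, n_random: int, model: str = "rewire", seed: int = 0
                    ) -> dict[str, tuple[float, float]]:
    """Clustering and path-length distributions over randomised instances.

    ``rewire``: degree-preserving double-edge swaps (10 |E| attempts per
    instance).  ``duplication``: regrow a same-size graph by node duplication
    with edge retention tuned to match the edge count (approximate).
    Returns means and standard deviations over instances.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    g0 = _as_graph(net)
    rng = np.random.default_rng(seed)
    cls, pls = [], []
    for _ in range(n_random):
        if model == "rewire":
            g = g0.copy()
            nswap = 10 * g.number_of_edges()
            if g.number_of_edges() >= 2:
                try:
                    nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap,
                                        seed=int(rng.integers(2 ** 31)))
                except nx.NetworkXException:
                    pass     # too few swappable edges; keep partial rewire
        elif model == "duplication":
            g = _duplication_graph(g0.number_of_nodes(), g0.number_of_edges(),
                                   rng)
        else:
            raise ValueError(f"unknown random model {model!r}")
        cls.append(avg_clustering(g))
        pls.append(avg_path_length(g)[0])
    return {
        "clustering": (float(np.mean(cls)), float(np.std(cls))),
        "path_length": (float(np.mean(pls)), float(np.std(pls))),
    }


@dataclass
class TopologySummary:
    power_law: tuple[float, float, float] | None   # (a, b, R^2)
    avg_clustering: float
    avg_path_length: float
    path_pairs_excluded: int
    random_clustering: tuple[float, float]
    random_path_length: tuple[float, float]
    n_random: int

    def to_dict(self) -> dict:
        return {
            "power_law": (None if self.power_law is None else
                          dict(zip(("a", "b", "r_squared"), self.power_law))),
            "avg_clustering": self.avg_clustering,
            "avg_path_length": self.avg_path_length,
            "path_pairs_excluded": self.path_pairs_excluded,
            "random_clustering": {"mean": self.random_clustering[0],
                                  "sd": self.random_clustering[1]},
            "random_path_length": {"mean": self.random_path_length[0],
                                   "sd": self.random_path_length[1]},
            "n_random": self.n_random,
        }


def topology_summary(net, n_random: int = 100, model: str = "rewire",
                     seed: int = 0) -> TopologySummary:
    try:
        pl = power_law_fit(degree_histogram(net))
    except ValueError:
        pl = None
    cl = avg_clustering(net)
    pathlen, excluded = avg_path_length(net)
    rb = random_baseline(net, n_random, model, seed)
    return TopologySummary(pl, cl, pathlen, excluded,
                           rb["clustering"], rb["path_length"], n_random)


def hubs(net, fraction: float = 0.10) -> list[str]:
    """Top ceil(fraction * |V|) nodes by degree; ties by degree then id."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0,1]")
    g = _as_graph(net)
    k = math.ceil(fraction * g.number_of_nodes())
    ranked = sorted(g.degree(), key=lambda t: (-t[1], t[0]))
    return [n for n, _ in ranked[:k]]


# ---------------------------------------------------------------------------
# co-expression

@dataclass
class CoexpressionCall:
    pair: tuple[str, str]
    r: float | None
    p_value: float | None
    co_expressed: bool


def coexpression_calls(pairs, expr: ExpressionMatrix, alpha: float = 0.05
                       ) -> list[CoexpressionCall]:
    """Pearson correlation per pair; co-expressed iff r > 0 and p < alpha.

    The p-value is two-sided (t transform, n-2 df), so under independence the
    expected flag rate is alpha/2 — only the positive tail qualifies.
    """
    out = []
    for a, b in pairs:
        xa = expr.values.loc[a].to_numpy(dtype=float)
        xb = expr.values.loc[b].to_numpy(dtype=float)
        if np.std(xa) == 0 or np.std(xb) == 0:
            warnings.warn(f"zero-variance member in pair ({a}, {b})")
            out.append(CoexpressionCall((a, b), None, None, False))
            continue
        r, p = stats.pearsonr(xa, xb)
        out.append(CoexpressionCall((a, b), float(r), float(p),
                                    bool(r > 0 and p < alpha)))
    return out
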