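"""Synergistic module discovery from bicliques of the binding network.

A maximal biclique (C, D) of the significant miRNA-mRNA bipartite binding
network — every miRNA in C binds every mRNA in D, and no superset has that
property — is a candidate module.  Each candidate is refined to the subset
pair (C*, D*) maximising the aggregate cumulative joint knock-off effect of
C* over the mRNAs of D*, subject to |C*| >= 2 and |D*| >= 2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

from .config import RunConfig
from .datatypes import BindingNetwork, ExpressionMatrix
from .synergy import CandidateSet, EffectScorer


@dataclass
class Biclique:
    miRNAs: frozenset[str]
    mRNAs: frozenset[str]

    def key(self) -> tuple:
        return (tuple(sorted(self.miRNAs)), tuple(sorted(self.mRNAs)))


@dataclass
class SynergyModule:
    miRNAs: list[str]            # C*, sorted
    mRNAs: list[str]             # D*, sorted
    score: float                 # aggregate objective over D*
    per_mrna_delta: dict[str, float]
    parent: Biclique


def enumerate_maximal_bicliques(binding: BindingNetwork, min_mirnas: int = 2,
                                min_mrnas: int = 2) -> list[Biclique]:
    """Every maximal biclique meeting both size minimums, deterministic order.

    Reduction: complete each side of the bipartite graph internally; maximal
    cliques of the augmented graph are exactly the maximal bicliques (a
    clique there can only mix sides through original binding edges).
    """
    mirnas = sorted(binding.mirnas)
    mrnas = sorted(binding.mrnas)
    if not mirnas or not mrnas:
        return []
    g = nx.Graph()
    g.add_nodes_from(mirnas)
    g.add_nodes_from(mrnas)
    g.add_edges_from(binding.edges)
    g.add_edges_from(itertools.combinations(mirnas, 2))
    g.add_edges_from(itertools.combinations(mrnas, 2))
    mi_set, mr_set = set(mirnas), set(mrnas)
    out = []
    for clique in nx.find_cliques(g):
        C = frozenset(c for c in clique if c in mi_set)
        D = frozenset(c for c in clique if c in mr_set)
        if len(C) >= min_mirnas and len(D) >= min_mrnas:
            out.append(Biclique(C, D))
    out.sort(key=Biclique.key)
    return out


def _objective(deltas: dict[str, float], objective: str) -> float:
    vals = list(deltas.values())
    return min(vals) if objective == "min" else sum(vals)


def refine_module(b: Biclique, data: ExpressionMatrix,
                  averages: dict[str, float], config: RunConfig
                  ) -> SynergyModule | None:
    """(C*, D*) maximising the per-mRNA delta aggregate within the biclique.

    Exhaustive over all subset pairs with |C*| >= 2, |D*| >= 2 when
    r + l <= config.module_exhaustive_cap, else alternating greedy refinement
    (improve C* with D* fixed, then D* with C* fixed, to convergence).
    Returns None when the best objective is <= 0.
    """
    C = sorted(b.miRNAs)
    D = sorted(b.mRNAs)
    min_c = config.min_module_mirnas
    min_d = config.min_module_mrnas
    if len(C) < min_c or len(D) < min_d:
        return None

    scorers = {y: EffectScorer(CandidateSet(y, set(C)), data, averages, config)
               for y in D}

    def deltas_for(c_sub: tuple[str, ...], d_sub: tuple[str, ...]):
        return {y: scorers[y].delta(frozenset(c_sub)) for y in d_sub}

    def score(c_sub, d_sub) -> float:
        return _objective(deltas_for(c_sub, d_sub), config.module_objective)

    best: tuple[float, tuple, tuple] | None = None

    def consider(c_sub, d_sub):
        nonlocal best
        s = score(c_sub, d_sub)
        cand = (s, tuple(sorted(c_sub)), tuple(sorted(d_sub)))
        if best is None:
            best = cand
            return
        bs, bc, bd = best
        if s != bs:
            if s > bs:
                best = cand
            return
        if len(c_sub) + len(d_sub) != len(bc) + len(bd):
            if len(c_sub) + len(d_sub) < len(bc) + len(bd):
                best = cand
            return
        if (cand[1], cand[2]) < (bc, bd):
            best = cand

    if len(C) + len(D) <= config.module_exhaustive_cap:
        for rc in range(min_c, len(C) + 1):
            for c_sub in itertools.combinations(C, rc):
                for rd in range(min_d, len(D) + 1):
                    for d_sub in itertools.combinations(D, rd):
                        consider(c_sub, d_sub)
    else:
        c_cur, d_cur = tuple(C), tuple(D)
        consider(c_cur, d_cur)
        for _ in range(20):
            improved = False
            # improve C* with D* fixed: try dropping/swapping one miRNA
            for c_sub in _one_step_subsets(c_cur, C, min_c):
                if score(c_sub, d_cur) > score(c_cur, d_cur):
                    c_cur = c_sub
                    improved = True
            for d_sub in _one_step_subsets(d_cur, D, min_d):
                if score(c_cur, d_sub) > score(c_cur, d_cur):
                    d_cur = d_sub
                    improved = True
            consider(c_cur, d_cur)
            if not improved:
                break

    if best is None or best[0] <= 0:
        return None
    s, c_star, d_star = best
    return SynergyModule(list(c_star), list(d_star), s,
                         deltas_for(c_star, d_star), b)


def _one_step_subsets(current: tuple[str, ...], universe: list[str],
                      min_size: int):
    """Neighbours of a subset: remove one member, add one member, or swap."""
    cur = set(current)
    if len(cur) > min_size:
        for m in sorted(cur):
            yield tuple(sorted(cur - {m}))
    for m in universe:
        if m not in cur:
            yield tuple(sorted(cur | {m}))
            for out in sorted(cur):
                yield tuple(sorted((cur - {out}) | {m}))
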