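"""miRNA synergistic network construction.

For every significant mRNA, the miRNAs with binding evidence form a
candidate set; the subset with the maximal cumulative joint knock-off effect
on that mRNA is its synergy set, and all within-set miRNA pairs become
network edges supported by the target.  Small candidate sets are searched
exhaustively, large ones greedily.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .causal import (Cpdag, enumerate_class, estimate_cpdag, fit_dag_weights,
                     path_sum_effects)
from .config import RunConfig
from .datatypes import BindingNetwork, ExpressionMatrix


@dataclass
class CandidateSet:
    target_id: str
    miRNAs: set[str]


@dataclass
class SynergySet:
    target_id: str
    miRNAs: list[str]        # sorted
    delta: float
    search_mode: str         # "exhaustive" | "greedy"


@dataclass
class SynergyNetwork:
    nodes: set[str] = field(default_factory=set)
    # unordered pair (sorted tuple) -> supporting target mRNAs
    edges: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.edges)


def candidate_sets(binding: BindingNetwork, selected_mirnas, selected_mrnas
                   ) -> list[CandidateSet]:
    """One candidate set per selected mRNA with >= 1 selected binding miRNA."""
    mi = set(selected_mirnas)
    out = []
    for mrna in sorted(set(selected_mrnas)):
        regs = binding.regulators_of(mrna) & mi
        if regs:
            out.append(CandidateSet(mrna, regs))
    return out


class EffectScorer:
    """Scores miRNA subsets against one target via the class-multiset maximum.

    Holds the CPDAG (local to {candidates} + {target} by default) and the
    sample covariance so that repeated subset scoring reuses both.
    """

    def __init__(self, cand: CandidateSet, data: ExpressionMatrix,
                 averages: dict[str, float], config: RunConfig,
                 cpdag: Cpdag | None = None):
        self.cand = cand
        self.averages = averages
        self.config = config
        local_ids = sorted(cand.miRNAs) + [cand.target_id]
        if cpdag is None:
            sub = data.subset(local_ids)
            cpdag = estimate_cpdag(sub, config.alpha_pc)
        self.cpdag = cpdag
        df = data.values if isinstance(data, ExpressionMatrix) else data
        arr = df.loc[list(self.cpdag.nodes)].to_numpy(dtype=float)
        self.cov = pd.DataFrame(np.cov(arr), index=self.cpdag.nodes,
                                columns=self.cpdag.nodes)
        # the class and the per-DAG edge weights do not depend on which
        # subset is intervened on, so both are computed once per target
        dags, self.truncated = enumerate_class(
            self.cpdag, self.config.equivalence_cap, strict=False)
        self._fits = [(d, fit_dag_weights(d, self.cov)) for d in dags]
        self._cache: dict[frozenset, float] = {}

    def delta(self, subset: frozenset) -> float:
        key = frozenset(subset)
        if key not in self._cache:
            X = sorted(subset)
            missing = [x for x in X if x not in self.averages]
            if missing:
                raise ValueError(f"no average expression for: {missing}")
            knock = np.array([0.0 - self.averages[x] for x in X])
            deltas = []
            for dag, B in self._fits:
                ef = path_sum_effects(dag.nodes, B, X,
                                      [self.cand.target_id])
                deltas.append(float(knock @ ef[:, 0]))
            best = (max(deltas, key=abs) if self.config.use_abs_delta
                    else max(deltas))
            self._cache[key] = best
        return self._cache[key]


def _better(delta_a: float, set_a: frozenset,
            delta_b: float | None, set_b: frozenset | None) -> bool:
    """Tie-breaks: larger delta, then smaller subset, then lexicographic."""
    if set_b is None:
        return True
    if delta_a != delta_b:
        return delta_a > delta_b
    if len(set_a) != len(set_b):
        return len(set_a) < len(set_b)
    return sorted(set_a) < sorted(set_b)


def find_max_synergy_set(cand: CandidateSet, data: ExpressionMatrix,
                         averages: dict[str, float], config: RunConfig,
                         scorer: EffectScorer | None = None
                         ) -> SynergySet | None:
    """Subset of the candidates maximising the cumulative joint effect.

    Exhaustive over all non-empty subsets when |A| <= subset_cap, greedy
    forward selection otherwise.  Returns None when the best delta is <= 0
    (knocking off genuine repressors should raise the target).
    """
    if not cand.miRNAs:
        raise ValueError("empty candidate set")
    if scorer is None:
        scorer = EffectScorer(cand, data, averages, config)
    members = sorted(cand.miRNAs)
    if len(members) <= config.subset_cap:
        mode = "exhaustive"
        best_set, best_delta = None, None
        for r in range(1, len(members) + 1):
            for combo in itertools.combinations(members, r):
                s = frozenset(combo)
                d = scorer.delta(s)
                if _better(d, s, best_delta, best_set):
                    best_set, best_delta = s, d
    else:
        mode = "greedy"
        current: frozenset = frozenset()
        current_delta = 0.0
        while True:
            best_add, best_d = None, current_delta
            for m in members:
                if m in current:
                    continue
                d = scorer.delta(current | {m})
                if d > best_d or (best_add is not None and d == best_d
                                  and m < best_add):
                    best_add, best_d = m, d
            if best_add is None:
                break
            current, current_delta = current | {best_add}, best_d
        best_set, best_delta = (current, current_delta) if current else (None, None)
    if best_set is None or best_delta is None or best_delta <= 0:
        return None
    return SynergySet(cand.target_id, sorted(best_set), best_delta, mode)


def build_network(sets: list[SynergySet]) -> SynergyNetwork:
    """Union of within-set miRNA pairs; supports merged across targets."""
    net = SynergyNetwork()
    for s in sets:
        if s is None or len(s.miRNAs) < 2:
            continue
        for a, b in itertools.combinations(sorted(s.miRNAs), 2):
            net.nodes.update((a, b))
            net.edges.setdefault((a, b), set()).add(s.target_id)
    return net


def sequence_level_pairs(binding: BindingNetwork,
                         mirnas=None) -> set[tuple[str, str]]:
    """All unordered miRNA pairs sharing >= 1 binding target (sequence level)."""
    allowed = set(mirnas) if mirnas is not None else None
    by_target: dict[str, set[str]] = {}
    for u, v in binding.edges:
        if allowed is None or u in allowed:
            by_target.setdefault(v, set()).add(u)
    pairs: set[tuple[str, str]] = set()
    for regs in by_target.values():
        for a, b in itertools.combinations(sorted(regs), 2):
            pairs.add((a, b))
    return pairs


@dataclass
class NetworkComparison:
    both: set[tuple[str, str]]
    sequence_only: set[tuple[str, str]]
    expression_only: set[tuple[str, str]]

    def to_dict(self) -> dict:
        return {
            "n_both": len(self.both),
            "n_sequence_only": len(self.sequence_only),
            "n_expression_only": len(self.expression_only),
            "both": sorted(map(list, self.both)),
            "sequence_only": sorted(map(list, self.sequence_only)),
            "expression_only": sorted(map(list, self.expression_only)),
        }


def compare_networks(seq_pairs: set[tuple[str, str]],
                     net: SynergyNetwork) -> NetworkComparison:
    expr_pairs = net.pairs
    return NetworkComparison(both=seq_pairs & expr_pairs,
                             sequence_only=seq_pairs - expr_pairs,
                             expression_only=expr_pairs - seq_pairs)
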