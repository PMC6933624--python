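"""Multiple-intervention causal effect estimation from observational data.

The workflow mirrors intervention calculus for Markov equivalence classes
(IDA and its joint-intervention generalisation): estimate a CPDAG with the
order-independent ("stable") PC algorithm using Gaussian conditional-
independence tests, enumerate the DAGs of the equivalence class, and for
each DAG compute the matrix of joint total effects of an intervened miRNA
set X on target mRNAs Y by severing the edges into X and summing fitted
path coefficients.  The per-class multiset of cumulative knock-off effects
is reduced by taking its maximum.

All graphs are over opaque string node ids.  A DAG is a frozen edge set plus
a node tuple; a CPDAG additionally carries undirected edges as frozensets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix


# ---------------------------------------------------------------------------
# graph containers

@dataclass(frozen=True)
class Dag:
    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if _has_cycle(self.nodes, self.edges):
            raise ValueError("edge set contains a directed cycle")

    def parents(self, v: str) -> list[str]:
        return sorted(u for (u, w) in self.edges if w == v)


@dataclass
class Cpdag:
    """Completed partially directed acyclic graph (equivalence-class summary)."""

    nodes: tuple[str, ...]
    directed: set[tuple[str, str]] = field(default_factory=set)
    undirected: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        d_pairs = {frozenset(e) for e in self.directed}
        if d_pairs & self.undirected:
            raise ValueError("an edge cannot be both directed and undirected")
        if _has_cycle(self.nodes, self.directed):
            raise ValueError("directed part contains a cycle")

    def skeleton(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.directed} | set(self.undirected)

    def adjacent(self, v: str) -> set[str]:
        out = {b for (a, b) in self.directed if a == v}
        out |= {a for (a, b) in self.directed if b == v}
        for e in self.undirected:
            if v in e:
                out |= set(e) - {v}
        return out


def _has_cycle(nodes, edges) -> bool:
    order = {n: i for i, n in enumerate(nodes)}
    adj: dict[str, list[str]] = {n: [] for n in nodes}
    for u, v in edges:
        adj[u].append(v)
    state = {n: 0 for n in nodes}   # 0 unseen, 1 on stack, 2 done

    def visit(n: str) -> bool:
        state[n] = 1
        for m in adj[n]:
            if state[m] == 1 or (state[m] == 0 and visit(m)):
                return True
        state[n] = 2
        return False

    return any(state[n] == 0 and visit(n) for n in sorted(nodes, key=order.get))


def v_structures(nodes, edges, skeleton=None) -> set[tuple[str, str, str]]:
    """Unshielded colliders (a, c, b) with a->c<-b, a-b non-adjacent, a < b.

    ``skeleton`` overrides the adjacency set used for the unshielded check
    (needed when ``edges`` is only the directed part of a partially directed
    graph).
    """
    skel = skeleton if skeleton is not None else {frozenset(e) for e in edges}
    into: dict[str, list[str]] = {}
    for u, v in edges:
        into.setdefault(v, []).append(u)
    out = set()
    for c, pars in into.items():
        for a, b in itertools.combinations(sorted(pars), 2):
            if frozenset((a, b)) not in skel:
                out.add((a, c, b))
    return out


# ---------------------------------------------------------------------------
# conditional independence: Fisher-z on partial correlations

def _fisher_z_pvalue(corr: np.ndarray, n: int, i: int, j: int,
                     S: tuple[int, ...]) -> float:
    """Two-sided p for zero partial correlation of i,j given S (indices)."""
    idx = [i, j, *S]
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
        r = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation submatrix; treating as independent")
        return 1.0
    if not np.isfinite(r):
        warnings.warn("undefined partial correlation; treating as independent")
        return 1.0
    r = float(np.clip(r, -0.9999999, 0.9999999))
    dof = n - len(S) - 3
    if dof <= 0:
        return 1.0
    z = 0.5 * np.log1p(2 * r / (1 - r)) * np.sqrt(dof)
    return float(2.0 * stats.norm.sf(abs(z)))


def estimate_cpdag(data: ExpressionMatrix | pd.DataFrame,
                   alpha: float = 0.05, max_cond: int | None = None) -> Cpdag:
    """PC-stable with Gaussian CI tests, v-structure orientation, Meek closure.

    ``data`` is entities x samples; each entity is one variable.  The stable
    variant removes edges level-by-level against an adjacency snapshot, so
    the result does not depend on variable order.
    """
    df = data.values if isinstance(data, ExpressionMatrix) else data
    nodes = tuple(df.index)
    n = df.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    X = df.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values present")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")     # constant rows yield NaN corr
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)

    p = len(nodes)
    adj: dict[int, set[int]] = {i: set(range(p)) - {i} for i in range(p)}
    sepset: dict[frozenset[int], set[int]] = {}
    level = 0
    limit = max_cond if max_cond is not None else p - 2
    while level <= limit and any(len(a) > level for a in adj.values()):
        snapshot = {i: sorted(a) for i, a in adj.items()}
        for i in range(p):
            for j in snapshot[i]:
                if j not in adj[i] or i > j:
                    continue
                removed = False
                for base in (snapshot[i], snapshot[j]):
                    cands = [k for k in base if k not in (i, j)]
                    for S in itertools.combinations(cands, level):
                        if _fisher_z_pvalue(corr, n, i, j, S) > alpha:
                            adj[i].discard(j)
                            adj[j].discard(i)
                            sepset[frozenset((i, j))] = set(S)
                            removed = True
                            break
                    if removed:
                        break
        level += 1

    # orient v-structures: i - k - j with i,j non-adjacent and k not in sepset
    arrows: set[tuple[int, int]] = set()
    for k in range(p):
        nbrs = sorted(adj[k])
        for i, j in itertools.combinations(nbrs, 2):
            if j in adj[i]:
                continue
            if k not in sepset.get(frozenset((i, j)), set()):
                arrows.add((i, k))
                arrows.add((j, k))
    # conflicting double arrows fall back to undirected
    conflict = {frozenset(e) for e in arrows if (e[1], e[0]) in arrows}
    arrows = {e for e in arrows if frozenset(e) not in conflict}

    name = {i: nodes[i] for i in range(p)}
    directed = {(name[u], name[v]) for (u, v) in arrows}
    undirected = {frozenset((name[i], name[j]))
                  for i in range(p) for j in adj[i] if i < j}
    undirected -= {frozenset(e) for e in directed}
    directed, undirected = meek_closure(nodes, directed, undirected)
    if _has_cycle(nodes, directed):        # pathological finite-sample output
        warnings.warn("orientation produced a cycle; reverting to skeleton")
        undirected |= {frozenset(e) for e in directed}
        directed = set()
    return Cpdag(nodes, directed, undirected)


# ---------------------------------------------------------------------------
# Meek orientation rules

def meek_closure(nodes, directed: set[tuple[str, str]],
                 undirected: set[frozenset[str]]):
    """Apply Meek's four orientation rules until fixpoint.

    An undirected edge a-b is oriented a->b only when the reverse would create
    a new v-structure or a directed cycle, per the standard rules R1-R4.
    """
    directed = set(directed)
    undirected = set(undirected)

    def adjacent(x, y):
        return (x, y) in directed or (y, x) in directed \
            or frozenset((x, y)) in undirected

    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=sorted):
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                orient = False
                # R1: z -> x, z not adjacent y  =>  x -> y
                for (z, w) in directed:
                    if w == x and z != y and not adjacent(z, y):
                        orient = True
                        break
                # R2: x -> z -> y  =>  x -> y
                if not orient:
                    for z in nodes:
                        if (x, z) in directed and (z, y) in directed:
                            orient = True
                            break
                # R3: x - z1 -> y, x - z2 -> y, z1,z2 non-adjacent  =>  x -> y
                if not orient:
                    zs = [z for z in nodes
                          if frozenset((x, z)) in undirected and (z, y) in directed]
                    for z1, z2 in itertools.combinations(sorted(zs), 2):
                        if not adjacent(z1, z2):
                            orient = True
                            break
                # R4: x - z, z -> w, w -> y, x - w (z,y non-adjacent) => x -> y
                if not orient:
                    for z in nodes:
                        if frozenset((x, z)) not in undirected:
                            continue
                        for w in nodes:
                            if ((z, w) in directed and (w, y) in directed
                                    and frozenset((x, w)) in undirected
                                    and not adjacent(z, y)):
                                orient = True
                                break
                        if orient:
                            break
                if orient:
                    undirected.discard(e)
                    directed.add((x, y))
                    changed = True
                    break
    return directed, undirected


def dag_to_cpdag(dag: Dag) -> Cpdag:
    """Canonical equivalence-class representative of a DAG.

    Keeps the skeleton, orients exactly the v-structure arrows, and closes
    under the Meek rules; every other edge is left undirected.
    """
    vs = v_structures(dag.nodes, dag.edges)
    directed: set[tuple[str, str]] = set()
    for a, c, b in vs:
        directed.add((a, c))
        directed.add((b, c))
    undirected = {frozenset(e) for e in dag.edges} - {frozenset(e) for e in directed}
    directed, undirected = meek_closure(dag.nodes, directed, undirected)
    return Cpdag(dag.nodes, directed, undirected)


# ---------------------------------------------------------------------------
# equivalence class enumeration

def enumerate_class(g: Cpdag, cap: int = 256,
                    strict: bool = True) -> tuple[list[Dag], bool]:
    """All consistent DAG extensions of a CPDAG, deterministically ordered.

    An extension orients every undirected edge such that the result is acyclic
    and has exactly the CPDAG's v-structures.  Depth-first search over the
    sorted undirected edges (lexicographically smaller orientation first),
    pruning cyclic partial orientations; each leaf is validated against the
    v-structure set.  Returns (dags, truncated): at most ``cap`` DAGs, with
    ``truncated`` set if the search was cut short.

    A finite-sample estimated graph may admit no consistent extension (the PC
    output need not be a valid CPDAG).  With ``strict`` the contract is an
    error; otherwise the v-structure requirement is dropped and all acyclic
    completions are returned, with a warning.
    """
    base_vs = _cpdag_v_structures(g)
    und = sorted(g.undirected, key=sorted)

    def search(check_vs: bool) -> tuple[list[Dag], bool]:
        dags: list[Dag] = []
        truncated = False

        def rec(i: int, directed: set[tuple[str, str]]) -> bool:
            nonlocal truncated
            if len(dags) >= cap:
                truncated = True
                return False
            if i == len(und):
                if not check_vs or v_structures(g.nodes, directed) == base_vs:
                    dags.append(Dag(g.nodes, frozenset(directed)))
                return True
            a, b = sorted(und[i])
            for e in ((a, b), (b, a)):
                directed.add(e)
                if not _has_cycle(g.nodes, directed):
                    if not rec(i + 1, directed):
                        directed.discard(e)
                        return False
                directed.discard(e)
            return True

        rec(0, set(g.directed))
        return dags, truncated

    dags, truncated = search(check_vs=True)
    if not dags and not truncated:
        if strict:
            raise ValueError("CPDAG admits no consistent extension")
        warnings.warn("estimated graph is not a valid CPDAG; "
                      "enumerating acyclic completions instead")
        dags, truncated = search(check_vs=False)
        if not dags and not truncated:
            raise ValueError("graph admits no acyclic completion")
    return dags, truncated


def _cpdag_v_structures(g: Cpdag) -> set[tuple[str, str, str]]:
    return v_structures(g.nodes, g.directed, skeleton=g.skeleton())


# ---------------------------------------------------------------------------
# joint effects

@dataclass
class JointEffectMatrix:
    X_ids: list[str]
    Y_ids: list[str]
    ef: np.ndarray           # p x q

    def __post_init__(self) -> None:
        self.ef = np.asarray(self.ef, dtype=float)
        if self.ef.shape != (len(self.X_ids), len(self.Y_ids)):
            raise ValueError("effect matrix shape does not match id lists")
        if not np.isfinite(self.ef).all():
            raise ValueError("non-finite effect entries")


@dataclass
class EffectMultiset:
    members: list[JointEffectMatrix]
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty effect multiset")


@dataclass
class CumulativeEffect:
    target_id: str
    miRNA_set: list[str]
    averages: dict[str, float]
    delta: float
    delta_multiset: list[float]


def fit_dag_weights(dag: Dag, cov: pd.DataFrame) -> np.ndarray:
    """Least-squares edge coefficients of each node on its DAG parents.

    Uses the sample covariance only; collinear parent sets fall back to the
    minimum-norm solution with a warning.  Returns B with B[i, j] the fitted
    coefficient on the edge nodes[i] -> nodes[j] (zero where no edge).
    """
    nodes = dag.nodes
    idx = {m: i for i, m in enumerate(nodes)}
    S = cov.loc[list(nodes), list(nodes)].to_numpy(dtype=float)
    B = np.zeros((len(nodes), len(nodes)))
    for v in nodes:
        pars = dag.parents(v)
        if not pars:
            continue
        pi = [idx[u] for u in pars]
        Spp = S[np.ix_(pi, pi)]
        Spv = S[pi, idx[v]]
        try:
            beta = np.linalg.solve(Spp, Spv)
        except np.linalg.LinAlgError:
            warnings.warn(f"collinear parents of {v!r}; minimum-norm solution")
            beta = np.linalg.lstsq(Spp, Spv, rcond=None)[0]
        for u, w in zip(pars, beta):
            B[idx[u], idx[v]] = w
    return B


def path_sum_effects(nodes, B: np.ndarray, X: list[str], Y: list[str]
                     ) -> np.ndarray:
    """ef[i, j]: path-weight sum X_i -> Y_j after severing edges into X."""
    idx = {m: i for i, m in enumerate(nodes)}
    Bs = B.copy()
    for x in X:
        Bs[:, idx[x]] = 0.0
    T = np.linalg.inv(np.eye(len(nodes)) - Bs)
    return np.array([[T[idx[x], idx[y]] for y in Y] for x in X])


def dag_joint_effects(dag: Dag, data: ExpressionMatrix | pd.DataFrame | None,
                      X: list[str], Y: list[str],
                      cov: pd.DataFrame | None = None) -> JointEffectMatrix:
    """Joint total effects of the intervened set X on targets Y under one DAG.

    Semantics: ef_ij is the change in E[Y_j] per unit increase of X_i while
    every other member of X is held fixed at its intervention value.  Either
    ``data`` or a precomputed covariance ``cov`` must be supplied.
    """
    overlap = set(X) & set(Y)
    if overlap:
        raise ValueError(f"X and Y overlap: {sorted(overlap)}")
    for v in (*X, *Y):
        if v not in dag.nodes:
            raise ValueError(f"{v!r} not a node of the DAG")
    if cov is None:
        if data is None:
            raise ValueError("need data or cov")
        df = data.values if isinstance(data, ExpressionMatrix) else data
        arr = df.loc[list(dag.nodes)].to_numpy(dtype=float)
        cov = pd.DataFrame(np.cov(arr), index=dag.nodes, columns=dag.nodes)
    B = fit_dag_weights(dag, cov)
    ef = path_sum_effects(dag.nodes, B, list(X), list(Y))
    return JointEffectMatrix(list(X), list(Y), ef)


def joint_effect_multiset(data, cpdag: Cpdag, X: list[str], Y: list[str],
                          cap: int = 256, cov: pd.DataFrame | None = None,
                          strict: bool = True) -> EffectMultiset:
    """One JointEffectMatrix per equivalence-class DAG, deterministic order."""
    if cov is None:
        df = data.values if isinstance(data, ExpressionMatrix) else data
        arr = df.loc[list(cpdag.nodes)].to_numpy(dtype=float)
        cov = pd.DataFrame(np.cov(arr), index=cpdag.nodes, columns=cpdag.nodes)
    dags, truncated = enumerate_class(cpdag, cap, strict=strict)
    members = [dag_joint_effects(d, None, X, Y, cov=cov) for d in dags]
    return EffectMultiset(members, truncated)


def cumulative_effect(ef: JointEffectMatrix, averages: dict[str, float],
                      target: str) -> float:
    """delta_j = sum_i (0 - average(X_i)) * ef_ij: simultaneous knock-off.

    ``averages`` are pre-standardisation mean expression levels; the (0 - avg)
    factor models setting each intervened miRNA to zero.
    """
    missing = [x for x in ef.X_ids if x not in averages]
    if missing:
        raise ValueError(f"no average expression for: {missing}")
    j = ef.Y_ids.index(target)
    return float(sum((0.0 - averages[x]) * ef.ef[i, j]
                     for i, x in enumerate(ef.X_ids)))


def estimated_cumulative_effect(multiset: EffectMultiset,
                                averages: dict[str, float], target: str,
                                use_abs: bool = False) -> CumulativeEffect:
    """Reduce the per-class multiset of deltas by its (signed) maximum."""
    deltas = [cumulative_effect(m, averages, target) for m in multiset.members]
    best = max(deltas, key=abs) if use_abs else max(deltas)
    X_ids = multiset.members[0].X_ids
    return CumulativeEffect(target, list(X_ids),
                            {x: averages[x] for x in X_ids}, best, deltas)
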