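"""Linear-Gaussian structural equation model (SEM) simulator.

Generates expression data from a known miRNA->mRNA causal DAG, a matched
binding network (optionally polluted with sequence-level-only edges that the
causal model does not support), survival annotations whose hazard depends on
a subset of the features, and the closed-form joint-intervention effect
oracle used as ground truth in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MIRNA, MRNA, BindingNetwork, ExpressionMatrix, SurvivalTable


@dataclass
class SemModel:
    """Weighted causal DAG with Gaussian noise.

    ``nodes`` are in a fixed topological order (miRNAs first).  ``weights``
    maps a directed edge (u, v) to its linear coefficient: each node equals
    its intercept plus the weighted sum of its parents plus N(0, noise_sd^2).
    """

    nodes: list[str]
    node_class: dict[str, str]                    # id -> "miRNA" | "mRNA"
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    intercepts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = {n: i for i, n in enumerate(self.nodes)}
        for (u, v) in self.weights:
            if order[u] >= order[v]:
                raise ValueError(f"edge {u}->{v} violates topological order")
        for n in self.nodes:
            self.noise_sd.setdefault(n, 1.0)
            self.intercepts.setdefault(n, 0.0)
            if self.noise_sd[n] <= 0:
                raise ValueError(f"noise_sd must be > 0 for {n}")

    @property
    def mirnas(self) -> list[str]:
        return [n for n in self.nodes if self.node_class[n] == MIRNA]

    @property
    def mrnas(self) -> list[str]:
        return [n for n in self.nodes if self.node_class[n] == MRNA]

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.weights)

    def weight_matrix(self) -> np.ndarray:
        """B with B[i, j] = weight of nodes[i] -> nodes[j] (strictly upper)."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        B = np.zeros((len(self.nodes), len(self.nodes)))
        for (u, v), w in self.weights.items():
            B[idx[u], idx[v]] = w
        return B

    def parents(self, v: str) -> list[str]:
        return [u for (u, w) in self.weights if w == v]


def random_sem(p: int, q: int, density: float, weight_range: tuple[float, float]
               = (0.5, 1.5), seed: int = 0, noise_sd: float = 1.0,
               intercept_range: tuple[float, float] = (0.0, 0.0)) -> SemModel:
    """Random DAG over p miRNAs and q mRNAs with forward edges at ``density``.

    miRNAs precede mRNAs in the topological order; every ordered forward pair
    (miRNA->miRNA, miRNA->mRNA, mRNA->mRNA) is an edge with probability
    ``density``.  Weights are uniform on +-[weight_range] with random sign.
    """
    if p < 1 or q < 1:
        raise ValueError("p and q must be >= 1")
    if not (0.0 < density <= 1.0):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    mirnas = [f"miR-{i + 1}" for i in range(p)]
    mrnas = [f"gene-{j + 1}" for j in range(q)]
    nodes = mirnas + mrnas
    classes = {n: (MIRNA if n in set(mirnas) else MRNA) for n in nodes}
    weights: dict[tuple[str, str], float] = {}
    lo, hi = weight_range
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if rng.random() < density:
                w = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
                weights[(u, v)] = float(w)
    ilo, ihi = intercept_range
    intercepts = {n: float(rng.uniform(ilo, ihi)) for n in nodes}
    return SemModel(nodes, classes, weights,
                    {n: noise_sd for n in nodes}, intercepts)


def sample_sem(model: SemModel, n: int, seed: int = 0) -> ExpressionMatrix:
    """Draw n i.i.d. samples from the SEM, generating nodes in causal order."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    idx = {m: i for i, m in enumerate(model.nodes)}
    X = np.zeros((len(model.nodes), n))
    parents: dict[str, list[tuple[str, float]]] = {m: [] for m in model.nodes}
    for (u, v), w in model.weights.items():
        parents[v].append((u, w))
    for node in model.nodes:
        val = model.intercepts[node] + rng.normal(
            0.0, model.noise_sd[node], size=n)
        for u, w in parents[node]:
            val = val + w * X[idx[u]]
        X[idx[node]] = val
    samples = [f"S{i + 1}" for i in range(n)]
    return ExpressionMatrix.from_array(
        X, model.nodes, samples, [model.node_class[m] for m in model.nodes])


def model_covariance(model: SemModel) -> np.ndarray:
    """Implied covariance: (I-B)^-T D (I-B)^-1 with D = diag(noise variances)."""
    B = model.weight_matrix()
    I = np.eye(len(model.nodes))
    T = np.linalg.inv(I - B)           # T[u, v] = path sum u -> v
    D = np.diag([model.noise_sd[m] ** 2 for m in model.nodes])
    return T.T @ D @ T


def true_joint_effects(model: SemModel, X: list[str], Y: list[str]) -> np.ndarray:
    """Closed-form joint-intervention effects ef[i, j] of X_i on Y_j.

    The do-operation removes every edge into each member of X; ef_ij is the
    sum over directed paths X_i -> Y_j in the surgered graph of the product
    of edge weights, computed as an entry of (I - B_surgered)^-1.
    """
    overlap = set(X) & set(Y)
    if overlap:
        raise ValueError(f"intervention and target sets overlap: {sorted(overlap)}")
    idx = {m: i for i, m in enumerate(model.nodes)}
    B = model.weight_matrix()
    for x in X:
        B[:, idx[x]] = 0.0             # sever incoming edges (do-operation)
    T = np.linalg.inv(np.eye(len(model.nodes)) - B)
    return np.array([[T[idx[x], idx[y]] for y in Y] for x in X])


@dataclass
class SyntheticBundle:
    model: SemModel
    expression: ExpressionMatrix       # raw SEM scale (may be negative)
    expression_nonneg: ExpressionMatrix  # 2**(x+shift)-1 scale, log2(v+1)=x+shift
    shift: float
    survival: SurvivalTable
    binding: BindingNetwork
    mismatch_edges: set[tuple[str, str]]   # binding-only (no causal support)
    truth_effects: dict[str, np.ndarray]   # mRNA -> oracle ef of its regulators
    truth_regulators: dict[str, list[str]]


def make_bundle(p: int, q: int, n: int, mismatch_fraction: float = 0.0,
                seed: int = 0, density: float = 0.4,
                weight_range: tuple[float, float] = (0.5, 1.5),
                intercept_range: tuple[float, float] = (1.0, 4.0),
                censor_fraction: float = 0.5) -> SyntheticBundle:
    """Full synthetic study: SEM + expression + binding + survival + truth.

    The binding network contains every true miRNA->mRNA causal edge plus
    ``round(mismatch_fraction * n_true)`` extra miRNA-mRNA pairs absent from
    the DAG — sequence-level-only interactions with no expression-level
    support.  Survival hazard is proportional to exp of a weighted sum over a
    random subset of nodes (half of them, at least one).
    """
    rng = np.random.default_rng(seed)
    model = random_sem(p, q, density, weight_range,
                       seed=int(rng.integers(2 ** 31)),
                       intercept_range=intercept_range)
    expr = sample_sem(model, n, seed=int(rng.integers(2 ** 31)))

    # shift so every value is non-negative and log2(v+1) recovers x + shift
    X = expr.values.to_numpy()
    shift = float(np.ceil(max(0.0, -X.min())) + 1.0)
    nonneg = ExpressionMatrix(
        pd.DataFrame(np.exp2(X + shift) - 1.0, index=expr.values.index,
                     columns=expr.values.columns),
        expr.entity_class.copy())

    true_edges = {(u, v) for (u, v) in model.edges
                  if model.node_class[u] == MIRNA and model.node_class[v] == MRNA}
    n_extra = int(round(mismatch_fraction * len(true_edges)))
    non_edges = sorted({(u, v) for u in model.mirnas for v in model.mrnas}
                       - true_edges)
    extra: set[tuple[str, str]] = set()
    if n_extra > 0 and non_edges:
        pick = rng.choice(len(non_edges), size=min(n_extra, len(non_edges)),
                          replace=False)
        extra = {non_edges[i] for i in pick}
    binding = BindingNetwork(true_edges | extra)

    # survival: exponential with hazard exp(linear predictor), uniform censoring
    k_risk = max(1, len(model.nodes) // 2)
    risk_nodes = list(rng.choice(model.nodes, size=k_risk, replace=False))
    betas = rng.uniform(0.3, 0.8, size=k_risk) * rng.choice([-1, 1], size=k_risk)
    Z = expr.values.loc[risk_nodes].to_numpy()
    Zs = (Z - Z.mean(axis=1, keepdims=True)) / Z.std(axis=1, keepdims=True)
    lin = betas @ Zs
    base = 1.0 / 365.0
    t_event = rng.exponential(1.0 / (base * np.exp(lin)))
    t_cens = rng.uniform(0, np.quantile(t_event, 1.0 - censor_fraction), size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    surv = SurvivalTable(pd.DataFrame(
        {"time": time, "event": event}, index=expr.sample_ids))

    truth_effects, truth_regs = {}, {}
    for y in model.mrnas:
        regs = sorted({u for (u, v) in true_edges if v == y})
        if regs:
            truth_regs[y] = regs
            truth_effects[y] = true_joint_effects(model, regs, [y])
    return SyntheticBundle(model, expr, nonneg, shift, surv, binding, extra,
                           truth_effects, truth_regs)
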