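"""Expression preprocessing and survival-based feature selection.

The fixed pipeline order is: missingness filter -> KNN imputation ->
log2(x+1) + per-entity z-score -> univariate Cox selection.  The z-score step
also returns each entity's mean log2 expression *before* standardisation;
that mean is the "average expression level" consumed later by the cumulative
joint-effect statistic (standardised data average to zero, which would make
the knock-off contrast degenerate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .datatypes import ExpressionMatrix, SurvivalTable

log = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    kept_ids: list[str]
    p_values: pd.Series          # per-entity two-sided Wald p
    alpha_cox: float
    dropped: list[str]           # entities whose fit failed / degenerate

    def __post_init__(self) -> None:
        bad = [i for i in self.kept_ids if not self.p_values[i] < self.alpha_cox]
        if bad:
            raise ValueError(f"kept entities with p >= alpha: {bad}")


def filter_missing(m: ExpressionMatrix, threshold: float) -> ExpressionMatrix:
    """Drop entities whose missing fraction strictly exceeds ``threshold``."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0,1]")
    frac = m.values.isna().mean(axis=1)
    keep = frac.index[frac <= threshold]
    return m.subset(keep)


def knn_impute(m: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Fill each missing cell with the mean over the k nearest entities.

    Distance between two entities is the Euclidean distance over samples where
    both are observed; neighbours lacking a value at the target sample are
    skipped in favour of the next nearest.  Observed cells are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = m.values.to_numpy(dtype=float)
    n_obs = (~np.isnan(X)).sum(axis=1)
    if (n_obs == 0).any():
        bad = [m.entity_ids[i] for i in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"entities with no observed values: {bad}")
    out = X.copy()
    rows_with_missing = np.flatnonzero(np.isnan(X).any(axis=1))
    for i in rows_with_missing:
        dists = np.full(X.shape[0], np.inf)
        for j in range(X.shape[0]):
            if j == i:
                continue
            both = ~np.isnan(X[i]) & ~np.isnan(X[j])
            if both.any():
                dists[j] = float(np.sqrt(np.sum((X[i, both] - X[j, both]) ** 2)))
        order = np.argsort(dists, kind="stable")
        for s in np.flatnonzero(np.isnan(X[i])):
            donors = [j for j in order
                      if np.isfinite(dists[j]) and not np.isnan(X[j, s])]
            if len(donors) < k:
                warnings.warn(
                    f"entity {m.entity_ids[i]!r}: only {len(donors)} usable "
                    f"neighbours for sample {m.sample_ids[s]!r} (k={k})")
            use = donors[:k]
            if not use:
                raise ValueError(
                    f"no neighbour with an observed value at sample "
                    f"{m.sample_ids[s]!r} for entity {m.entity_ids[i]!r}")
            out[i, s] = float(np.mean([X[j, s] for j in use]))
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(df, m.entity_class.copy())


def log2_zscore(m: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.Series]:
    """log2(x+1) then per-entity z-score; returns (normalised, pre-z means).

    Entities with zero variance after the log transform are excluded with a
    warning (their z-score is undefined).
    """
    X = m.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values present; impute first")
    if (X < 0).any():
        raise ValueError("negative values; log2(x+1) requires x >= 0")
    L = np.log2(X + 1.0)
    means = L.mean(axis=1)
    sds = L.std(axis=1, ddof=1)
    keep = sds > 0
    if not keep.all():
        dropped = [m.entity_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"excluding zero-variance entities: {dropped}")
    Z = (L[keep] - means[keep, None]) / sds[keep, None]
    ids = [e for e, k in zip(m.entity_ids, keep) if k]
    norm = ExpressionMatrix(
        pd.DataFrame(Z, index=ids, columns=m.sample_ids),
        m.entity_class.loc[ids].copy())
    pre_means = pd.Series(means[keep], index=ids, name="pre_zscore_mean")
    return norm, pre_means


def cox_select(m: ExpressionMatrix, s: SurvivalTable,
               alpha: float = 0.05) -> SelectionResult:
    """Univariate proportional-hazards screen, keep entities with Wald p < alpha.

    Each entity's expression is the sole continuous covariate of its own Cox
    model (Efron tie handling).  Entities whose fit does not converge, or with
    zero variance, are dropped with a warning.
    """
    missing = set(m.sample_ids) - set(s.sample_ids)
    if missing:
        raise ValueError(f"samples without survival annotation: {sorted(missing)}")
    surv = s.table.loc[m.sample_ids]
    pvals: dict[str, float] = {}
    dropped: list[str] = []
    for eid in m.entity_ids:
        x = m.values.loc[eid].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"constant covariate {eid!r} dropped from Cox selection")
            dropped.append(eid)
            continue
        df = pd.DataFrame({"time": surv["time"].to_numpy(),
                           "event": surv["event"].to_numpy(),
                           "x": x})
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            pvals[eid] = float(cph.summary.loc["x", "p"])
        except (ConvergenceError, ValueError) as exc:
            warnings.warn(f"Cox fit failed for {eid!r}: {exc}")
            dropped.append(eid)
    pser = pd.Series(pvals, dtype=float)
    kept = [e for e in m.entity_ids if e in pvals and pvals[e] < alpha]
    return SelectionResult(kept, pser, alpha, dropped)


def preprocess_pipeline(m: ExpressionMatrix, threshold: float, k: int
                        ) -> tuple[ExpressionMatrix, pd.Series]:
    """filter_missing -> knn_impute -> log2_zscore, in that fixed order."""
    filtered = filter_missing(m, threshold)
    imputed = knn_impute(filtered, k) if filtered.values.isna().any().any() else filtered
    return log2_zscore(imputed)
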