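"""Cycle quantification by non-negative LASSO regression.

Per cluster, fragment mean coverages Y are regressed on the cycle-membership
design matrix X (x_ji = number of times fragment j occurs in cycle i).  The
penalized objective is

    (1/|F_k|) * sum_j (y_j - b0 - sum_i x_ji b_i)^2  +  alpha * sum_i |b_i|

with an unpenalized intercept b0 modelling the linear-genome background
coverage, alpha = 0.1 by default, and coefficients constrained non-negative
(a proportion is a copy count; negative values are physically meaningless).
The optimized coefficients are read directly as per-cycle proportions in
coverage units -- columns are deliberately not standardized so that beta
stays comparable to coverage thresholds.

scikit-learn's coordinate descent minimizes (1/2n)||r||^2 + a||b||_1, so the
penalty passed down is alpha/2; the argmin is identical and the reported
objective is always re-evaluated with the formula above.  When a cycle
covers every cluster fragment with multiplicity one its column is collinear
with the intercept and L1 would zero it out; the fit therefore optionally
augments the system with a few background rows (y = background coverage,
x = 0) that anchor the intercept at the linear-genome level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cycles import Cycle, CycleCluster
from .fragments import Fragment

__all__ = [
    "DesignMatrix",
    "LassoFit",
    "QuantifiedCycle",
    "build_design_matrix",
    "fit_lasso",
    "select_cycles",
    "filter_candidates",
]


@dataclass
class DesignMatrix:
    """Fragment-occurrence matrix of one cluster (rows F_k, columns cycles)."""

    fragments: list[Fragment]
    cycles: list[Cycle]
    X: np.ndarray  # (|F_k|, n_cycles) occurrence counts
    Y: np.ndarray  # (|F_k|,) mean coverages


@dataclass
class LassoFit:
    beta: np.ndarray  # proportion per cycle (coverage units)
    beta0: float  # intercept: linear-genome background coverage
    alpha: float
    objective: float  # penalized objective evaluated on the F_k rows


@dataclass
class QuantifiedCycle:
    cycle: Cycle
    proportion: float
    selected: bool
    cluster_id: int
    label: str = ""  # 'ecDNA' | 'circular' after candidate filtering


def build_design_matrix(
    cluster: CycleCluster, fragments: list[Fragment], dedup_columns: bool = False
) -> DesignMatrix:
    """Tally fragment occurrences per cycle (simple cycles then derived).

    With ``dedup_columns`` cycles with identical fragment multisets (hence
    identical, collinear columns) are collapsed to a single representative,
    preferring the ring with more SV-supported junctions and then higher
    minimum junction weight: when a called rearrangement and a plain
    reference adjacency explain the same coverage, the breakend evidence
    wins.
    """
    cyc = cluster.all_cycles
    if dedup_columns:
        groups: dict[tuple, list[Cycle]] = {}
        for c in cyc:
            key = tuple(sorted(c.fragment_counts().items()))
            groups.setdefault(key, []).append(c)
        cyc = [
            min(
                g,
                key=lambda c: (
                    -sum(1 for j in c.junctions if j.kind == "sv"),
                    -c.min_junction_weight(),
                    c.canon_key,
                ),
            )
            for g in groups.values()
        ]
        cyc.sort(key=lambda c: (c.is_derived, c.canon_key))
    fid_set = set()
    for c in cyc:
        fid_set |= c.fragment_ids
    by_fid = {f.fid: f for f in fragments}
    rows = sorted(
        (by_fid[fid] for fid in fid_set), key=lambda f: (f.chrom, f.start)
    )
    X = np.zeros((len(rows), len(cyc)), dtype=float)
    row_idx = {f.fid: j for j, f in enumerate(rows)}
    for i, c in enumerate(cyc):
        for fid, count in c.fragment_counts().items():
            X[row_idx[fid], i] = count
    Y = np.array([f.mean_cov for f in rows], dtype=float)
    return DesignMatrix(rows, cyc, X, Y)


def _objective(X, Y, beta, beta0, alpha) -> float:
    resid = Y - beta0 - X @ beta
    return float(np.mean(resid**2) + alpha * np.sum(np.abs(beta)))


def fit_lasso(
    dm: DesignMatrix,
    alpha: float = 0.1,
    background_cov: float | None = None,
    n_background_rows: int | None = None,
    penalty_weights=None,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> LassoFit:
    """Fit the non-negative LASSO of coverage on cycle membership.

    ``background_cov`` adds background anchor rows (see module docstring);
    by default max(2, |F_k| // 4) of them.  ``alpha=0`` falls back to
    bounded least squares (the un-penalized limit).

    ``penalty_weights`` (one per cycle, default 1) rescale each column's L1
    penalty.  A derived ring's column equals the sum of its parents'
    columns, so the coverage fit alone cannot distinguish "one merged
    element" from "the co-occurring parents"; weighting a k-parent splice
    by k (with a small surcharge) makes the penalties commensurate and
    breaks the tie toward the parent decomposition -- the reading under
    which overlapping-footprint elements are reported separately.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    X, Y = dm.X, dm.Y
    w = np.ones(X.shape[1]) if penalty_weights is None else np.asarray(
        penalty_weights, dtype=float
    )
    if w.shape != (X.shape[1],) or np.any(w <= 0):
        raise ValueError("penalty_weights must be positive, one per cycle")
    X = X / w  # column scaling implements the weighted L1 penalty
    if background_cov is not None:
        n_bg = n_background_rows if n_background_rows is not None else max(2, len(dm.fragments) // 4)
        X = np.vstack([X, np.zeros((n_bg, X.shape[1]))])
        Y = np.concatenate([Y, np.full(n_bg, float(background_cov))])

    if not np.any(Y):
        beta = np.zeros(X.shape[1])
        return LassoFit(beta, 0.0, alpha, _objective(dm.X, dm.Y, beta, 0.0, alpha))

    if alpha == 0:
        from scipy.optimize import lsq_linear

        A = np.hstack([np.ones((X.shape[0], 1)), X])
        lb = np.r_[-np.inf, np.zeros(X.shape[1])]
        res = lsq_linear(A, Y, bounds=(lb, np.full(A.shape[1], np.inf)))
        beta0, beta = float(res.x[0]), res.x[1:]
    else:
        from sklearn.exceptions import ConvergenceWarning
        from sklearn.linear_model import Lasso

        model = Lasso(
            alpha=alpha / 2.0,  # sklearn's (1/2n) MSE scaling vs our (1/n)
            fit_intercept=True,
            positive=True,
            tol=tol,
            max_iter=max_iter,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                model.fit(X, Y)
            except ConvergenceWarning as exc:
                raise RuntimeError(
                    f"LASSO did not converge (alpha={alpha}, "
                    f"n={X.shape[0]}x{X.shape[1]}): {exc}"
                ) from exc
        beta0, beta = float(model.intercept_), np.asarray(model.coef_, dtype=float)

    beta = beta / w  # undo the penalty-weight column scaling
    beta = np.where(np.abs(beta) < 1e-12, 0.0, beta)
    return LassoFit(beta, beta0, alpha, _objective(dm.X, dm.Y, beta, beta0, alpha))


def select_cycles(
    fit: LassoFit, dm: DesignMatrix, cluster_id: int = 0
) -> list[QuantifiedCycle]:
    """Keep cycles with proportion strictly above t = max_i(min_j cov_j)/4.

    For each cycle the minimum mean coverage over its fragments is taken;
    the threshold is the maximum of those minima over the cluster's cycles,
    divided by 4.  Output is sorted by proportion, descending (the higher
    the proportion, the more likely the cycle is a real element).
    """
    cov = {f.fid: f.mean_cov for f in dm.fragments}
    mins = [min(cov[fid] for fid in c.fragment_ids) for c in dm.cycles]
    t = max(mins) / 4.0 if mins else 0.0
    out = [
        QuantifiedCycle(c, float(b), bool(b > t), cluster_id)
        for c, b in zip(dm.cycles, fit.beta)
    ]
    out.sort(key=lambda q: (-q.proportion, q.cycle.canon_key))
    return out


def filter_candidates(
    cycles: list[QuantifiedCycle],
    wgs_mean: float,
    min_ecdna_len: int = 100_000,
) -> list[QuantifiedCycle]:
    """Global candidate filter: drop proportions <= WGS mean coverage and
    label survivors longer than 0.1 Mb as ecDNA (shorter ones stay with
    label 'circular')."""
    if wgs_mean < 0:
        raise ValueError("wgs_mean must be >= 0")
    out = []
    for q in cycles:
        if q.proportion <= wgs_mean:
            continue
        q.label = "ecDNA" if q.cycle.total_len > min_ecdna_len else "circular"
        out.append(q)
    return out
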