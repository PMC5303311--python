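"""Scoring estimated networks against simulated truths.

Implements the edge-recovery benchmark: for each replicate a fresh
scale-free truth, Gaussian data and an accuracy-corrupted prior are
generated; every method is tuned by sparsity matching to the true edge
count; false-positive / false-negative edge counts are aggregated into a
mean (SD) table, and precision-recall curves compare methods along the
whole regularization path.

Method identifiers: ``"ns-or"``, ``"ns-and"``, ``"glasso"``, and
``"wglasso:<acc>"`` (e.g. ``"wglasso:0.6"`` uses a prior corrupted to
60% accuracy).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_selection import tune_lambda_to_sparsity, tune_ns_to_sparsity
from .simulate import (
    PrecisionTruth,
    build_precision_matrix,
    corrupt_weight_matrix,
    generate_scale_free_graph,
    sample_data,
)
from .solvers import (
    GeneNetwork,
    PenaltySpec,
    network_from_estimate,
    neighbor_selection_fit,
    wglasso_fit,
)

__all__ = [
    "ConfusionCounts",
    "BenchmarkReport",
    "count_fp_fn",
    "precision_recall_curve",
    "pr_area",
    "run_benchmark",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Edge confusion counts over unordered node pairs (upper triangle)."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else np.nan

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else np.nan


def count_fp_fn(estimated: GeneNetwork, truth: PrecisionTruth) -> ConfusionCounts:
    """Confusion counts between an estimated network and the truth.

    Counted on unordered pairs: fp = estimated edges absent from the
    truth, fn = true edges missed. Node sets must agree in size; node
    order of the network is taken as the truth's variable order.
    """
    p = truth.p
    if len(estimated.nodes) != p:
        raise ValueError(
            f"node-set mismatch: network has {len(estimated.nodes)} nodes, truth has {p}"
        )
    est_adj = estimated.adjacency().astype(bool)
    true_adj = truth.adjacency.astype(bool)
    iu = np.triu_indices(p, k=1)
    e, t = est_adj[iu], true_adj[iu]
    tp = int(np.sum(e & t))
    fp = int(np.sum(e & ~t))
    fn = int(np.sum(~e & t))
    tn = int(np.sum(~e & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _parse_method(method: str) -> tuple[str, float | None]:
    if method in ("ns-or", "ns-and", "glasso"):
        return method, None
    if method.startswith("wglasso"):
        _, _, acc_s = method.partition(":")
        acc = float(acc_s) if acc_s else 1.0
        return "wglasso", acc
    raise ValueError(f"unknown method {method!r}")


def _fit_network(
    kind: str,
    X: np.ndarray,
    S: np.ndarray,
    w: np.ndarray | None,
    lam: float,
    warm=None,
):
    if kind in ("ns-or", "ns-and"):
        return neighbor_selection_fit(X, lam, rule=kind.split("-")[1]), None
    est = wglasso_fit(S, PenaltySpec(lam=lam, w=w), warm_start=warm)
    return network_from_estimate(est), est


def precision_recall_curve(
    method: str,
    X: np.ndarray,
    w: np.ndarray | None,
    truth: PrecisionTruth,
    grid: np.ndarray,
) -> list[tuple[float, float]]:
    """(precision, recall) along a descending lambda grid.

    Points where no edge is predicted (precision undefined) are skipped.
    Points are returned in grid order; recall is not guaranteed monotone.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) > 0):
        raise ValueError("grid must be descending")
    kind, _ = _parse_method(method)
    S = X.T @ X
    points: list[tuple[float, float]] = []
    warm = None
    for lam in grid:
        net, warm = _fit_network(kind, X, S, w, lam, warm=warm)
        c = count_fp_fn(net, truth)
        if c.tp + c.fp == 0:
            continue
        points.append((c.precision, c.recall))
    return points


def pr_area(points: list[tuple[float, float]]) -> float:
    """Trapezoidal area under the recall-sorted upper hull of PR points.

    For duplicate recall values the best precision is kept; the curve is
    anchored at recall 0 with its first observed precision.
    """
    if not points:
        return 0.0
    byr: dict[float, float] = {}
    for prec, rec in points:
        byr[rec] = max(prec, byr.get(rec, 0.0))
    recs = np.array(sorted(byr))
    precs = np.array([byr[r] for r in recs])
    if recs[0] > 0:
        recs = np.concatenate([[0.0], recs])
        precs = np.concatenate([[precs[0]], precs])
    return float(np.trapezoid(precs, recs))


@dataclass
class BenchmarkReport:
    """Per-replicate confusion counts plus mean/SD summary.

    ``records`` has one row per (p, n, method, replicate) with unordered
    fp/fn counts. ``summary`` aggregates to means and SDs. Published
    benchmark tables of this kind tally each gene pair in both triangles
    of the adjacency matrix; pass ``both_directions=True`` to
    :meth:`table` to report on that doubled scale.
    """

    records: pd.DataFrame
    replicates: int
    n_failed: int = 0

    @property
    def summary(self) -> pd.DataFrame:
        if self.records.empty:
            raise RuntimeError("benchmark produced no usable replicates")
        g = self.records.groupby(["p", "n", "method"], sort=False)
        out = g.agg(
            fp_mean=("fp", "mean"),
            fp_sd=("fp", "std"),
            fn_mean=("fn", "mean"),
            fn_sd=("fn", "std"),
            replicates=("fp", "size"),
        ).reset_index()
        return out

    def table(self, both_directions: bool = False) -> pd.DataFrame:
        out = self.summary.copy()
        if both_directions:
            for c in ("fp_mean", "fp_sd", "fn_mean", "fn_sd"):
                out[c] = 2.0 * out[c]
        return out

    def mean(self, p: int, n: int, method: str, which: str = "fp") -> float:
        s = self.summary
        row = s[(s.p == p) & (s.n == n) & (s.method == method)]
        if row.empty:
            raise KeyError((p, n, method))
        return float(row[f"{which}_mean"].iloc[0])


def run_benchmark(
    scenarios: list[tuple[int, int]],
    methods: list[str],
    replicates: int,
    seed: int,
    max_bisect_steps: int = 40,
) -> BenchmarkReport:
    """Edge-recovery benchmark over (p, n) scenarios and methods.

    Per replicate: a fresh scale-free truth with p - 1 edges, one data
    matrix shared by all methods, and one corrupted prior per accuracy
    level; each method's lambda is bisected until its network matches the
    true edge count (closest sparser solution when the exact count is
    unreachable), and fp/fn are recorded. Replicates where a weighted
    solver fails to converge are dropped and counted in ``n_failed``.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    parsed = [(m, *_parse_method(m)) for m in methods]
    rows = []
    n_failed = 0
    root = np.random.default_rng(seed)
    for p, n in scenarios:
        target = p - 1
        for rep in range(replicates):
            s_graph, s_data, s_w = root.integers(2**31 - 1, size=3)
            adj = generate_scale_free_graph(p, seed=int(s_graph))
            truth = build_precision_matrix(adj)
            X = sample_data(truth.sigma, n, seed=int(s_data))
            S = X.T @ X
            w_cache: dict[float, np.ndarray] = {}
            try:
                for label, kind, acc in parsed:
                    if kind in ("ns-or", "ns-and"):
                        _, net, _ = tune_ns_to_sparsity(
                            X, target, rule=kind.split("-")[1], max_steps=max_bisect_steps
                        )
                    else:
                        w = None
                        if kind == "wglasso":
                            if acc not in w_cache:
                                # same data, one corrupted prior per accuracy level
                                w_cache[acc] = corrupt_weight_matrix(
                                    truth, acc, seed=int(s_w) + int(round(1000 * acc))
                                )
                            w = w_cache[acc]
                        _, est, _ = tune_lambda_to_sparsity(
                            S, w, target, max_steps=max_bisect_steps
                        )
                        if not est.converged:
                            raise RuntimeError("solver did not converge")
                        net = network_from_estimate(est)
                    c = count_fp_fn(net, truth)
                    rows.append(
                        {
                            "p": p,
                            "n": n,
                            "method": label,
                            "replicate": rep,
                            "tp": c.tp,
                            "fp": c.fp,
                            "fn": c.fn,
                            "tn": c.tn,
                            "edges": c.tp + c.fp,
                        }
                    )
            except RuntimeError as exc:  # non-convergent replicate
                n_failed += 1
                logger.warning("replicate %d at (p=%d, n=%d) dropped: %s", rep, p, n, exc)
                rows = [
                    r
                    for r in rows
                    if not (r["p"] == p and r["n"] == n and r["replicate"] == rep)
                ]
    records = pd.DataFrame(rows)
    if n_failed:
        logger.info("%d replicate(s) excluded for non-convergence", n_failed)
    return BenchmarkReport(records=records, replicates=replicates, n_failed=n_failed)
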