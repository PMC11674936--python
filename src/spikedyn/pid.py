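"""Two-source partial information decomposition (BROJA) on network motifs.

For every two-parent/one-target motif of an inferred network, the joint
information the parents carry about the target splits into four nonnegative
atoms:

    I(Y1, Y2; X) = Red + Unq1 + Unq2 + Syn
    I(Y1; X)     = Red + Unq1
    I(Y2; X)     = Red + Unq2

The unique information is defined by the BROJA optimization: Unq1 is the
minimum of I_Q(X; Y1 | Y2) over all distributions Q that preserve the
observed (X, Y1) and (X, Y2) pairwise marginals. For binary triads the
marginal-preserving polytope is exactly two-dimensional -- one free cell
per target state, bounded by Frechet limits -- and since the (X, Y2)
marginal is fixed, minimizing I_Q(X; Y1 | Y2) is equivalent to maximizing
the concave H_Q(X | Y1, Y2). The solver runs a coarse grid scan followed by
an L-BFGS-B polish on that 2-D box; a dense grid version of the same
objective serves as an independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import xlogy

from .estimators import entropy_from_counts
from .io import Raster

__all__ = [
    "TriadDistribution",
    "PIDResult",
    "estimate_triad_pmf",
    "broja_unique",
    "broja_decomposition",
    "enumerate_triads",
    "pid_table",
]

_LN2 = np.log(2.0)


@dataclass
class TriadDistribution:
    """Empirical pmf over (Y1_past, Y2_past, X_t), shape (2, 2, 2)."""

    pmf: np.ndarray
    parent1: str = "Y1"
    parent2: str = "Y2"
    target: str = "X"
    lag1: int = 1
    lag2: int = 1

    def __post_init__(self):
        p = np.asarray(self.pmf, dtype=float)
        if p.shape != (2, 2, 2):
            raise ValueError("triad pmf must have shape (2, 2, 2)")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("pmf entries must be nonnegative and sum to 1")
        self.pmf = p / p.sum()


@dataclass
class PIDResult:
    i_joint: float  # I(Y1, Y2; X), bits
    redundancy: float
    unique1: float
    unique2: float
    synergy: float
    syn_normalized: float  # synergy / H(X); nan when H(X) = 0

    def atoms(self) -> dict:
        return {
            "redundancy": self.redundancy,
            "unique1": self.unique1,
            "unique2": self.unique2,
            "synergy": self.synergy,
        }


def estimate_triad_pmf(
    raster: Raster,
    parent1: str,
    lag1: int,
    parent2: str,
    lag2: int,
    target: str,
    min_overlap: int = 100,
) -> TriadDistribution:
    """Empirical (Y1_{t-lag1}, Y2_{t-lag2}, X_t) frequencies over aligned bins.

    Each parent enters at its inferred lag from the mTE network. Raises if
    fewer than ``min_overlap`` aligned bins remain.
    """
    t0 = max(lag1, lag2)
    n = raster.n_bins
    if n - t0 < min_overlap:
        raise ValueError(f"aligned overlap shorter than {min_overlap} bins")
    y1 = raster.row(parent1)[t0 - lag1 : n - lag1].astype(np.int64)
    y2 = raster.row(parent2)[t0 - lag2 : n - lag2].astype(np.int64)
    x = raster.row(target)[t0:].astype(np.int64)
    counts = np.bincount(y1 * 4 + y2 * 2 + x, minlength=8).reshape(2, 2, 2)
    return TriadDistribution(
        counts / counts.sum(), str(parent1), str(parent2), str(target), lag1, lag2
    )


def _mi(joint2d: np.ndarray) -> float:
    """I between the two axes of a 2-D pmf, bits."""
    p = np.asarray(joint2d, dtype=float)
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log2(p / (px * py))
    return float(np.where(p > 0, term, 0.0).sum())


def _cond_entropy_x(q: np.ndarray) -> float:
    """H_Q(X | Y1, Y2) in bits for a (2, 2, 2) pmf with X on the last axis."""
    pyy = q.sum(axis=2)
    return float((-(xlogy(q, q)).sum() + (xlogy(pyy, pyy)).sum()) / _LN2)


def _polytope(pmf: np.ndarray):
    """Frechet box of the 2-D marginal-preserving family.

    For each x, Q(., ., x) is a 2x2 table with fixed row sums P(y1, x) and
    column sums P(y2, x); its single free parameter is q_x = Q(1, 1, x).
    Returns (lower bounds, upper bounds, builder) where builder maps
    (q_0, q_1) to the full (2, 2, 2) distribution.
    """
    a = pmf.sum(axis=1)  # P(y1, x)
    b = pmf.sum(axis=0)  # P(y2, x)
    s = pmf.sum(axis=(0, 1))  # P(x)
    lo = np.maximum(0.0, a[1] + b[1] - s)
    hi = np.minimum(a[1], b[1])

    def build(q11: np.ndarray) -> np.ndarray:
        # q11 has shape (2,) or (2, G); extra trailing axes broadcast through.
        q11 = np.asarray(q11, dtype=float)
        pad = (2,) + (1,) * (q11.ndim - 1)
        a1, b1, sx = a[1].reshape(pad), b[1].reshape(pad), s.reshape(pad)
        q = np.empty((2, 2) + q11.shape)
        q[1, 1] = q11
        q[1, 0] = a1 - q11
        q[0, 1] = b1 - q11
        q[0, 0] = sx - a1 - b1 + q11
        return q

    return lo, hi, build


def broja_unique(pmf: np.ndarray, return_q: bool = False):
    """Unq(Y1; X / Y2) in bits under the BROJA definition.

    Minimizes I_Q(X; Y1 | Y2) over the marginal-preserving polytope. Because
    H_Q(X | Y2) is fixed by the constraints, this equals maximizing
    H_Q(X | Y1, Y2) over a 2-D box: a 33x33 grid scan locates the basin and
    L-BFGS-B polishes it. Feasibility of the constraint box is checked to
    1e-8; an infeasible or non-convergent solve raises.
    """
    pmf = np.asarray(pmf, dtype=float)
    pmf = pmf / pmf.sum()
    lo, hi, build = _polytope(pmf)
    if (hi - lo < -1e-8).any():
        raise RuntimeError("marginal constraints infeasible for this pmf")
    hi = np.maximum(hi, lo)
    h_x_y2 = _entropy2(pmf.sum(axis=0)) - _entropy2(pmf.sum(axis=(0, 2)))

    def neg_h(q11):
        q = np.clip(build(np.asarray(q11)), 0.0, None)
        return -_cond_entropy_x(q)

    # Vectorized grid scan over the box (degenerate axes collapse to a point).
    grids = [
        np.linspace(lo[x], hi[x], 33) if hi[x] - lo[x] > 1e-12 else np.array([lo[x]])
        for x in (0, 1)
    ]
    g0, g1 = np.meshgrid(grids[0], grids[1], indexing="ij")
    q11 = np.stack([g0.ravel(), g1.ravel()], axis=-1)  # (G, 2)
    qg = np.clip(build(q11.T).transpose(3, 0, 1, 2), 0.0, None)  # (G, 2, 2, 2)
    pyy = qg.sum(axis=3)
    vals = (xlogy(qg, qg).sum(axis=(1, 2, 3)) - xlogy(pyy, pyy).sum(axis=(1, 2))) / _LN2
    start = q11[vals.argmin()]
    res = minimize(
        neg_h,
        start,
        method="L-BFGS-B",
        bounds=list(zip(lo, hi)),
        options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 500},
    )
    best = res.x if res.fun <= neg_h(start) else start
    q_star = np.clip(build(best), 0.0, None)
    q_star /= q_star.sum()
    unq1 = max(0.0, h_x_y2 - _cond_entropy_x(q_star))
    if return_q:
        return unq1, q_star
    return unq1


def _entropy2(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float).ravel()
    return entropy_from_counts(np.maximum(p, 0.0)) if p.sum() > 0 else 0.0


def broja_decomposition(triad) -> PIDResult:
    """Full four-atom decomposition of a triad pmf.

    Solves the BROJA optimization for Unq1 and recovers the remaining atoms
    from the marginal identities; the decomposition is nonnegative up to the
    optimizer tolerance (~1e-6 bits).
    """
    pmf = triad.pmf if isinstance(triad, TriadDistribution) else np.asarray(triad, float)
    pmf = pmf / pmf.sum()
    i1 = _mi(pmf.sum(axis=1))  # I(Y1; X)
    i2 = _mi(pmf.sum(axis=0))  # I(Y2; X)
    i_joint = _mi(pmf.reshape(4, 2))  # I(Y1, Y2; X)
    unq1 = broja_unique(pmf)
    red = i1 - unq1
    unq2 = i2 - red
    syn = i_joint - red - unq1 - unq2
    h_x = _entropy2(pmf.sum(axis=(0, 1)))
    syn_norm = syn / h_x if h_x > 0 else float("nan")
    return PIDResult(i_joint, red, unq1, unq2, syn, syn_norm)


def enumerate_triads(network) -> list:
    """All unordered parent pairs per target with in-degree >= 2.

    Returns (parent1_edge, parent2_edge, target) triples; a target with d
    parents contributes C(d, 2) motifs.
    """
    out = []
    for target, edges in network.parents.items():
        for e1, e2 in combinations(sorted(edges, key=lambda e: e.source), 2):
            out.append((e1, e2, target))
    return out


def pid_table(raster: Raster, network, min_overlap: int = 100) -> pd.DataFrame:
    """BROJA decomposition of every two-parent motif of an inferred network."""
    rows = []
    for e1, e2, target in enumerate_triads(network):
        triad = estimate_triad_pmf(
            raster, e1.source, e1.lag_bins, e2.source, e2.lag_bins, target,
            min_overlap=min_overlap,
        )
        res = broja_decomposition(triad)
        rows.append(
            {
                "culture": raster.culture_id,
                "condition": raster.condition,
                "parent1": e1.source,
                "parent2": e2.source,
                "target": target,
                "i_joint": res.i_joint,
                "redundancy": res.redundancy,
                "unique1": res.unique1,
                "unique2": res.unique2,
                "synergy": res.synergy,
                "syn_normalized": res.syn_normalized,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "culture", "condition", "parent1", "parent2", "target",
            "i_joint", "redundancy", "unique1", "unique2", "synergy",
            "syn_normalized",
        ],
    )
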