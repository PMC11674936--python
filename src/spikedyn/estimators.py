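"""Plug-in discrete information estimators for binary time series.

All estimators are maximum-likelihood ("plug-in") estimates over empirical
joint frequencies, in bits. No bias correction is applied: significance is
established by surrogate testing (shuffles for storage, circular shifts for
transfer), or by the asymptotic chi-squared null for the bivariate-TE
prefilter. Multidimensional pasts are encoded as integer words so joint
distributions reduce to ``np.bincount`` calls.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps

_LN2 = np.log(2.0)

__all__ = [
    "entropy_from_counts",
    "series_entropy",
    "embed_word",
    "conditional_mutual_information",
    "cmi_from_joint_counts",
    "analytic_cmi_pvalue",
    "SparseCMI",
]


def entropy_from_counts(counts: np.ndarray) -> float:
    """Plug-in Shannon entropy in bits from a vector/array of counts."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("entropy of an empty sample is undefined")
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def series_entropy(series: np.ndarray) -> float:
    """Plug-in entropy (bits) of a discrete nonnegative-integer series."""
    series = np.asarray(series)
    if series.size == 0:
        raise ValueError("entropy of an empty series is undefined")
    return entropy_from_counts(np.bincount(series.astype(np.int64)))


def embed_word(series: np.ndarray, lags, t0: int | None = None) -> np.ndarray:
    """Encode past values at the given lags into one integer word per time step.

    Returns an array aligned with ``series[t0:]`` where ``t0`` defaults to
    ``max(lags)``; the word at position ``t`` is ``sum_i series[t - lags[i]] << i``.
    An empty lag list yields the all-zero word (one conditioning state).
    """
    series = np.asarray(series)
    lags = list(lags)
    if t0 is None:
        t0 = max(lags) if lags else 0
    n = len(series)
    if lags and t0 < max(lags):
        raise ValueError("t0 must be at least the deepest lag")
    word = np.zeros(n - t0, dtype=np.int64)
    for i, lag in enumerate(lags):
        word |= series[t0 - lag : n - lag].astype(np.int64) << i
    return word


def cmi_from_joint_counts(joint: np.ndarray) -> float:
    """I(Y; X | C) in bits from a counts array of shape (n_cond, |X|, |Y|)."""
    N = np.asarray(joint, dtype=float)
    n = N.sum()
    if n <= 0:
        return 0.0
    Nc = N.sum(axis=(1, 2), keepdims=True)
    Ncx = N.sum(axis=2, keepdims=True)
    Ncy = N.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = N * Nc / (Ncx * Ncy)
        term = N * np.log2(ratio)
    return float(np.where(N > 0, term, 0.0).sum() / n)


def conditional_mutual_information(
    y: np.ndarray, x: np.ndarray, cond: np.ndarray, n_cond: int
) -> float:
    """Plug-in I(Y; X | C) in bits for binary ``y``/``x`` and integer ``cond``."""
    code = (cond.astype(np.int64) * 2 + x) * 2 + y
    joint = np.bincount(code, minlength=n_cond * 4).reshape(n_cond, 2, 2)
    return cmi_from_joint_counts(joint)


def analytic_cmi_pvalue(joint: np.ndarray, cmi_bits: float) -> float:
    """Asymptotic chi-squared p-value for a plug-in CMI being zero.

    Under independence, ``2 N * CMI`` (in nats) is asymptotically chi-squared
    with ``(|Y|-1)(|X|-1) * |C|`` degrees of freedom, counting only symbols and
    conditioning states actually observed. Degenerate (constant) variables give
    zero degrees of freedom and p = 1.
    """
    N = np.asarray(joint, dtype=float)
    n = N.sum()
    k_c = int((N.sum(axis=(1, 2)) > 0).sum())
    k_x = int((N.sum(axis=(0, 2)) > 0).sum())
    k_y = int((N.sum(axis=(0, 1)) > 0).sum())
    df = (k_x - 1) * (k_y - 1) * k_c
    if df <= 0:
        return 1.0
    stat = 2.0 * n * cmi_bits * _LN2
    return float(_sps.chi2.sf(stat, df))


class SparseCMI:
    """Fast repeated I(Y; X | C) for many candidate/surrogate sources Y.

    The target bit ``x`` and conditioning word ``cond`` are fixed; each
    evaluation supplies only the *positions* where a binary source is 1.
    Since spike trains are sparse, recounting the joint for a shifted or
    permuted source costs O(#spikes) instead of O(N).
    """

    def __init__(self, x: np.ndarray, cond: np.ndarray, n_cond: int):
        self.n = len(x)
        self.n_cond = n_cond
        self.cond = cond.astype(np.int64)
        self.code = self.cond * 2 + x
        self.total = np.bincount(self.code, minlength=n_cond * 2).reshape(n_cond, 2)
        self._m_c = self.total.sum(axis=1)  # stratum sizes
        self._good_c = self.total[:, 1]  # x = 1 per stratum

    def _joint(self, positions: np.ndarray) -> np.ndarray:
        N1 = np.bincount(self.code[positions], minlength=self.n_cond * 2)
        N1 = N1.reshape(self.n_cond, 2)
        N0 = self.total - N1
        return np.stack([N0, N1], axis=2)  # (cond, x, y)

    def cmi(self, positions: np.ndarray) -> float:
        return cmi_from_joint_counts(self._joint(positions))

    def cmi_and_pvalue(self, positions: np.ndarray) -> tuple[float, float]:
        joint = self._joint(positions)
        val = cmi_from_joint_counts(joint)
        return val, analytic_cmi_pvalue(joint, val)

    def cmi_shifted(self, positions: np.ndarray, shift: int) -> float:
        return self.cmi((positions + shift) % self.n)

    def cmi_permuted(self, n_ones: int, rng: np.random.Generator) -> float:
        return self.cmi(rng.choice(self.n, size=n_ones, replace=False))

    def ones_by_stratum(self, positions: np.ndarray) -> np.ndarray:
        """Count of source-1 bins per conditioning stratum (for the exact null)."""
        return np.bincount(self.cond[positions], minlength=self.n_cond)

    def cmi_stratified_null(self, n1_c: np.ndarray, rng: np.random.Generator) -> float:
        """One draw from the exact conditional-permutation null of I(Y; X | C).

        Permuting a binary source within each conditioning stratum preserves
        the (Y, C) joint while enforcing Y independent of X given C; the
        resulting per-stratum count of (y=1, x=1) bins is hypergeometric, so
        the null statistic can be drawn directly without moving any spikes.
        """
        k = rng.hypergeometric(
            np.maximum(self._good_c, 0), self._m_c - self._good_c, n1_c
        )
        N1 = np.stack([n1_c - k, k], axis=1)  # (cond, x)
        N0 = self.total - N1
        return cmi_from_joint_counts(np.stack([N0, N1], axis=2))
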