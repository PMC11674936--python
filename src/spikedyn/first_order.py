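"""Per-neuron information dynamics: entropy, active information storage
with nonuniform embedding, memory horizon, and entropy production.

Active information storage (AIS) is the mutual information between a
neuron's embedded past and its present bin, AIS(X) = I(X_past; X_t) =
H(X_t) - H(X_t | X_past), and decomposes the per-bin entropy as an
"information regression" H(X_t) = AIS(X) + H_mu(X), where H_mu is the
conditional entropy rate. The past embedding is selected nonuniformly: a
greedy forward pass over lags 1..tau_max adds, at each round, the lag with
maximal conditional mutual information given the already-selected lags, if
it beats a shuffle-surrogate null; it stops at the first non-significant
best candidate. All estimators are plug-in, so the regression identity
holds exactly on the shared empirical joint.

Entropy production measures time irreversibility: the series is losslessly
coarse-grained into non-overlapping 5-bin macroframes (32 possible words),
ordered successive frame pairs are counted, only pairs observed in both
directions are retained, forward pair frequencies are renormalized over
that symmetric support, and the Kullback-Leibler divergence between the
forward and reversed transition statistics is returned in bits. It is zero
iff the retained transition statistics satisfy detailed balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .estimators import SparseCMI, cmi_from_joint_counts, embed_word, series_entropy

__all__ = [
    "EntropyResult",
    "EmbeddingSpec",
    "AISResult",
    "TransitionModel",
    "shannon_entropy",
    "select_embedding",
    "active_information_storage",
    "memory_horizon",
    "entropy_production",
]


@dataclass
class EntropyResult:
    neuron_id: str
    H: float  # bits per bin
    p1: float  # empirical P(bin = 1)
    n_bins: int


@dataclass
class EmbeddingSpec:
    """Selected past lags (in bins) from the greedy nonuniform search."""

    selected_lags: list = field(default_factory=list)
    tau_max: int = 5
    p_values: dict = field(default_factory=dict)  # lag -> surrogate p at selection

    def __post_init__(self):
        lags = list(self.selected_lags)
        if len(set(lags)) != len(lags):
            raise ValueError("selected lags must be unique")
        if any(l < 1 or l > self.tau_max for l in lags):
            raise ValueError("lags must lie in 1..tau_max")
        self.selected_lags = sorted(lags)

    @property
    def is_empty(self) -> bool:
        return not self.selected_lags


@dataclass
class AISResult:
    neuron_id: str
    ais: float  # bits
    ais_normalized: float  # ais / H(X_t); nan when H = 0
    H: float  # H(X_t), bits, from the same aligned sample
    h_mu: float  # conditional entropy rate, bits
    embedding: EmbeddingSpec
    memory_horizon_ms: float  # nan when the embedding is empty


def shannon_entropy(series: np.ndarray, neuron_id: str = "") -> EntropyResult:
    """Plug-in Shannon entropy (bits) of a binary series, Eq.-style
    H = -sum_x P(x) log2 P(x) over the empirical bin-state frequencies."""
    series = np.asarray(series)
    if series.size == 0:
        raise ValueError("cannot compute the entropy of an empty series")
    return EntropyResult(
        neuron_id=str(neuron_id),
        H=series_entropy(series),
        p1=float(series.mean()),
        n_bins=int(series.size),
    )


def select_embedding(
    series: np.ndarray,
    tau_max: int = 5,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    rng=None,
) -> EmbeddingSpec:
    """Greedy nonuniform embedding of a series' own past.

    At each round the candidate lag in 1..tau_max with maximal conditional
    mutual information I(X_{t-lag}; X_t | selected past) is tested against
    ``n_shuffles`` surrogates of the *maximum* over all remaining candidate
    lags, each permuted within strata of the already-selected past word.
    The max-statistic keeps the per-round false-selection rate at ``alpha``
    despite the winning lag being the best of several candidates, and the
    stratified permutation (a plain marginal-preserving shuffle in round
    one) keeps the null calibrated for autocorrelated series, where a
    candidate lag co-varies with the selected lags. Selection stops when
    the best candidate's surrogate p-value exceeds ``alpha``. Exact CMI
    ties break toward the smaller lag.
    """
    rng = np.random.default_rng(rng)
    series = np.asarray(series, dtype=np.uint8)
    n = len(series)
    if n <= tau_max + 1:
        return EmbeddingSpec([], tau_max)
    x_t = series[tau_max:]
    cols = {lag: series[tau_max - lag : n - lag] for lag in range(1, tau_max + 1)}
    selected: list[int] = []
    p_values: dict[int, float] = {}
    while len(selected) < tau_max:
        cond = embed_word(series, selected, t0=tau_max)
        sp = SparseCMI(x_t, cond, 2 ** len(selected))
        remaining = [l for l in range(1, tau_max + 1) if l not in selected]
        best_lag, best_cmi = None, -1.0
        for lag in remaining:  # ascending, so ties keep the smallest lag
            val = sp.cmi(np.flatnonzero(cols[lag]))
            if val > best_cmi:
                best_lag, best_cmi = lag, val
        n_ones = int(cols[best_lag].sum())
        if n_ones in (0, len(x_t)):
            break  # constant candidate column carries nothing
        n1_by_lag = [
            sp.ones_by_stratum(np.flatnonzero(cols[l])) for l in remaining
        ]
        exceed = 0
        for _ in range(n_shuffles):
            m = max(sp.cmi_stratified_null(n1_c, rng) for n1_c in n1_by_lag)
            if m >= best_cmi:
                exceed += 1
        p = (1 + exceed) / (1 + n_shuffles)
        if p > alpha:
            break
        selected.append(best_lag)
        p_values[best_lag] = p
    return EmbeddingSpec(selected, tau_max, p_values)


def active_information_storage(
    series: np.ndarray,
    embedding: EmbeddingSpec,
    neuron_id: str = "",
    bin_width_ms: float = 1.0,
) -> AISResult:
    """AIS over the selected-lag past word, from one shared plug-in joint.

    H, AIS and H_mu are all computed on the sample aligned at the deepest
    selected lag, so H = AIS + H_mu holds exactly. An empty embedding gives
    AIS = 0 and H_mu = H. A constant series has H = 0; the normalized value
    is then undefined (nan) and callers exclude it downstream.
    """
    series = np.asarray(series, dtype=np.uint8)
    lags = embedding.selected_lags
    t0 = max(lags) if lags else 0
    x_t = series[t0:]
    H = series_entropy(x_t)
    if lags:
        past = embed_word(series, lags, t0=t0)
        ais = _mutual_information_word(past, x_t, 2 ** len(lags))
    else:
        ais = 0.0
    h_mu = H - ais
    ais_norm = ais / H if H > 0 else float("nan")
    if H == 0:
        warnings.warn(f"neuron {neuron_id!r}: constant series, normalized AIS undefined")
    horizon = memory_horizon(embedding, bin_width_ms)
    return AISResult(str(neuron_id), ais, ais_norm, H, h_mu, embedding, horizon)


def _mutual_information_word(word: np.ndarray, x: np.ndarray, n_word: int) -> float:
    """I(word; x) in bits via the CMI kernel with a single conditioning state."""
    joint = np.bincount(word * 2 + x, minlength=n_word * 2).reshape(1, n_word, 2)
    return cmi_from_joint_counts(joint)


def memory_horizon(embedding: EmbeddingSpec, bin_width_ms: float = 1.0) -> float:
    """Deepest selected lag in ms; nan (missing) for an empty embedding."""
    if embedding.is_empty:
        return float("nan")
    return max(embedding.selected_lags) * bin_width_ms


@dataclass
class TransitionModel:
    """Macroframe transition statistics and the entropy production estimate."""

    frame_bins: int
    counts: np.ndarray  # (n_states, n_states) ordered successive-pair counts
    retained: np.ndarray  # boolean mask of the reciprocal (symmetric) support
    entropy_production: float  # bits; nan when the retained support is empty
    n_frames: int

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]

    @property
    def forward_probabilities(self) -> np.ndarray:
        """Renormalized forward pair frequencies over the retained support."""
        kept = np.where(self.retained, self.counts, 0).astype(float)
        total = kept.sum()
        return kept / total if total > 0 else kept


def entropy_production(
    series: np.ndarray, frame_bins: int = 5, mode: str = "joint"
) -> TransitionModel:
    """Time irreversibility of a binary series, D_KL(forward || reverse), bits.

    The series is chopped into consecutive non-overlapping ``frame_bins``-bin
    macroframes (a trailing partial frame is dropped); ordered successive
    frame pairs are counted; only pairs whose reverse was also observed are
    retained; forward pair frequencies are renormalized over that symmetric
    support; and sum p_ij * log2(p_ij / p_ji) is returned. The default
    "joint" mode reads the transition probabilities as joint pair
    frequencies, making the estimate a true KL divergence (nonnegative).
    The "conditional" mode instead compares row-normalized transition
    probabilities (weighting by the renormalized joint); it is not
    guaranteed nonnegative and is provided as the alternative reading.
    """
    series = np.asarray(series, dtype=np.uint8)
    if len(series) < 2 * frame_bins:
        raise ValueError("series shorter than two macroframes")
    n_states = 2**frame_bins
    m = len(series) // frame_bins
    frames = series[: m * frame_bins].reshape(m, frame_bins)
    weights = 1 << np.arange(frame_bins - 1, -1, -1)
    words = frames @ weights  # first bin is the high-order bit
    a, b = words[:-1], words[1:]
    counts = np.bincount(a * n_states + b, minlength=n_states * n_states)
    counts = counts.reshape(n_states, n_states)
    retained = (counts > 0) & (counts.T > 0)
    if not retained.any():
        warnings.warn("no reciprocal macroframe transitions; entropy production missing")
        ep = float("nan")
    else:
        kept = np.where(retained, counts, 0).astype(float)
        q = kept / kept.sum()
        if mode == "joint":
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(retained, q / np.where(q.T > 0, q.T, 1.0), 1.0)
                ep = float(np.where(retained, q * np.log2(ratio), 0.0).sum())
        elif mode == "conditional":
            row = kept.sum(axis=1, keepdims=True)
            T = np.divide(kept, row, out=np.zeros_like(kept), where=row > 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(retained & (T.T > 0), T / np.where(T.T > 0, T.T, 1.0), 1.0)
                ep = float(np.where(retained, q * np.log2(ratio), 0.0).sum())
        else:
            raise ValueError("mode must be 'joint' or 'conditional'")
    return TransitionModel(frame_bins, counts, retained, ep, m)
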