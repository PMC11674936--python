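"""Seeded spike-raster generators with known information-dynamic structure.

These emulate the study design every estimator downstream is pointed at:
three one-hour recording conditions (control / drug / washout) per culture,
>= 30 neurons, sparse firing rates spanning orders of magnitude, a directed
coupling graph with per-edge lags and transmission probabilities, XOR-like
synergistic triads, and a controllable violation of detailed balance. Every
generator is a pure function of (config, seed), and the ground-truth ledger
records all true parameters so recovery can be scored without re-derivation.

The coupling model is a probabilistic OR: a target fires at t from its own
baseline rate, or because a parent fired at ``t - lag`` and transmitted with
its edge probability. Coupling graphs must be acyclic so each condition can
be simulated in topological order without a per-bin loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import CONDITIONS, Raster, SpikeTable, write_spike_csv

__all__ = [
    "CouplingEdge",
    "ConditionEffect",
    "GeneratorConfig",
    "ExperimentData",
    "gen_bernoulli_raster",
    "gen_coupled_raster",
    "gen_xor_triad",
    "gen_irreversible_series",
    "gen_experiment",
    "random_dag",
    "write_experiment",
    "score_edge_recovery",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class CouplingEdge:
    source: int
    target: int
    lag_bins: int = 1
    transmission: float = 0.6

    def __post_init__(self):
        if self.source == self.target:
            raise ValueError("self-loops are not allowed")
        if self.lag_bins < 1:
            raise ValueError("edge lag must be >= 1 bin")
        if not 0.0 <= self.transmission <= 1.0:
            raise ValueError("transmission probability must be in [0, 1]")


@dataclass(frozen=True)
class ConditionEffect:
    """Multiplicative effects on rate/transmission, additive on edge count."""

    rate_mult: float = 1.0
    transmission_mult: float = 1.0
    extra_edges: int = 0


def _default_effects() -> dict:
    # The "drug" condition raises firing entropy, weakens individual edges and
    # opens extra weak connections -- the qualitative signature under study.
    return {
        "control": ConditionEffect(),
        "drug": ConditionEffect(rate_mult=1.3, transmission_mult=0.7, extra_edges=5),
        "washout": ConditionEffect(),
    }


@dataclass
class GeneratorConfig:
    n_neurons: int = 30
    duration_ms: float = 3_600_000.0  # one hour per condition
    bin_width_ms: float = 1.0
    base_rate: float = 10.0  # spikes/s, for single-rate generators
    rate_range: tuple = (0.5, 20.0)  # spikes/s, log-spaced across neurons
    # None: gen_experiment draws a random DAG per culture; []: uncoupled.
    coupling_graph: list | None = None
    xor_triads: list = field(default_factory=list)  # (p1, p2, target, noise_p)
    irreversibility_bias: float = 0.0
    condition_effects: dict = field(default_factory=_default_effects)
    extra_edge_transmission: float = 0.25
    n_cultures: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.irreversibility_bias < 0.5:
            raise ValueError("irreversibility bias must be in [0, 0.5)")
        if self.coupling_graph is not None:
            self.coupling_graph = [
                e if isinstance(e, CouplingEdge) else CouplingEdge(*e)
                for e in self.coupling_graph
            ]

    @property
    def n_bins(self) -> int:
        return int(round(self.duration_ms / self.bin_width_ms))

    def rate_to_p(self, rate: float) -> float:
        p = rate * self.bin_width_ms / 1000.0
        if p > 1.0:
            raise ValueError(f"rate {rate}/s exceeds one spike per bin")
        return p


def gen_bernoulli_raster(config: GeneratorConfig, rng=None) -> Raster:
    """I.i.d. binary raster: P(spike in a bin) = base_rate * bin_width."""
    rng = _rng(config.seed if rng is None else rng)
    p = config.rate_to_p(config.base_rate)
    mat = (rng.random((config.n_neurons, config.n_bins)) < p).astype(np.uint8)
    return Raster(mat, config.bin_width_ms)


def _topological_order(n: int, edges: list) -> list:
    """Kahn's algorithm; raises if the coupling graph has a cycle."""
    indeg = [0] * n
    out = {i: [] for i in range(n)}
    for e in edges:
        indeg[e.target] += 1
        out[e.source].append(e.target)
    queue = [i for i in range(n) if indeg[i] == 0]
    order = []
    while queue:
        i = queue.pop()
        order.append(i)
        for j in out[i]:
            indeg[j] -= 1
            if indeg[j] == 0:
                queue.append(j)
    if len(order) != n:
        raise ValueError("coupling graph must be acyclic")
    return order


def gen_coupled_raster(
    config: GeneratorConfig, rng=None, rates=None
) -> tuple[Raster, list]:
    """Simulate the probabilistic-OR coupling model; returns (raster, true edges).

    Each neuron fires from an independent Bernoulli baseline, OR because a
    parent fired ``lag`` bins earlier and the edge transmitted. Targets are
    filled in topological order, so the full firing probability is exactly
    ``1 - (1 - p0) * prod_parents(1 - s * parent_{t-lag})``.
    """
    rng = _rng(config.seed if rng is None else rng)
    n, T = config.n_neurons, config.n_bins
    edges = config.coupling_graph or []
    if rates is None:
        rates = np.full(n, config.base_rate, dtype=float)
    p0 = np.array([config.rate_to_p(r) for r in rates])
    order = _topological_order(n, edges)
    by_target: dict[int, list] = {}
    for e in edges:
        by_target.setdefault(e.target, []).append(e)
    mat = np.zeros((n, T), dtype=np.uint8)
    for i in order:
        fired = rng.random(T) < p0[i]
        for e in by_target.get(i, ()):
            parent = mat[e.source]
            drive = np.zeros(T, dtype=bool)
            drive[e.lag_bins :] = parent[: T - e.lag_bins].astype(bool)
            fired |= drive & (rng.random(T) < e.transmission)
        mat[i] = fired
    return Raster(mat, config.bin_width_ms), list(edges)


def gen_xor_triad(
    n_bins: int,
    parent_p: float = 0.5,
    noise_p: float = 0.0,
    lag: int = 1,
    seed=0,
    bin_width_ms: float = 1.0,
) -> Raster:
    """Two independent Bernoulli parents and a target = XOR of their lagged bins.

    The target bit at t is ``parent1[t-lag] ^ parent2[t-lag]``, flipped with
    probability ``noise_p``. With uniform parents each parent alone carries
    zero information about the target -- the canonical purely synergistic
    motif. Rows are ordered (parent1, parent2, target).
    """
    if not 0.0 <= noise_p < 0.5:
        raise ValueError("noise probability must be in [0, 0.5)")
    rng = _rng(seed)
    y1 = (rng.random(n_bins) < parent_p).astype(np.uint8)
    y2 = (rng.random(n_bins) < parent_p).astype(np.uint8)
    x = np.zeros(n_bins, dtype=np.uint8)
    x[lag:] = y1[:-lag] ^ y2[:-lag]
    flips = rng.random(n_bins) < noise_p
    x ^= flips.astype(np.uint8)
    return Raster(
        np.stack([y1, y2, x]), bin_width_ms, ["parent1", "parent2", "target"]
    )


def gen_irreversible_series(bias: float, n_bins: int, seed=0) -> np.ndarray:
    """Binary series from an order-2 Markov chain with tunable irreversibility.

    A 2-state (order-1) binary chain always satisfies detailed balance, so
    irreversibility is injected at order 2: after a rising edge (0, 1) the
    chain continues with probability ``0.5 + bias``; after a falling edge
    (1, 0) with ``0.5 - bias``; otherwise 0.5. Bias 0 reduces to i.i.d. fair
    coin flips (reversible); larger bias breaks detailed balance of the
    macroframe transition statistics by a growing amount.
    """
    if not 0.0 <= bias < 0.5:
        raise ValueError("bias must be in [0, 0.5)")
    rng = _rng(seed)
    u = rng.random(n_bins)
    x = np.zeros(n_bins, dtype=np.uint8)
    if n_bins >= 1:
        x[0] = u[0] < 0.5
    if n_bins >= 2:
        x[1] = u[1] < 0.5
    p = {(0, 0): 0.5, (0, 1): 0.5 + bias, (1, 0): 0.5 - bias, (1, 1): 0.5}
    for t in range(2, n_bins):
        x[t] = u[t] < p[(x[t - 2], x[t - 1])]
    return x


def random_dag(
    n_neurons: int,
    parents_per_target: int = 2,
    lag_max: int = 5,
    transmission: float = 0.6,
    seed=0,
    forbid=(),
) -> list:
    """Random acyclic coupling graph: each neuron draws parents from lower indices."""
    rng = _rng(seed)
    forbidden = set(forbid)
    edges = []
    for tgt in range(1, n_neurons):
        k = min(parents_per_target, tgt)
        sources = rng.choice(tgt, size=k, replace=False)
        for src in sources:
            if (int(src), tgt) in forbidden:
                continue
            lag = int(rng.integers(1, lag_max + 1))
            edges.append(CouplingEdge(int(src), tgt, lag, transmission))
    return edges


@dataclass
class ExperimentData:
    """Per-culture, per-condition spike tables plus the ground-truth ledger."""

    tables: dict  # culture_id -> {condition -> SpikeTable}
    ledger: dict  # every true parameter, JSON-serializable


def gen_experiment(config: GeneratorConfig) -> ExperimentData:
    """Simulate the full three-condition experiment.

    Per culture: per-neuron baseline rates are log-spaced over
    ``config.rate_range`` (sparse firing spanning orders of magnitude), a
    random acyclic coupling graph is drawn unless one is supplied, and each
    condition applies its ``ConditionEffect`` -- rate and transmission
    multipliers plus extra weak edges for the drug condition.
    """
    if set(config.condition_effects) != set(CONDITIONS):
        raise ValueError(f"condition_effects must cover {CONDITIONS}")
    root = np.random.SeedSequence(config.seed)
    tables: dict = {}
    ledger: dict = {"config_seed": config.seed, "cultures": {}}
    for ci, child in enumerate(root.spawn(config.n_cultures)):
        culture_id = f"culture{ci}"
        rng = np.random.default_rng(child)
        rates = np.geomspace(config.rate_range[0], config.rate_range[1], config.n_neurons)
        rng.shuffle(rates)
        base_edges = (
            config.coupling_graph
            if config.coupling_graph is not None
            else random_dag(config.n_neurons, seed=rng.integers(2**31))
        )
        tables[culture_id] = {}
        ledger["cultures"][culture_id] = {
            "rates_hz": rates.tolist(),
            "conditions": {},
        }
        for cond in CONDITIONS:
            eff = config.condition_effects[cond]
            edges = [
                CouplingEdge(
                    e.source,
                    e.target,
                    e.lag_bins,
                    min(1.0, e.transmission * eff.transmission_mult),
                )
                for e in base_edges
            ]
            if eff.extra_edges:
                existing = {(e.source, e.target) for e in edges}
                weak = random_dag(
                    config.n_neurons,
                    parents_per_target=1,
                    transmission=config.extra_edge_transmission,
                    seed=rng.integers(2**31),
                    forbid=existing,
                )
                rng2 = np.random.default_rng(rng.integers(2**31))
                idx = rng2.permutation(len(weak))[: eff.extra_edges]
                edges.extend(weak[i] for i in idx)
            cond_cfg = GeneratorConfig(
                n_neurons=config.n_neurons,
                duration_ms=config.duration_ms,
                bin_width_ms=config.bin_width_ms,
                coupling_graph=edges,
                condition_effects=config.condition_effects,
                seed=config.seed,
            )
            raster, true_edges = gen_coupled_raster(
                cond_cfg, rng=rng, rates=rates * eff.rate_mult
            )
            for p1, p2, tgt, noise in config.xor_triads:
                # Override the target row: XOR of its two parents at lag 1,
                # flipped with the stated noise probability.
                word = raster.matrix[p1][:-1] ^ raster.matrix[p2][:-1]
                flips = (rng.random(config.n_bins - 1) < noise).astype(np.uint8)
                raster.matrix[tgt][1:] = word ^ flips
                raster.matrix[tgt][0] = 0
            table = raster.to_spike_table()
            table.condition = cond
            table.culture_id = culture_id
            table.duration_ms = config.duration_ms
            tables[culture_id][cond] = table
            ledger["cultures"][culture_id]["conditions"][cond] = {
                "rate_mult": eff.rate_mult,
                "transmission_mult": eff.transmission_mult,
                "extra_edges": eff.extra_edges,
                "edges": [asdict(e) for e in true_edges],
            }
    return ExperimentData(tables, ledger)


def write_experiment(exp: ExperimentData, out_dir) -> None:
    """Write spike CSVs (one per culture/condition) and the ground-truth ledger."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for culture_id, conds in exp.tables.items():
        cdir = out / culture_id
        cdir.mkdir(exist_ok=True)
        for cond, table in conds.items():
            write_spike_csv(table, cdir / f"{cond}.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(exp.ledger, fh, indent=1, sort_keys=True)


def score_edge_recovery(true_edges, inferred_edges) -> dict:
    """Precision/recall of inferred (source, target) pairs against ground truth.

    Accepts CouplingEdge lists, (source, target[, ...]) tuples, or objects with
    ``source``/``target`` attributes; neuron indices and string ids compare by
    string form.
    """

    def _pairs(edges):
        out = set()
        for e in edges:
            if hasattr(e, "source"):
                out.add((str(e.source), str(e.target)))
            else:
                out.add((str(e[0]), str(e[1])))
        return out

    true_p, inf_p = _pairs(true_edges), _pairs(inferred_edges)
    tp = len(true_p & inf_p)
    precision = tp / len(inf_p) if inf_p else 1.0 if not true_p else 0.0
    recall = tp / len(true_p) if true_p else 1.0
    return {
        "precision": precision,
        "recall": recall,
        "n_true": len(true_p),
        "n_inferred": len(inf_p),
        "n_correct": tp,
    }
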