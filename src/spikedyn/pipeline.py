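"""End-to-end orchestration: read -> filter -> first-order -> network -> PID -> stats.

Inputs are directories of per-culture spike CSVs, one file per condition
(``<input>/<culture>/<condition>.csv``). Outputs are tidy CSV tables plus a
JSON run manifest carrying the config, its hash, software versions, and
filter counts. Stage outputs are cached: a rerun with the same config hash
loads existing tables instead of recomputing, and deleting one stage's file
invalidates only that stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .first_order import active_information_storage, entropy_production, select_embedding, shannon_entropy
from .io import CONDITIONS, Raster, filter_common_active, filter_min_neurons, rasterize, read_spike_csv
from .network import NetworkConfig, _task_rng, infer_network, network_metrics
from .pid import pid_table
from .stats import condition_summary, plot_condition_cdfs

log = logging.getLogger("spikedyn")

__all__ = ["RunConfig", "run_pipeline", "first_order_table", "load_rasters"]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the study's values as defaults."""

    bin_width_ms: float = 1.0
    min_neurons: int = 30  # raster inclusion threshold (active neurons)
    min_spikes_active: int = 1  # "active in a condition" = this many spikes
    tau_max: int = 5  # deepest past lag for the nonuniform embedding
    ais_shuffles: int = 1000  # shuffle surrogates per embedding round
    alpha: float = 0.05
    source_max_lag: int = 30
    target_history: int = 5
    n_surrogates: int = 250  # circular-shift surrogates (network stage)
    frame_bins: int = 5  # macroframe width for entropy production
    entropy_production_mode: str = "joint"
    clustering_mode: str = "directed"
    pid_min_overlap: int = 100
    make_plots: bool = True
    jobs: int = 1
    seed: int = 0

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            source_max_lag=self.source_max_lag,
            target_history=self.target_history,
            n_surrogates=self.n_surrogates,
            alpha=self.alpha,
            clustering_mode=self.clustering_mode,
            jobs=self.jobs,
            seed=self.seed,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    out_dir: Path
    first_order: pd.DataFrame
    edges: pd.DataFrame
    nodes: pd.DataFrame
    triads: pd.DataFrame
    summary: pd.DataFrame
    comparisons: dict = field(default_factory=dict)
    filter_counts: dict = field(default_factory=dict)


def load_rasters(input_dir, config: RunConfig) -> dict:
    """Read, rasterize and filter all cultures; returns {culture: {cond: Raster}}.

    Applies both inclusion rules: cultures whose control raster has fewer
    than ``min_neurons`` active neurons are dropped, and within a culture
    only neurons active in all three conditions are retained.
    """
    input_dir = Path(input_dir)
    cultures: dict = {}
    counts = {"cultures_dropped": 0, "neurons_dropped": 0}
    for cdir in sorted(p for p in input_dir.iterdir() if p.is_dir()):
        rasters = {}
        for cond in CONDITIONS:
            path = cdir / f"{cond}.csv"
            if not path.exists():
                raise FileNotFoundError(f"missing condition file: {path}")
            table = read_spike_csv(path, condition=cond, culture_id=cdir.name)
            rasters[cond] = rasterize(table, config.bin_width_ms)
        # Conditions may end at different last-spike times; pad to a common
        # universe of neurons (rasterize keeps only neurons that spiked).
        universe = sorted(set().union(*(r.neuron_ids for r in rasters.values())))
        for cond, r in rasters.items():
            missing = [nid for nid in universe if nid not in r.neuron_ids]
            if missing:
                pad = np.zeros((len(missing), r.n_bins), dtype=np.uint8)
                rasters[cond] = Raster(
                    np.vstack([r.matrix, pad]),
                    r.bin_width_ms,
                    r.neuron_ids + missing,
                    cond,
                    cdir.name,
                ).subset(universe)
            else:
                rasters[cond] = r.subset(universe)
        if not all(
            filter_min_neurons(r, config.min_neurons, config.min_spikes_active)
            for r in rasters.values()
        ):
            counts["cultures_dropped"] += 1
            log.info("dropping culture %s: fewer than %d active neurons", cdir.name, config.min_neurons)
            continue
        before = len(universe)
        rasters = filter_common_active(rasters, config.min_spikes_active)
        counts["neurons_dropped"] += before - len(next(iter(rasters.values())).neuron_ids)
        cultures[cdir.name] = rasters
    counts["cultures_kept"] = len(cultures)
    load_rasters.last_filter_counts = counts  # stashed for the manifest
    return cultures


def first_order_table(raster: Raster, config: RunConfig) -> pd.DataFrame:
    """Per-neuron entropy, AIS (with embedding), horizon and entropy production."""
    rows = []
    for nid in raster.neuron_ids:
        series = raster.row(nid)
        rng = _task_rng(config.seed, raster.culture_id, raster.condition, nid, "ais")
        ent = shannon_entropy(series, nid)
        emb = select_embedding(
            series, config.tau_max, config.ais_shuffles, config.alpha, rng
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ais = active_information_storage(series, emb, nid, raster.bin_width_ms)
            tm = entropy_production(
                series, config.frame_bins, config.entropy_production_mode
            )
        rows.append(
            {
                "culture": raster.culture_id,
                "condition": raster.condition,
                "neuron": nid,
                "entropy": ent.H,
                "ais": ais.ais,
                "ais_normalized": ais.ais_normalized,
                "horizon_ms": ais.memory_horizon_ms,
                "entropy_production": tm.entropy_production,
                "selected_lags": ",".join(map(str, emb.selected_lags)),
            }
        )
    return pd.DataFrame(rows)


def _cached(path: Path, manifest: dict, stage: str, compute):
    """Load a stage CSV if present under the current config hash, else compute."""
    if path.exists() and manifest.get("stages", {}).get(stage) == manifest["config_hash"]:
        log.info("stage %s: cached", stage)
        return pd.read_csv(path, dtype={c: str for c in ("culture", "condition", "neuron", "source", "target", "parent1", "parent2")})
    df = compute()
    df.to_csv(path, index=False)
    manifest.setdefault("stages", {})[stage] = manifest["config_hash"]
    return df


def run_pipeline(config: RunConfig, input_dir, out_dir) -> ReportBundle:
    """Run the full analysis over a directory of spike CSVs.

    Deterministic given (config, seed): all randomness flows from the root
    seed through per-task derived streams keyed by (culture, condition,
    unit), so results are independent of neuron ordering and job count.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest["config"] = asdict(config)
    manifest["config_hash"] = config.config_hash()
    manifest["versions"] = {
        "spikedyn": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }

    cultures = load_rasters(input_dir, config)
    manifest["filter_counts"] = getattr(load_rasters, "last_filter_counts", {})
    if not cultures:
        raise RuntimeError("no culture passed the inclusion filters")

    def compute_first_order():
        frames = [
            first_order_table(r, config)
            for conds in cultures.values()
            for r in conds.values()
        ]
        return pd.concat(frames, ignore_index=True)

    first_order = _cached(out / "first_order.csv", manifest, "first_order", compute_first_order)

    networks: dict = {}

    def compute_networks():
        edge_frames, node_frames = [], []
        for culture, conds in cultures.items():
            for cond, raster in conds.items():
                net = infer_network(raster, config.network_config())
                networks[(culture, cond)] = net
                et = net.edge_table()
                et.insert(0, "culture", culture)
                et.insert(1, "condition", cond)
                edge_frames.append(et)
                nt = network_metrics(net, config.clustering_mode)
                nt.insert(0, "culture", culture)
                nt.insert(1, "condition", cond)
                node_frames.append(nt)
        return (
            pd.concat(edge_frames, ignore_index=True),
            pd.concat(node_frames, ignore_index=True),
        )

    edges_path, nodes_path = out / "edges.csv", out / "nodes.csv"
    hash_ok = manifest.get("stages", {}).get("network") == manifest["config_hash"]
    if edges_path.exists() and nodes_path.exists() and hash_ok:
        log.info("stage network: cached")
        edges = pd.read_csv(edges_path, dtype={"culture": str, "condition": str, "source": str, "target": str})
        nodes = pd.read_csv(nodes_path, dtype={"culture": str, "condition": str, "neuron_id": str})
    else:
        edges, nodes = compute_networks()
        edges.to_csv(edges_path, index=False)
        nodes.to_csv(nodes_path, index=False)
        manifest.setdefault("stages", {})["network"] = manifest["config_hash"]

    def compute_triads():
        frames = []
        for culture, conds in cultures.items():
            for cond, raster in conds.items():
                net = networks.get((culture, cond))
                if net is None:
                    net = _network_from_edges(edges, raster)
                frames.append(pid_table(raster, net, config.pid_min_overlap))
        return pd.concat(frames, ignore_index=True)

    triads = _cached(out / "triads.csv", manifest, "pid", compute_triads)

    # Repeated-measures battery: neurons (or per-target synergy means) pooled
    # across cultures, complete-cased across the three conditions.
    neuron_tidy = first_order.merge(
        nodes.rename(columns={"neuron_id": "neuron"}),
        on=["culture", "condition", "neuron"],
        how="left",
    )
    if len(triads):
        syn = (
            triads.groupby(["culture", "condition", "target"])["syn_normalized"]
            .mean()
            .reset_index()
            .rename(columns={"target": "neuron", "syn_normalized": "synergy_normalized"})
        )
        neuron_tidy = neuron_tidy.merge(
            syn, on=["culture", "condition", "neuron"], how="left"
        )
    else:
        neuron_tidy["synergy_normalized"] = np.nan
    measures = [
        "entropy", "ais", "ais_normalized", "horizon_ms", "entropy_production",
        "total_inflow", "in_degree", "clustering", "synergy_normalized",
    ]
    summary, comparisons = condition_summary(neuron_tidy, measures)
    summary.to_csv(out / "summary.csv", index=False)
    if config.make_plots:
        (out / "figures").mkdir(exist_ok=True)
        for measure in measures:
            if neuron_tidy[measure].notna().any():
                try:
                    plot_condition_cdfs(
                        neuron_tidy, measure, out / "figures" / f"cdf_{measure}.png"
                    )
                except ValueError:
                    pass

    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return ReportBundle(
        out,
        first_order,
        edges,
        nodes,
        triads,
        summary,
        comparisons,
        manifest.get("filter_counts", {}),
    )


def _network_from_edges(edges: pd.DataFrame, raster: Raster):
    """Rebuild a TENetwork for one culture/condition from the cached edge table."""
    from .network import TEEdge, TENetwork

    sub = edges[(edges["culture"] == raster.culture_id) & (edges["condition"] == raster.condition)]
    te_edges = [
        TEEdge(
            str(r.source), str(r.target), int(r.lag_bins),
            float(r.te_bits), float(r.te_normalized), float(r.p_value),
        )
        for r in sub.itertuples()
    ]
    return TENetwork(list(raster.neuron_ids), te_edges)
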