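"""End-to-end pipeline: filter, diversity, distances, clustering, plots.

One configuration object drives the whole chain and round-trips through
YAML. Outputs are deterministic for a fixed configuration and input: every
run writes the same bytes, and a structured run log records each stage, its
parameters, the input hash and row counts.

Stage order: frequencies are computed once; diversity is evaluated on the
full (unfiltered) matrix, because effective diversity is a property of the
whole population while filtered frequencies no longer sum to one; the
mean-frequency/persistence filter then restricts the matrix for distance
computation, clustering, consensus and ranking.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import viz
from .clustering import (
    call_clonal_clusters,
    linkage,
    quantify_thresholds,
    select_threshold,
)
from .core import read_barcode_table, to_frequencies, write_barcode_table, BarcodeTimeSeries
from .distance import build_distance_matrix, transform_trajectories
from .diversity import DEFAULT_ORDERS, diversity_timeseries
from .filtering import FilterSpec, apply_filters

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters plus I/O paths; round-trips through YAML."""

    input_path: str = ""
    output_dir: str = "."
    delimiter: str = ","
    # filter
    min_mean_frequency: float = 1e-4
    min_persistence: int = 12
    # frequencies
    floor_policy: str | float = "half_min_detectable"
    # diversity
    orders: tuple[float, ...] = DEFAULT_ORDERS
    # distance
    metric: str = "pearson"
    transform: str = "log10_floored"
    dtw_window: int | None = None
    # clustering
    linkage_method: str = "upgma"
    cut_height: float | None = None
    auto_threshold: str = "knee"
    grid_size: int = 100
    loess_span: float = 0.75
    loess_degree: int = 2
    min_cluster_frequency: float = 0.01
    # plotting
    plot_scale: str = "log"
    seed: int = 0
    schema_version: int = 1

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = dataclasses.asdict(self)
        d["orders"] = ["inf" if np.isinf(q) else float(q) for q in self.orders]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("schema_version", 1) != 1:
            raise ValueError("unsupported config schema version")
        d["orders"] = tuple(float(q) for q in d.get("orders", DEFAULT_ORDERS))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["orders"] = ["inf" if np.isinf(q) else float(q) for q in self.orders]
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def _file_hash(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig, ts: BarcodeTimeSeries | None = None) -> dict:
    """Execute the full chain and write all outputs into ``output_dir``.

    ``ts`` may be passed directly (e.g. a simulation result); otherwise
    ``config.input_path`` is read. Returns a dict of the in-memory products
    (frequency matrices, diversity profile, distance matrix, tree,
    quantification, clusters, run log).
    """
    os.makedirs(config.output_dir, exist_ok=True)
    log: list[dict] = []
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    def out(name: str) -> str:
        return os.path.join(config.output_dir, name)

    def stage(name: str, **info) -> None:
        log.append({"stage": name, **stamp, **info})

    try:
        if ts is None:
            ts = read_barcode_table(config.input_path, config.delimiter)
            stage("read", input_hash=_file_hash(config.input_path),
                  n_barcodes=ts.n_barcodes, n_timepoints=ts.n_timepoints)
        else:
            stage("read", input_hash="in-memory", n_barcodes=ts.n_barcodes,
                  n_timepoints=ts.n_timepoints)

        fm = to_frequencies(ts, config.floor_policy)

        profile = diversity_timeseries(fm, config.orders)
        profile.to_frame().to_csv(out("diversity.csv"), index=False)
        stage("diversity", orders=len(config.orders))

        spec = FilterSpec(config.min_mean_frequency, config.min_persistence,
                          fm.n_timepoints)
        fmf, report = apply_filters(fm, spec)
        report.to_csv(out("rejected.csv"), index=False)
        keep = set(fmf.barcode_ids)
        mask = np.array([b in keep for b in ts.barcode_ids])
        filtered_ts = BarcodeTimeSeries(
            [b for b in ts.barcode_ids if b in keep], ts.timepoints,
            ts.counts[mask],
        )
        write_barcode_table(filtered_ts, out("filtered.csv"))
        stage("filter", survivors=fmf.n_barcodes,
              rejected=int(len(report)))

        dm = build_distance_matrix(fmf, config.metric, config.transform,
                                   config.dtw_window)
        stage("distance", metric=config.metric, transform=config.transform,
              n=dm.n)

        T = transform_trajectories(fmf, config.transform)
        tree = linkage(
            dm, config.linkage_method,
            trajectories=T if config.linkage_method == "upgmc" else None,
        )
        with open(out("dendrogram.nwk"), "w") as fh:
            fh.write(tree.to_newick() + "\n")
        quant = quantify_thresholds(tree, dm, T, config.grid_size)
        quant.to_frame().to_csv(out("quantification.csv"), index=False)
        stage("quantify", grid_size=config.grid_size,
              max_height=tree.max_height)

        height = (
            float(config.cut_height)
            if config.cut_height is not None
            else select_threshold(quant, config.auto_threshold)
        )
        clusters = call_clonal_clusters(
            fmf, dm, tree, height,
            span=config.loess_span, degree=config.loess_degree,
            min_cluster_frequency=config.min_cluster_frequency,
        )
        clusters.assignment_frame().to_csv(out("clusters.csv"), index=False)
        clusters.consensus.to_csv(out("consensus.csv"), index=False)
        stage("cluster", cut_height=height, n_clusters=clusters.n_clusters)

        viz.plot_dynamics(fm, out("dynamics.png"), scale=config.plot_scale)
        viz.plot_diversity(profile, out("diversity.png"))
        viz.plot_clusters(fmf, clusters, out("clusters.png"),
                          scale=config.plot_scale)
        stage("plot", scale=config.plot_scale)
    except Exception as exc:
        failed_stage = log[-1]["stage"] if log else "read"
        raise RuntimeError(
            f"pipeline failed after stage {failed_stage!r}: {exc}"
        ) from exc

    with open(out("run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, default=str)
        fh.write("\n")
    return {
        "series": ts,
        "frequencies": fm,
        "filtered": fmf,
        "rejected": report,
        "diversity": profile,
        "distance": dm,
        "tree": tree,
        "quantification": quant,
        "cut_height": height,
        "clusters": clusters,
        "log": log,
    }
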