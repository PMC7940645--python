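"""End-to-end pipeline stages shared by the CLI and the analysis scripts.

Stages mirror the analysis workflow: simulate (or load) group tables,
analyze each group x pathway (persistence facets, graph metrics,
filtration snapshots), compare groups by permutation testing.  Every
stage writes a manifest of its artifacts with SHA-256 checksums, so two
runs from the same config can be verified byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import (
    PathwayDefinition,
    SubjectMatrix,
    default_pathways,
    extract_pathway,
    load_pathway_config,
    read_subject_table,
)
from .config import RunConfig
from .connectivity import pearson_matrix, to_distance
from .graph_metrics import (
    characteristic_path_length,
    eigenvector_centrality,
    filter_edges,
    network_diameter,
)
from .group_stats import pairwise_comparison_table
from .persistence import analyze_distance, snapshot_graph, to_newick
from .synthetic import pathways_from_layout, write_cohort

__all__ = [
    "run_simulate",
    "load_groups",
    "resolve_pathways",
    "run_analyze",
    "run_compare",
    "write_manifest",
]

log = logging.getLogger("phnet")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(root: Path, files: list[Path], name: str) -> Path:
    """Checksum manifest of all artifacts of one stage."""
    entries = {str(p.relative_to(root)): _sha256(p) for p in sorted(files)}
    out = root / name
    out.write_text(json.dumps({"artifacts": entries}, indent=2, sort_keys=True) + "\n")
    return out


def run_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate the synthetic cohort and write it under ``out_dir/cohort``."""
    spec = config.synthetic_spec
    if spec is None:
        raise ValueError("config has no synthetic spec; nothing to simulate")
    t0 = time.perf_counter()
    out = Path(config.out_dir) / "cohort"
    paths = write_cohort(spec, out)
    log.info("stage=simulate groups=%d out=%s wall=%.2fs",
             len(spec.group_names), out, time.perf_counter() - t0)
    return paths


def load_groups(config: RunConfig) -> list[SubjectMatrix]:
    """Load group tables (real-data mode) or the simulated cohort."""
    if config.group_tables:
        return [
            read_subject_table(path, group_label=label)
            for label, path in config.group_tables.items()
        ]
    spec = config.synthetic_spec
    cohort_dir = Path(config.out_dir) / "cohort"
    if not cohort_dir.exists():
        run_simulate(config)
    return [
        read_subject_table(cohort_dir / f"group_{name}.csv", group_label=name)
        for name in spec.group_names
    ]


def resolve_pathways(config: RunConfig) -> list[PathwayDefinition]:
    if config.pathway_config is not None:
        return load_pathway_config(config.pathway_config)
    spec = config.synthetic_spec
    if spec is not None and not config.group_tables:
        return pathways_from_layout(spec.pathway_layout)
    return default_pathways()


def _write_snapshot(dist, lam: float, out_dir: Path) -> list[Path]:
    snap = snapshot_graph(dist, lam)
    names = snap.roi_names
    edges = pd.DataFrame(
        [
            {
                "roi_a": names[i],
                "roi_b": names[j],
                "distance": w,
                "component": int(snap.component_labels[i]),
            }
            for i, j, w in snap.edges
        ],
        columns=["roi_a", "roi_b", "distance", "component"],
    )
    nodes = pd.DataFrame(
        {"roi": names, "component": snap.component_labels.astype(int)}
    )
    tag = f"{lam:.2f}".replace(".", "p")
    e_path = out_dir / f"snapshot_lambda_{tag}_edges.csv"
    n_path = out_dir / f"snapshot_lambda_{tag}_nodes.csv"
    edges.to_csv(e_path, index=False)
    nodes.to_csv(n_path, index=False)
    return [e_path, n_path]


def run_analyze(config: RunConfig, plots: bool = False) -> Path:
    """Per-group, per-pathway persistence + graph metrics + snapshots.

    Writes, for each group x pathway: Betti-0 curve, barcode, MST edges,
    SLD matrix, Newick dendrogram and snapshot edge lists; plus one tidy
    metrics table and a checksum manifest for the whole stage.
    """
    root = Path(config.out_dir)
    groups = load_groups(config)
    pathways = resolve_pathways(config)
    analysis_dir = root / "analysis"
    artifacts: list[Path] = []
    metric_rows = []
    for group in groups:
        for pathway in pathways:
            t0 = time.perf_counter()
            sub = extract_pathway(group, pathway)
            dist = to_distance(pearson_matrix(sub))
            res = analyze_distance(dist)
            out_dir = analysis_dir / group.group_label / pathway.name
            out_dir.mkdir(parents=True, exist_ok=True)

            bp = np.concatenate([[0.0], res.betti.breakpoints])
            pd.DataFrame({"interval_start": bp, "n_components": res.betti.counts}).to_csv(
                out_dir / "betti0_curve.csv", index=False
            )
            pd.DataFrame(res.barcode.bars, columns=["birth", "death"]).to_csv(
                out_dir / "barcode.csv", index=False
            )
            pd.DataFrame(
                [
                    {"roi_a": dist.roi_names[i], "roi_b": dist.roi_names[j], "weight": w}
                    for i, j, w in res.mst_edges
                ]
            ).to_csv(out_dir / "mst_edges.csv", index=False)
            pd.DataFrame(
                res.single_linkage.sld, index=dist.roi_names, columns=dist.roi_names
            ).to_csv(out_dir / "sld.csv")
            (out_dir / "dendrogram.nwk").write_text(
                to_newick(res.single_linkage) + "\n", encoding="utf-8"
            )
            stage_files = [
                out_dir / "betti0_curve.csv",
                out_dir / "barcode.csv",
                out_dir / "mst_edges.csv",
                out_dir / "sld.csv",
                out_dir / "dendrogram.nwk",
            ]
            for lam in config.snapshot_lambdas:
                stage_files.extend(_write_snapshot(dist, lam, out_dir))

            g = filter_edges(
                dist,
                threshold=config.edge_threshold,
                rule=config.retain_rule,
                density=config.density,
            )
            cpl = characteristic_path_length(g)
            nd = network_diameter(g)
            if g.edges:
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    ec = eigenvector_centrality(g)
                ec_mean = float(np.mean(list(ec.values())))
                pd.DataFrame(
                    {"roi": list(ec), "eigenvector_centrality": list(ec.values())}
                ).to_csv(out_dir / "ec_scores.csv", index=False)
                stage_files.append(out_dir / "ec_scores.csv")
            else:
                ec_mean = float("nan")
            rule_tag = json.dumps(g.retain_rule, sort_keys=True)
            for metric, value, ndisc in (
                ("sip_auc", res.sip_auc, 0),
                ("cpl", cpl.value, cpl.n_disconnected_pairs),
                ("nd", nd.value, nd.n_disconnected_pairs),
                ("ec_mean", ec_mean, 0),
            ):
                metric_rows.append(
                    {
                        "group": group.group_label,
                        "pathway": pathway.name,
                        "metric": metric,
                        "value": np.nan if value is None else value,
                        "retain_rule": rule_tag,
                        "n_disconnected_pairs": ndisc,
                    }
                )
            if plots:
                from . import plots as _plots

                stage_files.extend(_plots.plot_pathway(res, dist, out_dir / "plots"))
            artifacts.extend(stage_files)
            log.info(
                "stage=analyze group=%s pathway=%s n_roi=%d sip_auc=%.4f wall=%.2fs",
                group.group_label, pathway.name, len(pathway),
                res.sip_auc, time.perf_counter() - t0,
            )
    metrics_path = analysis_dir / "metrics.csv"
    pd.DataFrame(metric_rows).to_csv(metrics_path, index=False)
    artifacts.append(metrics_path)
    return write_manifest(root, artifacts, "manifest_analyze.json")


def run_compare(config: RunConfig) -> Path:
    """Pairwise permutation comparisons; writes the tidy table + metadata."""
    root = Path(config.out_dir)
    groups = load_groups(config)
    pathways = resolve_pathways(config)
    t0 = time.perf_counter()
    table = pairwise_comparison_table(
        groups,
        pathways,
        statistics=list(config.statistics),
        n_permutations=config.n_permutations,
        seed=config.seed,
        alpha=config.alpha,
        threshold=config.edge_threshold,
    )
    out_dir = root / "compare"
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "comparisons.csv"
    table.to_csv(csv_path, index=False)
    json_path = out_dir / "comparisons.json"
    json_path.write_text(table.to_json(orient="records", indent=2) + "\n")
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(
        json.dumps(
            {
                "seed": config.seed,
                "n_permutations": config.n_permutations,
                "alpha": config.alpha,
                "edge_threshold": config.edge_threshold,
                "retain_rule": config.retain_rule,
                "statistics": list(config.statistics),
                "null_construction": "subject-label permutation, group sizes preserved, "
                "statistic recomputed from correlation onward per shuffle",
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    log.info("stage=compare rows=%d wall=%.2fs", len(table), time.perf_counter() - t0)
    return write_manifest(root, [csv_path, json_path, meta_path], "manifest_compare.json")
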