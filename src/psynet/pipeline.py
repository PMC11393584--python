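"""Full study pipeline: data -> scoring -> descriptives -> per-group
networks -> centrality -> stability -> comparison -> bridge -> report.

The report mirrors the result shape of the study: a demographics table, a
covariate correlation matrix, per-group self-efficacy network summaries and
centrality tables, CS-coefficients, the network comparison (M, S, p-values,
per-edge change profile), and bridge centrality on the pooled 19-node
network.  Every stochastic stage draws its own child seed from the master
seed, so a config + seed pair fully determines the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import child_seed
from .bridge import bridge_table, cross_community_edges, top_bridge_nodes
from .centrality import centrality_table
from .descriptives import correlation_table, group_comparison_table
from .errors import PsynetError
from .ggm import estimate_network, network_summary
from .nct import edge_difference_tests, nct
from .scales import GSES, PHQ9, from_frame, read_item_table, score_sample
from .simulate import (
    GSES_ITEMS,
    PHQ9_ITEMS,
    GeneratorConfig,
    generate_two_group_study,
)
from .stability import case_dropping_bootstrap, cs_coefficient

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs; YAML-loadable."""

    input_path: str | None = None  # None -> simulate
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    estimator: dict = field(default_factory=dict)  # estimate_network kwargs
    stability_B: int = 1000
    stability_indices: tuple[str, ...] = ("strength", "expected_influence",
                                          "closeness", "betweenness", "edge")
    nct_iterations: int = 1000
    nct_correction: str | None = None
    alpha: float = 0.05
    cutoff: int = 10
    bridge_per_group: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            gen = dict(d["generator"])
            for key in ("base_edits", "group_edits"):
                if gen.get(key):
                    from .simulate import EdgeEdit

                    gen[key] = [EdgeEdit(**e) for e in gen[key]]
            d["generator"] = GeneratorConfig(**gen)
        if "stability_indices" in d:
            d["stability_indices"] = tuple(d["stability_indices"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "generator": self.generator.to_dict(),
            "estimator": dict(self.estimator),
            "stability_B": self.stability_B,
            "stability_indices": list(self.stability_indices),
            "nct_iterations": self.nct_iterations,
            "nct_correction": self.nct_correction,
            "alpha": self.alpha,
            "cutoff": self.cutoff,
            "bridge_per_group": self.bridge_per_group,
            "seed": self.seed,
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    config: AnalysisConfig
    group_counts: dict
    descriptives: pd.DataFrame
    correlations_r: pd.DataFrame
    correlations_p: pd.DataFrame
    network_summaries: dict  # group -> summary dict
    edge_lists: dict  # group -> DataFrame
    centrality: dict  # group -> DataFrame
    cs_coefficients: dict  # group -> {index: value}
    cs_quantiles: dict  # group -> DataFrame
    nct_summary: dict
    edge_changes: pd.DataFrame
    bridge: pd.DataFrame
    bridge_cross_edges: pd.DataFrame
    top_bridges: list
    timings: dict
    provenance: dict

    def to_dict(self) -> dict:
        def df(d):
            return d.reset_index().to_dict(orient="list") if isinstance(d, pd.DataFrame) else d

        return {
            "provenance": self.provenance,
            "group_counts": self.group_counts,
            "descriptives": df(self.descriptives),
            "correlations_r": df(self.correlations_r),
            "correlations_p": df(self.correlations_p),
            "network_summaries": self.network_summaries,
            "edge_lists": {g: df(t) for g, t in self.edge_lists.items()},
            "centrality": {g: df(t) for g, t in self.centrality.items()},
            "cs_coefficients": self.cs_coefficients,
            "cs_quantiles": {g: df(t) for g, t in self.cs_quantiles.items()},
            "nct": self.nct_summary,
            "edge_changes": df(self.edge_changes),
            "bridge": df(self.bridge),
            "bridge_cross_edges": df(self.bridge_cross_edges),
            "top_bridges": self.top_bridges,
            # timings stay off the serialized report so that a config + seed
            # pair yields a byte-identical JSON file
        }

    def to_json(self, indent: int = 2) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        return json.dumps(self.to_dict(), indent=indent, default=default,
                          sort_keys=True)


def _edge_list_frame(net) -> pd.DataFrame:
    return pd.DataFrame(net.edge_list(), columns=["node_i", "node_j", "weight"])


def run_full_analysis(config: AnalysisConfig | None = None) -> StudyReport:
    """Execute the whole pipeline; see the module docstring for the stages."""
    cfg = config or AnalysisConfig()
    timings: dict[str, float] = {}
    stage_t = time.perf_counter

    def tick(stage, t0):
        timings[stage] = round(stage_t() - t0, 3)

    # -- data ---------------------------------------------------------------
    t0 = stage_t()
    truths = None
    if cfg.input_path is not None:
        matrix = read_item_table(cfg.input_path)
    else:
        gen_cfg = cfg.generator
        gen_cfg.seed = child_seed(cfg.seed, "generator")
        study = generate_two_group_study(gen_cfg)
        truths = study
        frame = study.combined_frame().drop(columns=["group_true"])
        matrix = from_frame(frame)
    tick("data", t0)

    # -- scoring & descriptives --------------------------------------------
    t0 = stage_t()
    scored, grouped = score_sample(matrix, cutoff=cfg.cutoff)
    counts = grouped.counts()
    desc = group_comparison_table(scored)
    corr_vars = [c for c in ("age", "gender", "education") if c in scored]
    corr_vars += ["phq9_total", "gses_total"]
    corr = correlation_table(scored, corr_vars)
    tick("descriptives", t0)

    # -- per-group self-efficacy networks ----------------------------------
    t0 = stage_t()
    groups = {}
    for name in ("depressed", "control"):
        sub = matrix.rows((grouped.group == name).to_numpy()).subset(GSES_ITEMS)
        groups[name] = sub
    nets = {name: estimate_network(sub, **cfg.estimator) for name, sub in groups.items()}
    summaries = {name: network_summary(net) for name, net in nets.items()}
    edge_lists = {name: _edge_list_frame(net) for name, net in nets.items()}
    tick("estimate", t0)

    # -- centrality ---------------------------------------------------------
    t0 = stage_t()
    cent = {name: centrality_table(net) for name, net in nets.items()}
    tick("centrality", t0)

    # -- stability ----------------------------------------------------------
    t0 = stage_t()
    cs_values, cs_quant = {}, {}
    for name, sub in groups.items():
        res = case_dropping_bootstrap(
            sub, B=cfg.stability_B,
            seed=child_seed(cfg.seed, f"casedrop-{name}"),
            indices=cfg.stability_indices, estimator=cfg.estimator,
        )
        cs_values[name] = {ix: cs_coefficient(res, index=ix)
                           for ix in cfg.stability_indices}
        cs_quant[name] = res.quantile_table()
    tick("stability", t0)

    # -- network comparison -------------------------------------------------
    t0 = stage_t()
    result = nct(
        groups["control"], groups["depressed"],
        iterations=cfg.nct_iterations,
        seed=child_seed(cfg.seed, "nct"),
        estimator=cfg.estimator,
    )
    changes = edge_difference_tests(result, alpha=cfg.alpha,
                                    correction=cfg.nct_correction)
    tick("nct", t0)

    # -- bridge (pooled 19-node network) -------------------------------------
    t0 = stage_t()
    communities = {**{s: "self-efficacy" for s in GSES_ITEMS},
                   **{d: "depression" for d in PHQ9_ITEMS}}
    pooled_net = estimate_network(matrix.subset(GSES_ITEMS + PHQ9_ITEMS),
                                  **cfg.estimator)
    btable = bridge_table(pooled_net, communities)
    bcross = cross_community_edges(pooled_net, communities)
    tops = top_bridge_nodes(btable, k=2)
    tick("bridge", t0)

    log.info("stage timings (s): %s", timings)
    provenance = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "package_version": __version__,
        "n_input_rows": matrix.n + matrix.n_dropped,
        "n_dropped": matrix.n_dropped,
        "simulated": cfg.input_path is None,
    }
    if truths is not None:
        provenance["true_global_strength_control"] = truths.truth_control.global_strength()
        provenance["true_global_strength_depressed"] = truths.truth_depressed.global_strength()

    return StudyReport(
        config=cfg, group_counts=counts, descriptives=desc,
        correlations_r=corr.r, correlations_p=corr.p,
        network_summaries=summaries, edge_lists=edge_lists,
        centrality=cent, cs_coefficients=cs_values, cs_quantiles=cs_quant,
        nct_summary=result.summary(), edge_changes=changes,
        bridge=btable, bridge_cross_edges=bcross, top_bridges=tops,
        timings=timings, provenance=provenance,
    )


def export_report(report: StudyReport, outdir, formats=("json", "csv", "graphml")) -> list[str]:
    """Write the report as JSON + CSV tables + GraphML networks."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    if "json" in formats:
        path = out / "report.json"
        path.write_text(report.to_json())
        written.append(str(path))

    if "csv" in formats:
        tables = {
            "descriptives.csv": report.descriptives,
            "correlations_r.csv": report.correlations_r,
            "correlations_p.csv": report.correlations_p,
            "edge_changes.csv": report.edge_changes,
            "bridge.csv": report.bridge,
            "bridge_cross_edges.csv": report.bridge_cross_edges,
        }
        for name, tab in report.centrality.items():
            tables[f"centrality_{name}.csv"] = tab
        for name, tab in report.edge_lists.items():
            tables[f"edges_{name}.csv"] = tab
        for name, tab in report.cs_quantiles.items():
            tables[f"cs_quantiles_{name}.csv"] = tab
        for name, tab in tables.items():
            path = out / name
            tab.to_csv(path)
            written.append(str(path))

    if "graphml" in formats:
        import networkx as nx

        for name, edges in report.edge_lists.items():
            G = nx.Graph()
            labels = report.centrality[name].index.tolist()
            G.add_nodes_from(labels)
            for _, row in edges.iterrows():
                G.add_edge(row["node_i"], row["node_j"], weight=float(row["weight"]))
            path = out / f"network_{name}.graphml"
            nx.write_graphml(G, path)
            written.append(str(path))
    return written


def load_report_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
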