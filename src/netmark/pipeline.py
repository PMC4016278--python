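"""End-to-end orchestration: preprocess -> DE -> enrichment -> phenotype
correlation -> PPI subnetwork -> clustering, with provenance.

A run is configured either by file inputs (expression TSV, labels TSV,
edge-list TSV, GMT) or by a ``synthetic`` block with generator parameters.
All stage outputs are plain CSV/TSV/JSON in the output directory; the
summary JSON is deterministic (byte-identical for identical config+seed)
and carries the config hash, so a run is reconstructible from its log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx
import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .containers import ExpressionMatrix, PhenotypeLabels
from .errors import ParameterError
from .preprocess import (
    DEFAULT_TARGET_MEAN,
    log2_transform,
    normalize_global,
    preprocess,
    read_expression_table,
    read_labels,
)
from .sam import SamConfig, call_degs
from .pheno import correlation_table, intersect_with_degs
from .network import (
    Network,
    build_network,
    edge_coexpression,
    filter_edges,
    hub_ranking,
    read_edge_list,
    restrict_to_expression,
    write_network,
)
from .enrich import hypergeometric_enrichment, read_gmt
from .cluster import hierarchical_cluster, partition_genes, sample_separation_score
from .synthetic import SyntheticParams, generate_dataset

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One run's inputs and thresholds.

    Exactly one of (file inputs) or (synthetic block) must be given.
    Default thresholds are the analysis' canonical cutoffs: DE at BH
    q < 0.01, phenotype and edge correlation |r| > 0.8, enrichment
    FDR < 0.05.
    """

    synthetic: SyntheticParams | None = None
    expr_path: str | None = None
    probe_map_path: str | None = None
    labels_path: str | None = None
    edges_path: str | None = None
    gmt_path: str | None = None
    target_mean: float = DEFAULT_TARGET_MEAN
    log_scale: bool = True
    de_alpha: float = 0.01
    n_perm: int = 1000
    r_pheno: float = 0.8
    r_edge: float = 0.8
    enrich_fdr: float = 0.05
    endpoint_rule: str = "both"
    top_hubs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_alpha", "r_pheno", "r_edge", "enrich_fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"{name} must be in (0, 1), got {v}")
        has_files = self.expr_path is not None
        if has_files == (self.synthetic is not None):
            raise ParameterError(
                "config must provide either file inputs or a synthetic block, not both"
            )
        if has_files and (self.labels_path is None):
            raise ParameterError("file inputs require labels_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ParameterError(f"config {path} must be a mapping")
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticParams(**raw["synthetic"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ParameterError(f"bad config {path}: {exc}") from exc

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        bundle = generate_dataset(cfg.synthetic, cfg.seed)
        return bundle.expression, bundle.labels, bundle.edges, bundle.gene_sets, bundle.truth
    data = read_expression_table(cfg.expr_path, cfg.probe_map_path)
    labels = read_labels(cfg.labels_path)
    edges = read_edge_list(cfg.edges_path) if cfg.edges_path else None
    gene_sets = read_gmt(cfg.gmt_path) if cfg.gmt_path else None
    return data, labels, edges, gene_sets, None


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis; write stage outputs; return the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data, labels, edges, gene_sets, truth = _load_inputs(cfg)

    # 1. preprocess: (collapse) -> mean-100 normalization -> log2
    if isinstance(data, ExpressionMatrix):
        em = normalize_global(data, cfg.target_mean)
        em = log2_transform(em) if cfg.log_scale else em
    else:
        em = preprocess(data, cfg.target_mean, cfg.log_scale)
    labels.check_matches(em)

    # 2. SAM differential expression at BH q < alpha
    sam_cfg = SamConfig(n_perm=cfg.n_perm, alpha=cfg.de_alpha, seed=cfg.seed)
    degs = call_degs(em, labels, sam_cfg)
    degs.to_csv(out / "degs.csv")
    sig = degs[degs["significant"]]
    up = set(sig.index[sig["direction"] == "up"])
    down = set(sig.index[sig["direction"] == "down"])

    # 3. enrichment of the full, up, and down DEG lists
    enrichment_summary = {}
    if gene_sets:
        universe = set(em.gene_ids)
        for name, lst in (("all", up | down), ("up", up), ("down", down)):
            table = hypergeometric_enrichment(lst, gene_sets, universe, cfg.enrich_fdr)
            table.to_csv(out / f"enrichment_{name}.csv", index=False)
            enrichment_summary[name] = {
                "n_significant": int(table["significant"].sum()),
                "top_set": str(table.iloc[0]["set_id"]) if len(table) else None,
                "top_fdr": float(table.iloc[0]["fdr"]) if len(table) else None,
            }

    # 4. phenotype-correlation selection and intersection with DEGs
    pheno = correlation_table(em, labels, degs, cfg.r_pheno)
    pheno.to_csv(out / "pheno.csv")
    selected = set(pheno.index[pheno["selected"]])
    pheno_degs, exceptions = intersect_with_degs(selected, degs)

    # 5. co-expression-filtered PPI subnetwork and hubs
    net = Network()
    hubs: list[tuple[str, int]] = []
    n_expr_edges = n_filtered_edges = 0
    if edges is not None and len(edges):
        expr_edges = restrict_to_expression(edges, em)
        n_expr_edges = len(expr_edges)
        coexpr = edge_coexpression(expr_edges, em)
        filtered = filter_edges(coexpr, cfg.r_edge)
        n_filtered_edges = len(filtered)
        net = build_network(filtered, pheno_degs, cfg.endpoint_rule)
        if net.n_edges:
            write_network(net, out / "network.sif", "sif")
            write_network(net, out / "network.graphml", "graphml")
        hubs = hub_ranking(net, cfg.top_hubs)
        pd.DataFrame(hubs, columns=["gene_id", "degree"]).to_csv(
            out / "hubs.csv", index=False
        )
        if cfg.endpoint_rule == "both":
            assert net.nodes <= pheno_degs, "network nodes must be phenotype-related DEGs"
    assert pheno_degs <= (up | down), "phenotype-related DEGs must be DEGs"
    assert selected == pheno_degs | set(exceptions)

    # 6. clustering validation on the signature (network node genes)
    purity = None
    gene_groups_summary = None
    signature = sorted(net.nodes)
    if len(signature) >= 2:
        em_sig = ExpressionMatrix(em.values.loc[signature], scale=em.scale)
        stree = hierarchical_cluster(em_sig, axis="samples")
        purity = sample_separation_score(stree, em_sig.sample_ids, labels)
        gtree = hierarchical_cluster(em_sig, axis="genes")
        groups = partition_genes(gtree, em_sig, labels)
        groups.to_csv(out / "gene_clusters.csv")
        gene_groups_summary = {
            "n_up_group": int((groups["group_direction"] == "up").sum()),
            "n_down_group": int((groups["group_direction"] == "down").sum()),
        }

    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_genes": em.n_genes,
        "n_samples": em.n_samples,
        "s0": float(degs.attrs["s0"]),
        "n_degs": int(len(sig)),
        "n_up": len(up),
        "n_down": len(down),
        "n_phenotype_related": len(selected),
        "n_phenotype_related_degs": len(pheno_degs),
        "n_pheno_not_deg_exceptions": len(exceptions),
        "n_expression_matched_edges": n_expr_edges,
        "n_filtered_edges": n_filtered_edges,
        "n_network_edges": net.n_edges,
        "n_network_nodes": len(net.nodes),
        "hubs": [[g, int(d)] for g, d in hubs],
        "clustering_purity": purity,
        "gene_groups": gene_groups_summary,
        "enrichment": enrichment_summary,
    }
    if truth is not None:
        called = up | down
        tp = len(called & truth.de_gene_ids)
        summary["truth"] = {
            "de_sensitivity": tp / len(truth.de_gene_ids) if truth.de_gene_ids else None,
            "de_empirical_fdr": (len(called) - tp) / len(called) if called else 0.0,
            "planted_hub": truth.planted_hub,
            "hub_recovered": bool(hubs) and hubs[0][0] == truth.planted_hub,
            "enriched_set_id": truth.enriched_set_id,
            "enriched_set_top": (
                enrichment_summary.get("all", {}).get("top_set") == truth.enriched_set_id
                if enrichment_summary
                else None
            ),
        }
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run.log", "w", encoding="utf-8") as fh:
        fh.write(
            "netmark {} | python {} | numpy {} | scipy {} | pandas {} | networkx {}\n".format(
                __version__,
                platform.python_version(),
                np.__version__,
                scipy.__version__,
                pd.__version__,
                networkx.__version__,
            )
        )
        fh.write(f"seed={cfg.seed} config_hash={cfg.config_hash()}\n")
        fh.write(json.dumps(cfg.to_dict(), sort_keys=True) + "\n")
    return summary


def demo(seed: int, out_dir: str | Path, params: SyntheticParams | None = None) -> dict:
    """One-command synthetic end-to-end run at the default study conditions."""
    cfg = PipelineConfig(synthetic=params or SyntheticParams(), seed=seed)
    return run_pipeline(cfg, out_dir)
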