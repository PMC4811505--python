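"""End-to-end orchestration: simulate or load inputs, run every stage, report.

The pipeline mirrors the RIP-Seq analysis flow: enrichment calling from
counts, optional dual-criterion calling against the binding-dead mutant,
integration with knockdown expression, ARE group comparison of bound vs
control UTRs, network enrichment against pathway sets, and consensus-motif
characterization of candidate regions. Each stage is skipped when its inputs
are not configured. Outputs are TSV/JSON files plus a manifest sufficient to
re-run identically; the whole run is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as rio
from . import __version__
from .aremotif import canonicalize, group_are_summary, profile
from .enrichment import (
    CONTRAST_W_VS_C,
    CONTRAST_W_VS_WMUT,
    call_enriched,
    call_enriched_dual,
    fit_contrast,
    normalize_counts,
)
from .network import load_network, nea_batch
from .regulation import call_regulated_table, integrate, replicate_fold_changes
from .simulate import (
    GeneSet,
    RipSimConfig,
    UtrSimConfig,
    simulate_knockdown,
    simulate_network,
    simulate_ripseq_counts,
    simulate_utrs,
)
from .structure import align_regions, consensus_from_alignment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a pipeline run; unset paths skip their stage."""

    out_dir: str
    counts: str | None = None
    design: str | None = None
    expression: str | None = None
    bound_fasta: str | None = None
    control_fasta: str | None = None
    regions_fasta: str | None = None
    network: str | None = None
    gmt: str | None = None
    dual_mutant: bool = False
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    fold_threshold: float = 4.0
    min_reps: int = 2
    u_stretch_min: int = 17
    nea_cutoff: float = 0.5
    seed: int = 0

    def validate_paths(self) -> None:
        for name in ("counts", "design", "expression", "bound_fasta",
                     "control_fasta", "regions_fasta", "network", "gmt"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def simulate_bundle(out_dir: str | Path, seed: int = 0,
                    rip: RipSimConfig | None = None) -> dict[str, str]:
    """Write a complete synthetic input bundle and its truth tables.

    Returns a dict of logical name -> path, usable to fill a PipelineConfig.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rip = rip or RipSimConfig(seed=seed)
    cm, truth = simulate_ripseq_counts(rip)
    rio.write_counts_tsv(cm.counts, out / "counts.tsv")
    rio.write_design_tsv(cm.design, out / "design.tsv")
    truth.to_csv(out / "truth_rip.tsv", sep="\t")

    expr = simulate_knockdown(truth, seed=seed + 1)
    expr.to_csv(out / "expression.tsv", sep="\t", index_label="gene")

    bound_records, bound_truth = simulate_utrs(
        UtrSimConfig(n_sequences=100, gc_target=0.33, pentamer_rate=2.0,
                     u_stretch_prob=0.07, id_prefix="bound", seed=seed + 2))
    ctrl_records, ctrl_truth = simulate_utrs(
        UtrSimConfig(n_sequences=100, gc_target=0.46, pentamer_rate=0.0,
                     u_stretch_prob=0.02, id_prefix="ctrl", seed=seed + 3))
    rio.write_fasta(bound_records, out / "bound_utrs.fa")
    rio.write_fasta(ctrl_records, out / "control_utrs.fa")
    bound_truth.to_csv(out / "truth_bound_utrs.tsv", sep="\t")
    ctrl_truth.to_csv(out / "truth_control_utrs.tsv", sep="\t")

    # the network covers the simulated gene universe and wires the pathway
    # to the planted enriched genes, so the bound set recovers it
    enriched_genes = sorted(truth.index[truth["is_enriched"]])
    net, pathway, ags = simulate_network(
        n_nodes=rip.n_genes,
        n_edges=min(10 * rip.n_genes, rip.n_genes * (rip.n_genes - 1) // 2),
        pathway_size=min(40, max(5, rip.n_genes // 10)),
        planted_connectivity=5.0,
        seed=seed + 4,
        ags_nodes=enriched_genes,
    )
    edges = [(u, v, d["confidence"]) for u, v, d in sorted(net.edges(data=True))]
    rio.write_edge_list(edges, out / "network.tsv")
    decoys = []
    import numpy as np

    rng = np.random.default_rng(seed + 5)
    nodes = sorted(net.nodes)
    for i in range(9):
        members = rng.choice(len(nodes), size=len(pathway), replace=False)
        decoys.append(GeneSet(f"decoy_{i:02d}", frozenset(nodes[j] for j in members)))
    rio.write_gmt([pathway] + decoys, out / "pathways.gmt")
    rio.write_gene_set(ags, out / "ags.txt")

    regions, _ = simulate_utrs(
        UtrSimConfig(n_sequences=9, length_range=(18, 22), gc_target=0.25,
                     pentamer_rate=0.0, u_stretch_prob=0.0, id_prefix="region",
                     seed=seed + 6))
    rio.write_fasta(regions, out / "regions.fa")
    return {k: str(out / v) for k, v in {
        "counts": "counts.tsv", "design": "design.tsv",
        "expression": "expression.tsv", "bound_fasta": "bound_utrs.fa",
        "control_fasta": "control_utrs.fa", "network": "network.tsv",
        "gmt": "pathways.gmt", "regions_fasta": "regions.fa",
        "truth_rip": "truth_rip.tsv",
    }.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; write outputs, manifest and summary report.

    Returns the summary report as a dict (also written as JSON). Stage
    failures raise with the stage name; outputs of completed stages remain.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}
    bound = None

    if config.counts and config.design:
        try:
            cm = rio.read_count_matrix(config.counts, config.design)
            norm = normalize_counts(cm)
            res = fit_contrast(norm, CONTRAST_W_VS_C,
                               lfc_threshold=config.lfc_threshold, alpha=config.alpha)
            rio.write_results_tsv(res.table, out / "enrichment_W_vs_C.tsv")
            if config.dual_mutant:
                res_mut = fit_contrast(norm, CONTRAST_W_VS_WMUT,
                                       lfc_threshold=config.lfc_threshold, alpha=config.alpha)
                rio.write_results_tsv(res_mut.table, out / "enrichment_W_vs_Wmut.tsv")
                bound = call_enriched_dual(res, res_mut, config.lfc_threshold, config.alpha)
            else:
                bound = call_enriched(res, config.lfc_threshold, config.alpha, name="bound")
            rio.write_gene_set(bound, out / "bound.txt")
            report["stages"]["enrichment"] = {
                "n_genes": int(len(res.table)), "n_bound": len(bound),
                "dual": config.dual_mutant,
            }
        except Exception as e:
            raise RuntimeError(f"enrichment stage failed: {e}") from e

    if config.expression and bound is not None:
        try:
            expr = rio.read_expression_tsv(config.expression)
            kd = expr[[c for c in expr.columns if c.startswith("kd_")]]
            ctrl = expr[[c for c in expr.columns if c.startswith("ctrl_")]]
            fcs = replicate_fold_changes(kd, ctrl)
            calls = call_regulated_table(fcs, config.fold_threshold, config.min_reps)
            result = integrate(bound, calls)
            rio.write_results_tsv(result.table, out / "bound_regulated.tsv")
            report["stages"]["regulation"] = {
                "n_bound_regulated": int(len(result.table)),
                "n_up": result.n_up, "n_down": result.n_down,
                "pct_up": result.pct_up, "pct_down": result.pct_down,
            }
        except Exception as e:
            raise RuntimeError(f"regulation stage failed: {e}") from e

    if config.bound_fasta and config.control_fasta:
        try:
            bound_utrs = [canonicalize(s, rid) for rid, s in rio.read_fasta(config.bound_fasta)]
            ctrl_utrs = [canonicalize(s, rid) for rid, s in rio.read_fasta(config.control_fasta)]
            profs = [profile(u, config.u_stretch_min) for u in bound_utrs + ctrl_utrs]
            import pandas as pd

            prof_tab = pd.DataFrame([p.__dict__ for p in profs]).set_index("id")
            rio.write_results_tsv(prof_tab, out / "are_profiles.tsv", index_label="id")
            summary = group_are_summary(bound_utrs, ctrl_utrs, config.u_stretch_min)
            report["stages"]["are_motif"] = {
                "fractions": {k: [round(v[0], 4), round(v[1], 4)]
                              for k, v in summary.fractions.items()},
                "p_values": {k: float(t.p) for k, t in summary.tests.items()},
                "mean_gc": {k: round(v, 4) for k, v in summary.mean_gc.items()},
            }
        except Exception as e:
            raise RuntimeError(f"are_motif stage failed: {e}") from e

    if config.network and config.gmt and bound is not None:
        try:
            net = load_network(rio.read_edge_list(config.network), config.nea_cutoff)
            pathways = rio.read_gmt(config.gmt)
            ags = GeneSet("bound", frozenset(bound.genes))
            results = nea_batch(ags, pathways, net)
            import pandas as pd

            tab = pd.DataFrame([r.__dict__ for r in results]).set_index("pathway")
            rio.write_results_tsv(tab, out / "nea.tsv", index_label="pathway")
            report["stages"]["nea"] = {
                "n_pathways": len(results),
                "top_pathway": results[0].pathway,
                "top_p": float(results[0].p),
            }
        except Exception as e:
            raise RuntimeError(f"nea stage failed: {e}") from e

    if config.regions_fasta:
        try:
            regions = rio.read_fasta(config.regions_fasta)
            regions = [(rid, canonicalize(s, rid).sequence) for rid, s in regions]
            ids, rows = align_regions(regions)
            motif = consensus_from_alignment(ids, rows)
            with open(out / "consensus.txt", "w") as fh:
                fh.write(motif.consensus + "\n" + motif.structure + "\n")
            report["stages"]["structure"] = {
                "consensus": motif.consensus,
                "structure": motif.structure,
                "consensus_gc": round(motif.gc, 4),
                "mean_region_length": round(motif.mean_region_length, 2),
            }
        except Exception as e:
            raise RuntimeError(f"structure stage failed: {e}") from e

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "lfc": config.lfc_threshold, "alpha": config.alpha,
            "fold": config.fold_threshold, "min_reps": config.min_reps,
            "u_stretch": config.u_stretch_min, "nea_cutoff": config.nea_cutoff,
        },
        "inputs": {k: getattr(config, k) for k in
                   ("counts", "design", "expression", "bound_fasta", "control_fasta",
                    "regions_fasta", "network", "gmt") if getattr(config, k)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
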