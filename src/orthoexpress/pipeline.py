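"""End-to-end orchestration of the comparative transcriptome pipeline.

Stages: per-species differential expression -> ortholog clustering ->
functional enrichment (GSEA + ORA + cross-species term intersections)
-> ortholog fold-change conservation. Every intermediate table is
written to disk and the machine-readable run report is derived from
those files, so report numbers can be re-derived after the fact.

Each stochastic stage draws an independent sub-seed from the master
seed (stage-name hashing), so stages can be rerun in isolation and the
whole run is byte-identical given the same seed.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field as dc_field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import conservation, dge, enrichment, ortholog, syndata
from .errors import OrthoExpressError

log = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (printed style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 2) -> float:
    """100 * count / total, rounded half-up to ``ndigits`` decimals."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)


def stage_seed(master_seed: int, stage: str) -> int:
    """Independent sub-seed for a named stage, below 2**31."""
    return (master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Inputs, thresholds and seed of a full pipeline run."""

    output_dir: str
    seed: int = 0
    input_dir: str | None = None  # fixture-bundle layout; None -> simulate
    simulate: syndata.SimulationConfig | None = None
    reference_condition: str = "glycerol_acetate"
    min_cpm: float = 1.0
    min_samples: int = 2
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    gsea_n_perm: int = 500
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    ora_fdr_max: float = 0.25
    inflation: float = 1.5
    evalue_cutoff: float = 1e-5
    n_lists: int = 1000
    n_bootstrap: int = 1000

    def __post_init__(self):
        if self.input_dir is None and self.simulate is None:
            self.simulate = syndata.SimulationConfig(seed=stage_seed(self.seed, "simulate"))


def summarize_deg_accounting(
    dge_tables: dict[str, pd.DataFrame], gene_class: dict[str, dict[str, str]] | None = None
) -> pd.DataFrame:
    """Per-species DEG accounting table.

    Columns: genes tested, DEGs, percent DE (two decimals, half-up),
    up/down split (up = higher in glucose under the default contrast),
    and the ncRNA share among glycerol-induced (status ``down``) DEGs.
    """
    rows = []
    for sp, table in dge_tables.items():
        n_tested = len(table)
        n_up = int((table["status"] == "up").sum())
        n_down = int((table["status"] == "down").sum())
        n_de = n_up + n_down
        ncrna_share = float("nan")
        if gene_class is not None and sp in gene_class:
            classes = gene_class[sp]
            glycerol_up = table.index[table["status"] == "down"]
            n_nc = sum(1 for g in glycerol_up if classes.get(g) == "ncRNA")
            ncrna_share = percentage(n_nc, len(glycerol_up)) if len(glycerol_up) else 0.0
        rows.append(
            {
                "species": sp,
                "n_tested": n_tested,
                "n_de": n_de,
                "pct_de": percentage(n_de, n_tested),
                "n_up": n_up,
                "n_down": n_down,
                "pct_ncrna_glycerol_up": ncrna_share,
            }
        )
    return pd.DataFrame(rows).set_index("species")


@dataclass
class RunReport:
    seed: int
    stages: dict = dc_field(default_factory=dict)
    accounting: dict = dc_field(default_factory=dict)
    venn: dict = dc_field(default_factory=dict)
    term_intersections: dict = dc_field(default_factory=dict)
    conservation: list = dc_field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": self.stages,
            "accounting": self.accounting,
            "venn": self.venn,
            "term_intersections": self.term_intersections,
            "conservation": self.conservation,
        }


def _timed(stages: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            log.info("stage %s: done in %.1fs", name, dt)
            if exc is not None:
                raise OrthoExpressError(f"stage {name!r} failed: {exc}") from exc

    return _Timer()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage; write intermediates and a JSON report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)

    # --- inputs ------------------------------------------------------------
    if config.input_dir is not None:
        bundle_dir = Path(config.input_dir)
    else:
        bundle_dir = out / "input_bundle"
        with _timed(report.stages, "simulate"):
            dataset = syndata.simulate_dataset(config.simulate)
            syndata.write_fixture_bundle(dataset, bundle_dir)
    manifest = syndata.load_manifest(bundle_dir)
    species = manifest["species"]
    files = manifest["files"]

    def bpath(key: str) -> Path:
        return bundle_dir / files[key]

    gene_class: dict[str, dict[str, str]] = {}
    for sp in species:
        key = f"gene_class_{sp}"
        if key in files:
            cls = pd.read_csv(bpath(key), sep="\t")
            gene_class[sp] = dict(zip(cls["gene_id"], cls["gene_class"]))

    # --- per-species differential expression -------------------------------
    dge_tables: dict[str, pd.DataFrame] = {}
    norms: dict[str, dge.NormFactors] = {}
    designs: dict[str, pd.DataFrame] = {}
    with _timed(report.stages, "dge"):
        for sp in species:
            counts = dge.read_counts(bpath(f"counts_{sp}"))
            design = dge.read_design(bpath(f"design_{sp}"))
            table, norm, summary = dge.run_dge(
                counts,
                design,
                reference_condition=config.reference_condition,
                min_cpm=config.min_cpm,
                min_samples=config.min_samples,
                lfc_min=config.lfc_min,
                fdr_max=config.fdr_max,
            )
            table.to_csv(out / f"dge_{sp}.tsv", sep="\t")
            dge_tables[sp] = table
            norms[sp] = norm
            designs[sp] = design
            report.stages[f"dge_{sp}"] = {
                "n_input_genes": len(counts),
                "n_tested": summary.n_tested,
                "n_de": summary.n_de,
            }

    accounting = summarize_deg_accounting(dge_tables, gene_class or None)
    accounting.to_csv(out / "deg_accounting.tsv", sep="\t")
    report.accounting = json.loads(accounting.to_json(orient="index"))

    # --- ortholog clustering ------------------------------------------------
    with _timed(report.stages, "ortholog"):
        pairs = ortholog.parse_panther_pairs(bpath("orthologs"), species[0], species[1])
        edges = ortholog.read_similarity_edges(bpath("edges"))
        all_nodes = sorted(set(edges["protein_a"]) | set(edges["protein_b"]))
        clusters = ortholog.mcl_cluster(
            edges,
            inflation=config.inflation,
            evalue_cutoff=config.evalue_cutoff,
            extra_nodes=all_nodes,
        )
        labelled, venn = ortholog.classify_clusters(clusters)
        labelled.membership_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
        report.venn = venn.as_dict()
        with open(out / "venn.json", "w") as fh:
            json.dump(report.venn, fh, sort_keys=True, indent=1)
        annotations: dict[str, set[str]] = {}
        for sp in species:
            if f"annotations_{sp}" in files:
                for g, terms in ortholog.read_annotations(bpath(f"annotations_{sp}")).items():
                    annotations.setdefault(g, set()).update(terms)
        if annotations:
            shared_genes = [
                g
                for cl, lab in zip(labelled.clusters, labelled.labels)
                if lab.startswith("shared")
                for g in cl
            ]
            universe = [g for cl in labelled.clusters for g in cl]
            enr = ortholog.cluster_go_enrichment(shared_genes, annotations, universe)
            enr.to_csv(out / "cluster_enrichment.tsv", sep="\t", index=False)
        report.stages["ortholog"] = {
            "n_pairs": len(pairs),
            "n_edges_input": len(edges),
            "n_edges_kept": int((edges["e_value"] <= config.evalue_cutoff).sum()),
            "n_clusters": len(labelled.clusters),
        }

    # --- functional enrichment ----------------------------------------------
    with _timed(report.stages, "enrichment"):
        enriched_terms: dict[str, set[str]] = {}
        for sp in species:
            counts = dge.read_counts(bpath(f"counts_{sp}"))
            kept = counts.loc[dge_tables[sp].index]
            expr = dge.cpm(kept, norms[sp].effective)
            ranked = enrichment.rank_log2_ratio_of_classes(expr, designs[sp])
            collection = enrichment.read_gmt(bpath(f"genesets_{sp}"))
            try:
                gsea = enrichment.gsea_nes_fdr(
                    ranked,
                    collection,
                    n_perm=config.gsea_n_perm,
                    seed=stage_seed(config.seed, f"gsea_{sp}"),
                    min_size=config.gsea_min_size,
                    max_size=config.gsea_max_size,
                )
            except OrthoExpressError as exc:
                log.warning("GSEA skipped for %s: %s", sp, exc)
                continue
            gsea.table.to_csv(out / f"gsea_{sp}.tsv", sep="\t", index=False)
            passing = gsea.passing()
            enriched_terms[f"{sp}_glucose"] = set(passing.loc[passing["NES"] > 0, "set_id"])
            enriched_terms[f"{sp}_glycerol_acetate"] = set(
                passing.loc[passing["NES"] < 0, "set_id"]
            )
            ann = ortholog.read_annotations(bpath(f"annotations_{sp}"))
            degs = dge_tables[sp].index[dge_tables[sp]["status"] != "ns"]
            ora = enrichment.ora_hypergeometric(
                set(degs), set(dge_tables[sp].index), ann, fdr_max=config.ora_fdr_max
            )
            ora.to_csv(out / f"ora_{sp}.tsv", sep="\t", index=False)
        if len(enriched_terms) >= 2:
            inter = enrichment.intersect_terms(enriched_terms)
            report.term_intersections = inter.counts()
            with open(out / "term_intersections.json", "w") as fh:
                json.dump(report.term_intersections, fh, sort_keys=True, indent=1)

    # --- conservation -------------------------------------------------------
    with _timed(report.stages, "conservation"):
        ec_map = conservation.read_ec_map(bpath("ec_map")) if "ec_map" in files else None
        paired = conservation.pair_log2fc(
            dge_tables[species[0]], dge_tables[species[1]], pairs, ec_map=ec_map
        )
        paired.table.to_csv(out / "paired_log2fc.tsv", sep="\t", index=False)
        null = conservation.null_cutoff(
            dge_tables[species[0]],
            dge_tables[species[1]],
            n_pairs=len(paired),
            n_lists=config.n_lists,
            seed=stage_seed(config.seed, "null_cutoff"),
            exclude=pairs,
        )
        subsets = [paired]
        pathway_ids = sorted(paired.table["pathway_id"].dropna().unique())
        for pw in pathway_ids:
            subsets.append(conservation.subset_by_pathway(paired, pathway_id=pw))
        results = []
        for sub in subsets:
            if len(sub) < 3:
                log.warning("subset %s too small for correlation; skipped", sub.label)
                continue
            sub_null = (
                null
                if len(sub) == len(paired)
                else conservation.null_cutoff(
                    dge_tables[species[0]],
                    dge_tables[species[1]],
                    n_pairs=len(sub),
                    n_lists=config.n_lists,
                    seed=stage_seed(config.seed, f"null_{sub.label}"),
                    exclude=pairs,
                )
            )
            res = conservation.correlation_report(
                sub,
                sub_null,
                n_bootstrap=config.n_bootstrap,
                seed=stage_seed(config.seed, f"boot_{sub.label}"),
            )
            results.append(res)
        cons_frame = pd.DataFrame(
            [
                {
                    "subset_label": r.subset_label,
                    "n_pairs": r.n_pairs,
                    "r": r.r,
                    "slope": r.slope,
                    "cutoff": r.cutoff,
                    "null_sd": r.null_sd,
                    "p_permutation": r.p_permutation,
                    "p_ttest": r.p_ttest,
                }
                for r in results
            ]
        )
        cons_frame.to_csv(out / "conservation.tsv", sep="\t", index=False)
        report.conservation = json.loads(cons_frame.to_json(orient="records"))
        report.stages["conservation"] = {
            "n_pairs_paired": len(paired),
            "n_pairs_dropped": paired.n_dropped,
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report.as_dict(), fh, sort_keys=True, indent=1)
        fh.write("\n")
    return report


def rederive_accounting(output_dir, species: list[str]) -> pd.DataFrame:
    """Recompute the DEG accounting from the written per-species tables."""
    tables = {
        sp: pd.read_csv(Path(output_dir) / f"dge_{sp}.tsv", sep="\t", index_col=0)
        for sp in species
    }
    return summarize_deg_accounting(tables)
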