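"""Seeded synthetic two-species RNA-seq datasets with known ground truth.

The generator emulates the study design the rest of the package targets:
two microbial species grown in the same medium under two carbon sources
(``glucose`` vs ``glycerol_acetate``), three biological replicates each,
negative-binomially distributed gene counts, a designated differentially
expressed (DE) fraction, an ortholog map covering a configurable fraction
of genes, per-pathway cross-species log2 fold-change correlations, and an
ncRNA gene class biased toward glycerol-induced genes.

Sign convention throughout: positive log2FC = higher expression in
glucose; glycerol/acetate-induced genes carry negative log2FC.

All randomness flows from a single integer seed; the same seed yields a
byte-identical fixture bundle on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

SPECIES_A = "ECOLI"
SPECIES_B = "SCHPO"
CONDITIONS = ("glucose", "glycerol_acetate")

#: Per-pathway cross-species correlation presets for the three central
#: carbon-metabolism pathways the conservation stage analyses.
DEFAULT_PATHWAY_SPECS = (
    ("glycolysis_gluconeogenesis", 40, 0.36),
    ("tca_cycle", 40, -0.18),
    ("pentose_phosphate", 40, 0.77),
)


@dataclass(frozen=True)
class PathwaySpec:
    pathway_id: str
    n_ortholog_pairs: int
    rho: float


@dataclass
class SimulationConfig:
    """Parameters of a synthetic two-species experiment.

    Parameters
    ----------
    seed
        Master seed; every random draw derives from it.
    n_genes_per_species
        Number of genes simulated for each species.
    n_replicates
        Biological replicates per condition (3 in the emulated design).
    ortholog_fraction
        Fraction of each species' genes that have a one-to-one ortholog
        in the other species (~0.25 in the emulated proteomes).
    de_fraction
        Fraction of genes designated DE per species (|log2FC| fixed at
        ``de_log2fc_magnitude``; roughly 0.13 in the emulated data).
    de_log2fc_magnitude
        Absolute true log2 fold change assigned to designated DE genes
        (must be >= 1 so DE genes clear the conventional calling cutoff).
    dispersion
        Negative-binomial overdispersion phi: Var = mu + phi * mu^2.
    mean_log_expression
        Natural-log mean of the log-normal baseline expression weights.
    library_size_range
        (low, high) bounds for per-sample library sizes drawn uniformly;
        deliberately unequal so TMM normalization has real work to do.
    pathway_specs
        (pathway_id, n_ortholog_pairs, rho) triples; each pathway's
        ortholog pairs receive true log2FC drawn from a bivariate normal
        with correlation rho (scale ``pathway_log2fc_sd``).
    pathway_log2fc_sd
        Marginal standard deviation of pathway-pair log2 fold changes.
    ncrna_fraction
        Overall fraction of genes labelled ncRNA per species.
    ncrna_glycerol_bias
        Target share of ncRNAs among glycerol-induced DE genes (0.542
        in the emulated yeast data).
    n_decoy_edges
        Number of non-ortholog decoy edges, with e-values above the
        conventional 1e-5 similarity cutoff, added to the written
        protein-similarity edge list.
    """

    seed: int = 0
    n_genes_per_species: int = 2000
    n_replicates: int = 3
    ortholog_fraction: float = 0.25
    de_fraction: float = 0.13
    de_log2fc_magnitude: float = 2.0
    dispersion: float = 0.1
    mean_log_expression: float = 4.0
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    pathway_specs: tuple = DEFAULT_PATHWAY_SPECS
    pathway_log2fc_sd: float = 1.0
    ncrna_fraction: float = 0.15
    ncrna_glycerol_bias: float = 0.542
    n_decoy_edges: int = 20

    def __post_init__(self):
        self.pathway_specs = tuple(
            s if isinstance(s, PathwaySpec) else PathwaySpec(*s) for s in self.pathway_specs
        )
        for name in ("de_fraction", "ncrna_fraction", "ncrna_glycerol_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must lie in [0, 1]")
        if not 0.0 < self.ortholog_fraction <= 1.0:
            raise ConfigurationError("ortholog_fraction must lie in (0, 1]")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.de_log2fc_magnitude < 1:
            raise ConfigurationError("de_log2fc_magnitude must be >= 1")
        if self.n_genes_per_species < 10:
            raise ConfigurationError("need at least 10 genes per species")
        if self.n_replicates < 1:
            raise ConfigurationError("need at least 1 replicate")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("library_size_range must satisfy 0 < low <= high")
        for spec in self.pathway_specs:
            if not -1.0 <= spec.rho <= 1.0:
                raise ConfigurationError(f"rho={spec.rho} must lie in [-1, 1]")
            if spec.n_ortholog_pairs < 1:
                raise ConfigurationError("pathway n_ortholog_pairs must be >= 1")
        n_orth = int(round(self.ortholog_fraction * self.n_genes_per_species))
        demand = sum(s.n_ortholog_pairs for s in self.pathway_specs)
        if demand > n_orth:
            raise ConfigurationError(
                f"pathway specs demand {demand} ortholog pairs but the ortholog "
                f"fraction only provides {n_orth}"
            )

    @property
    def n_ortholog_pairs(self) -> int:
        return int(round(self.ortholog_fraction * self.n_genes_per_species))


@dataclass
class GroundTruth:
    """Known truth behind a simulated dataset.

    ``true_log2fc`` maps species -> {gene -> log2FC}. Genes fall into
    three classes: designated DE genes (log2FC = +/-de_log2fc_magnitude),
    pathway ortholog pairs (continuous correlated log2FC), and background
    genes (log2FC exactly 0).
    """

    true_log2fc: dict[str, dict[str, float]]
    de_genes: dict[str, set[str]]
    ortholog_pairs: list[tuple[str, str]]
    pathway_membership: dict[tuple[str, str], str]
    gene_class: dict[str, dict[str, str]]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    counts: dict[str, pd.DataFrame]
    designs: dict[str, pd.DataFrame]
    truth: GroundTruth
    decoy_edges: list[tuple[str, str, float]] = field(default_factory=list)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + phi * mu^2 (gamma-Poisson)."""
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    return rng.poisson(lam)


def _bivariate_normal(rng, n, rho, sd):
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    a = z1 * sd
    b = (rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2) * sd
    return a, b


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate counts, designs and ground truth for both species.

    Counts are NB(mu, phi) with mu = library size x relative expression;
    relative expression combines a log-normal baseline weight with the
    gene's condition effect split symmetrically across conditions
    (glucose mean x 2^(lfc/2), glycerol mean x 2^(-lfc/2)).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes_per_species
    gene_ids = {
        SPECIES_A: [f"EC_g{i:05d}" for i in range(n)],
        SPECIES_B: [f"SP_g{i:05d}" for i in range(n)],
    }

    # --- ortholog map: random subset of each species, paired in shuffled order
    n_orth = cfg.n_ortholog_pairs
    idx_a = rng.choice(n, size=n_orth, replace=False)
    idx_b = rng.choice(n, size=n_orth, replace=False)
    pairs = [(gene_ids[SPECIES_A][i], gene_ids[SPECIES_B][j]) for i, j in zip(idx_a, idx_b)]

    # --- pathway membership: consecutive blocks of the (already random) pair list
    pathway_membership: dict[tuple[str, str], str] = {}
    lfc = {sp: dict.fromkeys(gene_ids[sp], 0.0) for sp in (SPECIES_A, SPECIES_B)}
    cursor = 0
    for spec in cfg.pathway_specs:
        block = pairs[cursor : cursor + spec.n_ortholog_pairs]
        cursor += spec.n_ortholog_pairs
        fa, fb = _bivariate_normal(rng, len(block), spec.rho, cfg.pathway_log2fc_sd)
        for (ga, gb), va, vb in zip(block, fa, fb):
            pathway_membership[(ga, gb)] = spec.pathway_id
            lfc[SPECIES_A][ga] = float(va)
            lfc[SPECIES_B][gb] = float(vb)

    pathway_genes = {
        SPECIES_A: {ga for ga, _ in pathway_membership},
        SPECIES_B: {gb for _, gb in pathway_membership},
    }

    # --- designated DE genes outside the pathway blocks
    de_genes: dict[str, set[str]] = {}
    for sp in (SPECIES_A, SPECIES_B):
        eligible = [g for g in gene_ids[sp] if g not in pathway_genes[sp]]
        n_de = int(round(cfg.de_fraction * n))
        if n_de > len(eligible):
            raise ConfigurationError("de_fraction leaves no room beside pathway genes")
        chosen = list(rng.choice(eligible, size=n_de, replace=False)) if n_de else []
        signs = rng.choice([-1.0, 1.0], size=n_de)
        for g, s in zip(chosen, signs):
            lfc[sp][g] = float(s * cfg.de_log2fc_magnitude)
        de_genes[sp] = set(chosen)

    # --- ncRNA labels: biased toward glycerol-induced (negative log2FC) DE genes
    gene_class: dict[str, dict[str, str]] = {}
    for sp in (SPECIES_A, SPECIES_B):
        cls = dict.fromkeys(gene_ids[sp], "coding")
        glycerol_up = sorted(g for g in de_genes[sp] if lfc[sp][g] < 0)
        n_nc_de = int(round(cfg.ncrna_glycerol_bias * len(glycerol_up)))
        nc = set(rng.choice(glycerol_up, size=n_nc_de, replace=False)) if n_nc_de else set()
        target_total = int(round(cfg.ncrna_fraction * n))
        remaining = [g for g in gene_ids[sp] if g not in de_genes[sp]]
        n_more = max(0, target_total - len(nc))
        if n_more:
            nc |= set(rng.choice(remaining, size=min(n_more, len(remaining)), replace=False))
        for g in nc:
            cls[g] = "ncRNA"
        gene_class[sp] = cls

    # --- counts
    counts: dict[str, pd.DataFrame] = {}
    designs: dict[str, pd.DataFrame] = {}
    lo, hi = cfg.library_size_range
    for sp, prefix in ((SPECIES_A, "EC"), (SPECIES_B, "SP")):
        base = rng.lognormal(mean=cfg.mean_log_expression, sigma=1.0, size=n)
        fc = np.array([lfc[sp][g] for g in gene_ids[sp]])
        expr = {
            "glucose": base * np.exp2(fc / 2.0),
            "glycerol_acetate": base * np.exp2(-fc / 2.0),
        }
        sample_ids, conditions, replicates, cols = [], [], [], []
        for cond in CONDITIONS:
            rel = expr[cond] / expr[cond].sum()
            for rep in range(1, cfg.n_replicates + 1):
                lib = int(rng.integers(lo, hi + 1))
                mu = lib * rel
                cols.append(_nb_sample(rng, mu, cfg.dispersion))
                sample_ids.append(f"{prefix}_{cond}_{rep}")
                conditions.append(cond)
                replicates.append(rep)
        counts[sp] = pd.DataFrame(
            np.column_stack(cols), index=pd.Index(gene_ids[sp], name="gene_id"), columns=sample_ids
        )
        designs[sp] = pd.DataFrame(
            {"sample_id": sample_ids, "condition": conditions, "replicate": replicates}
        ).set_index("sample_id")

    # --- decoy similarity edges among non-ortholog cross-species gene pairs
    paired = set(pairs)
    decoys: list[tuple[str, str, float]] = []
    while len(decoys) < cfg.n_decoy_edges:
        ga = gene_ids[SPECIES_A][int(rng.integers(n))]
        gb = gene_ids[SPECIES_B][int(rng.integers(n))]
        if (ga, gb) in paired:
            continue
        decoys.append((ga, gb, 10.0 ** float(rng.uniform(-4.9, -1.0))))

    truth = GroundTruth(
        true_log2fc=lfc,
        de_genes=de_genes,
        ortholog_pairs=pairs,
        pathway_membership=pathway_membership,
        gene_class=gene_class,
    )
    return SimulatedDataset(cfg, counts, designs, truth, decoys)


def truth_dge_tables(dataset: SimulatedDataset) -> dict[str, pd.DataFrame]:
    """Noise-free DGE-shaped tables built directly from the ground truth.

    Useful for exercising downstream stages (pairing, conservation
    statistics) with the true log2 fold changes rather than estimates.
    """
    out = {}
    for sp, mapping in dataset.truth.true_log2fc.items():
        genes = list(mapping)
        out[sp] = pd.DataFrame(
            {"log2FC": [mapping[g] for g in genes]}, index=pd.Index(genes, name="gene_id")
        )
    return out


# ---------------------------------------------------------------------------
# fixture bundle on disk
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "counts": "counts_{sp}.tsv",
    "design": "design_{sp}.tsv",
    "gene_class": "gene_class_{sp}.tsv",
    "annotations": "annotations_{sp}.tsv",
    "genesets": "genesets_{sp}.gmt",
    "orthologs": "orthologs_panther.tsv",
    "edges": "similarity_edges.tsv",
    "ec_map": "ec_map.tsv",
    "manifest": "manifest.json",
}


def _panther_row(ga: str, gb: str, otype: str, fam: str) -> str:
    a = f"{SPECIES_A}|EcoGene={ga}|UniProtKB=U{ga[-5:]}"
    b = f"{SPECIES_B}|PomBase={gb}|UniProtKB=U{gb[-5:]}"
    return f"{a}\t{b}\t{otype}\tEukaryota-Bacteria\t{fam}"


def write_fixture_bundle(dataset: SimulatedDataset, directory) -> dict[str, str]:
    """Write every input file the pipeline stages read; return a manifest.

    Ortholog pairs appear in the similarity edge list with e-value 1e-10;
    decoy edges carry e-values above the 1e-5 cutoff and must be dropped
    by downstream graph filtering. The written ortholog file round-trips
    through the reference-genome ortholog parser losslessly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    manifest_files: dict[str, str] = {}

    def _path(key: str, sp: str | None = None) -> Path:
        name = BUNDLE_FILES[key].format(sp=sp) if sp else BUNDLE_FILES[key]
        manifest_files[f"{key}_{sp}" if sp else key] = name
        return directory / name

    for sp in (SPECIES_A, SPECIES_B):
        dataset.counts[sp].to_csv(_path("counts", sp), sep="\t")
        dataset.designs[sp].to_csv(_path("design", sp), sep="\t")
        cls = dataset.truth.gene_class[sp]
        pd.DataFrame(
            {"gene_id": list(cls), "gene_class": [cls[g] for g in cls]}
        ).to_csv(_path("gene_class", sp), sep="\t", index=False)

    # pathway annotations per species: term per pathway, plus an ncRNA term
    side = {SPECIES_A: 0, SPECIES_B: 1}
    for sp in (SPECIES_A, SPECIES_B):
        rows = []
        for pair, pw in dataset.truth.pathway_membership.items():
            rows.append((pair[side[sp]], f"TERM:{pw}", pw.replace("_", " ")))
        for g, c in dataset.truth.gene_class[sp].items():
            if c == "ncRNA":
                rows.append((g, "TERM:ncrna", "non-coding RNA"))
        pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"]).to_csv(
            _path("annotations", sp), sep="\t", index=False
        )
        with open(_path("genesets", sp), "w") as fh:
            for spec in cfg.pathway_specs:
                members = sorted(
                    pair[side[sp]]
                    for pair, pw in dataset.truth.pathway_membership.items()
                    if pw == spec.pathway_id
                )
                fh.write("\t".join([spec.pathway_id, spec.pathway_id.replace("_", " ")] + members))
                fh.write("\n")

    with open(_path("orthologs"), "w") as fh:
        for i, (ga, gb) in enumerate(dataset.truth.ortholog_pairs):
            otype = "O" if i % 5 == 4 else "LDO"
            fh.write(_panther_row(ga, gb, otype, f"PTHR{i:05d}") + "\n")

    with open(_path("edges"), "w") as fh:
        fh.write("protein_a\tprotein_b\te_value\tbitscore\n")
        for ga, gb in dataset.truth.ortholog_pairs:
            fh.write(f"{ga}\t{gb}\t1e-10\t500.0\n")
        for ga, gb, ev in dataset.decoy_edges:
            fh.write(f"{ga}\t{gb}\t{ev:.6e}\t40.0\n")

    ec_rows = []
    for i, (pair, pw) in enumerate(sorted(dataset.truth.pathway_membership.items())):
        ec = f"1.1.1.{i + 1}"
        ec_rows.append((pair[0], ec, pw))
        ec_rows.append((pair[1], ec, pw))
    pd.DataFrame(ec_rows, columns=["gene_id", "ec_number", "pathway_id"]).to_csv(
        _path("ec_map"), sep="\t", index=False
    )

    manifest = {
        "seed": cfg.seed,
        "config": {
            "n_genes_per_species": cfg.n_genes_per_species,
            "n_replicates": cfg.n_replicates,
            "ortholog_fraction": cfg.ortholog_fraction,
            "de_fraction": cfg.de_fraction,
            "de_log2fc_magnitude": cfg.de_log2fc_magnitude,
            "dispersion": cfg.dispersion,
            "mean_log_expression": cfg.mean_log_expression,
            "library_size_range": list(cfg.library_size_range),
            "pathway_specs": [
                [s.pathway_id, s.n_ortholog_pairs, s.rho] for s in cfg.pathway_specs
            ],
            "pathway_log2fc_sd": cfg.pathway_log2fc_sd,
            "ncrna_fraction": cfg.ncrna_fraction,
            "ncrna_glycerol_bias": cfg.ncrna_glycerol_bias,
            "n_decoy_edges": cfg.n_decoy_edges,
        },
        "species": [SPECIES_A, SPECIES_B],
        "files": manifest_files,
        "ground_truth": {
            "true_log2fc": dataset.truth.true_log2fc,
            "de_genes": {sp: sorted(v) for sp, v in dataset.truth.de_genes.items()},
            "ortholog_pairs": [list(p) for p in dataset.truth.ortholog_pairs],
            "pathway_membership": {
                f"{a}|{b}": pw for (a, b), pw in dataset.truth.pathway_membership.items()
            },
            "gene_class": dataset.truth.gene_class,
        },
    }
    with open(directory / BUNDLE_FILES["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest_files["manifest"] = BUNDLE_FILES["manifest"]
    return manifest_files


def load_manifest(directory) -> dict:
    with open(Path(directory) / BUNDLE_FILES["manifest"]) as fh:
        return json.load(fh)
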