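"""Ortholog pair parsing, Markov clustering, and cluster enrichment.

Two complementary ortholog sources are supported:

* reference-genome ortholog pair flat files (tab-separated rows whose
  gene fields look like ``SPECIES|DB=ID|UniProtKB=ACC`` with an ortholog
  type column, LDO = least diverged ortholog, O = other ortholog);
* de novo clustering of a protein-similarity edge list via Markov
  clustering (MCL) with the conventional inflation 1.5 and e-value
  cutoff 1e-5, mirroring OrthoVenn-style orthologous group detection.

Clusters are classified as shared between species, species-specific, or
singletons, and shared-cluster gene sets can be scored for GO-term
over-representation with an upper-tail hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dge import bh_adjust
from .errors import ConfigurationError, EmptyResultError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ortholog pair files
# ---------------------------------------------------------------------------


def _parse_gene_field(fieldtext: str, prefer_token: str = "DB"):
    """Split ``SPECIES|DB=ID|UniProtKB=ACC`` into (species, gene id).

    ``prefer_token="DB"`` takes the first non-UniProtKB ``key=value``
    token's value; ``prefer_token="UniProtKB"`` takes the UniProtKB
    accession instead.
    """
    parts = fieldtext.split("|")
    if len(parts) < 2:
        raise ValueError(f"malformed gene field: {fieldtext!r}")
    species = parts[0]
    db_tokens = []
    uniprot = None
    for tok in parts[1:]:
        if "=" not in tok:
            raise ValueError(f"malformed gene token: {tok!r}")
        key, val = tok.split("=", 1)
        if key == "UniProtKB":
            uniprot = val
        else:
            db_tokens.append(val)
    if prefer_token == "UniProtKB":
        chosen = uniprot or (db_tokens[0] if db_tokens else None)
    else:
        chosen = (db_tokens[0] if db_tokens else None) or uniprot
    if chosen is None:
        raise ValueError(f"no usable ID token in gene field: {fieldtext!r}")
    return species, chosen


def parse_panther_pairs(
    path, species_a: str, species_b: str, prefer_token: str = "DB"
) -> pd.DataFrame:
    """Extract ortholog pairs between two species from a pair flat file.

    Returns a frame with columns ``gene_a`` (species_a side), ``gene_b``
    (species_b side), ``ortholog_type`` and ``family_id``; rows for other
    species pairs are ignored, malformed rows are skipped with a logged
    line number, and duplicate unordered pairs are collapsed (keeping the
    first occurrence).
    """
    wanted = {species_a, species_b}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                log.warning("skipping malformed line %d: too few fields", lineno)
                continue
            try:
                sp1, g1 = _parse_gene_field(fields[0], prefer_token)
                sp2, g2 = _parse_gene_field(fields[1], prefer_token)
            except ValueError as exc:
                log.warning("skipping malformed line %d: %s", lineno, exc)
                continue
            if {sp1, sp2} != wanted:
                continue
            otype = fields[2].strip()
            family = fields[4].strip() if len(fields) >= 5 else ""
            if sp1 == species_a:
                rows.append((g1, g2, otype, family))
            else:
                rows.append((g2, g1, otype, family))
    if not rows:
        raise EmptyResultError(
            f"no ortholog pairs between {species_a} and {species_b} found in {path}"
        )
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "ortholog_type", "family_id"])
    return df.drop_duplicates(subset=["gene_a", "gene_b"], keep="first").reset_index(drop=True)


# ---------------------------------------------------------------------------
# similarity graph and Markov clustering
# ---------------------------------------------------------------------------

MAX_EDGE_WEIGHT = 200.0  # cap on -log10(e-value)


def read_similarity_edges(path) -> pd.DataFrame:
    """Read a protein-similarity edge list TSV.

    Expected columns: ``protein_a``, ``protein_b``, ``e_value`` and
    optionally ``bitscore``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"protein_a", "protein_b", "e_value"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"edge list must have columns {sorted(required)}")
    return df


def evalue_weight(e_value) -> np.ndarray:
    """Monotone significance weight -log10(e), capped at 200."""
    e = np.maximum(np.asarray(e_value, dtype=float), 1e-300)
    return np.minimum(-np.log10(e), MAX_EDGE_WEIGHT)


@dataclass
class ClusterSet:
    """A partition of proteins with species composition and labels."""

    clusters: list[tuple[str, ...]]
    species_of: dict[str, str]
    labels: list[str] = field(default_factory=list)
    converged: bool = True

    def species_counts(self, cluster: tuple[str, ...]) -> dict[str, int]:
        out: dict[str, int] = {}
        for node in cluster:
            sp = self.species_of[node]
            out[sp] = out.get(sp, 0) + 1
        return out

    def membership_frame(self) -> pd.DataFrame:
        rows = []
        labels = self.labels or [""] * len(self.clusters)
        for cid, (cluster, lab) in enumerate(zip(self.clusters, labels)):
            for node in cluster:
                rows.append((cid, node, self.species_of[node], lab))
        return pd.DataFrame(rows, columns=["cluster_id", "protein", "species", "label"])


@dataclass
class VennSummary:
    """Cluster counts shared by both species or exclusive to one."""

    shared: int
    only_a: int
    only_b: int
    species_a: str
    species_b: str
    singletons: int = 0

    def as_dict(self) -> dict:
        return {
            "shared": self.shared,
            f"only_{self.species_a}": self.only_a,
            f"only_{self.species_b}": self.only_b,
            "singletons": self.singletons,
        }


def species_from_prefix(node: str) -> str:
    """Default node -> species map for the synthetic id scheme."""
    return "ECOLI" if node.startswith("EC_") else "SCHPO"


def mcl_cluster(
    edges: pd.DataFrame,
    species_of: dict[str, str] | None = None,
    inflation: float = 1.5,
    evalue_cutoff: float = 1e-5,
    prune: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 200,
    extra_nodes: list[str] | None = None,
) -> ClusterSet:
    """Markov clustering of a protein-similarity graph.

    Edges above ``evalue_cutoff`` are dropped and the rest weighted by
    -log10(e-value) (capped at 200). Each node receives a self-loop of
    its maximum incident weight; the column-stochastic transition matrix
    is then alternately expanded (matrix square) and inflated
    (elementwise power ``inflation``, entries below ``prune`` zeroed,
    columns renormalized) until the largest elementwise change is below
    ``tol`` or ``max_iter`` sweeps. Clusters are the connected
    components of the converged attractor structure; nodes with no
    retained edge become singletons. Node order is lexicographic, so the
    result is deterministic.
    """
    if inflation <= 1:
        raise ConfigurationError("inflation must be > 1")
    kept = edges[edges["e_value"] <= evalue_cutoff]
    kept = kept[kept["protein_a"] != kept["protein_b"]]
    nodes = sorted(
        set(kept["protein_a"]) | set(kept["protein_b"]) | set(extra_nodes or [])
    )
    if species_of is None:
        species_of = {n: species_from_prefix(n) for n in nodes}
    if not nodes:
        return ClusterSet([], dict(species_of))
    index = {n: i for i, n in enumerate(nodes)}
    k = len(nodes)
    W = np.zeros((k, k))
    weights = evalue_weight(kept["e_value"])
    for a, b, w in zip(kept["protein_a"], kept["protein_b"], weights):
        i, j = index[a], index[b]
        W[i, j] = max(W[i, j], w)
        W[j, i] = max(W[j, i], w)
    loop = W.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(W, loop)
    M = W / W.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        expanded = M @ M
        inflated = expanded**inflation
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        dead = colsum[0] == 0
        if dead.any():  # fully pruned column: park mass on the diagonal
            inflated[np.flatnonzero(dead), np.flatnonzero(dead)] = 1.0
            colsum = inflated.sum(axis=0, keepdims=True)
        inflated /= colsum
        if np.max(np.abs(inflated - M)) < tol:
            M = inflated
            converged = True
            break
        M = inflated
    if not converged:
        log.warning("MCL did not converge within %d iterations", max_iter)

    support = (M > prune) | (M.T > prune)
    graph = nx.from_numpy_array(support.astype(float))
    clusters = [
        tuple(sorted(nodes[i] for i in comp)) for comp in nx.connected_components(graph)
    ]
    clusters.sort(key=lambda c: c[0])
    return ClusterSet(clusters, dict(species_of), converged=converged)


def classify_clusters(clusters: ClusterSet) -> tuple[ClusterSet, VennSummary]:
    """Label clusters shared / species-specific / singleton; Venn counts.

    ``shared``: at least one protein from each species; ``species
    specific``: all proteins of one species and size >= 2; singletons
    are counted separately. A shared cluster with exactly one protein
    per species is a single-copy orthologous group (label suffix
    ``:single_copy``).
    """
    species = sorted(set(clusters.species_of.values()))
    if len(species) != 2:
        raise ConfigurationError(f"exactly two species expected, got {species}")
    sp_a, sp_b = species
    labels = []
    shared = only_a = only_b = singles = 0
    for cluster in clusters.clusters:
        comp = clusters.species_counts(cluster)
        if len(cluster) == 1:
            labels.append("singleton")
            singles += 1
        elif len(comp) == 2:
            shared += 1
            if all(v == 1 for v in comp.values()):
                labels.append("shared:single_copy")
            else:
                labels.append("shared")
        else:
            (sp,) = comp
            labels.append(f"species_specific:{sp}")
            if sp == sp_a:
                only_a += 1
            else:
                only_b += 1
    labelled = ClusterSet(
        clusters.clusters, clusters.species_of, labels=labels, converged=clusters.converged
    )
    return labelled, VennSummary(shared, only_a, only_b, sp_a, sp_b, singletons=singles)


# ---------------------------------------------------------------------------
# hypergeometric enrichment of cluster groups
# ---------------------------------------------------------------------------


def read_annotations(path) -> dict[str, set[str]]:
    """Read a gene -> term TSV (columns ``gene_id``, ``term_id``, ...)."""
    df = pd.read_csv(path, sep="\t")
    ann: dict[str, set[str]] = {}
    for g, t in zip(df["gene_id"], df["term_id"]):
        ann.setdefault(g, set()).add(t)
    return ann


def hypergeom_upper_tail(k: int, n: int, big_k: int, big_n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N=big_n, K=big_k, n draws)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, big_n, big_k, n))


def cluster_go_enrichment(
    focal_genes, annotations: dict[str, set[str]], universe
) -> pd.DataFrame:
    """Term over-representation of a focal cluster group.

    For each term with K carriers among the N universe genes and k
    carriers among the n focal genes, the upper-tail hypergeometric
    probability P(X >= k) is computed, then BH-adjusted across terms.
    Terms absent from the universe are skipped.
    """
    if not annotations:
        raise ConfigurationError("annotations must be nonempty")
    universe = set(universe)
    focal = set(focal_genes) & universe
    term_universe: dict[str, int] = {}
    term_focal: dict[str, int] = {}
    for gene in universe:
        for term in annotations.get(gene, ()):
            term_universe[term] = term_universe.get(term, 0) + 1
            if gene in focal:
                term_focal[term] = term_focal.get(term, 0) + 1
    rows = []
    big_n, n = len(universe), len(focal)
    for term in sorted(term_universe):
        big_k = term_universe[term]
        k = term_focal.get(term, 0)
        rows.append((term, k, n, big_k, big_n, hypergeom_upper_tail(k, n, big_k, big_n)))
    df = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p_value"])
    if len(df):
        df["fdr"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return df
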