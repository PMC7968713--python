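"""Gene-set enrichment and over-representation analysis.

GSEA here follows the weighted Kolmogorov-Smirnov formulation: genes are
ranked by the log2 ratio of class means, the enrichment score (ES) is
the maximal signed deviation of a running sum that steps up by
|metric|^p at set members and down by 1/(N - N_hits) elsewhere, and ES
is normalized (NES) and assigned a nominal p and FDR q against a
gene-label permutation null. Sets pass at the conventional lenient
gates FDR q < 0.25 and nominal p < 0.05.

Over-representation analysis (ORA) scores a foreground gene list
against a universe with the upper-tail hypergeometric test and BH-FDR,
by default at the same lenient FDR < 0.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dge import bh_adjust
from .errors import ConfigurationError, EmptyResultError
from .ortholog import hypergeom_upper_tail

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene sets (GMT) and ranked lists
# ---------------------------------------------------------------------------


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file into {set_id: (description, members)}."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ConfigurationError(f"GMT line has no members: {line!r}")
            members = list(dict.fromkeys(fields[2:]))  # unique, order kept
            sets[fields[0]] = (fields[1], members)
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for set_id, (desc, members) in sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def rank_log2_ratio_of_classes(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    class_1: str = "glucose",
    class_2: str = "glycerol_acetate",
    eps: float = 1.0,
) -> pd.Series:
    """Rank genes by log2( (mean_1 + eps) / (mean_2 + eps) ), descending.

    ``expr`` is a normalized expression (CPM) table; ``eps`` is a
    pseudo-value guarding against zero class means (1 CPM-equivalent by
    default). Ties are broken by gene id so the order is deterministic.
    """
    cond = design.loc[list(expr.columns), "condition"]
    m1 = expr.loc[:, (cond == class_1).to_numpy()].mean(axis=1)
    m2 = expr.loc[:, (cond == class_2).to_numpy()].mean(axis=1)
    if eps == 0 and ((m1 == 0).any() or (m2 == 0).any()):
        raise ConfigurationError(
            "zero class means encountered with eps=0; set eps > 0 to rank these genes"
        )
    metric = np.log2((m1 + eps) / (m2 + eps))
    # mergesort is stable; pre-sorting by gene id makes equal metrics order lexically
    frame = (
        pd.DataFrame({"metric": metric})
        .sort_index()
        .sort_values(by="metric", ascending=False, kind="mergesort")
    )
    return frame["metric"]


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------


def _es_from_mask(metric: np.ndarray, hit: np.ndarray, weight_p: float):
    n = metric.size
    n_hits = int(hit.sum())
    w = np.abs(metric[hit]) ** weight_p
    total = w.sum()
    steps = np.full(n, -1.0 / (n - n_hits))
    steps[hit] = w / total if total > 0 else 1.0 / n_hits
    run = np.cumsum(steps)
    idx = int(np.argmax(np.abs(run)))
    return float(run[idx]), run


def gsea_es(ranked: pd.Series, gene_set, weight_p: float = 1.0):
    """Enrichment score of a gene set on a ranked list.

    Returns ``(ES, running_sum)``; ES is the running-sum value of
    maximal absolute deviation from zero (signed, first occurrence on
    ties). Raises if the set is disjoint from the list or covers it
    entirely (the miss decrement would be undefined).
    """
    genes = set(gene_set)
    hit = ranked.index.isin(genes)
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise EmptyResultError("gene set shares no genes with the ranked list")
    if n_hits == len(ranked):
        raise ConfigurationError("gene set equals the entire ranked list")
    return _es_from_mask(ranked.to_numpy(dtype=float), hit, weight_p)


def _null_es(metric: np.ndarray, size: int, n_perm: int, rng, weight_p: float) -> np.ndarray:
    """Null ES distribution for sets of a given size (gene-label draws)."""
    n = metric.size
    keys = rng.random((n_perm, n))
    positions = np.argpartition(keys, size, axis=1)[:, :size]
    out = np.empty(n_perm)
    hit = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        hit[:] = False
        hit[positions[i]] = True
        out[i], _ = _es_from_mask(metric, hit, weight_p)
    return out


@dataclass
class GseaResult:
    """Per-set GSEA statistics (GS size, ES, NES, nominal p, FDR q)."""

    table: pd.DataFrame
    n_perm: int

    def passing(self, q_max: float = 0.25, p_max: float = 0.05) -> pd.DataFrame:
        t = self.table
        return t[(t["fdr_q"] < q_max) & (t["nom_p"] < p_max)]


def gsea_nes_fdr(
    ranked: pd.Series,
    collection: dict[str, tuple[str, list[str]]],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_p: float = 1.0,
    min_size: int = 10,
    max_size: int = 500,
) -> GseaResult:
    """GSEA with permutation-based NES, nominal p and FDR q per set.

    The null permutes gene labels (equivalently: draws random sets of
    matching size from the ranked list), so null ES distributions are
    shared across sets of equal size. NES = ES divided by the mean
    |null ES| of matching sign; the nominal p is the same-sign null
    tail fraction; q uses the sign-stratified ratio-of-tails estimator
    over pooled null NES. Sets are restricted to ``min_size <= GS <=
    max_size`` genes present in the ranked list.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    metric = ranked.to_numpy(dtype=float)
    entries = []
    for set_id, (desc, members) in collection.items():
        hit = ranked.index.isin(set(members))
        gs = int(hit.sum())
        if gs < min_size or gs > max_size or gs == len(ranked):
            continue
        es, _ = _es_from_mask(metric, hit, weight_p)
        entries.append((set_id, desc, gs, es))
    if not entries:
        raise EmptyResultError("no gene set met the size bounds on the ranked list")

    sizes = sorted({gs for _, _, gs, _ in entries})
    null_by_size = {gs: _null_es(metric, gs, n_perm, rng, weight_p) for gs in sizes}

    rows = []
    pooled_null_nes: list[np.ndarray] = []
    for set_id, desc, gs, es in entries:
        null = null_by_size[gs]
        pos = null[null > 0]
        neg = null[null < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        null_nes = np.where(null > 0, null / mean_pos, null / mean_neg)
        null_nes = null_nes[np.isfinite(null_nes)]
        pooled_null_nes.append(null_nes)
        if es >= 0:
            if pos.size == 0:
                log.warning("set %s: no positive null ES; NES undefined", set_id)
                rows.append((set_id, desc, gs, es, np.nan, 1.0, 1.0))
                continue
            nes = es / mean_pos
            nom_p = float((pos >= es).sum() / pos.size)
        else:
            if neg.size == 0:
                log.warning("set %s: no negative null ES; NES undefined", set_id)
                rows.append((set_id, desc, gs, es, np.nan, 1.0, 1.0))
                continue
            nes = es / mean_neg  # es < 0, mean_neg > 0 -> nes < 0
            nom_p = float((neg <= es).sum() / neg.size)
        rows.append((set_id, desc, gs, es, nes, nom_p, np.nan))

    table = pd.DataFrame(
        rows, columns=["set_id", "description", "GS", "ES", "NES", "nom_p", "fdr_q"]
    )
    all_null = np.concatenate(pooled_null_nes) if pooled_null_nes else np.array([])
    obs = table["NES"].to_numpy()
    null_pos = all_null[all_null >= 0]
    null_neg = all_null[all_null < 0]
    obs_pos = obs[np.isfinite(obs) & (obs >= 0)]
    obs_neg = obs[np.isfinite(obs) & (obs < 0)]
    qs = []
    for nes, q0 in zip(obs, table["fdr_q"]):
        if not np.isfinite(nes):
            qs.append(q0)
            continue
        if nes >= 0:
            null_frac = (null_pos >= nes).mean() if null_pos.size else 1.0
            obs_frac = (obs_pos >= nes).mean() if obs_pos.size else 1.0
        else:
            null_frac = (null_neg <= nes).mean() if null_neg.size else 1.0
            obs_frac = (obs_neg <= nes).mean() if obs_neg.size else 1.0
        qs.append(float(np.clip(null_frac / max(obs_frac, 1e-300), 0.0, 1.0)))
    table["fdr_q"] = qs
    table = table.sort_values(
        by=["NES", "set_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.insert(0, "ranking", np.arange(1, len(table) + 1))
    table["pass"] = (table["fdr_q"] < 0.25) & (table["nom_p"] < 0.05)
    return GseaResult(table, n_perm)


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------


def ora_hypergeometric(
    foreground,
    universe,
    annotations: dict[str, set[str]],
    fdr_max: float = 0.25,
) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in a foreground list.

    Returns the per-term table (k, n, K, N, p, BH-FDR) restricted to
    terms with FDR below ``fdr_max`` (use ``fdr_max=1.01`` to keep
    everything). The foreground must be a subset of the universe.
    """
    universe = set(universe)
    foreground = set(foreground)
    if not foreground:
        return pd.DataFrame(columns=["term_id", "k", "n", "K", "N", "p_value", "fdr"])
    if not foreground <= universe:
        raise ConfigurationError("foreground must be a subset of the universe")
    term_k: dict[str, int] = {}
    term_big_k: dict[str, int] = {}
    for gene in universe:
        for term in annotations.get(gene, ()):
            term_big_k[term] = term_big_k.get(term, 0) + 1
            if gene in foreground:
                term_k[term] = term_k.get(term, 0) + 1
    rows = []
    big_n, n = len(universe), len(foreground)
    for term in sorted(term_big_k):
        big_k = term_big_k[term]
        k = term_k.get(term, 0)
        rows.append((term, k, n, big_k, big_n, hypergeom_upper_tail(k, n, big_k, big_n)))
    df = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p_value"])
    df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return df[df["fdr"] < fdr_max].reset_index(drop=True)


# ---------------------------------------------------------------------------
# term-set intersections
# ---------------------------------------------------------------------------


@dataclass
class TermIntersection:
    """Exact intersections of labelled enriched-term sets."""

    sets: dict[str, set[str]]
    global_intersection: list[str] = field(default_factory=list)
    pairwise: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    exclusive: dict[str, list[str]] = field(default_factory=dict)

    def counts(self) -> dict:
        return {
            "global": len(self.global_intersection),
            "pairwise": {" & ".join(k): len(v) for k, v in self.pairwise.items()},
            "exclusive": {k: len(v) for k, v in self.exclusive.items()},
            "per_set": {k: len(v) for k, v in self.sets.items()},
        }


def intersect_terms(labelled_sets: dict[str, set[str]]) -> TermIntersection:
    """Pairwise and global intersections of >= 2 labelled term sets."""
    if len(labelled_sets) < 2:
        raise ConfigurationError("need at least two labelled term sets")
    labels = list(labelled_sets)
    sets = {k: set(v) for k, v in labelled_sets.items()}
    common = set.intersection(*sets.values())
    pairwise = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            pairwise[(a, b)] = sorted(sets[a] & sets[b])
    exclusive = {}
    for a in labels:
        others = set().union(*(sets[b] for b in labels if b != a))
        exclusive[a] = sorted(sets[a] - others)
    return TermIntersection(
        sets=sets,
        global_intersection=sorted(common),
        pairwise=pairwise,
        exclusive=exclusive,
    )
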