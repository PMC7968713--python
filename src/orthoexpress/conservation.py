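"""Cross-species conservation of ortholog fold changes.

The statistic: pair the per-species log2 fold changes of ortholog gene
pairs, compute the Pearson correlation r (globally, per metabolic
pathway, or per shared EC number), and judge it against a null cutoff
defined as the average r over many randomly drawn, randomly paired
non-orthologous gene lists. Significance is reported two ways: a
permutation p against the full null distribution (the principled
default) and a one-sample t-test of a bootstrap r sample against the
cutoff (mirroring common practice when only the cutoff scalar is kept).

Positive r means the two species moved ortholog expression in the same
direction between carbon sources; r near zero means no conserved
response; negative r means opposing responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, EmptyResultError, UndefinedStatisticError

log = logging.getLogger(__name__)


def read_ec_map(path) -> pd.DataFrame:
    """Read a gene -> EC/pathway TSV (``gene_id``, ``ec_number``, ``pathway_id``)."""
    return pd.read_csv(path, sep="\t")


@dataclass
class PairedFC:
    """Ortholog pairs with both species' log2 fold changes attached."""

    table: pd.DataFrame  # gene_a, gene_b, log2fc_a, log2fc_b, ec_number, pathway_id
    n_dropped: int = 0
    label: str = "global"

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CorrelationResult:
    subset_label: str
    n_pairs: int
    r: float
    cutoff: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    p_permutation: float | None = None
    p_ttest: float | None = None
    slope: float | None = None


@dataclass
class NullDistribution:
    """Distribution of r over random non-ortholog pairings."""

    r_values: np.ndarray
    n_pairs: int

    @property
    def cutoff(self) -> float:
        return float(self.r_values.mean())

    @property
    def sd(self) -> float:
        return float(self.r_values.std(ddof=1)) if len(self.r_values) > 1 else 0.0


def pair_log2fc(
    dge_a: pd.DataFrame,
    dge_b: pd.DataFrame,
    pairs: pd.DataFrame,
    ec_map: pd.DataFrame | None = None,
    ldo_only: bool = False,
) -> PairedFC:
    """Join ortholog pairs with both species' estimated log2 fold changes.

    Pairs whose gene was filtered out of either DGE table are dropped
    and counted. Co-ortholog fans expand to all pairs by default;
    ``ldo_only`` restricts to least-diverged-ortholog rows. EC number
    and pathway annotations are joined on the first species' gene (a
    pair is annotated when either side carries the annotation).
    """
    tab = pairs.copy()
    if ldo_only and "ortholog_type" in tab.columns:
        tab = tab[tab["ortholog_type"] == "LDO"]
    fc_a = dge_a["log2FC"]
    fc_b = dge_b["log2FC"]
    before = len(tab)
    tab = tab[tab["gene_a"].isin(fc_a.index) & tab["gene_b"].isin(fc_b.index)].copy()
    n_dropped = before - len(tab)
    if len(tab) == 0:
        raise EmptyResultError("no ortholog pair survived in both DGE tables")
    tab["log2fc_a"] = fc_a.loc[tab["gene_a"]].to_numpy()
    tab["log2fc_b"] = fc_b.loc[tab["gene_b"]].to_numpy()
    tab["ec_number"] = pd.Series(pd.NA, index=tab.index, dtype="string")
    tab["pathway_id"] = pd.Series(pd.NA, index=tab.index, dtype="string")
    if ec_map is not None:
        ann = ec_map.drop_duplicates("gene_id").set_index("gene_id")
        for side in ("gene_a", "gene_b"):
            for col in ("ec_number", "pathway_id"):
                mapped = tab[side].map(ann[col]).astype("string")
                tab[col] = tab[col].fillna(mapped)
    keep = ["gene_a", "gene_b", "ortholog_type", "log2fc_a", "log2fc_b", "ec_number", "pathway_id"]
    keep = [c for c in keep if c in tab.columns]
    return PairedFC(tab[keep].reset_index(drop=True), n_dropped=n_dropped)


def pearson_r(paired: PairedFC | pd.DataFrame) -> float:
    """Sample Pearson correlation of the paired log2 fold changes.

    Identical to the signed square root of the R-squared of the
    least-squares regression of one species' log2FC on the other's.
    """
    tab = paired.table if isinstance(paired, PairedFC) else paired
    if len(tab) < 3:
        raise UndefinedStatisticError(f"need >= 3 pairs for r, got {len(tab)}")
    x = tab["log2fc_a"].to_numpy(dtype=float)
    y = tab["log2fc_b"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined: a coordinate is constant")
    return float(stats.pearsonr(x, y).statistic)


def regression_slope(paired: PairedFC) -> float:
    """Least-squares slope of log2FC_b on log2FC_a (for transparency)."""
    x = paired.table["log2fc_a"].to_numpy(dtype=float)
    y = paired.table["log2fc_b"].to_numpy(dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def subset_by_pathway(
    paired: PairedFC, pathway_id: str | None = None, ec_class: str | None = None
) -> PairedFC:
    """Restrict pairs to one pathway or an EC class prefix.

    ``ec_class`` matches full 4-level EC strings exactly, or as a prefix
    when it has fewer levels (e.g. ``"1.1.1"``). An empty subset is
    returned with a warning (callers exclude it from testing).
    """
    tab = paired.table
    if pathway_id is not None:
        sub = tab[tab["pathway_id"] == pathway_id]
        label = pathway_id
    elif ec_class is not None:
        ec = tab["ec_number"].astype("string")
        if ec_class.count(".") >= 3:
            sub = tab[ec == ec_class]
        else:
            sub = tab[ec.str.startswith(ec_class + ".").fillna(False)]
        label = f"EC:{ec_class}"
    else:
        return PairedFC(tab.copy(), paired.n_dropped, label="global")
    if len(sub) == 0:
        log.warning("subset %s is empty", label)
    return PairedFC(sub.reset_index(drop=True), paired.n_dropped, label=label)


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom) if denom > 0 else np.nan


def null_cutoff(
    dge_a: pd.DataFrame,
    dge_b: pd.DataFrame,
    n_pairs: int,
    n_lists: int = 1000,
    seed: int | None = None,
    exclude: pd.DataFrame | None = None,
) -> NullDistribution:
    """Null distribution of r from randomly paired non-ortholog gene lists.

    Each of ``n_lists`` draws samples ``n_pairs`` genes per species
    uniformly without replacement, pairs them in drawn order, removes
    any pairing that coincides with a true ortholog pair (``exclude``),
    and records the Pearson r. The mean of these r values is the cutoff
    the observed correlation is judged against; deterministic given the
    seed.
    """
    genes_a = dge_a.index.to_numpy()
    genes_b = dge_b.index.to_numpy()
    fc_a = dge_a["log2FC"].to_numpy(dtype=float)
    fc_b = dge_b["log2FC"].to_numpy(dtype=float)
    if n_pairs > len(genes_a) or n_pairs > len(genes_b):
        raise ConfigurationError(
            f"n_pairs={n_pairs} exceeds available genes ({len(genes_a)}, {len(genes_b)})"
        )
    if n_pairs < 3:
        raise ConfigurationError("n_pairs must be >= 3 for a defined correlation")
    excluded = set()
    if exclude is not None:
        excluded = set(zip(exclude["gene_a"], exclude["gene_b"]))
    rng = np.random.default_rng(seed)
    rs = np.empty(n_lists)
    for i in range(n_lists):
        ia = rng.choice(len(genes_a), size=n_pairs, replace=False)
        ib = rng.choice(len(genes_b), size=n_pairs, replace=False)
        if excluded:
            mask = np.fromiter(
                ((genes_a[a], genes_b[b]) not in excluded for a, b in zip(ia, ib)),
                dtype=bool,
                count=n_pairs,
            )
            ia, ib = ia[mask], ib[mask]
        rs[i] = _corr(fc_a[ia], fc_b[ib])
    rs = rs[np.isfinite(rs)]
    return NullDistribution(rs, n_pairs)


def test_against_cutoff(
    observed_r: float,
    null: NullDistribution,
    method: str = "permutation",
    paired: PairedFC | None = None,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    two_sided: bool = False,
) -> float:
    """p-value for the observed r against the random-pairing null.

    ``permutation``: p = (1 + #{null r >= observed}) / (1 + n_lists),
    one-sided toward positive association by default. ``t_test``:
    one-sample t-test of a bootstrap sample of r (pairs resampled with
    replacement) against the null cutoff; requires ``paired``.
    """
    if null.sd == 0:
        raise UndefinedStatisticError("degenerate null distribution (zero variance)")
    if method == "permutation":
        n = len(null.r_values)
        if two_sided:
            center = null.cutoff
            exceed = np.abs(null.r_values - center) >= abs(observed_r - center)
            return float((1 + exceed.sum()) / (1 + n))
        return float((1 + (null.r_values >= observed_r).sum()) / (1 + n))
    if method == "t_test":
        if paired is None:
            raise ConfigurationError("t_test method needs the paired table for bootstrap")
        rng = np.random.default_rng(seed)
        x = paired.table["log2fc_a"].to_numpy(dtype=float)
        y = paired.table["log2fc_b"].to_numpy(dtype=float)
        n = len(x)
        rs = np.empty(n_bootstrap)
        for i in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            rs[i] = _corr(x[idx], y[idx])
        rs = rs[np.isfinite(rs)]
        res = stats.ttest_1samp(rs, popmean=null.cutoff)
        return float(res.pvalue)
    raise ConfigurationError(f"unknown method {method!r}")


def correlation_report(
    paired: PairedFC,
    null: NullDistribution,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> CorrelationResult:
    """Observed r, null cutoff, and both significance tests for a subset."""
    r = pearson_r(paired)
    return CorrelationResult(
        subset_label=paired.label,
        n_pairs=len(paired),
        r=r,
        cutoff=null.cutoff,
        null_mean=null.cutoff,
        null_sd=null.sd,
        p_permutation=test_against_cutoff(r, null, "permutation"),
        p_ttest=test_against_cutoff(r, null, "t_test", paired, n_bootstrap, seed),
        slope=regression_slope(paired),
    )
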