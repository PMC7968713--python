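"""Per-species two-condition differential expression for count data.

Pipeline: expression filter (>= 1 count per million in >= 2 samples),
trimmed-mean-of-M-values (TMM) library normalization, negative-binomial
GLM likelihood-ratio test per gene, Benjamini-Hochberg FDR, and DEG
calling at |log2FC| >= 1 and FDR <= 0.05 (inclusive thresholds).

The contrast is parameterized by a reference condition; with the default
reference ``glycerol_acetate``, genes higher in glucose get positive
log2FC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from .errors import ConfigurationError, EmptyResultError

log = logging.getLogger(__name__)

LN2 = np.log(2.0)


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples count TSV (first column ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ConfigurationError(f"duplicate gene or sample IDs in {path}")
    return df


def read_design(path) -> pd.DataFrame:
    """Read a sample design TSV (``sample_id``, ``condition``, ``replicate``)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def _check_design(counts: pd.DataFrame, design: pd.DataFrame) -> None:
    missing = set(counts.columns) - set(design.index)
    if missing:
        raise ConfigurationError(f"samples missing from design: {sorted(missing)}")
    levels = design.loc[list(counts.columns), "condition"].unique()
    if len(levels) != 2:
        raise ConfigurationError(f"exactly two conditions required, got {list(levels)}")


def cpm(counts: pd.DataFrame, lib_sizes: np.ndarray | None = None) -> pd.DataFrame:
    """Counts per million on raw (or supplied effective) library sizes."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).to_numpy(dtype=float)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        raise ConfigurationError("library sizes must be positive")
    return counts / lib_sizes * 1e6


def cpm_filter(counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 2) -> pd.DataFrame:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples.

    CPM is computed on raw library sizes (pre-normalization); gene order
    is preserved.
    """
    keep = (cpm(counts) >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise EmptyResultError(
            f"CPM filter (>= {min_cpm} CPM in >= {min_samples} samples) removed all "
            f"{len(counts)} genes; library sizes: {counts.sum(axis=0).to_dict()}"
        )
    return counts.loc[keep]


# ---------------------------------------------------------------------------
# TMM normalization (Robinson & Oshlack trimmed mean of M-values)
# ---------------------------------------------------------------------------


@dataclass
class NormFactors:
    """Per-sample TMM factors and library sizes.

    Factors are rescaled to geometric mean 1; ``effective`` is
    factor x library size, the offset basis for the GLM stage.
    """

    sample_ids: list[str]
    factors: np.ndarray
    lib_sizes: np.ndarray

    @property
    def effective(self) -> np.ndarray:
        return self.factors * self.lib_sizes

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tmm_factor": self.factors, "lib_size": self.lib_sizes, "effective": self.effective},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    log_ratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
    weighted: bool = True,
) -> float:
    """TMM factor of one sample against the reference sample.

    M (log ratio) and A (average log abundance) are formed over genes
    expressed in both samples; the upper and lower ``log_ratio_trim``
    quantiles of M and ``abs_expr_trim`` of A are trimmed, and the
    retained M values are averaged with inverse asymptotic-variance
    (delta-method binomial) weights.
    """
    obs = obs.astype(float)
    ref = ref.astype(float)
    n_obs, n_ref = obs.sum(), ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, var = log_r[fin], abs_e[fin], var[fin]
    if log_r.size == 0:
        log.warning("sample shares no expressed genes with the reference; factor set to 1")
        return 1.0
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_m = np.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_expr_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / var[keep]) / np.sum(1.0 / var[keep])
    else:
        f = np.mean(log_r[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame, ref_sample: str | None = None) -> NormFactors:
    """TMM normalization factors for every sample of a count matrix.

    The reference defaults to the sample whose 75th CPM percentile is
    closest to the mean across samples. Factors are rescaled so their
    geometric mean is exactly 1.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ConfigurationError("all samples must have positive library size")
    mat = counts.to_numpy(dtype=float)
    if ref_sample is None:
        q75 = np.quantile(mat, 0.75, axis=0) / lib
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_sample)
    ref = mat[:, ref_idx]
    factors = np.array([_tmm_pair(mat[:, j], ref) for j in range(mat.shape[1])])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(list(counts.columns), factors, lib)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


@dataclass
class DispersionEstimate:
    common: float
    per_gene: pd.Series
    prior_df: float


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB log-likelihood with Var = mu + phi mu^2 (size r = 1/phi)."""
    mu = np.maximum(mu, 1e-12)
    if phi <= 0:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    r = 1.0 / phi
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def estimate_dispersion(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    norm: NormFactors,
    prior_df: float = 10.0,
) -> DispersionEstimate:
    """Common and shrunken per-gene NB dispersions.

    The common phi maximizes the Cox-Reid adjusted profile likelihood
    pooled over genes (group means profiled out per condition, offsets =
    effective library sizes). Per-gene phi is a method-of-moments
    estimate shrunk toward the common value with weight
    prior_df / (prior_df + residual df), floored at 1e-8.
    """
    _check_design(counts, design)
    cond = design.loc[list(counts.columns), "condition"].to_numpy()
    levels = pd.unique(cond)
    y = counts.to_numpy(dtype=float)
    eff = norm.effective
    groups = [np.flatnonzero(cond == lv) for lv in levels]
    if max(len(g) for g in groups) < 2:
        log.warning("no condition has replicates; falling back to fixed phi=0.1")
        per_gene = pd.Series(0.1, index=counts.index, name="dispersion")
        return DispersionEstimate(0.1, per_gene, prior_df)

    # profiled group means: mu_gs = p_gc * eff_s with p_gc = sum(y)/sum(eff)
    mus = []
    for idx in groups:
        p = y[:, idx].sum(axis=1) / eff[idx].sum()
        mus.append(np.outer(p, eff[idx]))

    def neg_apl(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        r = 1.0 / phi
        total = 0.0
        for idx, mu in zip(groups, mus):
            yy = y[:, idx]
            mu_c = np.maximum(mu, 1e-12)
            ll = (
                special.gammaln(yy + r)
                - special.gammaln(r)
                - special.gammaln(yy + 1)
                + r * np.log(r / (r + mu_c))
                + yy * np.log(mu_c / (r + mu_c))
            )
            info = (mu_c / (1.0 + phi * mu_c)).sum(axis=1)
            total += ll.sum() - 0.5 * np.sum(np.log(np.maximum(info, 1e-300)))
        return -total

    res = optimize.minimize_scalar(
        neg_apl, bounds=(np.log(1e-6), np.log(5.0)), method="bounded",
        options={"xatol": 1e-6},
    )
    common = float(np.exp(res.x))

    # per-gene method of moments on library-size-adjusted counts
    scale = np.exp(np.mean(np.log(eff)))
    z = y / eff * scale
    num = np.zeros(len(counts))
    den = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        m = z[:, idx].mean(axis=1)
        s2 = z[:, idx].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            mom = (s2 - m) / m**2
        mom = np.where(np.isfinite(mom), mom, 0.0)
        num += np.clip(mom, 0.0, None) * (len(idx) - 1)
        den += len(idx) - 1
    phi_mom = num / max(den, 1.0)
    resid_df = max(y.shape[1] - len(groups), 1)
    w = prior_df / (prior_df + resid_df)
    per_gene = np.maximum(w * common + (1.0 - w) * phi_mom, 1e-8)
    return DispersionEstimate(
        common, pd.Series(per_gene, index=counts.index, name="dispersion"), prior_df
    )


# ---------------------------------------------------------------------------
# NB GLM likelihood-ratio test
# ---------------------------------------------------------------------------


def fit_nb_glm_lrt(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    norm: NormFactors,
    dispersion: DispersionEstimate | float,
    reference_condition: str = "glycerol_acetate",
) -> pd.DataFrame:
    """Per-gene NB GLM likelihood-ratio test of the condition effect.

    Full model: log mu = offset + b0 + b1 * [condition != reference];
    null model drops b1. Fitted by IRLS (relative tolerance 1e-8, at
    most 50 iterations). Returns a table with ``log2FC`` (= b1 / ln 2,
    positive when the non-reference condition is higher), ``lrt_stat``
    (2 x log-likelihood difference, clamped at 0), ``p_value`` from the
    upper tail of chi-square(1), and ``mean_cpm`` on effective library
    sizes. Genes whose fit does not converge are flagged, given p = 1,
    and a moderated group-mean log2FC.
    """
    _check_design(counts, design)
    cond = design.loc[list(counts.columns), "condition"].to_numpy()
    levels = set(pd.unique(cond))
    if reference_condition not in levels:
        raise ConfigurationError(
            f"reference condition {reference_condition!r} not among {sorted(levels)}"
        )
    indicator = (cond != reference_condition).astype(float)
    offset = np.log(norm.effective)
    y_all = counts.to_numpy(dtype=float)
    if isinstance(dispersion, DispersionEstimate):
        phis = dispersion.per_gene.reindex(counts.index).to_numpy()
    else:
        phis = np.full(len(counts), float(dispersion))

    n = len(counts.columns)
    X_full = np.column_stack([np.ones(n), indicator])
    X_null = np.ones((n, 1))
    eff = norm.effective
    mean_cpm = (y_all / eff * 1e6).mean(axis=1)

    rows = np.empty((len(counts), 3))
    converged = np.ones(len(counts), dtype=bool)
    eps = 0.5  # moderation pseudo-count for fallback fold changes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(len(counts)):
            y = y_all[i]
            fam = sm.families.NegativeBinomial(alpha=max(phis[i], 1e-8))
            try:
                full = sm.GLM(y, X_full, family=fam, offset=offset).fit(
                    maxiter=50, tol=1e-8, scale=1.0
                )
                null = sm.GLM(y, X_null, family=fam, offset=offset).fit(
                    maxiter=50, tol=1e-8, scale=1.0
                )
                ok = (
                    np.all(np.isfinite(full.params))
                    and np.isfinite(full.llf)
                    and np.isfinite(null.llf)
                    and np.abs(full.params[1]) < 50
                )
            except Exception:
                ok = False
            if ok:
                lrt = max(0.0, 2.0 * (full.llf - null.llf))
                rows[i] = (full.params[1] / LN2, lrt, stats.chi2.sf(lrt, df=1))
            else:
                converged[i] = False
                m1 = (y[indicator == 1] / eff[indicator == 1]).mean()
                m0 = (y[indicator == 0] / eff[indicator == 0]).mean()
                scale = np.exp(np.mean(np.log(eff)))
                lfc = np.log2((m1 * scale + eps) / (m0 * scale + eps))
                rows[i] = (lfc, 0.0, 1.0)

    out = pd.DataFrame(
        rows, columns=["log2FC", "lrt_stat", "p_value"], index=counts.index.copy()
    )
    out.insert(0, "mean_cpm", mean_cpm)
    out["converged"] = converged
    n_bad = int((~converged).sum())
    if n_bad:
        log.warning("%d genes did not converge; flagged with p=1", n_bad)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    fdr = sm.stats.multipletests(p, method="fdr_bh")[1]
    return fdr


@dataclass
class DEGSummary:
    n_tested: int
    n_up: int
    n_down: int

    @property
    def n_de(self) -> int:
        return self.n_up + self.n_down

    @property
    def pct_de(self) -> float:
        from .pipeline import round_half_up

        return round_half_up(100.0 * self.n_de / self.n_tested) if self.n_tested else 0.0


def call_degs(
    table: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.05
) -> tuple[pd.DataFrame, DEGSummary]:
    """Attach DE status at |log2FC| >= lfc_min and FDR <= fdr_max (inclusive).

    ``up`` means higher in the non-reference condition (glucose under
    the default contrast); ``down`` means higher in the reference.
    """
    out = table.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    sig = out["fdr"] <= fdr_max
    status = np.where(
        sig & (out["log2FC"] >= lfc_min),
        "up",
        np.where(sig & (out["log2FC"] <= -lfc_min), "down", "ns"),
    )
    out["status"] = status
    summary = DEGSummary(
        n_tested=len(out),
        n_up=int((out["status"] == "up").sum()),
        n_down=int((out["status"] == "down").sum()),
    )
    return out, summary


def run_dge(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    reference_condition: str = "glycerol_acetate",
    min_cpm: float = 1.0,
    min_samples: int = 2,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> tuple[pd.DataFrame, NormFactors, DEGSummary]:
    """Full single-species DE analysis; returns (DGE table, norm, summary)."""
    filtered = cpm_filter(counts, min_cpm=min_cpm, min_samples=min_samples)
    norm = tmm_factors(filtered)
    disp = estimate_dispersion(filtered, design, norm)
    table = fit_nb_glm_lrt(filtered, design, norm, disp, reference_condition)
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    table, summary = call_degs(table, lfc_min=lfc_min, fdr_max=fdr_max)
    return table, norm, summary
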