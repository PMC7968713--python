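"""Differential-expression stage: filtering, TMM, dispersion, GLM-LRT, BH."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special

from orthoexpress import dge
from orthoexpress.errors import ConfigurationError, EmptyResultError
from reference_impl import bh_step_up


def _design(conditions):
    return pd.DataFrame(
        {
            "condition": conditions,
            "replicate": list(range(1, len(conditions) + 1)),
        },
        index=pd.Index([f"s{i}" for i in range(len(conditions))], name="sample_id"),
    )


def _counts(mat, n_samples=None):
    mat = np.asarray(mat)
    return pd.DataFrame(
        mat,
        index=[f"g{i}" for i in range(mat.shape[0])],
        columns=[f"s{i}" for i in range(mat.shape[1])],
    )


# ---------------------------------------------------------------------------
# CPM filter
# ---------------------------------------------------------------------------


class TestCpmFilter:
    def test_all_zero_gene_removed_and_expressed_gene_kept(self):
        mat = np.zeros((2, 6), dtype=int)
        mat[1] = [10, 10, 0, 0, 0, 0]
        mat = np.vstack([mat, np.full((1, 6), 1_000_000)])  # keeps libraries ~1e6
        counts = _counts(mat)
        kept = dge.cpm_filter(counts)
        assert "g0" not in kept.index  # all-zero gene
        assert "g1" in kept.index  # CPM ~10 in two samples

    def test_filter_matches_row_by_row_recomputation(self):
        rng = np.random.default_rng(21)
        mat = rng.integers(0, 40, size=(200, 6))
        mat[rng.random(200) < 0.3] = 0
        counts = _counts(mat)
        kept = dge.cpm_filter(counts, min_cpm=1.0, min_samples=2)
        libs = mat.sum(axis=0)
        expected = [
            f"g{i}"
            for i in range(200)
            if sum(mat[i, j] / libs[j] * 1e6 >= 1.0 for j in range(6)) >= 2
        ]
        assert list(kept.index) == expected

    def test_empty_result_raises_with_diagnostic(self):
        counts = _counts([[1, 1], [2, 1]])  # tiny libraries -> huge CPM; invert test
        with pytest.raises(EmptyResultError):
            dge.cpm_filter(counts, min_cpm=1e9)


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        col = np.random.default_rng(1).integers(1, 500, size=80)
        counts = _counts(np.column_stack([col] * 4))
        nf = dge.tmm_factors(counts)
        assert np.allclose(nf.factors, 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        col = np.random.default_rng(2).integers(1, 500, size=80)
        counts = _counts(np.column_stack([col, 2 * col]))
        nf = dge.tmm_factors(counts)
        assert np.allclose(nf.factors, 1.0)
        assert nf.effective[1] == pytest.approx(2 * nf.effective[0])

    def test_two_sample_factor_matches_direct_trimmed_mean(self):
        """Spreadsheet-style recomputation of the doubly trimmed weighted mean."""
        rng = np.random.default_rng(3)
        mat = rng.integers(1, 2000, size=(50, 2)).astype(float)
        mat[:5, 1] *= 6  # asymmetry so the factor is not 1
        counts = _counts(mat)
        obs, ref = mat[:, 1], mat[:, 0]
        n_obs, n_ref = obs.sum(), ref.sum()
        m = np.log2((obs / n_obs) / (ref / n_ref))
        a = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
        n = len(m)
        lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        rm = np.argsort(np.argsort(m)) + 1  # no ties in random floats
        ra = np.argsort(np.argsort(a)) + 1
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        f = 2 ** (np.sum(m[keep] / v[keep]) / np.sum(1 / v[keep]))
        expected = np.array([1.0, f])
        expected /= np.exp(np.mean(np.log(expected)))
        nf = dge.tmm_factors(counts, ref_sample="s0")
        assert np.allclose(nf.factors, expected, rtol=1e-12)

    def test_factors_invariant_to_scaling(self):
        rng = np.random.default_rng(4)
        mat = rng.integers(1, 800, size=(120, 4)).astype(float)
        counts = _counts(mat)
        nf = dge.tmm_factors(counts, ref_sample="s0")
        # scaling every sample by the same constant: exactly invariant
        # (M, A and the precision-weight ratios are all unchanged)
        nf_global = dge.tmm_factors(counts * 3, ref_sample="s0")
        assert np.allclose(nf.factors, nf_global.factors, atol=1e-12)
        # scaling one sample: the depth change moves to the library size;
        # factors shift only through the reference side of the precision
        # weights, so they agree closely but not exactly
        scaled = counts.copy()
        scaled["s2"] = scaled["s2"] * 7
        nf_scaled = dge.tmm_factors(scaled, ref_sample="s0")
        assert np.allclose(nf.factors, nf_scaled.factors, rtol=0.05)
        assert np.allclose(nf_scaled.effective, nf.effective * [1, 1, 7, 1], rtol=0.05)

    def test_matches_edger_reference_implementation(self, tmp_path):
        """Cross-check against the canonical TMM implementation in R."""
        rng = np.random.default_rng(42)
        base = rng.lognormal(4, 1, 300)
        mat = np.column_stack([rng.poisson(base * f) for f in (1.0, 2.5, 0.7, 1.3)])
        mat[:30, 0] *= 5
        counts = _counts(mat)
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.delim("{path}", row.names=1));'
            'cat(sprintf("%.12f", calcNormFactors(x, method="TMM")), sep="\\n")'
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        if proc.returncode != 0:
            pytest.skip(f"Rscript/edgeR unavailable: {proc.stderr[-200:]}")
        expected = np.array([float(x) for x in proc.stdout.split()])
        nf = dge.tmm_factors(counts)
        assert np.allclose(nf.factors, expected, rtol=1e-8)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


class TestDispersion:
    def _norm(self, counts):
        libs = counts.sum(axis=0).to_numpy(dtype=float)
        return dge.NormFactors(list(counts.columns), np.ones(len(libs)), libs)

    def test_poisson_counts_give_near_zero_common_dispersion(self):
        rng = np.random.default_rng(8)
        mu = rng.lognormal(4, 1, 2000)
        mat = rng.poisson(np.repeat(mu[:, None], 6, axis=1))
        counts = _counts(mat)
        est = dge.estimate_dispersion(counts, _design(["a"] * 3 + ["b"] * 3), self._norm(counts))
        assert est.common <= 0.01

    def test_recovers_simulated_dispersion(self):
        rng = np.random.default_rng(9)
        phi = 0.2
        mu = rng.lognormal(4, 1, 2000)
        lam = rng.gamma(1 / phi, phi * np.repeat(mu[:, None], 6, axis=1))
        counts = _counts(rng.poisson(lam))
        est = dge.estimate_dispersion(counts, _design(["a"] * 3 + ["b"] * 3), self._norm(counts))
        assert 0.15 <= est.common <= 0.25

    def test_constant_gene_shrinks_fully_to_prior_weighted_common(self):
        rng = np.random.default_rng(10)
        phi = 0.1
        mu = rng.lognormal(4, 0.5, 50)
        lam = rng.gamma(1 / phi, phi * np.repeat(mu[:, None], 6, axis=1))
        mat = rng.poisson(lam).astype(float)
        mat[0] = 7.0  # identical counts in every sample
        counts = _counts(mat)
        norm = dge.NormFactors(list(counts.columns), np.ones(6), np.full(6, 1e6))
        est = dge.estimate_dispersion(counts, _design(["a"] * 3 + ["b"] * 3), norm)
        # MoM term is 0, so the shrunk estimate is w * common with
        # w = prior_df / (prior_df + residual_df), residual_df = 6 - 2
        w = est.prior_df / (est.prior_df + 4)
        assert est.per_gene.iloc[0] == pytest.approx(w * est.common, rel=1e-9)


# ---------------------------------------------------------------------------
# NB GLM likelihood-ratio test
# ---------------------------------------------------------------------------


def _nb_negloglik(params, y, indicator, offset, phi):
    b0, b1 = params
    mu = np.exp(offset + b0 + b1 * indicator)
    r = 1.0 / phi
    return -float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


class TestGlmLrt:
    design = _design(["glycerol_acetate"] * 3 + ["glucose"] * 3)

    def _norm(self, counts):
        return dge.NormFactors(
            list(counts.columns), np.ones(6), np.full(6, 1e6)
        )

    def test_equal_means_give_zero_lfc_and_p_one(self):
        counts = _counts([[50, 50, 50, 50, 50, 50]])
        table = dge.fit_nb_glm_lrt(counts, self.design, self._norm(counts), 0.1)
        assert table["log2FC"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert table["lrt_stat"].iloc[0] == pytest.approx(0.0, abs=1e-8)
        assert table["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-4)

    def test_exact_doubling_gives_unit_log2fc_with_contrast_sign(self):
        counts = _counts([[50, 50, 50, 100, 100, 100]])
        table = dge.fit_nb_glm_lrt(counts, self.design, self._norm(counts), 0.1)
        # glucose samples are doubled and glucose is the non-reference level
        assert table["log2FC"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        flipped = dge.fit_nb_glm_lrt(
            counts, self.design, self._norm(counts), 0.1, reference_condition="glucose"
        )
        assert flipped["log2FC"].iloc[0] == pytest.approx(-1.0, abs=1e-6)
        assert flipped["lrt_stat"].iloc[0] == pytest.approx(
            table["lrt_stat"].iloc[0], rel=1e-9
        )

    def test_lrt_matches_direct_likelihood_optimization(self):
        """IRLS fit agrees with brute-force optimization of the NB likelihood."""
        rng = np.random.default_rng(17)
        phi = 0.15
        mu = rng.lognormal(4, 1, 10)
        fold = rng.uniform(0.3, 3.0, 10)
        libs = rng.integers(8e5, 1.2e6, size=6).astype(float)
        rel = np.outer(mu, np.ones(6))
        rel[:, 3:] *= fold[:, None]
        lam = rng.gamma(1 / phi, phi * rel / rel.sum(axis=0) * libs)
        counts = _counts(rng.poisson(lam))
        norm = dge.NormFactors(list(counts.columns), np.ones(6), libs)
        table = dge.fit_nb_glm_lrt(counts, self.design, norm, phi)
        indicator = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        offset = np.log(norm.effective)
        for i in range(10):
            y = counts.to_numpy(dtype=float)[i]
            full = optimize.minimize(
                _nb_negloglik, x0=[0.0, 0.0], args=(y, indicator, offset, phi),
                method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            )
            null = optimize.minimize_scalar(
                lambda b0: _nb_negloglik((b0, 0.0), y, np.zeros(6), offset, phi),
                bounds=(-30, 10), method="bounded", options={"xatol": 1e-12},
            )
            lrt = max(0.0, 2 * (null.fun - full.fun))
            assert table["lrt_stat"].iloc[i] == pytest.approx(lrt, abs=1e-4)
            assert table["log2FC"].iloc[i] == pytest.approx(
                full.x[1] / np.log(2), abs=1e-4
            )


# ---------------------------------------------------------------------------
# BH adjustment and DEG calling
# ---------------------------------------------------------------------------


class TestBh:
    def test_single_p_unchanged(self):
        assert dge.bh_adjust([0.01])[0] == pytest.approx(0.01)

    def test_hand_computed_example(self):
        out = dge.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_step_up_enumeration(self, p_values):
        assert np.allclose(dge.bh_adjust(p_values), bh_step_up(p_values), atol=1e-12)
        assert np.all(dge.bh_adjust(p_values) >= np.asarray(p_values) - 1e-12)


class TestCallDegs:
    def _table(self, lfc, fdr):
        return pd.DataFrame(
            {"log2FC": lfc, "p_value": fdr, "fdr": fdr},
            index=[f"g{i}" for i in range(len(lfc))],
        )

    def test_thresholds_are_inclusive(self):
        table, summary = dge.call_degs(self._table([1.0, 0.99, -1.0, 2.0],
                                                   [0.05, 0.001, 0.05, 0.2]))
        assert list(table["status"]) == ["up", "ns", "down", "ns"]
        assert summary.n_up == 1 and summary.n_down == 1 and summary.n_de == 2

    def test_counts_and_percentage(self):
        table, summary = dge.call_degs(self._table([2.0] * 3 + [0.0] * 7, [0.01] * 10))
        assert summary.n_tested == 10
        assert summary.pct_de == 30.0


def test_run_dge_recovers_planted_effects(small_dataset, small_dge):
    """End-to-end per-species DE run detects most planted |log2FC|=2 genes."""
    from orthoexpress.syndata import SPECIES_A

    table, _, summary = small_dge[SPECIES_A]
    truth = small_dataset.truth
    called = set(table.index[table["status"] != "ns"])
    planted = truth.de_genes[SPECIES_A] & set(table.index)
    sensitivity = len(called & planted) / len(planted)
    assert sensitivity >= 0.8
    # sign convention: glucose-up genes have positive true and estimated lfc
    for g in sorted(planted)[:20]:
        assert np.sign(table.loc[g, "log2FC"]) == np.sign(truth.true_log2fc[SPECIES_A][g])
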