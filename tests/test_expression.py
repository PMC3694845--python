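"""Quantile normalization, probe merging and the moderated t-statistic."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import optimize, special

from methgate.expression import (
    ContrastResult,
    ContrastSpec,
    fit_moderated_t,
    merge_probes_to_genes,
    quantile_normalize,
    select_de_genes,
)

from conftest import GROUP_A, GROUP_B, make_matrix, two_group_matrix


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


class TestQuantileNormalize:
    def test_single_column_unchanged(self):
        m = make_matrix(np.array([[3.0], [1.0], [2.0]]))
        out = quantile_normalize(m)
        assert np.array_equal(out.values.to_numpy(), m.values.to_numpy())

    def test_two_columns_rankwise_means(self):
        m = make_matrix(np.array([[2.0, 1.0], [4.0, 3.0], [6.0, 5.0]]))
        out = quantile_normalize(m)
        expected = np.array([[1.5, 1.5], [3.5, 3.5], [5.5, 5.5]])
        assert np.allclose(out.values.to_numpy(), expected)

    def test_tied_values_get_mean_of_tied_reference(self):
        # column 0 has a 3-way tie occupying ranks 0..2; the tied entries
        # must receive the mean of the reference over those ranks
        m = make_matrix(np.array([[1.0, 1.0], [1.0, 2.0], [1.0, 3.0], [9.0, 4.0]]))
        out = quantile_normalize(m)
        ref = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)
        col0 = out.values.to_numpy()[:, 0]
        assert np.allclose(col0[:3], ref[:3].mean())
        assert np.isclose(col0[3], ref[3])

    def test_rejects_non_finite(self):
        m = make_matrix(np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(ValueError, match="non-finite"):
            quantile_normalize(m)

    @given(
        arrays(
            float, (20, 5),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
            unique=True,
        )
    )
    def test_columns_share_one_multiset_and_idempotent(self, arr):
        # tie-free columns: the normalized columns share one multiset and
        # a second normalization is the identity (with ties the averaging
        # rule contracts tied ranks, so idempotency holds only here)
        out = quantile_normalize(make_matrix(arr))
        v = out.values.to_numpy()
        ref = np.sort(v[:, 0])
        for j in range(v.shape[1]):
            assert np.allclose(np.sort(v[:, j]), ref, atol=1e-12)
        again = quantile_normalize(out)
        assert np.allclose(again.values.to_numpy(), v, atol=1e-12)


# ---------------------------------------------------------------------------
# probe -> gene merging
# ---------------------------------------------------------------------------


class TestMergeProbes:
    def _probe_matrix(self):
        values = np.array([[4.0, 8.0], [6.0, 10.0], [1.0, 2.0], [5.0, 5.0]])
        m = make_matrix(values, level="probe")
        m.values.index = ["p1", "p2", "p3", "p_unmapped"]
        return m

    def test_mean_of_probes_and_unmapped_dropped(self):
        m = self._probe_matrix()
        mapping = pd.Series({"p1": "GA", "p2": "GA", "p3": "GB"})
        out = merge_probes_to_genes(m, mapping)
        assert out.level == "gene"
        assert sorted(out.values.index) == ["GA", "GB"]
        assert np.allclose(out.values.loc["GA"], [5.0, 9.0])  # mean of p1,p2
        assert np.allclose(out.values.loc["GB"], [1.0, 2.0])  # single probe copied

    def test_probe_order_irrelevant(self):
        m = self._probe_matrix()
        mapping = pd.Series({"p1": "GA", "p2": "GA", "p3": "GB"})
        shuffled = make_matrix(m.values.to_numpy()[::-1], level="probe")
        shuffled.values.index = list(m.values.index)[::-1]
        a = merge_probes_to_genes(m, mapping).values
        b = merge_probes_to_genes(shuffled, mapping).values
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            merge_probes_to_genes(self._probe_matrix(), pd.Series(dtype=object))

    def test_gene_level_input_rejected(self):
        m = make_matrix(np.ones((2, 2)), level="gene")
        with pytest.raises(ValueError, match="probe-level"):
            merge_probes_to_genes(m, pd.Series({"g0": "X"}))


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def oracle_hyperparameters(s2: np.ndarray, d: int):
    """Independent moment-equation solve (brentq on the trigamma equation)."""
    z = np.log(s2[s2 > 0])
    excess = np.var(z, ddof=1) - special.polygamma(1, d / 2.0)
    if excess <= 0:
        return np.inf, float(np.mean(s2))
    x = optimize.brentq(
        lambda v: special.polygamma(1, v) - excess, 1e-6, 1e8, xtol=1e-14
    )
    d0 = 2.0 * x
    log_s0 = (
        np.mean(z)
        - special.digamma(d / 2.0)
        + special.digamma(d0 / 2.0)
        - np.log(d0 / d)
    )
    return d0, float(np.exp(log_s0))


class TestModeratedT:
    def test_equal_group_means_give_null_statistics(self):
        rng = np.random.default_rng(0)
        a = rng.normal(5, 1, size=(50, 3))
        m = two_group_matrix(a, a.copy())
        res = fit_moderated_t(m, ContrastSpec(GROUP_A, GROUP_B))
        assert np.allclose(res.table["log2fc"], 0)
        assert np.allclose(res.table["t"], 0)
        assert np.allclose(res.table["p"], 1)

    def test_identical_variances_yield_infinite_prior_df(self):
        # every gene has the same pooled variance v -> the log-variance
        # spread is zero, the moment equations imply d0 = inf, and the
        # moderated t equals the pooled t computed with v
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, size=(40, 1))
        a = base + np.array([[0.0, 1.0, 2.0]])  # identical spread per gene
        b = a + 1.0
        m = two_group_matrix(a, b)
        res = fit_moderated_t(m, ContrastSpec(GROUP_A, GROUP_B))
        assert np.isinf(res.d0)
        v = res.table["s2"].iloc[0]
        assert np.allclose(res.table["s2"], v)
        expected_t = 1.0 / np.sqrt(v * (1 / 3 + 1 / 3))
        assert np.allclose(res.table["t"], expected_t)

    def test_hyperparameter_recovery_and_oracle_agreement(self):
        # planted d0=4, s0_sq=0.04, n=3+3; recovery within +/-50% / +/-25%
        # (median over 50 seeds) and exact agreement with the independent
        # moment-equation solve on every draw
        d0_true, s0_true, n = 4.0, 0.04, 3
        d0_est, s0_est = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=200)
            a = rng.normal(0, np.sqrt(sigma2)[:, None], size=(200, n))
            b = rng.normal(0, np.sqrt(sigma2)[:, None], size=(200, n))
            m = two_group_matrix(a, b)
            res = fit_moderated_t(m, ContrastSpec(GROUP_A, GROUP_B))
            d0_o, s0_o = oracle_hyperparameters(res.table["s2"].to_numpy(), res.d)
            assert res.d0 == pytest.approx(d0_o, abs=1e-9, rel=1e-9)
            assert res.s0_sq == pytest.approx(s0_o, abs=1e-9, rel=1e-9)
            d0_est.append(res.d0)
            s0_est.append(res.s0_sq)
        assert abs(np.median(d0_est) - d0_true) <= 0.5 * d0_true
        assert abs(np.median(s0_est) - s0_true) <= 0.25 * s0_true

    def test_matches_limma_fitfdist(self, tmp_path):
        """Hyperparameters agree with Bioconductor limma's F-distribution
        fit on the same gene-wise variances."""
        rng = np.random.default_rng(11)
        sigma2 = 4 * 0.04 / rng.chisquare(4, size=300)
        a = rng.normal(0, np.sqrt(sigma2)[:, None], size=(300, 3))
        b = rng.normal(0, np.sqrt(sigma2)[:, None], size=(300, 3))
        m = two_group_matrix(a, b)
        res = fit_moderated_t(m, ContrastSpec(GROUP_A, GROUP_B))
        s2_path = tmp_path / "s2.txt"
        np.savetxt(s2_path, res.table["s2"].to_numpy())
        script = (
            f's2 <- scan("{s2_path}"); '
            f"fit <- limma::fitFDist(s2, df1={res.d}); "
            'cat(sprintf("%.10g %.10g", fit$df2, fit$scale))'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        d0_limma, s0_limma = map(float, out.stdout.split())
        assert res.d0 == pytest.approx(d0_limma, rel=1e-4)
        assert res.s0_sq == pytest.approx(s0_limma, rel=1e-4)

    def test_zero_variance_everywhere_falls_back_with_warning(self):
        a = np.tile([[1.0]], (5, 2))
        b = np.tile([[3.0]], (5, 2))
        m = two_group_matrix(a, b)
        with pytest.warns(RuntimeWarning, match="zero"):
            res = fit_moderated_t(m, ContrastSpec(GROUP_A, GROUP_B))
        assert np.isinf(res.d0)
        assert np.all(np.isinf(res.table["t"]))
        assert np.allclose(res.table["p"], 0)

    def test_moderation_interpolates_between_gene_and_prior_variance(self):
        rng = np.random.default_rng(3)
        sigma2 = 4 * 0.04 / rng.chisquare(4, size=300)
        a = rng.normal(0, np.sqrt(sigma2)[:, None], size=(300, 3))
        b = rng.normal(1, np.sqrt(sigma2)[:, None], size=(300, 3))
        m = two_group_matrix(a, b)
        res = fit_moderated_t(m, ContrastSpec(GROUP_A, GROUP_B))
        s2 = res.table["s2"].to_numpy()
        s_tilde_sq = (res.d0 * res.s0_sq + res.d * s2) / (res.d0 + res.d)
        lo = np.minimum(s2, res.s0_sq) - 1e-12
        hi = np.maximum(s2, res.s0_sq) + 1e-12
        assert np.all((s_tilde_sq >= lo) & (s_tilde_sq <= hi))

    def test_too_small_group_rejected(self):
        m = two_group_matrix(np.ones((3, 1)), np.ones((3, 3)))
        with pytest.raises(ValueError, match=">= 2 samples"):
            fit_moderated_t(m, ContrastSpec(GROUP_A, GROUP_B))


def _result_from_rows(rows):
    table = pd.DataFrame(rows, columns=["log2fc", "s2", "t", "p"],
                         index=[f"g{i}" for i in range(len(rows))])
    return ContrastResult(table=table, d0=4.0, s0_sq=0.04, d=4, n_a=3, n_b=3)


class TestSelectDeGenes:
    def test_boundary_fold_change_excluded(self):
        # fold change must be STRICTLY greater than the cut
        res = _result_from_rows([[1.0, 0.01, 10.0, 1e-6]])
        assert len(select_de_genes(res, fc_fold=2, p_max=0.01, direction="up")) == 0

    def test_included_above_cut(self):
        res = _result_from_rows([[2.5, 0.01, 10.0, 1e-3]])  # 2^2.5 > 4
        sel = select_de_genes(res, fc_fold=4, p_max=0.01, direction="up")
        assert sel.members == {"g0"}

    def test_direction_down(self):
        res = _result_from_rows([[-2.0, 0.01, -10.0, 1e-3], [2.0, 0.01, 10.0, 1e-3]])
        sel = select_de_genes(res, fc_fold=2, p_max=0.01, direction="down")
        assert sel.members == {"g0"}

    def test_unknown_direction_rejected(self):
        res = _result_from_rows([[2.0, 0.01, 10.0, 1e-3]])
        with pytest.raises(ValueError, match="direction"):
            select_de_genes(res, direction="sideways")

    @given(
        st.lists(
            st.tuples(
                st.floats(-4, 4, allow_nan=False),
                st.floats(1e-12, 1.0, allow_nan=False),
            ),
            min_size=1, max_size=30,
        )
    )
    def test_monotone_in_both_thresholds(self, rows):
        res = _result_from_rows([[fc, 0.01, 0.0, p] for fc, p in rows])
        loose = select_de_genes(res, fc_fold=2, p_max=0.05, direction="up").members
        tight_fc = select_de_genes(res, fc_fold=4, p_max=0.05, direction="up").members
        tight_p = select_de_genes(res, fc_fold=2, p_max=0.001, direction="up").members
        assert tight_fc <= loose
        assert tight_p <= loose
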