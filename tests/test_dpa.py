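"""Moderated differential abundance: formula oracles, BH, enrichment."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stratomics.dpa import (bh_adjust, build_design, directional_enrichment,
                            fit_moderated, log_cpm, ora_hypergeometric, squeeze_var)
from stratomics.layers import GeneSetCollection, LayerKind, OmicsLayer, SampleTable


def make_layer(values):
    n, p = values.shape
    return OmicsLayer(LayerKind.PROTEOMICS, [f"s{i}" for i in range(n)],
                      [f"f{j}" for j in range(p)], values)


def two_group_design(n0, n1):
    ids = [f"s{i}" for i in range(n0 + n1)]
    st = SampleTable(ids, None, pd.DataFrame(index=ids))
    return build_design(st, np.array([0] * n0 + [1] * n1))


class TestDesign:
    def test_rank_deficient_names_aliased(self):
        ids = [f"s{i}" for i in range(8)]
        cov = pd.DataFrame({"a": [1.0] * 8}, index=ids)  # aliased with intercept
        st = SampleTable(ids, None, cov)
        with pytest.raises(ValueError, match="aliased"):
            build_design(st, [0, 0, 0, 0, 1, 1, 1, 1], covariates=["a"])

    def test_ordinal_and_reference_coding(self):
        ids = [f"s{i}" for i in range(6)]
        cov = pd.DataFrame({"fruit_intake": ["lt1_month", "gt1_week", "gt1_day",
                                             "gt1_day", "gt1_week", "lt1_month"],
                            "smoking": ["never", "ex", "current",
                                        "never", "current", "ex"]}, index=ids)
        st = SampleTable(ids, None, cov)
        d = build_design(st, [0, 0, 0, 1, 1, 1],
                         covariates=["fruit_intake", "smoking"])
        assert list(d.matrix["fruit_intake"]) == [0.0, 1.0, 2.0, 2.0, 1.0, 0.0]
        # 3-level categorical -> 2 indicators, first observed level reference
        assert sum(c.startswith("smoking[") for c in d.matrix.columns) == 2


class TestModeratedFit:
    def test_identical_groups_null_feature(self, rng):
        vals = rng.standard_normal((20, 5))
        vals[:, 0] = np.tile(np.arange(10.0), 2)[:20]
        vals[10:, 0] = vals[:10, 0]  # identical in both groups
        fit = fit_moderated(make_layer(vals), two_group_design(10, 10))
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.p[0] == pytest.approx(1.0)

    def test_d0_zero_equals_ordinary_t(self, rng):
        vals = rng.standard_normal((30, 40)) * rng.uniform(0.5, 2.0, size=40)
        vals[15:] += 0.4
        fit = fit_moderated(make_layer(vals), two_group_design(15, 15), d0_override=0)
        t_ref, p_ref = stats.ttest_ind(vals[15:], vals[:15], equal_var=True)
        np.testing.assert_allclose(fit.t, t_ref, atol=1e-10)
        np.testing.assert_allclose(fit.p, p_ref, atol=1e-10)

    def test_hand_computed_shrinkage_fixture(self, rng):
        # 5 features with distinct variances; replicate OLS + squeeze by hand
        n0 = n1 = 12
        scales = np.array([0.3, 0.7, 1.0, 1.8, 3.0])
        vals = rng.standard_normal((n0 + n1, 5)) * scales
        vals[n1:] += 0.5
        fit = fit_moderated(make_layer(vals), two_group_design(n0, n1))
        x, y = vals[:n0], vals[n0:]
        coef = y.mean(0) - x.mean(0)
        d = n0 + n1 - 2
        s2 = ((x - x.mean(0)) ** 2).sum(0) + ((y - y.mean(0)) ** 2).sum(0)
        s2 /= d
        d0, s0_2 = squeeze_var(s2, d)
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        u = 1 / n0 + 1 / n1
        t_manual = coef / np.sqrt(u * s2_post)
        np.testing.assert_allclose(fit.coef, coef, atol=1e-8)
        np.testing.assert_allclose(fit.t, t_manual, atol=1e-8)

    def test_moderated_converges_to_ordinary_with_equal_variances(self, rng):
        vals = rng.standard_normal((200, 60))
        fit = fit_moderated(make_layer(vals), two_group_design(100, 100))
        t_ref, _ = stats.ttest_ind(vals[100:], vals[:100], equal_var=True)
        assert np.max(np.abs(fit.t - t_ref)) < 0.3

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_bioconductor_limma(self, tmp_path, rng):
        # independent oracle: the reference empirical-Bayes implementation
        n0 = n1 = 10
        vals = rng.standard_normal((n0 + n1, 30)) * rng.uniform(0.4, 2.5, size=30)
        vals[n1:, :5] += 1.0
        mat = pd.DataFrame(vals.T, columns=[f"s{i}" for i in range(n0 + n1)])
        mat.to_csv(tmp_path / "expr.csv")
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            x <- as.matrix(read.csv('%s/expr.csv', row.names=1))
            group <- c(rep(0, %d), rep(1, %d))
            design <- cbind(1, group)
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[, 2], p=fit$p.value[, 2],
                              d0=fit$df.prior, s0=fit$s2.prior)
            write.csv(out, '%s/limma.csv')
        """ % (tmp_path, n0, n1, tmp_path))
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        fit = fit_moderated(make_layer(vals), two_group_design(n0, n1))
        np.testing.assert_allclose(fit.t, ref["t"].to_numpy(), rtol=1e-4)
        np.testing.assert_allclose(fit.p, ref["p"].to_numpy(), rtol=1e-4)
        assert fit.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-3)
        assert fit.s0_2 == pytest.approx(float(ref["s0"].iloc[0]), rel=1e-3)


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_with_warning(self):
        with pytest.warns(UserWarning, match="NaN"):
            out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[0])

    def test_matches_brute_force_step_up(self, rng):
        for _ in range(10):
            p = rng.random(25)
            got = bh_adjust(p)
            m = len(p)
            order = np.argsort(p)
            manual = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                manual[i] = running
            np.testing.assert_allclose(got, manual, atol=1e-12)


class TestORA:
    def test_query_equals_universe(self):
        sets = GeneSetCollection({"s": [f"g{i}" for i in range(5)]})
        uni = [f"g{i}" for i in range(5)]
        res = ora_hypergeometric(uni, sets, uni)
        assert res[0].p == pytest.approx(1.0)

    def test_full_overlap_enumeration(self):
        from math import comb
        uni = [f"g{i}" for i in range(20)]
        sets = GeneSetCollection({"s": uni[:5]})
        res = ora_hypergeometric(uni[:5], sets, uni)
        assert res[0].p == pytest.approx(1 / comb(20, 5), rel=1e-9)
        assert res[0].overlap == 5

    def test_zero_overlap_near_one(self):
        uni = [f"g{i}" for i in range(50)]
        sets = GeneSetCollection({"s": uni[:3]})
        res = ora_hypergeometric(uni[40:45], sets, uni)
        assert res[0].p > 0.7

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            ora_hypergeometric([], GeneSetCollection({"s": ["a"]}), [])


class TestDirectionalEnrichment:
    def test_zero_statistics_not_significant(self, rng):
        feats = {f"g{i}": 0.0 for i in range(20)}
        feats.update({f"n{i}": float(rng.standard_normal()) for i in range(80)})
        sets = GeneSetCollection({"zeros": [f"g{i}" for i in range(20)]})
        res = directional_enrichment(feats, sets, n_perm=200, seed=0)
        assert res[0].p >= 0.99 * (1 / 201)
        assert res[0].direction == "none" or abs(res[0].stat) < 1e-12

    def test_planted_upward_shift_detected(self, rng):
        feats = {f"n{i}": float(rng.standard_normal()) for i in range(200)}
        feats.update({f"g{i}": float(2.0 + 0.3 * rng.standard_normal())
                      for i in range(15)})
        sets = GeneSetCollection({"planted": [f"g{i}" for i in range(15)]})
        res = directional_enrichment(feats, sets, n_perm=1000, seed=1)
        assert res[0].p <= 0.01
        assert res[0].direction == "up"

    def test_p_bounds_and_missing_set_skipped(self, rng):
        feats = {f"g{i}": float(rng.standard_normal()) for i in range(30)}
        sets = GeneSetCollection({"some": ["g0", "g1"], "absent": ["zz1", "zz2"]})
        with pytest.warns(UserWarning, match="absent"):
            res = directional_enrichment(feats, sets, n_perm=100, seed=2)
        assert len(res) == 1
        assert 1 / 101 <= res[0].p <= 1.0


class TestLogCPM:
    def test_row_scaling_invariance(self, rng):
        counts = rng.poisson(50, size=(6, 30)).astype(float)
        layer = OmicsLayer(LayerKind.TRANSCRIPTOMICS,
                           [f"s{i}" for i in range(6)],
                           [f"t{j}" for j in range(30)], counts)
        doubled = OmicsLayer(LayerKind.TRANSCRIPTOMICS, layer.sample_ids,
                             layer.feature_ids, counts * 2)
        a = log_cpm(layer).values
        b = log_cpm(doubled).values
        # doubling the library size leaves log-CPM nearly unchanged
        assert np.max(np.abs(a - b)) < 0.05
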