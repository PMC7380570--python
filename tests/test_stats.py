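"""Stability interaction tests, BH/Bonferroni adjustment, the moderated t
statistic (including an R/limma cross-check), and the rank tests."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rifdecay import (
    DecaySeries,
    adjust_pvalues,
    call_differential,
    dunn_posthoc,
    kruskal_wallis,
    moderated_t_test,
    stability_interaction_test,
)
from rifdecay.kinetics import fit_exponential_decay
from rifdecay.stats import call_stability, stability_interaction_matrix

LN2 = np.log(2.0)


def _pair(seed=0, k_a=0.2, k_b=0.1, noise=0.05, n=12):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 11, n)
    ya = 5.0 - k_a * t + rng.normal(0, noise, n)
    yb = 5.3 - k_b * t + rng.normal(0, noise, n)
    return (
        DecaySeries("g", "A", t, ya),
        DecaySeries("g", "B", t, yb),
    )


class TestStabilityInteraction:
    def test_identical_series_give_zero_interaction(self):
        a, _ = _pair()
        b = DecaySeries("g", "B", a.times_min, a.ln_intensity)
        log2fc, p = stability_interaction_test(a, b)
        assert log2fc == 0.0
        assert p == 1.0

    def test_swapping_conditions_negates_fold_change(self):
        a, b = _pair(seed=3)
        fc_ab, p_ab = stability_interaction_test(a, b)
        fc_ba, p_ba = stability_interaction_test(b, a)
        assert fc_ba == pytest.approx(-fc_ab, rel=1e-12)
        assert p_ba == pytest.approx(p_ab, rel=1e-12)

    def test_clear_twofold_change_detected(self):
        a, b = _pair(seed=1, k_a=LN2 / 3, k_b=LN2 / 6, noise=0.05)
        log2fc, p = stability_interaction_test(a, b)
        assert log2fc == pytest.approx(1.0, abs=0.25)
        assert p < 1e-4

    def test_per_condition_slopes_equal_separate_fits(self):
        # separate intercepts per condition make the interaction model's
        # slopes identical to independent per-condition regressions
        a, b = _pair(seed=7)
        mat_a = pd.DataFrame([a.ln_intensity], index=["g"])
        mat_b = pd.DataFrame([b.ln_intensity], index=["g"])
        res = stability_interaction_matrix(mat_a, a.times_min, mat_b, b.times_min)
        assert res.loc["g", "slope_a"] == pytest.approx(
            -fit_exponential_decay(a).k_per_min, rel=1e-12
        )
        assert res.loc["g", "slope_b"] == pytest.approx(
            -fit_exponential_decay(b).k_per_min, rel=1e-12
        )

    def test_matrix_path_matches_scalar_path(self):
        a, b = _pair(seed=11)
        mat_a = pd.DataFrame([a.ln_intensity], index=["g"])
        mat_b = pd.DataFrame([b.ln_intensity], index=["g"])
        res = stability_interaction_matrix(mat_a, a.times_min, mat_b, b.times_min)
        log2fc, p = stability_interaction_test(a, b)
        assert res.loc["g", "log2_fc_halflife"] == pytest.approx(log2fc, rel=1e-10)
        assert res.loc["g", "p_value"] == pytest.approx(p, rel=1e-10)

    def test_call_stability_thresholds(self):
        table = pd.DataFrame(
            {
                "log2_fc_halflife": [1.2, -0.8, 0.9, 0.4],
                "p_value": [0.001, 0.002, 0.5, 0.04],
            },
            index=list("abcd"),
        )
        out = call_stability(table, alpha=0.1, method="BH")
        assert out.loc["a", "status"] == "stabilized"
        assert out.loc["b", "status"] == "destabilized"
        assert out.loc["c", "status"] == "unchanged"


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        for method in ("BH", "bonferroni"):
            np.testing.assert_allclose(adjust_pvalues([0.03], method), [0.03])

    def test_bh_step_up_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "BH"), [0.03, 0.03, 0.03]
        )

    def test_bonferroni_caps_at_one(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.5], "bonferroni"), [0.02, 1.0]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])

    def test_bh_matches_brute_force_step_up_on_random_vectors(self):
        # oracle: literal step-up — sort, p*(m/rank), cumulative min from
        # the largest, cap at 1
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            adj = adjust_pvalues(p, "BH")
            order = np.argsort(p)
            m = p.size
            stepped = p[order] * m / np.arange(1, m + 1)
            stepped = np.minimum.accumulate(stepped[::-1])[::-1]
            brute = np.empty(m)
            brute[order] = np.minimum(stepped, 1.0)
            np.testing.assert_allclose(adj, brute, rtol=1e-12)
            assert (adj >= p - 1e-15).all()


class TestModeratedT:
    def test_equal_groups_give_null_result(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(50, 3))
        res = moderated_t_test(a, a.copy())
        gene0 = res.iloc[0]
        assert gene0["log2_fc"] == 0.0
        assert gene0["t_statistic"] == 0.0
        assert gene0["p_value"] == 1.0

    def test_d0_zero_equals_ordinary_pooled_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(40, 4))
        b = rng.normal(0.5, 1, size=(40, 4))
        res = moderated_t_test(a, b, d0=0.0)
        t_ref, p_ref = sps.ttest_ind(b, a, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_statistic"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(res["p_value"], p_ref, rtol=1e-10)

    def test_converges_to_ordinary_t_with_many_replicates(self):
        # equal true variances: moderation has nothing to shrink, and with
        # many replicates the two tests agree closely
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=(2000, 30))
        b = rng.normal(0, 1, size=(2000, 30))
        res = moderated_t_test(a, b)
        _, p_ref = sps.ttest_ind(b, a, axis=1, equal_var=True)
        rel = np.abs(res["p_value"].to_numpy() - p_ref) / p_ref
        assert np.median(rel) < 0.05

    def test_null_type_one_error_calibrated(self):
        fractions = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, size=(2000, 3))
            b = rng.normal(0, 1, size=(2000, 3))
            res = moderated_t_test(a, b)
            fractions.append((res["p_value"] < 0.05).mean())
        assert 0.035 <= np.mean(fractions) <= 0.065

    def test_matches_r_limma_on_shared_fixture(self, tmp_path):
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript unavailable"
        rng = np.random.default_rng(7)
        n = 200
        sd = rng.uniform(0.2, 1.0, n)
        a = rng.normal(0, sd[:, None], (n, 3))
        b = rng.normal(0.3, sd[:, None], (n, 3))
        mat = np.hstack([a, b])
        data = pd.DataFrame(mat, columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        data.to_csv(tmp_path / "mat.tsv", sep="\t", index=False)
        script = tmp_path / "limma_check.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim(commandArgs(TRUE)[1]))
            design <- cbind(Intercept=1, B=c(0,0,0,1,1,1))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[, "B"], p=fit$p.value[, "B"],
                              d0=fit$df.prior, s0=fit$s2.prior)
            write.table(out, commandArgs(TRUE)[2], sep="\t", row.names=FALSE)
            """
        )
        out_path = tmp_path / "limma_out.tsv"
        subprocess.run(
            [rscript, str(script), str(tmp_path / "mat.tsv"), str(out_path)],
            check=True,
            capture_output=True,
        )
        ref = pd.read_csv(out_path, sep="\t")
        res = moderated_t_test(a, b)
        assert res.attrs["d0"] == pytest.approx(ref["d0"][0], rel=1e-4)
        assert res.attrs["s0_squared"] == pytest.approx(ref["s0"][0], rel=1e-4)
        np.testing.assert_allclose(res["t_statistic"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(res["p_value"], ref["p"], rtol=1e-6)


class TestCallDifferential:
    @pytest.mark.parametrize(
        "adj_p,fc,expected",
        [
            (0.005, 1.5, "up"),
            (0.005, 0.9, "none"),  # fold change below the cutoff
            (0.02, 3.0, "none"),  # p above alpha
            (0.005, -1.5, "down"),
        ],
    )
    def test_threshold_rules(self, adj_p, fc, expected):
        table = pd.DataFrame({"log2_fc": [fc], "adj_p_value": [adj_p]})
        out = call_differential(table, alpha=0.01, lfc=1.0)
        assert out["status"].iloc[0] == expected


class TestRankTests:
    def test_identical_groups_yield_null(self):
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_constant_data_defined_as_null(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert (h, p) == (0.0, 1.0)

    def test_matches_hand_ranked_h(self):
        groups = [[1.0, 2.0, 3.0], [10.0, 11.0, 12.0], [20.0, 21.0, 22.0]]
        h, p = kruskal_wallis(groups)
        # brute force: joint ranks, H = 12/(N(N+1)) * sum n_i rbar_i^2 - 3(N+1)
        flat = np.concatenate(groups)
        ranks = sps.rankdata(flat)
        n = flat.size
        rbars = [ranks[i * 3 : (i + 1) * 3].mean() for i in range(3)]
        h_brute = 12.0 / (n * (n + 1)) * sum(3 * r**2 for r in rbars) - 3 * (n + 1)
        assert h == pytest.approx(h_brute, rel=1e-12)
        assert p == pytest.approx(sps.chi2.sf(h_brute, 2), rel=1e-12)

    def test_two_groups_consistent_with_rank_sum(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.8, 1, 40)
        _, p_kw = kruskal_wallis([a, b])
        p_rs = sps.ranksums(a, b).pvalue
        assert p_kw == pytest.approx(p_rs, rel=0.10)

    def test_dunn_identical_groups_all_null(self):
        g = [1.0, 2.0, 3.0, 4.0]
        out = dunn_posthoc([g, list(g), list(g)])
        np.testing.assert_allclose(out.to_numpy(), 1.0)

    def test_dunn_matrix_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 30) for m in (0, 1, 2, 3)]
        out = dunn_posthoc(groups)
        np.testing.assert_allclose(out.to_numpy(), out.to_numpy().T)
        np.testing.assert_allclose(np.diag(out.to_numpy()), 1.0)

    def test_dunn_separates_shifted_lognormal_groups(self):
        # half-life-like distributions with the three phase medians
        for seed in range(10):
            rng = np.random.default_rng(seed)
            groups = [
                np.exp(rng.normal(np.log(m), 0.5, 200)) for m in (3.1, 6.3, 9.5)
            ]
            out = dunn_posthoc(groups)
            off = out.to_numpy()[~np.eye(3, dtype=bool)]
            assert (off < 0.05).all()

    def test_dunn_z_matches_brute_force_formula(self):
        rng = np.random.default_rng(8)
        groups = [rng.integers(0, 6, size=n).astype(float) for n in (9, 14, 11)]
        out = dunn_posthoc(groups, adjust="bonferroni")
        # brute force with explicit tie bookkeeping
        flat = np.concatenate(groups)
        ranks = sps.rankdata(flat)
        n = flat.size
        _, counts = np.unique(flat, return_counts=True)
        ties = (counts**3 - counts).sum() / (12.0 * (n - 1))
        splits = np.split(ranks, np.cumsum([len(g) for g in groups])[:-1])
        raw = {}
        for i in range(3):
            for j in range(i + 1, 3):
                var = (n * (n + 1) / 12.0 - ties) * (
                    1.0 / len(groups[i]) + 1.0 / len(groups[j])
                )
                z = (splits[i].mean() - splits[j].mean()) / np.sqrt(var)
                raw[(i, j)] = 2 * sps.norm.sf(abs(z))
        for (i, j), p in raw.items():
            assert out.iloc[i, j] == pytest.approx(min(1.0, 3 * p), rel=1e-12)
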