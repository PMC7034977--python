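import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sexdim import diffexpr, synthetic_data as sd
from sexdim.data import CountStudy, cpm

from conftest import make_null_de_study


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def bh_stepup_oracle(p):
    """Textbook Benjamini-Hochberg step-up, written longhand."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def tmm_oracle(counts, ref_idx, trim_m=0.30, trim_a=0.05):
    """Literal trim-then-weighted-mean TMM transliteration (per-sample loop)."""
    y = np.asarray(counts, dtype=float)
    lib = y.sum(axis=0)
    logf = np.zeros(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref_idx:
            continue
        keep = (y[:, j] > 0) & (y[:, ref_idx] > 0)
        fs = y[keep, j] / lib[j]
        fr = y[keep, ref_idx] / lib[ref_idx]
        M = np.log2(fs / fr)
        A = 0.5 * np.log2(fs * fr)
        n = M.size
        rm = stats.rankdata(M)
        ra = stats.rankdata(A)
        lo_m, lo_a = np.floor(n * trim_m) + 1, np.floor(n * trim_a) + 1
        sel = (
            (rm >= lo_m)
            & (rm <= n + 1 - lo_m)
            & (ra >= lo_a)
            & (ra <= n + 1 - lo_a)
        )
        w = 1.0 / (
            (lib[j] - y[keep, j]) / (lib[j] * y[keep, j])
            + (lib[ref_idx] - y[keep, ref_idx]) / (lib[ref_idx] * y[keep, ref_idx])
        )
        logf[j] = np.sum(w[sel] * M[sel]) / np.sum(w[sel])
    f = 2.0**logf
    return f / np.exp(np.mean(np.log(f)))


def poisson_lrt_oracle(y_a, y_b, s_a, s_b):
    """Closed-form Poisson LRT for merging two groups with offsets."""
    ta, tb = y_a.sum(), y_b.sum()
    sa, sb = s_a.sum(), s_b.sum()

    def term(t, s):
        return t * np.log(t / s) if t > 0 else 0.0

    return 2.0 * (term(ta, sa) + term(tb, sb) - term(ta + tb, sa + sb))


# ---------------------------------------------------------------------------
# CPM filter
# ---------------------------------------------------------------------------


class TestCpmFilter:
    def test_gene_with_a_zero_sample_removed(self):
        counts = pd.DataFrame(
            {"s1": [1, 1], "s2": [0, 1]}, index=["gA", "gB"], dtype=float
        )
        lib = pd.Series([1e6, 1e6], index=["s1", "s2"])
        kept = diffexpr.cpm_filter(counts, 0.1, lib)
        assert list(kept) == ["gB"]

    def test_empty_result_fails(self):
        counts = pd.DataFrame({"s1": [0.0, 0.0], "s2": [1e4, 1e4]}, index=["a", "b"])
        with pytest.raises(ValueError):
            diffexpr.cpm_filter(counts, threshold=1e9)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(40, 6)).astype(float),
            index=[f"g{i}" for i in range(40)],
        )
        kept = set(diffexpr.cpm_filter(counts, 0.1))
        lib = counts.sum(axis=0)
        expected = {
            g
            for g in counts.index
            if all(counts.loc[g, s] / lib[s] * 1e6 > 0.1 for s in counts.columns)
        }
        assert kept == expected


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30.0], "b": [10, 20, 30.0]})
        np.testing.assert_allclose(diffexpr.tmm_factors(counts), 1.0)

    def test_global_doubling_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        a = rng.integers(10, 1000, 50).astype(float)
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        np.testing.assert_allclose(diffexpr.tmm_factors(counts), 1.0, atol=1e-12)

    def test_matches_literal_oracle_on_toys(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            counts = pd.DataFrame(
                rng.integers(1, 500, size=(20, 4)).astype(float),
                columns=list("abcd"),
            )
            mine = diffexpr.tmm_factors(counts)
            p75 = np.percentile(counts / counts.sum(axis=0) * 1e6, 75, axis=0)
            ref = int(np.argmin(np.abs(p75 - p75.mean())))
            np.testing.assert_allclose(mine, tmm_oracle(counts, ref), atol=1e-10)

    def test_factors_multiply_to_one_and_permute(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.01, size=(100, 5)).astype(float),
            columns=list("abcde"),
        )
        f = diffexpr.tmm_factors(counts)
        assert np.prod(f) == pytest.approx(1.0)
        perm = ["c", "a", "e", "b", "d"]
        f2 = diffexpr.tmm_factors(counts[perm])
        np.testing.assert_allclose(f2[perm].to_numpy(), f[perm].to_numpy(), rtol=1e-12)

    def test_zero_library_fails(self):
        counts = pd.DataFrame({"a": [0.0, 0.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="a"):
            diffexpr.tmm_factors(counts)


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------


class TestBhFdr:
    def test_hand_computed_stepup(self):
        q = diffexpr.bh_fdr(pd.Series([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        q = diffexpr.bh_fdr(pd.Series([1.0, 1.0, 1.0]))
        np.testing.assert_allclose(q, 1.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_textbook_oracle(self, p):
        q = diffexpr.bh_fdr(pd.Series(p))
        np.testing.assert_allclose(q, bh_stepup_oracle(p), atol=1e-12)

    def test_nan_passthrough_and_monotone(self):
        p = pd.Series([0.5, np.nan, 0.001, 0.2])
        q = diffexpr.bh_fdr(p)
        assert np.isnan(q.iloc[1])
        valid = q.dropna()
        assert (valid >= p.dropna() - 1e-15).all()


# ---------------------------------------------------------------------------
# NB group model + LRT
# ---------------------------------------------------------------------------


class TestGroupModel:
    def test_poisson_limit_matches_closed_form(self):
        """With dispersion -> 0 the NB LRT reduces to the Poisson deviance."""
        rng = np.random.default_rng(11)
        study = make_null_de_study(seed=11, n_genes=30, reps=4)
        fit = diffexpr.fit_group_model(study, dispersion=1e-13)
        res = diffexpr.contrast_test(fit, "female_evolution")
        labels = study.design["group"] + ":" + study.design["sex"]
        cols_a = labels == "ancestral:F"
        cols_b = labels == "evolved:F"
        s = fit.offsets
        for i, g in enumerate(study.genes):
            y = study.counts.loc[g].to_numpy()
            expected = poisson_lrt_oracle(
                y[cols_a.to_numpy()], y[cols_b.to_numpy()],
                s[cols_a.to_numpy()], s[cols_b.to_numpy()],
            )
            assert res["lr"].loc[g] == pytest.approx(expected, abs=1e-6)

    def test_null_pvalues_calibrated(self):
        """No group effect: raw p approximately uniform; rejection rate at
        p<0.05 within the 99% binomial interval around 0.05 (2000 genes)."""
        study = make_null_de_study(seed=1)
        fit = diffexpr.fit_group_model(study)
        res = diffexpr.contrast_test(fit, "female_evolution")
        p = res["p"].dropna()
        assert len(p) > 1900
        rate = (p < 0.05).mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / len(p))
        assert abs(rate - 0.05) < half
        # coarse uniformity across the unit interval
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.05

    def test_lfc_recovery_at_high_counts(self):
        """True |log2 FC| = 1 at high expression is recovered within 0.2."""
        rng = np.random.default_rng(5)
        reps, G = 6, 200
        rows = []
        for grp in ("ancestral", "evolved"):
            for sex in ("F", "M"):
                for r in range(reps):
                    rows.append(
                        {"sample": f"{grp}_{sex}_{r}", "sex": sex, "group": grp,
                         "tissue": "whole", "replicate": f"r{r}"}
                    )
        design = pd.DataFrame(rows).set_index("sample")
        base = np.full(G, 500.0)
        mu = np.tile(base[:, None], (1, len(design)))
        evolved_f = ((design["group"] == "evolved") & (design["sex"] == "F")).to_numpy()
        signs = rng.choice([-1.0, 1.0], G)
        mu[:, evolved_f] *= 2.0 ** signs[:, None]
        y = rng.negative_binomial(1 / 0.02, (1 / 0.02) / (1 / 0.02 + mu)).astype(float)
        counts = pd.DataFrame(y, index=[f"g{i}" for i in range(G)], columns=design.index)
        study = CountStudy(counts, design)
        fit = diffexpr.fit_group_model(study)
        res = diffexpr.contrast_test(fit, "female_evolution")
        err = np.abs(res["lfc"].to_numpy() - signs)
        assert err.mean() < 0.2

    def test_pvalues_invariant_to_library_scaling(self):
        study = make_null_de_study(seed=3, n_genes=50, reps=3)
        base = study.library_sizes.to_numpy(float)
        fit1 = diffexpr.fit_group_model(study, dispersion=0.05, offsets=base)
        res1 = diffexpr.contrast_test(fit1, "male_evolution")
        # common scaling of all effective library sizes shifts eta, not the LRT
        fit2 = diffexpr.fit_group_model(study, dispersion=0.05, offsets=base * 7.5)
        res2 = diffexpr.contrast_test(fit2, "male_evolution")
        np.testing.assert_allclose(res1["lr"], res2["lr"], rtol=1e-6, atol=1e-8)

    def test_too_few_replicates_rejected(self):
        study = make_null_de_study(seed=4, n_genes=10, reps=1)
        with pytest.raises(ValueError):
            diffexpr.fit_group_model(study)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _contrast(q, lfc):
    idx = [f"g{i}" for i in range(len(q))]
    return pd.DataFrame({"q": q, "lfc": lfc}, index=idx)


class TestClassification:
    @pytest.mark.parametrize(
        "fq,flfc,mq,mlfc,expected",
        [
            (0.01, 1.0, 0.01, 2.0, "concordant_up"),
            (0.01, -1.0, 0.01, -2.0, "concordant_down"),
            (0.5, 1.0, 0.01, -1.0, "male_specific_down"),
            (0.5, 1.0, 0.01, 1.0, "male_specific_up"),
            (0.01, 1.0, 0.5, -1.0, "female_specific_up"),
            (0.01, -1.0, 0.01, 1.0, "antagonistic_Mup_Fdown"),
            (0.01, 1.0, 0.01, -1.0, "antagonistic_Mdown_Fup"),
            (0.5, 1.0, 0.5, 1.0, "unchanged"),
        ],
    )
    def test_rule_lattice(self, fq, flfc, mq, mlfc, expected):
        out = diffexpr.classify_genes(_contrast([fq], [flfc]), _contrast([mq], [mlfc]))
        assert out.iloc[0] == expected

    def test_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(6)
        n = 500
        f = _contrast(rng.random(n), rng.normal(size=n))
        m = _contrast(rng.random(n), rng.normal(size=n))
        out = diffexpr.classify_genes(f, m)
        assert out.isin(diffexpr.CATEGORIES).all()
        assert out.value_counts().sum() == n

    def test_gene_mismatch_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.classify_genes(_contrast([0.5], [1.0]), _contrast([0.5, 0.5], [1, 1]))


class TestSexBiasEvolution:
    @pytest.mark.parametrize(
        "aq,alfc,eq,elfc,expected",
        [
            (0.5, 0.1, 0.01, -1.0, "gained"),
            (0.01, 1.0, 0.5, 0.2, "lost"),
            (0.01, 1.0, 0.01, -1.0, "reversed"),
            (0.01, 1.0, 0.01, 2.0, "strengthened"),
            (0.01, 2.0, 0.01, 1.0, "weakened"),
            (0.5, 0.0, 0.5, 0.0, "unchanged"),
        ],
    )
    def test_call_lattice(self, aq, alfc, eq, elfc, expected):
        out = diffexpr.sex_bias_evolution(
            _contrast([aq], [alfc]), _contrast([eq], [elfc])
        )
        assert out["call"].iloc[0] == expected

    def test_null_mostly_unchanged(self):
        """Truly unbiased genes are called unchanged for ~95% at q=0.05."""
        study = make_null_de_study(seed=8)
        fit = diffexpr.fit_group_model(study)
        anc = diffexpr.contrast_test(fit, "sex_bias_ancestral")
        evo = diffexpr.contrast_test(fit, "sex_bias_evolved")
        calls = diffexpr.sex_bias_evolution(anc, evo)
        assert (calls["call"] == "unchanged").mean() > 0.9
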