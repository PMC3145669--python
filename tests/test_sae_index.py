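"""Normal ranges, I_SAE scoring, responder splits, stability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import saeindex as sx
from conftest import fast_config, toy_matrix


def make_signature(directions, probes=None, symbols=None):
    probes = probes or [f"p{i}" for i in range(len(directions))]
    symbols = symbols or [f"G{i}" for i in range(len(directions))]
    table = pd.DataFrame({
        "gene_symbol": symbols,
        "direction": directions,
        "fold_change": 2.0, "p": 0.001, "q": 0.005,
        "index_eligible": True,
    }, index=pd.Index(probes, name="probe_id"))
    return sx.SmokingSignature(table=table)


def isae_bruteforce(logv, directions, thresholds):
    """Double-loop reference implementation of the index."""
    n_genes, n_samples = logv.shape
    out = np.zeros(n_samples)
    for j in range(n_samples):
        count = 0
        for g in range(n_genes):
            if directions[g] == "up" and logv[g, j] > thresholds[g]:
                count += 1
            elif directions[g] == "down" and logv[g, j] < thresholds[g]:
                count += 1
        out[j] = 100.0 * count / n_genes
    return out


class TestFitNormalRanges:
    def test_up_threshold_two_sd_above_mean(self):
        # reference log2 values with mean 5, SD 0.5 -> threshold 6.0
        ref = 2.0 ** np.array([4.5, 5.0, 5.5, 4.5, 5.5, 5.0])
        sd = np.std([4.5, 5.0, 5.5, 4.5, 5.5, 5.0], ddof=1)
        m = toy_matrix([ref], normalized=True)
        ranges = sx.fit_normal_ranges(m, make_signature(["up"]), list(m.sample_ids))
        assert ranges.table["mean"].iloc[0] == pytest.approx(5.0)
        assert ranges.table["threshold"].iloc[0] == pytest.approx(5.0 + 2 * sd)

    def test_down_threshold_two_sd_below_mean(self):
        ref = 2.0 ** np.array([4.5, 5.0, 5.5, 4.5, 5.5, 5.0])
        sd = np.std([4.5, 5.0, 5.5, 4.5, 5.5, 5.0], ddof=1)
        m = toy_matrix([ref], normalized=True)
        ranges = sx.fit_normal_ranges(m, make_signature(["down"]), list(m.sample_ids))
        assert ranges.table["threshold"].iloc[0] == pytest.approx(5.0 - 2 * sd)

    def test_constant_gene_threshold_at_mean(self, caplog):
        m = toy_matrix([[8.0, 8.0, 8.0]], normalized=True)
        with caplog.at_level("WARNING", logger="saeindex"):
            ranges = sx.fit_normal_ranges(m, make_signature(["up"]),
                                          list(m.sample_ids))
        assert ranges.table["threshold"].iloc[0] == pytest.approx(3.0)  # log2(8)
        # any strictly higher value is abnormal
        q = toy_matrix([[8.0, 8.1]], normalized=True)
        idx = sx.compute_isae(q, ranges)
        assert idx.isae.tolist() == [0.0, 100.0]

    def test_single_reference_sample_rejected(self):
        m = toy_matrix([[8.0]], normalized=True)
        with pytest.raises(sx.AnalysisError, match=">= 2"):
            sx.fit_normal_ranges(m, make_signature(["up"]), list(m.sample_ids))


class TestComputeIsae:
    def test_all_in_range_gives_zero(self, rng):
        ref = 2.0 ** rng.normal(6, 0.5, size=(4, 10))
        m = toy_matrix(ref, normalized=True)
        ranges = sx.fit_normal_ranges(m, make_signature(["up"] * 4),
                                      list(m.sample_ids))
        mid = toy_matrix(2.0 ** np.full((4, 3), 6.0), normalized=True)
        assert (sx.compute_isae(mid, ranges).isae == 0).all()

    def test_three_abnormal_of_375_gives_point_eight(self, rng):
        n = 375
        ref = 2.0 ** rng.normal(6, 0.1, size=(n, 20))
        m = toy_matrix(ref, normalized=True)
        ranges = sx.fit_normal_ranges(m, make_signature(["up"] * n),
                                      list(m.sample_ids))
        query_vals = np.full((n, 1), 2.0 ** 6.0)
        query_vals[:3, 0] = 2.0 ** 12.0
        idx = sx.compute_isae(toy_matrix(query_vals, normalized=True), ranges)
        assert idx.isae.iloc[0] == pytest.approx(100 * 3 / 375)
        assert idx.abnormal_counts.iloc[0] == 3

    def test_missing_index_gene_error_lists_gene(self, rng):
        ref = 2.0 ** rng.normal(6, 0.5, size=(2, 5))
        m = toy_matrix(ref, normalized=True)
        ranges = sx.fit_normal_ranges(m, make_signature(["up", "down"]),
                                      list(m.sample_ids))
        other = toy_matrix([[1.0]], probes=["p0"], normalized=True)
        with pytest.raises(sx.AnalysisError, match="p1"):
            sx.compute_isae(other, ranges)

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(1, 20))
        n_ref, n_query = int(rng.integers(2, 10)), int(rng.integers(1, 8))
        directions = list(rng.choice(["up", "down"], size=n_genes))
        ref = rng.normal(6, 0.5, size=(n_genes, n_ref))
        query = rng.normal(6, 1.0, size=(n_genes, n_query))
        m = toy_matrix(2.0 ** ref, normalized=True)
        sig = make_signature(directions)
        ranges = sx.fit_normal_ranges(m, sig, list(m.sample_ids))
        q = toy_matrix(2.0 ** query, samples=[f"q{j}" for j in range(n_query)],
                       normalized=True)
        expected = isae_bruteforce(query, directions,
                                   ranges.table["threshold"].to_numpy())
        np.testing.assert_allclose(sx.compute_isae(q, ranges).isae, expected,
                                   atol=1e-12)

    def test_invariant_under_per_gene_rescaling(self, rng):
        # multiplying all samples' linear values of one gene by c shifts
        # mean, threshold and values by the same log2 constant
        ref = 2.0 ** rng.normal(6, 0.5, size=(5, 12))
        query = 2.0 ** rng.normal(6, 1.0, size=(5, 6))
        sig = make_signature(["up", "down", "up", "down", "up"])
        samples = [f"q{j}" for j in range(6)]

        def score(scale):
            m = toy_matrix(ref * scale[:, None], normalized=True)
            ranges = sx.fit_normal_ranges(m, sig, list(m.sample_ids))
            q = toy_matrix(query * scale[:, None], samples=samples, normalized=True)
            return sx.compute_isae(q, ranges).isae

        base = score(np.ones(5))
        scaled = score(np.array([1.0, 13.7, 0.2, 5.0, 1e3]))
        pd.testing.assert_series_equal(base, scaled)

    def test_monotone_in_smoking_direction(self, rng):
        ref = 2.0 ** rng.normal(6, 0.5, size=(2, 10))
        sig = make_signature(["up", "down"])
        m = toy_matrix(ref, normalized=True)
        ranges = sx.fit_normal_ranges(m, sig, list(m.sample_ids))
        grid = np.linspace(3, 9, 41)
        up_scores = [sx.compute_isae(
            toy_matrix([[2.0 ** v], [2.0 ** 6]], samples=["q"], normalized=True),
            ranges).isae.iloc[0] for v in grid]
        down_scores = [sx.compute_isae(
            toy_matrix([[2.0 ** 6], [2.0 ** v]], samples=["q"], normalized=True),
            ranges).isae.iloc[0] for v in grid]
        assert (np.diff(up_scores) >= 0).all()
        assert (np.diff(down_scores) <= 0).all()

    def test_suppression_on_up_gene_contributes_nothing(self, rng):
        # one-sided abnormality: an extreme LOW value on an up gene scores 0
        ref = 2.0 ** rng.normal(6, 0.5, size=(1, 10))
        ranges = sx.fit_normal_ranges(toy_matrix(ref, normalized=True),
                                      make_signature(["up"]),
                                      [f"s{j}" for j in range(10)])
        q = toy_matrix([[2.0 ** -5]], samples=["q"], normalized=True)
        assert sx.compute_isae(q, ranges).isae.iloc[0] == 0.0

    def test_in_sample_scores_below_out_of_sample(self):
        # fitting and scoring on the same reference shrinks exceedances
        in_means, out_means = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ref = rng.normal(6, 0.5, size=(30, 12))
            fresh = rng.normal(6, 0.5, size=(30, 12))
            sig = make_signature(list(rng.choice(["up", "down"], size=30)))
            m = toy_matrix(2.0 ** ref, normalized=True)
            ranges = sx.fit_normal_ranges(m, sig, list(m.sample_ids))
            q = toy_matrix(2.0 ** fresh, samples=[f"q{j}" for j in range(12)],
                           normalized=True)
            in_means.append(sx.compute_isae(m, ranges).isae.mean())
            out_means.append(sx.compute_isae(q, ranges).isae.mean())
        assert np.mean(in_means) <= np.mean(out_means)


class TestClassifyResponders:
    def test_median_split_even_count(self):
        isae = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        labels = sx.classify_responders(isae)
        assert labels.boundary == 2.5
        assert labels.samples("low") == ["a", "b"]
        assert labels.samples("high") == ["c", "d"]

    def test_value_at_median_is_low(self):
        isae = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        labels = sx.classify_responders(isae)
        assert labels.labels["b"] == "low"

    def test_quantile_rule_counts(self):
        isae = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        labels = sx.classify_responders(isae, rule="quantile", alpha=0.2)
        assert len(labels.samples("low")) == 2
        assert len(labels.samples("high")) == 2
        assert labels.labels.isna().sum() == 6
        assert labels.samples("high") == ["s8", "s9"]

    def test_identical_values_all_low_with_warning(self, caplog):
        isae = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        with caplog.at_level("WARNING", logger="saeindex"):
            labels = sx.classify_responders(isae)
        assert (labels.labels == "low").all()
        assert "identical" in caplog.text

    def test_bad_alpha_rejected(self):
        with pytest.raises(sx.AnalysisError):
            sx.classify_responders(pd.Series([1.0, 2.0]), rule="quantile",
                                   alpha=0.7)


class TestRangeMembership:
    def test_query_equal_reference_full_membership(self):
        ref = pd.Series([1.0, 5.0, 9.0])
        member, frac = sx.range_membership(ref, ref, mode="interval")
        assert frac == 1.0

    def test_query_below_reference_min(self):
        member, frac = sx.range_membership(pd.Series([0.1, 0.2]),
                                           pd.Series([1.0, 2.0]))
        assert frac == 0.0

    def test_at_least_min_counts_values_above_reference_max(self):
        _, interval = sx.range_membership(pd.Series([10.0]),
                                          pd.Series([1.0, 5.0]), mode="interval")
        _, atleast = sx.range_membership(pd.Series([10.0]),
                                         pd.Series([1.0, 5.0]))
        assert interval == 0.0 and atleast == 1.0

    def test_synthetic_copd_within_high_responder_range(self):
        fracs = []
        for seed in range(10):
            cfg = fast_config(seed=700 + seed)
            m, pheno, truth = sx.generate_cohort(cfg)
            mn = sx.normalize_per_chip(m)
            sig = sx.select_signature(mn, pheno, truth.annotation)
            ref = pheno.loc[pheno["group"] == "nonsmoker", "sample_id"].tolist()
            idx = sx.compute_isae(mn, sx.fit_normal_ranges(mn, sig, ref))
            smokers = pheno.loc[pheno["group"] == "healthy_smoker", "sample_id"]
            copd = pheno.loc[pheno["group"] == "copd", "sample_id"]
            labels = sx.classify_responders(idx.isae.loc[smokers])
            _, frac = sx.range_membership(idx.isae.loc[copd],
                                          idx.isae.loc[labels.samples("high")])
            fracs.append(frac)
        assert np.mean(fracs) >= 0.8


class TestStability:
    def _paired(self, t1_vals, t2_vals):
        subjects = [f"u{i}" for i in range(len(t1_vals))]
        isae_t1 = pd.Series(t1_vals, index=subjects, dtype=float)
        isae_t2 = pd.Series(t2_vals, index=subjects, dtype=float)
        labels = sx.classify_responders(isae_t1)
        labels = sx.ResponderLabels(labels=labels.labels, rule=labels.rule,
                                    boundary=labels.boundary)
        return isae_t1, isae_t2, labels

    def test_identical_timepoints_full_retention(self):
        t1, t2, labels = self._paired([1, 2, 30, 40], [1, 2, 30, 40])
        report = sx.stability_over_time(t1, t2, labels)
        assert report.retention == 1.0

    def test_unpaired_subject_excluded_with_warning(self, caplog):
        t1, t2, labels = self._paired([1, 2, 30, 40], [1, 2, 30, 40])
        with caplog.at_level("WARNING", logger="saeindex"):
            report = sx.stability_over_time(t1, t2.drop("u0"), labels)
        assert len(report.table) == 3
        assert "unpaired" in caplog.text

    def test_permuted_second_visit_retention_near_chance(self):
        # shuffling subjects' t2 values destroys retention beyond chance
        rng = np.random.default_rng(0)
        retentions = []
        for _ in range(100):
            vals = np.sort(rng.uniform(0, 50, size=20))
            t1, _, labels = self._paired(vals, vals)
            t2 = pd.Series(rng.permutation(vals), index=t1.index)
            retentions.append(sx.stability_over_time(t1, t2, labels).retention)
        assert abs(np.mean(retentions) - 0.5) < 0.05

    def test_synthetic_repeat_visit_high_retention(self):
        retentions = []
        for seed in range(25):
            cfg = fast_config(seed=800 + seed)
            m, pheno, truth = sx.generate_cohort(cfg)
            mn = sx.normalize_per_chip(m)
            sig = sx.select_signature(mn, pheno, truth.annotation)
            ref = pheno.loc[pheno["group"] == "nonsmoker", "sample_id"].tolist()
            ranges = sx.fit_normal_ranges(mn, sig, ref)
            idx1 = sx.compute_isae(mn, ranges)
            smokers = pheno.loc[pheno["group"] == "healthy_smoker", "sample_id"]
            labels = sx.classify_responders(idx1.isae.loc[smokers])
            subj = truth.subjects.reset_index().set_index("sample_id")
            smoker_subjects = subj.loc[smokers, "subject_id"].tolist()
            m2, pheno2 = sx.plant_repeat_visit(cfg, truth, subjects=smoker_subjects)
            idx2 = sx.compute_isae(sx.normalize_per_chip(m2), ranges)
            sample_to_subject = pheno2.set_index("sample_id")["subject_id"]
            isae_t1 = idx1.isae.loc[smokers].rename(
                subj.loc[smokers, "subject_id"].to_dict())
            isae_t2 = idx2.isae.rename(sample_to_subject.to_dict())
            lab_subj = sx.ResponderLabels(
                labels=labels.labels.rename(subj["subject_id"].to_dict()),
                rule=labels.rule, boundary=labels.boundary)
            report = sx.stability_over_time(isae_t1, isae_t2, lab_subj)
            retentions.append(report.retention)
        assert np.mean(retentions) >= 0.9
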