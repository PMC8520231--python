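"""Signature derivation, trend classification, scores, matrices, clustering."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from bemkit.sigscore import (
    CONCORDANT_A,
    CONCORDANT_B,
    NOT_EXPRESSED,
    UNSPECIFIED,
    SignatureSet,
    SignatureThresholds,
    TrendCallTable,
    TrendWindow,
    classify_trends,
    cluster_profiles,
    derive_signatures,
    filter_expressed,
    round_half_away,
    similarity_matrix,
    similarity_scores,
)
from bemkit.synthdata import RefSimConfig, StudyMixConfig, gen_reference_counts, gen_study_counts

from conftest import make_counts, reorder_samples


class TestFilterExpressed:
    def test_boundary_mean_is_removed(self):
        cm = make_counts(
            {"s1": [10, 0, 5], "s2": [10, 60, 5], "s3": [10, 0, 40]},
            {"s1": "g", "s2": "g", "s3": "g"},
        )
        out = filter_expressed(cm, 10.0)
        # gene0 mean exactly 10 -> dropped (strictly greater than); gene1 mean 20 kept
        assert list(out.gene_ids) == ["g1", "g2"]

    def test_all_removed_warns(self):
        cm = make_counts({"s1": [1.0], "s2": [2.0]}, {"s1": "g", "s2": "g"})
        with pytest.warns(UserWarning):
            out = filter_expressed(cm, 10.0)
        assert out.values.empty


class TestDeriveSignatures:
    def test_null_reference_nearly_empty_lists(self):
        cfg = RefSimConfig(n_genes=800, n_sig_a=0, n_sig_b=0, effect_fc=1.0, dispersion=0.2, seed=31)
        ref, _ = gen_reference_counts(cfg)
        sigs = derive_signatures(filter_expressed(ref))
        assert len(sigs.all_genes) <= 0.05 * 800

    def test_recovery_of_planted_genes(self, low_noise_reference):
        ref, truth = low_noise_reference
        sigs = derive_signatures(filter_expressed(ref))
        assert len(set(sigs.up_in_a) & truth.up_in_a) >= 95
        assert len(set(sigs.up_in_a) & truth.up_in_b) == 0
        assert len(set(sigs.up_in_b) & truth.up_in_b) >= 95

    def test_hand_computed_clear_case(self):
        # gene0: means 30 vs 10, within-group SD ~1 -> FC 3 and tiny p -> up_in_a
        cm = make_counts(
            {
                "a1": [29.0, 20.0],
                "a2": [30.0, 20.5],
                "a3": [31.0, 19.5],
                "b1": [9.0, 20.5],
                "b2": [10.0, 19.5],
                "b3": [11.0, 20.0],
            },
            {k: ("A" if k.startswith("a") else "B") for k in ["a1", "a2", "a3", "b1", "b2", "b3"]},
        )
        t0 = scipy.stats.ttest_ind([29, 30, 31], [9, 10, 11], equal_var=False)
        assert t0.pvalue < 0.05  # brute-force confirmation of the planted contrast
        sigs = derive_signatures(cm, SignatureThresholds(min_avg_count=0), mode="two_group")
        assert sigs.up_in_a == ["g0"] and sigs.up_in_b == []

    def test_insufficient_replication_rejected(self):
        cm = make_counts({"a1": [1.0], "b1": [2.0], "b2": [3.0]}, {"a1": "A", "b1": "B", "b2": "B"})
        with pytest.raises(ValueError, match="replic"):
            derive_signatures(cm)

    def test_label_swap_symmetry(self, low_noise_reference):
        ref, _ = low_noise_reference
        swapped_order = ref.samples_of("microglia") + ref.samples_of("monocyte")
        swapped = reorder_samples(ref, swapped_order)
        sigs = derive_signatures(filter_expressed(ref))
        sigs_sw = derive_signatures(filter_expressed(swapped))
        assert sigs_sw.name_a == sigs.name_b
        assert sorted(sigs_sw.up_in_a) == sorted(sigs.up_in_b)
        assert sorted(sigs_sw.up_in_b) == sorted(sigs.up_in_a)

    def test_multi_stage_recovers_planted_extremes(self):
        cfg = RefSimConfig(
            stages=("embryonic", "postnatal", "adult"),
            n_genes=1000, n_sig_a=60, n_sig_b=60, effect_fc=4.0, dispersion=0.05, seed=32,
        )
        ref, truth = gen_reference_counts(cfg)
        sigs = derive_signatures(filter_expressed(ref), mode="multi_stage")
        assert sigs.name_a == "embryonic" and sigs.name_b == "adult"
        assert len(set(sigs.up_in_a) & truth.up_in_a) >= 55
        assert len(set(sigs.up_in_b) & truth.up_in_b) >= 55


def tiny_study_and_signatures():
    """Hand-sized study (6 genes, 2 groups x 3 reps) plus its exhaustive calls.

    The oracle classification below is computed gene by gene with explicit
    scalar arithmetic, independent of classify_trends.
    """
    sigs = SignatureSet("mono", "micro", ["gA1", "gA2", "gA3"], ["gB1", "gB2"], 6)
    values = {
        # grp samples,  base samples
        "t1": [200.0, 30.0, 100.0, 40.0, 100.0],
        "t2": [210.0, 30.5, 101.0, 41.0, 100.0],
        "t3": [190.0, 29.5, 99.0, 39.0, 100.0],
        "c1": [100.0, 30.0, 100.0, 90.0, 100.0],
        "c2": [101.0, 29.0, 101.0, 91.0, 100.0],
        "c3": [99.0, 31.0, 99.0, 89.0, 100.0],
    }
    df = pd.DataFrame(values)
    df.index = pd.Index(["gA1", "gA2", "gA3", "gB1", "gB2"], name="gene_id")
    return df, sigs


class TestClassifyTrends:
    def test_exhaustive_hand_classification(self):
        from bemkit.containers import CountMatrix

        df, sigs = tiny_study_and_signatures()
        groups = pd.Series({s: ("treated" if s.startswith("t") else "control") for s in df.columns})
        cm = CountMatrix(df, groups)
        calls = classify_trends(cm, sigs, baseline="control")

        # independent scalar oracle: FC vs control mean, Welch p, BH by hand
        expected = {}
        ps = {}
        for gene in df.index:
            grp = df.loc[gene, ["t1", "t2", "t3"]].to_numpy()
            ctl = df.loc[gene, ["c1", "c2", "c3"]].to_numpy()
            fc = grp.mean() / ctl.mean()
            res = scipy.stats.ttest_ind(grp, ctl, equal_var=False)
            p = 1.0 if math.isnan(res.pvalue) else res.pvalue
            ps[gene] = (fc, p)
        raw = sorted(ps.items(), key=lambda kv: kv[1][1])
        qs = {}
        prev = 1.0
        for i in range(len(raw) - 1, -1, -1):
            gene, (fc, p) = raw[i]
            prev = min(prev, p * len(raw) / (i + 1))
            qs[gene] = prev
        for gene, (fc, p) in ps.items():
            if fc > 1.5 and qs[gene] <= 0.01:
                expected[gene] = CONCORDANT_A if gene.startswith("gA") else CONCORDANT_B
            else:
                expected[gene] = UNSPECIFIED
        # gene gB2 identical in both groups -> degenerate, unspecified
        for gene in df.index:
            assert calls.calls.loc[gene, "treated"] == expected[gene], gene

    def test_window_boundary_fc_exactly_upper_is_unspecified(self):
        from bemkit.containers import CountMatrix

        df = pd.DataFrame(
            {
                "t1": [150.0, 200.0], "t2": [150.0, 200.0],
                "c1": [100.0, 100.0], "c2": [100.0, 100.0],
            },
            index=pd.Index(["exact", "clear"], name="gene_id"),
        )
        cm = CountMatrix(df, pd.Series({"t1": "T", "t2": "T", "c1": "C", "c2": "C"}))
        sigs = SignatureSet("a", "b", ["exact", "clear"], [], 2)
        calls = classify_trends(cm, sigs, baseline="C")
        # constant samples with different means -> p=0 -> FDR 0; only the
        # window decides: FC 1.5 exactly stays unspecified, FC 2.0 concordant
        assert calls.calls.loc["exact", "T"] == UNSPECIFIED
        assert calls.calls.loc["clear", "T"] == CONCORDANT_A

    def test_missing_baseline_group_rejected(self, study_with_mixture):
        study, _, truth = study_with_mixture
        sigs = SignatureSet("a", "b", list(truth.up_in_a)[:5], [], 5)
        with pytest.raises(ValueError, match="baseline"):
            classify_trends(study, sigs, baseline="no_such_group")

    def test_completeness_partition(self, study_with_mixture):
        study, _, truth = study_with_mixture
        # include two genes that cannot be in the filtered study matrix
        listed_a = list(sorted(truth.up_in_a))[:40] + ["ghost1"]
        listed_b = list(sorted(truth.up_in_b))[:40] + ["ghost2"]
        sigs = SignatureSet("mono", "micro", listed_a, listed_b, 82)
        calls = classify_trends(filter_expressed(study), sigs)
        for grp in study.groups:
            c = calls.counts(grp)
            assert sum(c.values()) == sigs.listed_total
        assert (calls.calls.loc[["ghost1", "ghost2"]] == NOT_EXPRESSED).all().all()


class TestSimilarityScores:
    # every count -> integer-percent pair printed for the monocyte/microglia
    # (denominator 1201) and embryonic/adult (denominator 2402) signature lists
    PRINTED = [
        (718, 1201, 60), (685, 1201, 57), (612, 1201, 51), (331, 1201, 28), (386, 1201, 32),
        (1306, 2402, 54), (381, 2402, 16), (445, 2402, 19), (405, 2402, 17),
        (1649, 2402, 69), (1409, 2402, 59), (1507, 2402, 63), (759, 2402, 32),
    ]

    @staticmethod
    def _table_with_counts(n_a: int, denominator: int) -> TrendCallTable:
        genes = [f"g{i}" for i in range(denominator)]
        up_a, up_b = genes[: denominator // 2], genes[denominator // 2 :]
        sigs = SignatureSet("a", "b", up_a, up_b, denominator)
        col = np.array([UNSPECIFIED] * denominator, dtype=object)
        col[:n_a] = CONCORDANT_A
        calls = pd.DataFrame({"grp": col}, index=pd.Index(genes, name="gene_id"))
        empty = pd.DataFrame(index=calls.index, columns=["grp"], dtype=float)
        return TrendCallTable(calls, sigs, "pooled_mean", empty, empty)

    @pytest.mark.parametrize("n,denom,pct", PRINTED)
    def test_printed_count_percentage_pairs(self, n, denom, pct):
        table = self._table_with_counts(n, denom)
        score = similarity_scores(table)[0]
        assert score.n_a == n and score.denominator == denom
        assert score.score_a == pct

    def test_zero_count_zero_percent(self):
        assert similarity_scores(self._table_with_counts(0, 100))[0].score_a == 0

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(59.5) == 60
        assert round_half_away(-0.5) == -1
        assert round_half_away(0.4999) == 0

    def test_expressed_only_denominator(self, study_with_mixture):
        study, _, truth = study_with_mixture
        listed = list(sorted(truth.up_in_a))[:30] + ["ghost"]
        sigs = SignatureSet("mono", "micro", listed, [], 31)
        calls = classify_trends(filter_expressed(study), sigs)
        s_listed = similarity_scores(calls, "listed_total")[0]
        s_expr = similarity_scores(calls, "expressed_only")[0]
        assert s_listed.denominator == 31 and s_expr.denominator == 30


class TestMixtureSweep:
    def test_score_a_monotone_and_mid_between(self, low_noise_reference):
        ref, truth = low_noise_reference
        sigs = derive_signatures(filter_expressed(ref))
        scores_a, scores_b = [], []
        for pi in (0.0, 0.25, 0.5, 0.75, 1.0):
            mix = dict.fromkeys(StudyMixConfig().group_names, 0.0)
            mix["WBRT+CSF1Ri"] = pi
            study, _ = gen_study_counts(
                truth, StudyMixConfig(mixture_fractions=mix, dispersion=0.1, seed=42)
            )
            calls = classify_trends(filter_expressed(study), sigs)
            s = {x.group: x for x in similarity_scores(calls)}["WBRT+CSF1Ri"]
            scores_a.append(s.score_a)
            scores_b.append(s.score_b)
        assert scores_a == sorted(scores_a)
        assert scores_a[0] < scores_a[2] < scores_a[-1]
        # B-signature genes are never elevated above a B-dominated pooled
        # baseline, so the B score cannot increase along the sweep
        assert scores_b == sorted(scores_b, reverse=True)

    def test_full_mixture_matches_pure_population_a(self, low_noise_reference):
        ref, truth = low_noise_reference
        sigs = derive_signatures(filter_expressed(ref))
        mix = dict.fromkeys(StudyMixConfig().group_names, 0.0)
        mix["WBRT+CSF1Ri"] = 1.0
        study, _ = gen_study_counts(truth, StudyMixConfig(mixture_fractions=mix, dispersion=0.1, seed=43))
        # a second, independently drawn pi=1 group stands in for pure-A replicates
        study2, _ = gen_study_counts(truth, StudyMixConfig(mixture_fractions=mix, dispersion=0.1, seed=44))
        s1 = {x.group: x for x in similarity_scores(classify_trends(filter_expressed(study), sigs))}
        s2 = {x.group: x for x in similarity_scores(classify_trends(filter_expressed(study2), sigs))}
        assert abs(s1["WBRT+CSF1Ri"].score_a - s2["WBRT+CSF1Ri"].score_a) <= 3


class TestSimilarityMatrixAndClustering:
    def test_self_and_scaled_profiles_correlate_perfectly(self):
        rng = np.random.default_rng(9)
        x = rng.lognormal(5, 1, 500)
        prof = pd.DataFrame({"p": x, "p2": 2 * x})
        corr = similarity_matrix(prof, log_transform=False)
        assert corr.loc["p", "p"] == 1.0
        assert corr.loc["p", "p2"] == pytest.approx(1.0)
        corr_log = similarity_matrix(prof)
        assert corr_log.loc["p", "p2"] == pytest.approx(1.0, abs=1e-3)

    def test_independent_noise_profiles_uncorrelated(self):
        rng = np.random.default_rng(10)
        prof = pd.DataFrame(rng.lognormal(5, 1, (1000, 2)), columns=["u", "v"])
        corr = similarity_matrix(prof)
        assert abs(corr.loc["u", "v"]) < 0.1

    def test_zero_variance_profile_warns_nan(self):
        prof = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "x": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = similarity_matrix(prof, log_transform=False)
        assert np.isnan(corr.loc["flat", "x"])
        assert corr.loc["x", "x"] == 1.0

    def test_duplicate_profiles_merge_first_at_zero(self):
        rng = np.random.default_rng(11)
        x = rng.lognormal(5, 0.5, 100)
        prof = pd.DataFrame({"a": x, "b": x, "c": rng.lognormal(5, 0.5, 100)})
        spec = cluster_profiles(prof)
        assert spec.heights[0] == pytest.approx(0.0, abs=1e-12)
        assert len(spec.heights) == 2  # n-1 merges
        order = spec.leaf_order()
        assert abs(order.index("a") - order.index("b")) == 1

    def test_mixture_groups_cluster_by_profile(self, low_noise_reference):
        ref, truth = low_noise_reference
        sigs = derive_signatures(filter_expressed(ref))
        mix = {"pureB_1": 0.0, "pureB_2": 0.0, "pureA": 1.0}
        study, _ = gen_study_counts(
            truth,
            StudyMixConfig(group_names=tuple(mix), mixture_fractions=mix, dispersion=0.05, seed=45),
        )
        prof = study.group_means().loc[[g for g in sigs.all_genes if g in study.gene_ids]]
        spec = cluster_profiles(prof)
        order = spec.leaf_order()
        assert abs(order.index("pureB_1") - order.index("pureB_2")) == 1
        nwk = spec.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 2

    def test_heights_non_decreasing(self, study_with_mixture):
        study, _, _ = study_with_mixture
        spec = cluster_profiles(study.group_means())
        assert np.all(np.diff(spec.heights) >= -1e-12)
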