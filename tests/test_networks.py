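"""Volume-weighted profiles, repeated-measures comparisons, sign tests."""

import numpy as np
import pandas as pd
import pytest

from sentnet.data import ContrastPanel, TASKS, TimeSeriesPanel
from sentnet.networks import (
    internetwork_correlations,
    network_profiles,
    profile_comparisons,
    sign_test,
)
from conftest import make_region_table


def _two_region_panel(v1, v2, n_sub=4):
    vals = np.zeros((n_sub, 2, 3, 2))
    vals[:, 0, :, 0] = v1
    vals[:, 1, :, 0] = v2
    return ContrastPanel(
        [f"s{i}" for i in range(n_sub)], ["p1", "p2"], vals
    )


class TestProfiles:
    def test_equal_volumes_unweighted_mean(self):
        regions = make_region_table(2, volumes=[100.0, 100.0])
        panel = _two_region_panel(0.4, 0.8)
        prof = network_profiles({"p1": "N1", "p2": "N1"}, panel, regions)
        act = prof.per_subject.query("task == 'PROD'")["activation"]
        np.testing.assert_allclose(act, 0.6)

    def test_hand_weighted_mean(self):
        regions = make_region_table(2, volumes=[100.0, 300.0])
        panel = _two_region_panel(0.4, 0.8)
        prof = network_profiles({"p1": "N1", "p2": "N1"}, panel, regions)
        act = prof.per_subject.query("task == 'PROD'")["activation"]
        np.testing.assert_allclose(act, 0.7)

    def test_network_volume_is_member_sum(self):
        regions = make_region_table(2, volumes=[100.0, 300.0])
        panel = _two_region_panel(0.4, 0.8)
        prof = network_profiles({"p1": "N1", "p2": "N1"}, panel, regions)
        assert prof.volumes["N1"] == pytest.approx(400.0)

    def test_region_split_invariance(self):
        """Splitting a region into two half-volume copies changes nothing."""
        regions_a = make_region_table(1, volumes=[200.0])
        vals = np.zeros((3, 1, 3, 2))
        vals[:, 0, :, 0] = 0.5
        vals[:, 0, :, 1] = 0.2
        panel_a = ContrastPanel(["s0", "s1", "s2"], ["p1"], vals)
        prof_a = network_profiles({"p1": "N"}, panel_a, regions_a)

        regions_b = make_region_table(2, volumes=[100.0, 100.0])
        vals_b = np.repeat(vals, 2, axis=1)
        panel_b = ContrastPanel(["s0", "s1", "s2"], ["p1", "p2"], vals_b)
        prof_b = network_profiles(
            {"p1": "N", "p2": "N"}, panel_b, regions_b
        )
        pd.testing.assert_frame_equal(
            prof_a.per_subject, prof_b.per_subject
        )


class TestProfileComparisons:
    def test_constant_data_all_null(self):
        regions = make_region_table(2, volumes=[100.0, 100.0])
        panel = _two_region_panel(0.5, 0.5, n_sub=6)
        prof = network_profiles(
            {"p1": "N1", "p2": "N2"}, panel, regions
        )
        anova, pairwise = profile_comparisons(prof)
        assert (anova["Pr > F"] == 1.0).all()
        assert (anova["F Value"] == 0.0).all()
        assert (pairwise["p_holm"] == 1.0).all()

    def test_planted_task_ordering_detected(self):
        """PROD > READ > LISN in the core network is found by the
        Holm-corrected paired contrasts in nearly every replicate."""
        n_regions, n_sub = 18, 144  # study-scale core network
        regions = make_region_table(n_regions, volumes=[100.0] * n_regions)
        pair_ids = [f"p{i + 1}" for i in range(n_regions)]
        hits = 0
        n_seeds = 20
        means = {"PROD": 0.73, "LISN": 0.43, "READ": 0.55}
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            vals = np.zeros((n_sub, n_regions, 3, 2))
            for t, task in enumerate(TASKS):
                vals[:, :, t, 0] = means[task] + rng.normal(
                    0, 0.3, (n_sub, n_regions)
                )
            panel = ContrastPanel(
                [f"s{i}" for i in range(n_sub)], pair_ids, vals
            )
            prof = network_profiles(
                {p: "N1" for p in pair_ids}, panel, regions
            )
            _, pairwise = profile_comparisons(prof)
            hits += int(pairwise["significant_holm05"].all())
        assert hits >= 0.9 * n_seeds

    def test_null_interaction_p_roughly_uniform(self):
        """With task labels permuted per subject the interaction p is
        calibrated (roughly uniform across replicates)."""
        from scipy import stats

        regions = make_region_table(2, volumes=[100.0, 100.0])
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            vals = rng.normal(0.3, 0.2, (24, 2, 3, 2))
            # permute task labels independently per subject
            for s in range(24):
                vals[s] = vals[s][:, rng.permutation(3), :]
            panel = ContrastPanel(
                [f"s{i}" for i in range(24)], ["p1", "p2"], vals
            )
            prof = network_profiles(
                {"p1": "N1", "p2": "N2"}, panel, regions
            )
            anova, _ = profile_comparisons(prof)
            ps.append(float(anova.loc["network:task", "Pr > F"]))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSignTest:
    def test_all_negative_closed_form(self):
        assert sign_test(10, 10) == pytest.approx(2.0**-10)

    def test_reference_worked_examples(self):
        assert sign_test(78, 138) == pytest.approx(0.074, abs=5e-4)
        assert sign_test(86, 138) == pytest.approx(0.0024, abs=5e-5)

    def test_binomial_oracle_property(self):
        from math import comb

        from hypothesis import given, settings, strategies as st

        @settings(derandomize=True, max_examples=60, deadline=None)
        @given(st.integers(1, 200).flatmap(
            lambda n: st.tuples(st.just(n), st.integers(0, n))
        ))
        def check(pair):
            n, m = pair
            oracle = sum(comb(n, j) for j in range(m, n + 1)) / 2.0**n
            assert sign_test(m, n) == pytest.approx(oracle, rel=1e-12)

        check()

    def test_matches_binomial_oracle_exhaustively(self):
        """Exact binomial tail oracle for every n <= 200."""
        from math import comb

        for n in range(1, 201):
            m = (2 * n) // 3
            oracle = sum(comb(n, j) for j in range(m, n + 1)) / 2.0**n
            assert sign_test(m, n) == pytest.approx(oracle, rel=1e-12)


class TestInternetwork:
    def test_planted_negative_pair_detected(self, reduced_cohort):
        filt_names = reduced_cohort.contrasts.pair_ids
        ts = TimeSeriesPanel(
            reduced_cohort.rest_raw.subjects,
            reduced_cohort.rest_raw.series,
            filt_names,
            reduced_cohort.rest_raw.sampling_interval,
        )
        sel = reduced_cohort.truth.selected_set
        table = internetwork_correlations(
            ts.subset_regions(sel), reduced_cohort.truth.partition
        )
        row = table.query("network_a == 'M1' and network_b == 'M2'").iloc[0]
        assert row["mean_r"] < -0.1
        assert row["significant_bonferroni05"]

    def test_missing_network_rejected(self, reduced_cohort):
        from sentnet.data import DataError

        ts = TimeSeriesPanel(
            reduced_cohort.rest_raw.subjects,
            reduced_cohort.rest_raw.series,
            reduced_cohort.contrasts.pair_ids,
            reduced_cohort.rest_raw.sampling_interval,
        )
        sel = reduced_cohort.truth.selected_set
        mapping = dict(reduced_cohort.truth.partition)
        mapping["ghost"] = "M9"
        with pytest.raises(DataError, match="M9"):
            internetwork_correlations(ts.subset_regions(sel), mapping)
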