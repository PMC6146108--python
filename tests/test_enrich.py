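"""Enrichment calling: control pooling, Welch test, BH correction,
decision rules and activity summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from nsip.bands import DensityEstimate
from nsip.config import AnalysisConfig
from nsip.enrich import (bh_correct, mean_activity_by_domain, pool_controls,
                         run_enrichment, summarize_activity, welch_test)
from nsip.io import Treatment
from nsip.synth import otu_ids, simulate_community, simulate_experiment

from conftest import CONTROLS, LABELED_NH4
from test_bands import make_band


def make_estimate(mean, var, n, reads=10000, k=5):
    return DensityEstimate(mean_density=mean, weighted_variance=var,
                           effective_n=n, total_reads=reads, n_fractions=k)


class TestPoolControls:
    def test_single_band_is_identity(self):
        band = make_band([1.700, 1.705, 1.710], [20, 60, 20])
        pooled = pool_controls([band])
        solo = pool_controls([band, band])  # idempotent up to weighting
        assert pooled.mean_density == pytest.approx(solo.mean_density,
                                                    abs=1e-12)

    def test_two_identical_bands_keep_the_mean(self):
        band = make_band([1.700, 1.705, 1.710], [20, 60, 20])
        single = pool_controls([band])
        double = pool_controls([band, band])
        assert double.mean_density == pytest.approx(single.mean_density,
                                                    abs=1e-12)

    def test_equal_mass_controls_average(self):
        # two single-fraction controls at 1.705 and 1.707 with equal total
        # normalized mass pool to the midpoint
        a = make_band([1.705], [10.0])
        b = make_band([1.707], [10.0])
        pooled = pool_controls([a, b])
        assert pooled.mean_density == pytest.approx(1.706, abs=1e-12)

    def test_empty_pool_rejected(self):
        from nsip.errors import InputError
        with pytest.raises(InputError):
            pool_controls([])


class TestWelch:
    def test_identical_estimates_give_half_p(self):
        a = make_estimate(1.705, 1e-5, 8)
        t, df, p, degenerate = welch_test(a, a)
        assert t == 0.0
        assert p == pytest.approx(0.5)
        assert not degenerate

    def test_equal_variance_equal_n_satterthwaite_limit(self):
        a = make_estimate(1.710, 1e-6, 8)
        b = make_estimate(1.705, 1e-6, 8)
        _, df, _, _ = welch_test(a, b)
        assert df == pytest.approx(2 * 8 - 2)

    def test_hand_computed_statistic(self):
        a = make_estimate(1.713, 1e-6, 8)
        b = make_estimate(1.705, 1e-6, 8)
        t, df, p, _ = welch_test(a, b)
        assert t == pytest.approx(16.0)
        assert df == pytest.approx(14.0)
        # independent one-sided p through the regularized incomplete beta
        p_beta = 0.5 * special.betainc(14 / 2, 0.5, 14 / (14 + t ** 2))
        assert p == pytest.approx(p_beta, rel=1e-10)

    def test_one_sided_beats_two_sided_for_positive_shift(self):
        a = make_estimate(1.710, 1e-6, 6)
        b = make_estimate(1.706, 1e-6, 6)
        _, _, p1, _ = welch_test(a, b, two_sided=False)
        _, _, p2, _ = welch_test(a, b, two_sided=True)
        assert p1 == pytest.approx(p2 / 2)

    def test_degenerate_zero_variance_equal_means(self):
        a = make_estimate(1.705, 0.0, 4)
        t, df, p, degenerate = welch_test(a, a)
        assert degenerate and p == 1.0

    def test_degenerate_zero_variance_different_means(self):
        a = make_estimate(1.710, 0.0, 4)
        b = make_estimate(1.705, 0.0, 4)
        t, df, p, degenerate = welch_test(a, b)
        assert degenerate and p == 0.0 and t == np.inf


def bh_brute_force(p, fdr):
    """Textbook step-up: q_i = min over j >= rank(i) of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q, q <= fdr


class TestBH:
    def test_single_p_is_its_own_q(self):
        q, rej = bh_correct([0.03])
        assert q[0] == pytest.approx(0.03)
        assert rej[0]

    def test_worked_example(self):
        q, rej = bh_correct([0.01, 0.02, 0.04, 0.2], fdr=0.1)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.2],
                                   atol=1e-12)
        assert rej.sum() == 3

    def test_all_ones_reject_nothing(self):
        q, rej = bh_correct([1.0, 1.0, 1.0])
        assert not rej.any()
        np.testing.assert_allclose(q, 1.0)

    def test_empty_family(self):
        q, rej = bh_correct([])
        assert len(q) == 0 and len(rej) == 0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20), st.sampled_from([0.05, 0.1, 0.2]))
    def test_matches_brute_force(self, p, fdr):
        q, rej = bh_correct(p, fdr)
        q2, rej2 = bh_brute_force(p, fdr)
        np.testing.assert_allclose(q, q2, atol=1e-12)
        np.testing.assert_array_equal(rej, rej2)

    def test_q_never_below_p(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=15)
        q, _ = bh_correct(p)
        assert np.all(q >= p - 1e-12)


class TestPipelineDecisions:
    def test_results_schema_and_invariants(self, small_experiment):
        res = run_enrichment(small_experiment["gradients"],
                             small_experiment["counts"], AnalysisConfig())
        assert len(res) > 0
        tested = res[~res["excluded"] & res["q_value"].notna()]
        assert (tested["q_value"] >= tested["p_value"] - 1e-12).all()
        assert not (res["enriched"] & res["excluded"]).any()
        assert (res.loc[res["enriched"], "shift"] > 0).all()

    def test_detects_true_assimilators(self, small_experiment):
        res = run_enrichment(small_experiment["gradients"],
                             small_experiment["counts"], AnalysisConfig())
        true_ids = set(small_experiment["true_ids"])
        hits = set(res.loc[res["enriched"], "otu_id"])
        assert len(hits & true_ids) >= len(true_ids) // 2
        false_hits = hits - true_ids
        assert len(false_hits) <= 2

    def test_min_otu_reads_filter_shrinks_family(self, small_experiment):
        strict = run_enrichment(
            small_experiment["gradients"], small_experiment["counts"],
            AnalysisConfig(min_otu_reads=10 ** 9))
        assert (strict["exclude_reason"] == "low_reads").all()
        assert strict["q_value"].isna().all()
        lax = run_enrichment(
            small_experiment["gradients"], small_experiment["counts"],
            AnalysisConfig(min_otu_reads=0))
        assert not lax["excluded"].all()

    def test_percent_rule_conjunction(self, small_experiment):
        # min_percent above any true shift turns every call off
        res = run_enrichment(small_experiment["gradients"],
                             small_experiment["counts"],
                             AnalysisConfig(min_percent=1000.0))
        assert not res["enriched"].any()

    def test_enrichment_monotone_in_atom_fraction(self):
        """More label in the DNA can only increase the number of calls."""
        from nsip.config import SimConfig
        calls = []
        for atom in (0.15, 0.45, 0.9):
            cfg = SimConfig(seed=77, reads_per_fraction=20000)
            ids = otu_ids(40)
            comm = simulate_community(40, cfg, {LABELED_NH4: ids[:8]},
                                      atom_fraction=atom)
            gradients, counts, _, _ = simulate_experiment(
                comm, [LABELED_NH4] + CONTROLS, cfg)
            res = run_enrichment(gradients, counts, AnalysisConfig())
            calls.append(int(res["enriched"].sum()))
        assert calls == sorted(calls)


class TestSummaries:
    @staticmethod
    def _fixture_results():
        rows = []
        for i, (otu, sub, enr) in enumerate([
                ("p1", "NH4", True), ("p2", "NH4", True),
                ("p3", "NH4", True), ("p4", "urea", True),
                ("e1", "NH4", True), ("e2", "urea", True),
                ("p5", "NO3", False)]):
            rows.append({"otu_id": otu, "substrate": sub,
                         "light_level": "50", "enriched": enr,
                         "excluded": False})
        taxonomy = pd.DataFrame({
            "otu_id": ["p1", "p2", "p3", "p4", "p5", "e1", "e2"],
            "domain_flag": ["prokaryote"] * 5 + ["eukaryote_chloroplast"] * 2,
        })
        return pd.DataFrame(rows), taxonomy

    def test_counts_by_domain(self):
        results, taxonomy = self._fixture_results()
        summary = summarize_activity(results, taxonomy)
        total = summary.set_index("substrate")
        assert summary["n_enriched"].sum() == 6
        assert total.loc["NH4", "n_prokaryote"] == 3
        assert total.loc["NH4", "n_eukaryote"] == 1
        # 4 prokaryote + 2 eukaryote enrichments overall -> share 1/3
        share = summary["n_eukaryote"].sum() / summary["n_enriched"].sum()
        assert share == pytest.approx(1 / 3)

    def test_no_enrichment_gives_zero_counts(self):
        results, taxonomy = self._fixture_results()
        results["enriched"] = False
        summary = summarize_activity(results, taxonomy)
        assert (summary["n_enriched"] == 0).all()

    def test_multi_treatment_activity(self):
        rows = [{"otu_id": "a", "substrate": s, "light_level": lvl,
                 "enriched": True, "excluded": False}
                for s, lvl in [("NH4", "50"), ("urea", "50"), ("NH4", "10")]]
        rows.append({"otu_id": "b", "substrate": "NH4", "light_level": "50",
                     "enriched": True, "excluded": False})
        taxonomy = pd.DataFrame({
            "otu_id": ["a", "b"],
            "domain_flag": ["eukaryote_chloroplast", "prokaryote"]})
        means = mean_activity_by_domain(pd.DataFrame(rows), taxonomy)
        assert means["eukaryote_chloroplast"] == pytest.approx(3.0)
        assert means["prokaryote"] == pytest.approx(1.0)
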