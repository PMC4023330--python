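"""Comparative-CT folds, segregation chi-square, marker and SSR association."""

import math

import numpy as np
import pytest
from scipy import stats

from _oracles import brute_concordance
from lactomap.validate import (
    HOUSEKEEPING,
    TARGET,
    MarkerCall,
    QPCRMeasurement,
    SSRGenotype,
    chi_square_ratio,
    ddct_fold_change,
    marker_concordance,
    ssr_allele_association,
)
from lactomap.volatiles import ProducerStatus


def qpcr_set(cts):
    """cts: {(condition, gene): [ct, ...]}"""
    out = []
    for (cond, gene), values in cts.items():
        for rep, ct in enumerate(values, start=1):
            out.append(QPCRMeasurement(f"s_{cond}", cond, gene, ct, rep))
    return out


class TestDDCT:
    def test_all_equal_cts_fold_one(self):
        m = qpcr_set({
            ("rip", TARGET): [24.0], ("rip", HOUSEKEEPING): [24.0],
            ("cal", TARGET): [24.0], ("cal", HOUSEKEEPING): [24.0],
        })
        res = ddct_fold_change(m, "rip", "cal")
        assert res.fold == 1.0 and res.ddct == 0.0

    def test_ddct_minus_one_fold_two_exact(self):
        m = qpcr_set({
            ("rip", TARGET): [23.0], ("rip", HOUSEKEEPING): [20.0],
            ("cal", TARGET): [24.0], ("cal", HOUSEKEEPING): [20.0],
        })
        res = ddct_fold_change(m, "rip", "cal")
        assert res.ddct == -1.0 and res.fold == 2.0

    def test_sample_equal_calibrator_fold_one_for_any_input(self):
        m = qpcr_set({
            ("c", TARGET): [27.3, 27.1, 27.2], ("c", HOUSEKEEPING): [19.8, 20.1, 20.0],
        })
        res = ddct_fold_change(m, "c", "c")
        assert res.fold == 1.0 and res.ddct == 0.0

    def test_triplicate_fixture_matches_hand_oracle(self):
        t_s = [22.10, 22.30, 22.20]
        h_s = [20.00, 19.90, 20.10]
        t_c = [26.50, 26.40, 26.60]
        h_c = [20.05, 19.95, 20.00]
        m = qpcr_set({
            ("samp", TARGET): t_s, ("samp", HOUSEKEEPING): h_s,
            ("cal", TARGET): t_c, ("cal", HOUSEKEEPING): h_c,
        })
        res = ddct_fold_change(m, "samp", "cal")
        # spreadsheet-style recomputation
        ddct = (np.mean(t_s) - np.mean(h_s)) - (np.mean(t_c) - np.mean(h_c))
        sd = math.sqrt(np.std(t_s, ddof=1) ** 2 + np.std(h_s, ddof=1) ** 2)
        assert res.ddct == pytest.approx(ddct, abs=1e-9)
        assert res.fold == pytest.approx(2.0 ** -ddct, abs=1e-9)
        assert res.sd == pytest.approx(sd, abs=1e-9)
        assert res.fold_lo == pytest.approx(2.0 ** -(ddct + sd), abs=1e-9)

    def test_no_amplification_gives_fold_zero_with_flag(self):
        m = qpcr_set({
            ("samp", TARGET): [None, None, None], ("samp", HOUSEKEEPING): [20.0],
            ("cal", TARGET): [25.0], ("cal", HOUSEKEEPING): [20.0],
        })
        res = ddct_fold_change(m, "samp", "cal")
        assert res.fold == 0.0 and res.no_amplification

    def test_missing_housekeeping_rejected(self):
        m = qpcr_set({("samp", TARGET): [25.0], ("cal", TARGET): [25.0],
                      ("cal", HOUSEKEEPING): [20.0]})
        with pytest.raises(ValueError, match="housekeeping"):
            ddct_fold_change(m, "samp", "cal")

    @pytest.mark.parametrize("k", [1.0, 2.5, 4.0])
    def test_shifting_sample_target_ct_multiplies_fold(self, k):
        def measurements(shift):
            return qpcr_set({
                ("samp", TARGET): [24.0 - shift], ("samp", HOUSEKEEPING): [20.0],
                ("cal", TARGET): [25.0], ("cal", HOUSEKEEPING): [20.0],
            })

        base = ddct_fold_change(measurements(0.0), "samp", "cal").fold
        shifted = ddct_fold_change(measurements(k), "samp", "cal").fold
        assert shifted == pytest.approx(base * 2.0**k, rel=1e-12)


class TestChiSquare:
    def test_perfect_fit_statistic_zero(self):
        res = chi_square_ratio([10, 10], [1, 1])
        assert res.chi_square == 0.0 and res.p_value == pytest.approx(1.0)

    def test_15_to_5_closed_form(self):
        res = chi_square_ratio([15, 5], [1, 1])
        assert res.chi_square == pytest.approx(5.0)
        assert res.df == 1

    def test_p_value_matches_survival_function_oracle(self, rng):
        for _ in range(20):
            obs = rng.integers(1, 60, size=rng.integers(2, 5))
            ratio = rng.integers(1, 4, size=len(obs)).astype(float)
            res = chi_square_ratio(obs, ratio)
            assert res.p_value == pytest.approx(
                stats.chi2.sf(res.chi_square, res.df), abs=1e-9
            )

    def test_relabeling_invariance(self):
        a = chi_square_ratio([30, 10], [3, 1])
        b = chi_square_ratio([10, 30], [1, 3])
        assert a.chi_square == pytest.approx(b.chi_square)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            chi_square_ratio([0, 0], [1, 1])


def panel(markers, phenos):
    calls = [MarkerCall(g, m) for g, m in markers.items()]
    statuses = {
        g: ProducerStatus.PRODUCER if p else ProducerStatus.NONPRODUCER
        for g, p in phenos.items()
    }
    return calls, statuses


class TestMarkerConcordance:
    def test_perfectly_linked_panel(self):
        phenos = {f"g{i}": i % 2 == 0 for i in range(16)}
        calls, statuses = panel(phenos, phenos)
        res = marker_concordance(calls, statuses)
        assert res.concordance == 1.0 and res.discordant == ()
        assert res.p_method == "chi_square"  # diagonal table, no zero margin

    def test_one_flipped_call_in_twenty(self):
        phenos = {f"g{i}": i % 2 == 0 for i in range(20)}
        markers = dict(phenos)
        markers["g0"] = False
        calls, statuses = panel(markers, phenos)
        res = marker_concordance(calls, statuses)
        assert res.concordance == pytest.approx(0.95)
        assert res.discordant == ("g0",)

    def test_degenerate_margin_uses_exact_binomial(self):
        # marker present in everyone -> zero margin -> exact probability
        phenos = {f"g{i}": i % 2 == 0 for i in range(8)}
        markers = {g: True for g in phenos}
        calls, statuses = panel(markers, phenos)
        res = marker_concordance(calls, statuses)
        assert res.p_method == "exact_binomial"
        assert res.p_value == pytest.approx(0.5**7)

    def test_failed_control_and_insufficient_data_excluded(self):
        calls = [MarkerCall("a", True), MarkerCall("b", True, control_present=False)]
        statuses = {"a": ProducerStatus.PRODUCER, "b": ProducerStatus.NONPRODUCER,
                    "c": ProducerStatus.INSUFFICIENT_DATA}
        res = marker_concordance(calls, statuses)
        assert res.n == 1 and res.concordance == 1.0

    def test_matches_elementwise_oracle_on_random_panels(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 30))
            markers = {f"g{i}": bool(rng.integers(2)) for i in range(n)}
            phenos = {f"g{i}": bool(rng.integers(2)) for i in range(n)}
            if len(set(phenos.values())) < 2 or len(set(markers.values())) < 2:
                continue
            calls, statuses = panel(markers, phenos)
            res = marker_concordance(calls, statuses)
            want_conc, want_disc = brute_concordance(markers, phenos)
            assert res.concordance == pytest.approx(want_conc)
            assert sorted(res.discordant) == sorted(want_disc)

    def test_symmetric_under_simultaneous_negation(self, rng):
        n = 12
        markers = {f"g{i}": bool(rng.integers(2)) for i in range(n)}
        phenos = {f"g{i}": bool(rng.integers(2)) for i in range(n)}
        calls, statuses = panel(markers, phenos)
        neg_calls, neg_statuses = panel(
            {g: not m for g, m in markers.items()},
            {g: not p for g, p in phenos.items()},
        )
        a = marker_concordance(calls, statuses)
        b = marker_concordance(neg_calls, neg_statuses)
        assert a.concordance == b.concordance
        assert a.discordant == b.discordant

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError, match="no genotypes"):
            marker_concordance([MarkerCall("x", True)], {"y": ProducerStatus.PRODUCER})


class TestSSRAssociation:
    def make(self):
        genos, statuses = [], {}
        for i in range(10):
            producer = i < 6
            alleles = {209}
            if producer:
                alleles.add(205)
            if i % 3 == 0:
                alleles.add(215)
            genos.append(SSRGenotype(f"g{i}", frozenset(alleles)))
            statuses[f"g{i}"] = (ProducerStatus.PRODUCER if producer
                                 else ProducerStatus.NONPRODUCER)
        return genos, statuses

    def test_linked_allele_is_perfect_predictor(self):
        genos, statuses = self.make()
        table = ssr_allele_association(genos, statuses)
        assert table.loc[205, "perfect_predictor"]
        assert not table.loc[205, "monomorphic"]

    def test_monomorphic_allele_not_predictor(self):
        genos, statuses = self.make()
        table = ssr_allele_association(genos, statuses)
        assert table.loc[209, "monomorphic"]
        assert not table.loc[209, "perfect_predictor"]
        assert table.loc[209, "freq_producers"] == 1.0
        assert table.loc[209, "freq_nonproducers"] == 1.0

    def test_unlinked_allele_not_perfect_predictor_on_large_panels(self, rng):
        # an independent fair allele is a perfect predictor with probability
        # 0.5^n; across these panels it should essentially never happen
        for _ in range(20):
            n = 24
            genos, statuses = [], {}
            for i in range(n):
                producer = i < n // 2
                alleles = {209} | ({215} if rng.integers(2) else set())
                genos.append(SSRGenotype(f"g{i}", frozenset(alleles)))
                statuses[f"g{i}"] = (ProducerStatus.PRODUCER if producer
                                     else ProducerStatus.NONPRODUCER)
            table = ssr_allele_association(genos, statuses)
            if 215 in table.index:
                assert not table.loc[215, "perfect_predictor"]

    def test_single_class_rejected(self):
        genos = [SSRGenotype("a", frozenset({209}))]
        with pytest.raises(ValueError, match="phenotype class"):
            ssr_allele_association(genos, {"a": ProducerStatus.PRODUCER})

    def test_empty_allele_set_rejected(self):
        with pytest.raises(ValueError, match="empty allele"):
            SSRGenotype("a", frozenset())
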