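"""Generator tests: Mendelian ratios, deletion consistency, parameter recovery."""

import math

import numpy as np
import pytest

from lactomap.sim import (
    CROSS_CARRIER_PROB,
    LocusModel,
    QPCRDesign,
    SimConfig,
    SimGenotype,
    causal_gene_id,
    simulate_cross,
    simulate_expression,
    simulate_marker_panel,
    simulate_panel,
    simulate_pileups,
    simulate_qpcr,
    simulate_volatile_tables,
)
from lactomap.validate import TARGET, ddct_fold_change
from lactomap.variants import filter_snps
from lactomap.volatiles import TrendClass, series_from_peaks

LOCUS = LocusModel()


def carriers(genos):
    return [g.carrier for g in genos]


class TestSimulateCross:
    def test_null_by_null_transmits_nothing(self):
        locus = LocusModel(carrier_parent_id=None)
        assert not any(carriers(simulate_cross(locus, "F1", 50, seed=1)))

    @pytest.mark.parametrize("cross", sorted(CROSS_CARRIER_PROB))
    def test_mendelian_fraction_within_3_binomial_sd(self, cross):
        n = 10_000
        p = CROSS_CARRIER_PROB[cross]
        frac = np.mean(carriers(simulate_cross(LOCUS, cross, n, seed=7)))
        assert abs(frac - p) <= 3 * math.sqrt(p * (1 - p) / n)

    def test_same_seed_is_byte_identical(self):
        a = simulate_cross(LOCUS, "F1", 200, seed=3)
        b = simulate_cross(LOCUS, "F1", 200, seed=3)
        assert a == b

    def test_different_seed_differs(self):
        a = simulate_cross(LOCUS, "F1", 200, seed=3)
        b = simulate_cross(LOCUS, "F1", 200, seed=4)
        assert a != b

    def test_unknown_cross_rejected(self):
        with pytest.raises(ValueError, match="unknown cross"):
            simulate_cross(LOCUS, "F2", 10, seed=0)

    def test_noncarriers_have_no_trend_class(self):
        for g in simulate_cross(LOCUS, "F1", 100, seed=5):
            if not g.carrier:
                assert g.trend_class is TrendClass.NONPRODUCER
            else:
                assert g.trend_class is not TrendClass.NONPRODUCER


class TestSimulatePanel:
    def test_composition_and_parents(self):
        panel = simulate_panel(SimConfig(seed=2))
        assert len(panel) == 16
        assert sum(carriers(panel)) == 11
        assert panel[0].role == "parent_producer" and panel[0].carrier
        assert panel[1].role == "parent_nonproducer" and not panel[1].carrier


class TestSimulateExpression:
    def test_noncarrier_causal_counts_zero_at_every_stage(self):
        cfg = SimConfig(n_genes=50, causal_gene_index=10, n_decoy_genes=5, seed=11)
        panel = simulate_panel(cfg)
        non = [g.id for g in panel if not g.carrier]
        for stage in ("green", "blushing", "ripe"):
            m = simulate_expression(panel, cfg, stage)
            assert (m.counts.loc[causal_gene_id(cfg), non] == 0).all()

    def test_unknown_stage_rejected(self):
        cfg = SimConfig(n_genes=10, causal_gene_index=0, n_decoy_genes=0)
        with pytest.raises(ValueError, match="unknown stage"):
            simulate_expression(simulate_panel(cfg), cfg, "overripe")

    def test_ripening_fold_recovered_monte_carlo(self):
        # mean causal count over many carriers, ripe vs blushing, should
        # recover the configured ripening factor within 3 standard errors
        cfg = SimConfig(
            n_genes=5, causal_gene_index=2, n_decoy_genes=0,
            detect_noise_sd=0.0, seed=23,
        )
        n = 3000
        panel = [
            SimGenotype(id=f"C{i:04d}", role="F1", carrier=True,
                        trend_class=TrendClass.PEAK)
            for i in range(n)
        ]
        gid = causal_gene_id(cfg)
        ripe = simulate_expression(panel, cfg, "ripe").counts.loc[gid].to_numpy(float)
        blush = simulate_expression(panel, cfg, "blushing").counts.loc[gid].to_numpy(float)
        ratio = ripe.mean() / blush.mean()
        se = ratio * math.sqrt(
            (ripe.std() / ripe.mean()) ** 2 / n + (blush.std() / blush.mean()) ** 2 / n
        )
        assert abs(ratio - cfg.ripening_fold) <= 3 * se

    def test_decoys_segregate_independently_of_phenotype(self):
        # with 50 decoys over 16 genotypes, the chance that any decoy's
        # presence vector matches the carrier vector (either orientation)
        # is 1-(1-2*0.5^16)^50 ~ 0.0015, so none should match here
        cfg = SimConfig(seed=31)
        panel = simulate_panel(cfg)
        m = simulate_expression(panel, cfg, "ripe")
        carrier_vec = np.array(carriers(panel))
        causal = causal_gene_id(cfg)
        detected = (m.counts > 0).to_numpy()
        matches = 0
        for i, gene in enumerate(m.counts.index):
            if gene == causal:
                continue
            if (detected[i] == carrier_vec).all() or (detected[i] == ~carrier_vec).all():
                matches += 1
        assert matches == 0

    def test_determinism(self):
        cfg = SimConfig(n_genes=30, causal_gene_index=3, n_decoy_genes=3, seed=9)
        panel = simulate_panel(cfg)
        a = simulate_expression(panel, cfg, "ripe")
        b = simulate_expression(panel, cfg, "ripe")
        assert a.counts.equals(b.counts)
        assert a.gene_lengths.equals(b.gene_lengths)


class TestSimulateVolatiles:
    CFG = SimConfig(seed=13)

    def test_noncarrier_never_exceeds_noise_floor(self):
        panel = simulate_panel(self.CFG)
        samples = simulate_volatile_tables(panel, self.CFG)
        non = {g.id for g in panel if not g.carrier}
        for s in samples:
            if s.genotype_id in non:
                assert s.gd_area / s.is_area <= self.CFG.volatile_baseline

    def test_peak_class_mid_harvest_greatest(self):
        g = SimGenotype(id="pk", role="F1", carrier=True, trend_class=TrendClass.PEAK)
        series = series_from_peaks(simulate_volatile_tables([g], self.CFG))["pk"]
        v = series.means.to_numpy()
        assert v[1] > v[0] and v[1] > v[2]

    def test_fewer_than_three_harvests_rejected(self):
        with pytest.raises(ValueError, match="at least three"):
            simulate_volatile_tables(simulate_panel(self.CFG), self.CFG, n_harvests=2)

    def test_environment_fold_recovered_monte_carlo(self):
        cfg = SimConfig(seed=17, volatile_noise_sd=0.1, n_replicates=2)
        n = 400
        panel = [
            SimGenotype(id=f"C{i:04d}", role="F1", carrier=True,
                        trend_class=TrendClass.PEAK)
            for i in range(n)
        ]
        samples = simulate_volatile_tables(
            panel, cfg, n_harvests=3,
            environments=["noninductive", "noninductive", "inductive"],
        )
        series = series_from_peaks(samples)
        v1 = np.mean([s.means.iloc[0] for s in series.values()])  # shape 1.0
        v3 = np.mean([s.means.iloc[2] for s in series.values()])  # shape 1.0 x env
        assert abs(v3 / v1 - cfg.env_effect_fold) / cfg.env_effect_fold < 0.10


class TestMarkerPanel:
    def test_deletion_consistency_of_marker_and_ssr(self):
        panel = simulate_panel(SimConfig(seed=19))
        markers, ssr = simulate_marker_panel(panel, seed=19)
        by_id = {g.id: g for g in panel}
        ssr_by_id = {s.genotype_id: s for s in ssr}
        for call in markers:
            carrier = by_id[call.genotype_id].carrier
            assert call.amplicon_present == carrier
            alleles = ssr_by_id[call.genotype_id].alleles
            assert (205 in alleles) == carrier
            assert 209 in alleles  # monomorphic, so never an empty set


class TestPileups:
    def test_planted_sites_pass_filter(self):
        cfg = SimConfig(seed=29, snp_pass_fraction=1.0)
        sites = simulate_pileups(50, 8, cfg)
        assert len(filter_snps(sites)) == 50

    def test_passing_fraction_matches_planted_fraction(self):
        cfg = SimConfig(seed=37, snp_pass_fraction=0.3)
        n = 10_000
        sites = simulate_pileups(n, 8, cfg)
        frac = len(filter_snps(sites)) / n
        assert abs(frac - 0.3) <= 3 * math.sqrt(0.3 * 0.7 / n)


class TestQPCRGenerator:
    def test_zero_noise_fold_one_is_exact(self):
        cfg = SimConfig(seed=41, ct_noise_sd=0.0)
        m = simulate_qpcr([], cfg, QPCRDesign(fold=1.0))
        res = ddct_fold_change(m, "ripe", "blushing")
        assert res.fold == 1.0 and res.ddct == 0.0

    def test_zero_noise_fold_two_gives_ddct_minus_one(self):
        cfg = SimConfig(seed=41, ct_noise_sd=0.0)
        m = simulate_qpcr([], cfg, QPCRDesign(fold=2.0))
        res = ddct_fold_change(m, "ripe", "blushing")
        assert res.ddct == pytest.approx(-1.0, abs=1e-12)
        assert res.fold == pytest.approx(2.0, abs=1e-12)

    def test_noisy_fold_recovered_within_5_percent(self):
        cfg = SimConfig(seed=43, ct_noise_sd=0.05)
        m = simulate_qpcr([], cfg, QPCRDesign(fold=21.0, n_replicates=1000))
        res = ddct_fold_change(m, "ripe", "blushing")
        assert abs(res.fold - 21.0) / 21.0 < 0.05

    def test_genotype_panel_noncarriers_never_amplify(self):
        cfg = SimConfig(seed=47)
        panel = simulate_panel(cfg)
        m = simulate_qpcr(panel, cfg, QPCRDesign(kind="genotype_panel"))
        non = {g.id for g in panel if not g.carrier}
        for meas in m:
            if meas.gene == TARGET and meas.sample_id in non:
                assert meas.ct is None


def test_full_deletion_consistency_invariant():
    """carrier=False <=> causal counts zero <=> no amplicon <=> no allele 205
    <=> volatile at or below the noise floor in every harvest."""
    cfg = SimConfig(seed=53)
    panel = simulate_panel(cfg)
    matrix = simulate_expression(panel, cfg, "ripe")
    samples = simulate_volatile_tables(panel, cfg)
    markers, ssr = simulate_marker_panel(panel, seed=53)
    series = series_from_peaks(samples)
    marker_by = {c.genotype_id: c.amplicon_present for c in markers}
    ssr_by = {s.genotype_id: s.alleles for s in ssr}
    causal = causal_gene_id(cfg)
    for g in panel:
        silent_expr = (matrix.counts.loc[causal, g.id] == 0)
        silent_vol = (series[g.id].means <= cfg.volatile_baseline).all()
        assert silent_expr == (not g.carrier)
        assert marker_by[g.id] == g.carrier
        assert (205 in ssr_by[g.id]) == g.carrier
        assert silent_vol == (not g.carrier)
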