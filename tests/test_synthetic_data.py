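"""Generators: determinism, truth self-consistency, generative/analytic duality."""

import numpy as np
import pytest

from mircons.errors import ConfigurationError, ParameterError, PlantingError
from mircons.qpcr_stats import compute_dcp, ddct_fold_change, mann_whitney, spearman
from mircons.synthetic_data import (
    PredictorProfile,
    SimTruth,
    simulate_cp_table,
    simulate_phenotype,
    simulate_predictor_calls,
    simulate_promoters,
    simulate_two_color_array,
    simulate_utr_set,
    substream,
)
from mircons.target_consensus import consensus_interactions

from _oracles import naive_motif_count, naive_seed_sites

MIRNAS = {
    "miR-17-like": "CAAAGUGCUUACAGUGCAGGUAG",
    "miR-144-like": "UACAGUAUAGAUGAUGUACU",
    "miR-22-like": "AAGCUGCCAGUUGAAGAACUGU",
    "miR-181a-like": "AACAUUCAACGCUGUCGGUGAGU",
    "miR-21-like": "UAGCUUAUCAGACUGAUGUUGA",
}


class TestSubstreams:
    def test_label_streams_are_independent_and_reproducible(self):
        a1 = substream(1, "x").normal(size=5)
        a2 = substream(1, "x").normal(size=5)
        b = substream(1, "y").normal(size=5)
        assert np.array_equal(a1, a2)
        assert not np.array_equal(a1, b)


class TestTwoColorArray:
    def test_de_count_follows_rounding_rule(self):
        sim = simulate_two_color_array(n_probes=580, n_arrays=10,
                                       de_fraction=0.06, seed=1)
        assert sim.truth["is_de"].sum() == 35          # round(0.06 * 580)
        assert len(sim.probe_ids) == 580

    def test_null_case_has_no_de_truth(self):
        sim = simulate_two_color_array(n_probes=100, n_arrays=6,
                                       de_fraction=0.0, seed=2)
        assert not sim.truth["is_de"].any()
        assert (sim.truth["true_log2_ratio"] == 0).all()

    def test_all_intensities_positive_and_controls_null(self):
        sim = simulate_two_color_array(n_probes=200, n_arrays=4, seed=3)
        for tab in (sim.foreground_red, sim.foreground_green,
                    sim.background_red, sim.background_green):
            assert (tab.to_numpy() > 0).all()
        assert (sim.truth.loc[sim.control_probe_ids, "true_log2_ratio"] == 0).all()

    def test_foreground_mean_matches_closed_form(self):
        # E[fg] = bg_mean + signal_mean for null probes
        sim = simulate_two_color_array(n_probes=10_000, n_arrays=2,
                                       de_fraction=0.0, bg_mean=100, bg_sd=15,
                                       signal_mean=200, seed=4)
        fg = sim.foreground_green.to_numpy().ravel()
        se = np.sqrt((15**2 + 200**2) / fg.size)
        assert abs(fg.mean() - 300) < 3 * se

    def test_determinism_and_seed_sensitivity(self):
        a = simulate_two_color_array(n_probes=50, n_arrays=4, seed=7)
        b = simulate_two_color_array(n_probes=50, n_arrays=4, seed=7)
        c = simulate_two_color_array(n_probes=50, n_arrays=4, seed=8)
        assert a.foreground_red.equals(b.foreground_red)
        assert not a.foreground_red.equals(c.foreground_red)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            simulate_two_color_array(n_probes=0)
        with pytest.raises(ParameterError):
            simulate_two_color_array(bg_sd=0)
        with pytest.raises(ParameterError):
            simulate_two_color_array(de_fraction=1.5)


class TestCpTable:
    def test_noise_free_inversion_is_exact(self):
        sim = simulate_cp_table(["Hprt", "g"], n_per_group=3,
                                true_log2fc={"g": -1.0}, cp_noise_sd=0.0, seed=1)
        dcp = compute_dcp(sim.to_cp_table())
        ddct, fc = ddct_fold_change(dcp, "g")
        assert ddct == pytest.approx(1.0)
        assert fc == pytest.approx(0.5)

    def test_reference_must_be_null_and_present(self):
        with pytest.raises(ConfigurationError):
            simulate_cp_table(["g"], true_log2fc={"g": 1.0}, reference_gene="Hprt")
        with pytest.raises(ConfigurationError):
            simulate_cp_table(["Hprt", "g"], true_log2fc={"Hprt": 1.0})

    def test_null_simulation_p_values_spread_over_support(self):
        # under H0 the exact MW p is discrete; check it is not degenerate
        ps = []
        for seed in range(40):
            sim = simulate_cp_table(["Hprt", "g"], n_per_group=5,
                                    cp_noise_sd=0.3, seed=seed)
            dcp = compute_dcp(sim.to_cp_table())
            groups = sim.group_labels
            x = dcp.dcp.loc[groups == "treated", "g"].to_numpy()
            y = dcp.dcp.loc[groups == "control", "g"].to_numpy()
            ps.append(mann_whitney(x, y)[1])
        ps = np.asarray(ps)
        assert (ps <= 0.05).mean() <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 40)
        assert len(np.unique(ps)) > 3


class TestUtrSet:
    def test_creb1_like_composition_planted_exactly(self):
        counts = {"Creb1-like": {"miR-17-like": 3, "miR-144-like": 1,
                                 "miR-22-like": 2, "miR-181a-like": 2}}
        sim = simulate_utr_set(10, 400, MIRNAS, counts, seed=1)
        creb_sites = [s for s in sim.truth_sites if s.gene == "Creb1-like"]
        assert len(creb_sites) == 8

    def test_truth_sites_validated_by_independent_naive_scan(self):
        counts = {"g1": {"miR-17-like": 2}, "g2": {"miR-21-like": 1}}
        sim = simulate_utr_set(6, 300, MIRNAS, counts, seed=2)
        for mid, mseq in MIRNAS.items():
            for gene, utr in sim.utr_sequences.items():
                found = naive_seed_sites(mseq, utr)
                truth = {(s.start, s.end, s.site_type) for s in sim.truth_sites
                         if s.gene == gene and s.mirna == mid}
                assert found == truth

    def test_no_planting_means_no_sites_anywhere(self):
        sim = simulate_utr_set(8, 250, MIRNAS, {}, seed=3)
        for mseq in MIRNAS.values():
            for utr in sim.utr_sequences.values():
                assert naive_seed_sites(mseq, utr) == set()

    def test_same_gene_truth_sites_do_not_overlap(self):
        sim = simulate_utr_set(4, 500, MIRNAS,
                               {"g1": {"miR-17-like": 5, "miR-22-like": 5}}, seed=4)
        sites = sorted((s.start, s.end) for s in sim.truth_sites if s.gene == "g1")
        for (s1, e1), (s2, e2) in zip(sites, sites[1:]):
            assert s2 >= e1 + 2       # >= 2 nt spacer

    def test_infeasible_density_raises(self):
        with pytest.raises(PlantingError):
            simulate_utr_set(1, 30, MIRNAS, {"g": {"miR-17-like": 5}}, seed=5)

    def test_determinism(self):
        a = simulate_utr_set(5, 200, MIRNAS, {"g": {"miR-17-like": 1}}, seed=6)
        b = simulate_utr_set(5, 200, MIRNAS, {"g": {"miR-17-like": 1}}, seed=6)
        assert a.utr_sequences == b.utr_sequences
        assert a.truth_sites == b.truth_sites


class TestPredictorCalls:
    @pytest.fixture()
    def utr_sim(self):
        return simulate_utr_set(
            10, 400, MIRNAS,
            {"g1": {"miR-17-like": 2, "miR-144-like": 1},
             "g2": {"miR-22-like": 3}}, seed=1)

    def test_perfect_predictors_reproduce_truth(self, utr_sim):
        profiles = [PredictorProfile(f"p{i}") for i in range(5)]
        calls = simulate_predictor_calls(utr_sim, profiles, seed=1)
        truth = sorted((s.gene, s.mirna, s.start, s.end)
                       for s in utr_sim.truth_sites)
        for name, sites in calls.items():
            assert sorted((s.gene, s.mirna, s.start, s.end) for s in sites) == truth

    def test_perfect_full_consensus_recovers_truth_pairs(self, utr_sim):
        profiles = [PredictorProfile(f"p{i}") for i in range(5)]
        calls = simulate_predictor_calls(utr_sim, profiles, seed=1)
        targets = consensus_interactions(calls, k=5)
        pairs = {(t.gene, m) for t in targets for m in t.merged_sites}
        assert pairs == {(s.gene, s.mirna) for s in utr_sim.truth_sites}
        counts = {(t.gene, m): c for t in targets for m, c in t.merged_sites.items()}
        assert counts[("g1", "miR-17-like")] == 2
        assert counts[("g2", "miR-22-like")] == 3

    def test_zero_sensitivity_is_empty(self, utr_sim):
        calls = simulate_predictor_calls(
            utr_sim, [PredictorProfile("dead", sensitivity=0.0)], seed=1)
        assert calls["dead"] == []

    def test_pair_recall_matches_binomial_closed_form(self):
        # one site per pair; k=5 consensus keeps a pair w.p. sensitivity^5
        sim = simulate_utr_set(
            30, 120, {"miR-17-like": MIRNAS["miR-17-like"]},
            {f"g{i}": {"miR-17-like": 1} for i in range(30)}, seed=2)
        sens, n_pred, reps = 0.9, 5, 30
        hits = total = 0
        for rep in range(reps):
            profiles = [PredictorProfile(f"p{i}", sensitivity=sens)
                        for i in range(n_pred)]
            calls = simulate_predictor_calls(sim, profiles, seed=100 + rep)
            targets = consensus_interactions(calls, k=n_pred)
            kept = {(t.gene, m) for t in targets for m in t.merged_sites}
            hits += len(kept)
            total += 30
        p_expected = sens**n_pred
        se = np.sqrt(p_expected * (1 - p_expected) / total)
        assert abs(hits / total - p_expected) < 3 * se

    def test_false_calls_scale_with_rate(self, utr_sim):
        calls = simulate_predictor_calls(
            utr_sim, [PredictorProfile("fp", sensitivity=0.0,
                                       false_calls_per_kb=5.0)], seed=3)
        # 10 genes x 400 nt x 5/kb = 20 expected false calls
        assert 5 < len(calls["fp"]) < 50

    def test_profile_validation(self):
        with pytest.raises(ParameterError):
            PredictorProfile("bad", sensitivity=1.5)
        with pytest.raises(ParameterError):
            PredictorProfile("bad", coordinate_jitter=4)


class TestPromoters:
    def test_planted_counts_are_exact(self):
        sim = simulate_promoters(20, length=600,
                                 planted={"g1": 2, "g2": 1, "g3": 0}, seed=1)
        assert naive_motif_count(sim.promoter_sequences["g1"], "TGACGTCA") == 2
        assert naive_motif_count(sim.promoter_sequences["g2"], "TGACGTCA") == 1
        for gene, seq in sim.promoter_sequences.items():
            expected = len(sim.truth_cre[gene])
            assert naive_motif_count(seq, "TGACGTCA") == expected

    def test_truth_positions_hold_the_motif(self):
        sim = simulate_promoters(5, length=400, planted={"g1": 3}, seed=2)
        for gene, starts in sim.truth_cre.items():
            for s in starts:
                assert sim.promoter_sequences[gene][s:s + 8] == "TGACGTCA"

    def test_infeasible_density(self):
        with pytest.raises(PlantingError):
            simulate_promoters(1, length=30, planted={"g1": 4}, seed=3)


class TestPhenotype:
    @pytest.fixture()
    def dcp(self):
        sim = simulate_cp_table(["Hprt", "gA", "gB"], n_per_group=6,
                                true_log2fc={"gA": 2.0}, cp_noise_sd=0.4, seed=1)
        return compute_dcp(sim.to_cp_table())

    def test_noise_free_coupling_gives_rho_plus_minus_one(self, dcp):
        pheno_up = simulate_phenotype(dcp, ["gA"], slope=2.0, noise_sd=0.0, seed=1)
        rho, _ = spearman(dcp.dcp["gA"].to_numpy(), pheno_up.to_numpy())
        assert rho == pytest.approx(1.0)
        pheno_dn = simulate_phenotype(dcp, ["gA"], slope=-2.0, noise_sd=0.0, seed=1)
        rho, _ = spearman(dcp.dcp["gA"].to_numpy(), pheno_dn.to_numpy())
        assert rho == pytest.approx(-1.0)

    def test_empty_or_unknown_coupling_rejected(self, dcp):
        with pytest.raises(ConfigurationError):
            simulate_phenotype(dcp, [], slope=1.0)
        with pytest.raises(ConfigurationError):
            simulate_phenotype(dcp, ["nope"], slope=1.0)


class TestSimTruth:
    def test_round_trip_through_dict(self):
        truth = SimTruth(
            seed=7,
            array_truth={"p1": (1.5, True), "p2": (0.0, False)},
            cp_truth={"g": -1.0},
            utr_sites=[("g", "m", 3, 11, "8mer")],
            cre_positions={"g": [10, 40]},
        )
        assert SimTruth.from_dict(truth.to_dict()) == truth
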