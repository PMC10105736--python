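"""Synthetic generators: determinism, limit cases, distributional checks."""

import numpy as np
import pytest

from y2hnet.mappit_fdr import validate_batches
from y2hnet.netcore import Pair
from y2hnet.screen_sim import (
    BatchParams,
    make_screen_truth,
    simulate_interactome,
    simulate_pooled_screen,
    simulate_retests,
    simulate_rnai_outcomes,
    simulate_validation_scores,
)


class TestSimulateInteractome:
    def test_edge_count_near_target(self):
        net, _ = simulate_interactome(100, mean_degree=4.0, seed=0)
        assert 150 <= net.n_edges <= 200  # target 200, duplicates rejected

    def test_zero_mixing_all_intra_module(self):
        net, bundle = simulate_interactome(80, 3.0, module_count=4, mixing=0.0, seed=1)
        for e in net.edges:
            assert bundle.module_of[e.a] == bundle.module_of[e.b]

    def test_deterministic(self):
        a, _ = simulate_interactome(60, 4.0, seed=9)
        b, _ = simulate_interactome(60, 4.0, seed=9)
        assert a.edges == b.edges

    def test_infeasible_degree_rejected(self):
        with pytest.raises(ValueError):
            simulate_interactome(10, mean_degree=20.0)
        with pytest.raises(ValueError):
            simulate_interactome(5)

    def test_annotations_consistent(self):
        net, bundle = simulate_interactome(80, 3.0, seed=2)
        genes = net.nodes
        for members in bundle.gene_sets.values():
            assert members <= genes
        # pub_counts derived from gene_pubs
        derived = {g: 0 for g in genes}
        for pub_genes in bundle.gene_pubs.values():
            for g in pub_genes:
                derived[g] += 1
        assert derived == bundle.pub_counts

    def test_heavy_tailed_degrees(self):
        net, _ = simulate_interactome(400, 4.0, gamma=2.3, seed=3)
        degs = np.array(net.degree_sequence())
        assert degs.max() >= 4 * degs.mean()


class TestScreenTruth:
    def test_pools_partition_universe(self):
        net, _ = simulate_interactome(100, 4.0, seed=0)
        truth = make_screen_truth(net, pool_size=30, seed=0)
        pools = truth.pools()
        all_members = [g for mem in pools.values() for g in mem]
        assert sorted(all_members) == sorted(net.nodes)
        assert max(len(m) for m in pools.values()) <= 30

    def test_batches_from_versions_and_replicates(self):
        net, _ = simulate_interactome(50, 3.0, seed=0)
        truth = make_screen_truth(
            net, assay_sensitivity={"v1": 0.7, "v3": 0.9},
            replicates_per_version=2, seed=0,
        )
        assert truth.batches() == ["v1_s1", "v1_s2", "v3_s1", "v3_s2"]


class TestPooledScreen:
    def _truth(self, sens, aa_fraction=0.0, lam_bg=0.5, n=40, seed=0):
        net, _ = simulate_interactome(n, 3.0, seed=seed)
        return net, make_screen_truth(
            net, pool_size=20,
            assay_sensitivity={"v1": sens}, replicates_per_version=1,
            aa_fraction=aa_fraction,
            batch_params=BatchParams(lam_sig=50.0, lam_bg=lam_bg),
            seed=seed,
        )

    def test_noise_free_signal_only_at_true_edges(self):
        net, truth = self._truth(sens=1.0, lam_bg=0.0)
        baits = sorted(net.nodes)[:10]
        reads = simulate_pooled_screen(truth, baits, seed=1)
        ad = reads[reads["role"] == "AD"]
        nonzero = ad[ad["reads"] > 0]
        for _, row in nonzero.iterrows():
            assert Pair(row["bait_id"], row["orf_id"]) in net.edges

    def test_zero_sensitivity_background_poisson(self):
        net, truth = self._truth(sens=0.0, lam_bg=0.5)
        baits = sorted(net.nodes)[:10]
        reads = simulate_pooled_screen(truth, baits, seed=1)
        x = reads.loc[reads["role"] == "AD", "reads"].to_numpy()
        se = np.sqrt(0.5 / len(x))
        assert abs(x.mean() - 0.5) < 3 * se

    def test_true_edge_reads_mean_near_signal_rate(self):
        net, truth = self._truth(sens=1.0, lam_bg=0.0, n=60)
        baits = sorted(net.nodes)
        reads = simulate_pooled_screen(truth, baits, seed=2)
        ad = reads[reads["role"] == "AD"]
        is_edge = [
            Pair(b, o) in net.edges for b, o in zip(ad["bait_id"], ad["orf_id"])
        ]
        x = ad.loc[is_edge, "reads"].to_numpy()
        assert len(x) > 50
        se = np.sqrt(50.0 / len(x))
        assert abs(x.mean() - 50.0) < 3 * se

    def test_db_row_per_well(self):
        net, truth = self._truth(sens=0.5)
        baits = sorted(net.nodes)[:5]
        reads = simulate_pooled_screen(truth, baits, seed=0)
        per_well = reads.groupby("well")["role"].apply(lambda r: (r == "DB").sum())
        assert (per_well == 1).all()

    def test_unknown_bait_rejected(self):
        net, truth = self._truth(sens=0.5)
        with pytest.raises(ValueError):
            simulate_pooled_screen(truth, ["NOT_A_GENE"], seed=0)

    def test_deterministic_in_seed(self):
        net, truth = self._truth(sens=0.5)
        baits = sorted(net.nodes)[:5]
        a = simulate_pooled_screen(truth, baits, seed=3)
        b = simulate_pooled_screen(truth, baits, seed=3)
        assert a.equals(b)


class TestRetestSimulation:
    def test_autoactivator_baits_flagged_in_adnull(self):
        net, _ = simulate_interactome(40, 3.0, seed=0)
        truth = make_screen_truth(net, pool_size=20, aa_fraction=0.2, seed=0)
        baits = sorted(net.nodes)
        cands = [(b, sorted(net.nodes)[0]) for b in baits[:20]]
        _, adnull = simulate_retests(cands, truth, seed=0)
        for bait, flagged in adnull.items():
            assert flagged == (bait in truth.autoactivators)


class TestValidationScores:
    def test_rrs_block_size_per_batch(self):
        from y2hnet.netcore import Network

        ms = simulate_validation_scores(
            [], Network(), n_rrs=25, n_prs=10, n_batches=3, seed=0
        )
        for b in range(1, 4):
            block = [m for m in ms if m.batch == f"vbatch{b}" and m.set_label == "RRS"]
            assert len(block) == 25

    def test_null_equal_to_rrs_gives_one_percent_positives(self):
        from y2hnet.netcore import Network

        pairs = [Pair(f"pA{i:04d}", f"pB{i:04d}") for i in range(2000)]
        ms = simulate_validation_scores(
            pairs, Network(), mu0=0.0, mu1=1.5, n_rrs=500, n_prs=0, seed=4
        )
        # pairs are absent from the (empty) truth network -> same null as RRS
        calls, _ = validate_batches(ms)
        tested = [c for c in calls if c.set_label == "screen"]
        rate = sum(c.call == "positive" for c in tested) / len(tested)
        assert abs(rate - 0.01) < 3 * np.sqrt(0.01 * 0.99 / 2000) + 0.005

    def test_strong_separation_high_power(self):
        from y2hnet.netcore import Network

        truth = Network.from_edges([(f"tA{i:04d}", f"tB{i:04d}") for i in range(500)])
        pairs = sorted(truth.edges)
        ms = simulate_validation_scores(
            pairs, truth, mu0=0.0, mu1=2.0, sigma=0.5, n_rrs=216, n_prs=0, seed=5
        )
        calls, _ = validate_batches(ms)
        tested = [c for c in calls if c.set_label == "screen"]
        rate = sum(c.call == "positive" for c in tested) / len(tested)
        assert rate > 0.9  # mu1 - mu0 = 4 sigma

    def test_mu1_below_mu0_warns(self):
        from y2hnet.netcore import Network

        with pytest.warns(UserWarning):
            simulate_validation_scores([], Network(), mu0=1.0, mu1=0.5, seed=0)


class TestRnaiOutcomes:
    def test_extreme_rates(self):
        lines = simulate_rnai_outcomes({"a", "b"}, {"c"}, p_net=1.0, p_rand=0.0, seed=0)
        net_lines = [ln for ln in lines if ln.set_label == "autophagy"]
        rand_lines = [ln for ln in lines if ln.set_label == "random"]
        assert all(ln.modifier for ln in net_lines)
        assert not any(ln.modifier for ln in rand_lines)

    def test_empirical_rate_within_binomial_error(self):
        genes = {f"n{i}" for i in range(200)}
        lines = simulate_rnai_outcomes(genes, set(), p_net=0.5, p_rand=0.25, seed=1)
        rate = np.mean([ln.modifier for ln in lines])
        se = np.sqrt(0.25 / len(lines))
        assert abs(rate - 0.5) < 3 * se

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            simulate_rnai_outcomes({"a"}, {"a"}, seed=0)

    def test_line_ids_unique_within_gene(self):
        lines = simulate_rnai_outcomes(
            {f"n{i}" for i in range(30)}, set(), lines_per_gene=(1, 5), seed=2
        )
        seen = set()
        for ln in lines:
            assert (ln.gene, ln.line_id) not in seen
            seen.add((ln.gene, ln.line_id))
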