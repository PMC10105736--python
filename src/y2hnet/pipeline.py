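"""End-to-end driver: simulate -> screen -> score -> predict -> validate
-> integrate -> enrich -> expand.

Each stage writes plain TSV outputs into the run directory and
contributes to a machine-readable ``summary.json``; no stage mutates
another stage's outputs, so rerunning a downstream stage with unchanged
upstream inputs is idempotent.  All randomness descends from the single
configured root seed through named substreams.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import integrate_ref, l3_predict, mappit_fdr, null_stats, screen_sim, seed_expand
from .config import PipelineConfig
from .netcore import GeneId, Network, Pair, write_edge_tsv, write_mitab
from .swim_calling import (
    RetestCall,
    calls_by_pair,
    call_fipps,
    classify_retest,
    positive_pairs,
    remove_denovo_autoactivators,
    score_wells,
    wells_from_read_table,
)

__all__ = [
    "run_pipeline",
    "report",
    "screen_and_call",
    "recovery_benchmark",
    "fdr_calibration_benchmark",
    "modifier_rate_benchmark",
]

log = logging.getLogger("y2hnet")

_STAGE_NAMES = (
    "interactome", "screen", "retest", "l3", "l3_retest",
    "validation", "integrate", "enrich", "expand",
)


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return {
        name: np.random.default_rng(child)
        for name, child in zip(_STAGE_NAMES, children)
    }


def screen_and_call(
    truth: screen_sim.ScreenTruth,
    baits: Sequence[GeneId],
    cfg: PipelineConfig,
    rng_screen: np.random.Generator,
    rng_retest: np.random.Generator,
) -> tuple[set[Pair], list[RetestCall], pd.DataFrame, list[tuple[GeneId, GeneId]]]:
    """Primary screen through retest: reads -> SWIM -> FiPPs -> calls.

    Returns the final positive pair set, the per-orientation retest
    calls (after AD-null auto-activator removal), the scored-well table,
    and the oriented first-pass pairs.
    """
    reads = screen_sim.simulate_pooled_screen(truth, baits, seed=rng_screen)
    bp = next(iter(truth.batch_params.values()))
    wells = wells_from_read_table(reads, (bp.M, bp.N))
    scored = score_wells(wells)
    fipps = call_fipps(scored, quantile=cfg.screen.fipp_quantile)
    log.info("screen: %d wells scored, %d FiPPs", len(scored), len(fipps))
    obs, adnull = screen_sim.simulate_retests(
        fipps,
        truth,
        seed=rng_retest,
        retest_sensitivity=cfg.retest.sensitivity,
        false_rate=cfg.retest.false_rate,
        unscorable_rate=cfg.retest.unscorable_rate,
    )
    calls = [
        classify_retest(o, cfg.retest.delta, cfg.retest.g_min, cfg.retest.c_max)
        for o in obs
    ]
    calls = remove_denovo_autoactivators(calls, adnull)
    return positive_pairs(calls), calls, scored, fipps


def _screen_metrics(
    positives: set[Pair],
    truth: screen_sim.ScreenTruth,
    baits: Sequence[GeneId],
) -> dict:
    bait_set = set(baits)
    screened_truth = {
        e for e in truth.truth_net.edges if e.a in bait_set or e.b in bait_set
    }
    tp = len(positives & screened_truth)
    precision = tp / len(positives) if positives else float("nan")
    recall = tp / len(screened_truth) if screened_truth else float("nan")
    return {
        "n_positive_pairs": len(positives),
        "n_truth_edges_screened": len(screened_truth),
        "precision_vs_truth": precision,
        "recall_vs_truth": recall,
    }


def recovery_benchmark(
    seed: int = 0,
    n_genes: int = 300,
    mean_degree: float = 4.0,
    pool_size: int = 100,
    sensitivity: float = 0.8,
    lam_sig: float = 50.0,
    lam_bg: float = 0.5,
    aa_fraction: float = 0.0,
) -> dict:
    """Truth-recovery experiment: screen a simulated interactome end to end.

    Runs the full primary-screen path (pooled reads, SWIM scores,
    per-batch FiPP cutoffs, pairwise retests, AD-null auto-activator
    removal) against a known ground truth and reports precision and
    recall of the recovered pair set over the screened search space.
    With ``aa_fraction > 0`` auto-activating baits are screened too and
    the fraction of auto-activator-derived false pairs eliminated before
    the final positive set is reported.
    """
    cfg = PipelineConfig()
    cfg.screen.pool_size = pool_size
    cfg.screen.sensitivity = {"v1": sensitivity, "v3": sensitivity}
    cfg.screen.lam_sig = lam_sig
    cfg.screen.lam_bg = lam_bg
    cfg.screen.aa_fraction = aa_fraction
    rng_int, rng_screen, rng_retest = (
        np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(3)
    )
    net, _ = screen_sim.simulate_interactome(n_genes, mean_degree, seed=rng_int)
    truth = screen_sim.make_screen_truth(
        net,
        pool_size=pool_size,
        assay_sensitivity=cfg.screen.sensitivity,
        aa_fraction=aa_fraction,
        batch_params=screen_sim.BatchParams(lam_sig=lam_sig, lam_bg=lam_bg),
        seed=rng_int,
    )
    baits = sorted(net.nodes)  # auto-activators screened too (de novo removal)
    positives, calls, _, fipps = screen_and_call(
        truth, baits, cfg, rng_screen, rng_retest
    )
    out = _screen_metrics(positives, truth, baits)
    aa_false = {
        Pair(b, p)
        for b, p in fipps
        if b in truth.autoactivators and Pair(b, p) not in net.edges
    }
    if aa_false:
        eliminated = sum(1 for p in aa_false if p not in positives)
        out["aa_false_fipp_pairs"] = len(aa_false)
        out["aa_elimination_rate"] = eliminated / len(aa_false)
    return out


def fdr_calibration_benchmark(
    seed: int = 0, n_rrs: int = 216, n_test: int = 1000
) -> dict:
    """False-positive rate of validation calling under a pure null.

    One batch: ``n_rrs`` random-reference scores and ``n_test`` test
    pairs drawn from the identical log-normal null; the threshold is the
    empirical 99th percentile of the RRS block, so on average 1% of the
    test pairs exceed it.
    """
    pairs = [Pair(f"nullA{i:05d}", f"nullB{i:05d}") for i in range(n_test)]
    ms = screen_sim.simulate_validation_scores(
        pairs, Network(), n_rrs=n_rrs, n_prs=0, n_batches=1,
        seed=np.random.default_rng(seed),
    )
    calls, _ = mappit_fdr.validate_batches(ms)
    tested = [c for c in calls if c.set_label == "screen"]
    n_pos = sum(1 for c in tested if c.call == "positive")
    return {
        "n_test": len(tested),
        "n_positive": n_pos,
        "positive_rate": n_pos / len(tested),
    }


def modifier_rate_benchmark(
    seed: int = 0,
    n_network_genes: int = 170,
    n_random_genes: int = 106,
    p_net: float = 0.5,
    p_rand: float = 0.25,
    n_repeats: int = 5,
) -> dict:
    """Network-derived vs random-gene RNAi modifier rates, line-balanced.

    The network set carries several RNAi lines per gene, so its rate is
    taken as the mean over ``n_repeats`` one-line-per-gene subsamples;
    the random control set has one line per gene by construction.
    """
    rng = np.random.default_rng(seed)
    net_genes = {f"NETG{i:04d}" for i in range(n_network_genes)}
    rand_genes = {f"RNDG{i:04d}" for i in range(n_random_genes)}
    lines = screen_sim.simulate_rnai_outcomes(
        net_genes, rand_genes, p_net=p_net, p_rand=p_rand, seed=rng
    )
    net_lines = [ln for ln in lines if ln.set_label == "autophagy"]
    rand_lines = [ln for ln in lines if ln.set_label == "random"]
    rates, mean_rate = seed_expand.subsample_one_line_per_gene(
        net_lines, n_repeats=n_repeats, seed=rng
    )
    return {
        "network_subsample_rates": rates,
        "network_subsample_mean": mean_rate,
        "random_rate": seed_expand.modifier_rate(rand_lines),
        "n_network_genes": n_network_genes,
        "n_random_genes": n_random_genes,
    }


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all enabled stages; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = _stage_rngs(cfg.seed)
    summary: dict = {"seed": cfg.seed}

    # --- ground truth -----------------------------------------------------
    ic = cfg.interactome
    truth_net, bundle = screen_sim.simulate_interactome(
        ic.n_genes, ic.mean_degree, ic.gamma, ic.module_count, ic.mixing,
        seed=rngs["interactome"],
    )
    truth = screen_sim.make_screen_truth(
        truth_net,
        pool_size=cfg.screen.pool_size,
        assay_sensitivity=cfg.screen.sensitivity,
        aa_fraction=cfg.screen.aa_fraction,
        replicates_per_version=cfg.screen.replicates_per_version,
        batch_params=screen_sim.BatchParams(
            M=cfg.screen.M, N=cfg.screen.N,
            lam_sig=cfg.screen.lam_sig, lam_bg=cfg.screen.lam_bg,
            depth=cfg.screen.depth,
        ),
        seed=rngs["interactome"],
    )
    write_edge_tsv(truth_net, out / "truth_edges.tsv")
    summary["interactome"] = {
        "n_genes": truth_net.n_nodes,
        "n_truth_edges": truth_net.n_edges,
        "n_autoactivators": len(truth.autoactivators),
    }
    log.info("interactome: %d genes, %d edges", truth_net.n_nodes, truth_net.n_edges)

    positives: set[Pair] = set()
    if cfg.stages.screen:
        baits = sorted(truth_net.nodes - truth.autoactivators)
        positives, calls, scored, _ = screen_and_call(
            truth, baits, cfg, rngs["screen"], rngs["retest"]
        )
        scored.to_csv(out / "scored_wells.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"bait": c.bait, "prey": c.prey, "call": c.call} for c in calls]
        ).to_csv(out / "retest_calls.tsv", sep="\t", index=False)
        screen_net = Network.from_edges(positives, source="screen")
        write_edge_tsv(screen_net, out / "screen_positives.tsv")
        summary["screen"] = _screen_metrics(positives, truth, baits)
        log.info("screen: %s", summary["screen"])

    if cfg.stages.l3 and positives:
        screen_net = Network.from_edges(positives)
        preds = l3_predict.rank_candidates(screen_net, cfg.l3.top_k)
        pd.DataFrame(
            [
                {"gene_a": p.pair.a, "gene_b": p.pair.b,
                 "score": p.score, "rank": p.rank}
                for p in preds
            ]
        ).to_csv(out / "l3_predictions.tsv", sep="\t", index=False)
        pred_orient = [(p.pair.a, p.pair.b) for p in preds]
        obs, adnull = screen_sim.simulate_retests(
            pred_orient, truth, seed=rngs["l3_retest"],
            retest_sensitivity=cfg.retest.sensitivity,
            false_rate=cfg.retest.false_rate,
            unscorable_rate=cfg.retest.unscorable_rate,
        )
        pcalls = remove_denovo_autoactivators(
            [
                classify_retest(o, cfg.retest.delta, cfg.retest.g_min, cfg.retest.c_max)
                for o in obs
            ],
            adnull,
        )
        call_map = calls_by_pair(pcalls)
        for p in preds:  # dropped positives become undetermined, not missing
            call_map.setdefault(p.pair, "NA")
        k = min(cfg.l3.top_k, len(preds))
        if k:
            n_tested, n_und, n_pos, prec = l3_predict.precision_at_k(
                preds, call_map, k
            )
            summary["l3"] = {
                "k": k, "n_tested": n_tested, "n_undetermined": n_und,
                "n_positive": n_pos, "precision": prec,
            }
            log.info("l3: %s", summary["l3"])

    if cfg.stages.validation:
        vc = cfg.validation
        rng = rngs["validation"]
        pos_sample = sorted(positives)[: vc.n_screen_pairs]
        measurements = screen_sim.simulate_validation_scores(
            pos_sample, truth_net,
            mu0=vc.mu0, mu1=vc.mu1, sigma=vc.sigma,
            n_rrs=vc.n_rrs, n_prs=vc.n_prs, n_batches=vc.n_batches,
            seed=rng,
        )
        calls_v, thresholds = mappit_fdr.validate_batches(measurements, q=vc.quantile)
        rep = mappit_fdr.recovery_report(calls_v)
        rep.to_csv(out / "validation_recovery.tsv", sep="\t", index=False)
        summary["validation"] = {
            "thresholds": thresholds,
            "recovery": rep.to_dict(orient="records"),
        }
        log.info("validation: thresholds %s", thresholds)

    if cfg.stages.integrate:
        rng = rngs["integrate"]
        icfg = cfg.integrate
        edges_sorted = sorted(truth_net.edges)
        genes_sorted = sorted(truth_net.nodes)
        # simulated legacy study: true edges score high, noise pairs low
        n_true = int(icfg.n_legacy * icfg.legacy_true_fraction)
        legacy: list[integrate_ref.ScoredLegacyPair] = []
        take = rng.choice(len(edges_sorted), size=min(n_true, len(edges_sorted)),
                          replace=False)
        for i in take:
            legacy.append(
                integrate_ref.ScoredLegacyPair(
                    edges_sorted[i], float(np.clip(rng.normal(0.8, 0.1), 0, 1))
                )
            )
        while len(legacy) < icfg.n_legacy:
            a, b = rng.choice(len(genes_sorted), size=2, replace=False)
            p = Pair(genes_sorted[a], genes_sorted[b])
            if p in truth_net.edges:
                continue
            legacy.append(
                integrate_ref.ScoredLegacyPair(
                    p, float(np.clip(rng.normal(0.4, 0.15), 0, 1))
                )
            )
        legacy_kept = integrate_ref.filter_legacy_by_score(legacy, icfg.legacy_cutoff)
        # simulated literature evidence over true edges
        methods = ["MI:0018", "MI:0397", "MI:0809"]
        ev: list[integrate_ref.EvidenceRecord] = []
        lit_take = rng.choice(
            len(edges_sorted), size=min(icfg.n_lit_pairs, len(edges_sorted)),
            replace=False,
        )
        for j, i in enumerate(lit_take):
            n_lines = 1 + int(rng.random() < 0.5)
            for li in range(n_lines):
                ev.append(
                    integrate_ref.EvidenceRecord(
                        edges_sorted[i], f"LITPUB{j:04d}_{li}",
                        methods[int(rng.integers(len(methods)))], "binary_direct",
                    )
                )
        lit_class = integrate_ref.classify_literature(ev)
        litbm = {p for p, c in lit_class.items() if c == "Lit-BM"}
        reference = integrate_ref.build_reference(positives, legacy_kept, litbm)
        write_edge_tsv(reference, out / "reference_network.tsv")
        write_mitab(reference, out / "reference_network.mitab")
        space = integrate_ref.SearchSpace(
            baits=set(genes_sorted), preys=set(genes_sorted)
        )
        table, odds, pval = integrate_ref.overlap_fisher(
            positives, legacy_kept, space
        )
        summary["integrate"] = {
            "n_legacy_kept": len(legacy_kept),
            "n_litbm": len(litbm),
            "n_litbs": sum(1 for c in lit_class.values() if c == "Lit-BS"),
            "reference_edges": reference.n_edges,
            "reference_nodes": reference.n_nodes,
            "overlap_table": table,
            "overlap_odds_ratio": odds,
            "overlap_p": pval,
        }
        log.info("integrate: %d reference edges", reference.n_edges)

    if cfg.stages.enrich and positives:
        ec = cfg.enrich
        rng = rngs["enrich"]
        screen_net = Network.from_edges(positives)
        res = []
        res.append(
            null_stats.enrichment_vs_null(
                screen_net,
                lambda n: null_stats.shared_term_fraction(
                    n, bundle.gene_sets, ec.max_term_size
                ),
                n_null=ec.n_null, seed=rng, name="shared_term_fraction",
            )
        )
        res.append(
            null_stats.enrichment_vs_null(
                screen_net,
                lambda n: null_stats.colocalization_fraction(n, bundle.organelle),
                n_null=ec.n_null, seed=rng, name="colocalization_fraction",
            )
        )
        res.append(
            null_stats.enrichment_vs_null(
                screen_net,
                lambda n: null_stats.cocitation_counts(
                    n, bundle.gene_pubs, ec.max_genes_per_pub
                )[1],
                n_null=ec.n_null, seed=rng, name="mean_cocitation",
            )
        )
        res.append(
            null_stats.enrichment_vs_null(
                screen_net,
                lambda n: null_stats.coexpression_shared_celltypes(n, bundle.expr),
                n_null=ec.n_null, seed=rng, name="mean_shared_celltypes",
            )
        )
        rep = null_stats.enrichment_report(res)
        rep.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        mat = null_stats.adjacency_bin_matrix(
            screen_net, bundle.pub_counts, ec.n_bins
        )
        np.savetxt(out / "adjacency_bins.tsv", mat, fmt="%d", delimiter="\t")
        summary["enrich"] = rep.to_dict(orient="records")
        log.info("enrich: %d statistics vs %d nulls", len(res), ec.n_null)

    if cfg.stages.expand and positives:
        xc = cfg.expand
        rng = rngs["expand"]
        screen_net = Network.from_edges(positives)
        nodes_sorted = sorted(screen_net.nodes)
        seeds = set(
            nodes_sorted[i]
            for i in rng.choice(len(nodes_sorted),
                                size=min(xc.n_seeds, len(nodes_sorted)),
                                replace=False)
        )
        expansion = seed_expand.expand_seeds(screen_net, seeds)
        controls = seed_expand.random_control_set(
            screen_net,
            min(xc.n_random, screen_net.n_nodes - len(expansion.combined)),
            exclude=set(expansion.combined),
            seed=rng,
        )
        lines = screen_sim.simulate_rnai_outcomes(
            set(expansion.combined) & screen_net.nodes, controls,
            p_net=xc.p_net, p_rand=xc.p_rand,
            lines_per_gene=(1, xc.lines_per_gene_max), seed=rng,
        )
        net_lines = [ln for ln in lines if ln.set_label == "autophagy"]
        rand_lines = [ln for ln in lines if ln.set_label == "random"]
        rates, mean_rate = seed_expand.subsample_one_line_per_gene(
            net_lines, n_repeats=xc.n_repeats, seed=rng
        )
        rows = [
            {"gene": g, "list": name}
            for name, members in (
                ("seed", expansion.seeds),
                ("first_shell", expansion.first_shell),
                ("second_shell", expansion.second_shell),
            )
            for g in sorted(members)
        ]
        pd.DataFrame(rows).to_csv(out / "expansion_lists.tsv", sep="\t", index=False)
        summary["expand"] = {
            "n_seeds": len(expansion.seeds),
            "n_first_shell": len(expansion.first_shell),
            "n_second_shell": len(expansion.second_shell),
            "n_combined": len(expansion.combined),
            "network_set_subsample_rates": rates,
            "network_set_subsample_mean": mean_rate,
            "random_set_rate": seed_expand.modifier_rate(rand_lines),
        }
        log.info("expand: %s", summary["expand"])

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return out


def report(run_dir: str | Path) -> str:
    """Render a human-readable summary of a completed run (no recomputation)."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json in {run_dir}")
    with open(summary_path, encoding="utf-8") as fh:
        s = json.load(fh)
    lines = [f"Run summary ({run_dir}), seed {s.get('seed')}"]
    if "interactome" in s:
        i = s["interactome"]
        lines.append(
            f"  truth: {i['n_genes']} genes, {i['n_truth_edges']} edges, "
            f"{i['n_autoactivators']} auto-activator baits"
        )
    if "screen" in s:
        sc = s["screen"]
        lines.append(
            f"  screen: {sc['n_positive_pairs']} positives; "
            f"precision {sc['precision_vs_truth']:.3f}, "
            f"recall {sc['recall_vs_truth']:.3f} vs truth"
        )
    if "l3" in s:
        l3 = s["l3"]
        lines.append(
            f"  L3: top {l3['k']} tested, {l3['n_undetermined']} undetermined, "
            f"{l3['n_positive']} positive, precision {l3['precision']:.3f}"
        )
    if "validation" in s:
        lines.append("  validation recovery (per set): ")
        for row in s["validation"]["recovery"]:
            if row["n"]:
                lines.append(
                    f"    {row['set_label']:>10}: {row['rate']:.3f} "
                    f"± {row['se']:.3f} (n={row['n']})"
                )
    if "integrate" in s:
        it = s["integrate"]
        lines.append(
            f"  reference network: {it['reference_edges']} edges / "
            f"{it['reference_nodes']} nodes "
            f"(legacy kept {it['n_legacy_kept']}, Lit-BM {it['n_litbm']})"
        )
    if "enrich" in s:
        lines.append("  enrichment vs node-shuffle nulls:")
        for row in s["enrich"]:
            lines.append(
                f"    {row['statistic']:>24}: observed {row['observed']:.3f}, "
                f"null {row['null_mean']:.3f} ± {row['null_sem']:.3f}, "
                f"p = {row['empirical_p']:.4g}"
            )
    if "expand" in s:
        x = s["expand"]
        lines.append(
            f"  expansion: {x['n_seeds']} seeds + {x['n_first_shell']} + "
            f"{x['n_second_shell']} -> {x['n_combined']} genes; "
            f"network-set modifier rate {x['network_set_subsample_mean']:.2f} "
            f"vs random {x['random_set_rate']:.2f}"
        )
    missing = [k for k in ("screen", "l3", "validation") if k not in s]
    if missing:
        lines.append(f"  (stages without outputs: {', '.join(missing)})")
    return "\n".join(lines)


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s %(levelname)s] %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.DEBUG if verbose else logging.INFO)
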