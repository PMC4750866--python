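"""End-to-end orchestration: spikes -> avalanches -> models -> enrichment.

The pipeline mirrors the analysis order of a sleep session: avalanche
statistics and heavy-tail tests, VLMC depth selection by cross validation,
AIM construction, RUN-order enrichment with z-scores, RUN-optimal rate
comparison, conditional log-likelihood matrices with the enriched network,
and context clustering.  All stages run off one config whose defaults are
the analysis parameter values (maxISI = 50 ms, 0.99 tail quantile, 100 ISI
randomizations, depths 0..5, 10 folds, P_min = 0.006, gamma = 0.001,
r = 1.05, alpha = 0.05, 1000 label permutations).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import enrichment as enr
from . import io as aio
from . import parsing, run_optimal, vlmc

logger = logging.getLogger("avaseq")


@dataclass
class PipelineConfig:
    max_isi_s: float = 0.05
    quantile: float = 0.99
    n_isi_randomizations: int = 100
    depths: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    folds: int = 10
    p_min: float = vlmc.P_MIN_DEFAULT
    gamma: float = vlmc.GAMMA_DEFAULT
    r: float = vlmc.R_DEFAULT
    alpha: float = 0.05
    n_label_permutations: int = 1000
    optimizer_restarts: int = 10
    permutation_max_m: int = 7
    run_sequence: tuple[int, ...] | None = None
    bin_width_s: float | None = None     # None: mean ensemble ISI
    seed: int = 0

    def validate(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (0 < self.quantile < 1):
            raise ValueError("quantile must be in (0,1)")
        if self.max_isi_s <= 0:
            raise ValueError("max_isi_s must be positive")
        if not (0 <= self.p_min < 1) or not (0 < self.gamma < 1) or self.r <= 1:
            raise ValueError("PST hyperparameters out of range")
        if self.n_isi_randomizations < 1 or self.n_label_permutations < 1:
            raise ValueError("randomization counts must be positive")


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-22s %6.2f s", name, t1 - t0)
    return t1


def run_pipeline(ensemble: parsing.SpikeEnsemble, config: PipelineConfig,
                 outdir: str | Path) -> dict:
    """Run every stage on a sleep-epoch ensemble and write the report bundle.

    Returns a summary dict (also written as ``summary.json``).  Enrichment
    stages require ``config.run_sequence``; they are skipped with a notice
    when it is absent.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline config: %s", asdict(config))
    summary: dict = {"config": asdict(config)}
    t0 = time.perf_counter()

    # --- avalanche statistics and tail tests -------------------------------
    delta = config.bin_width_s or parsing.ensemble_bin_size(ensemble)
    avalanches = parsing.detect_avalanches(ensemble, delta)
    bseq = parsing.parse_burst_words(ensemble, avalanches, config.max_isi_s)
    seq = bseq.symbols
    summary["bin_width_s"] = delta
    summary["n_avalanches"] = len(avalanches.avalanches)
    summary["mean_avalanche_size"] = float(np.mean(avalanches.sizes)) if avalanches.avalanches else 0.0
    summary["mean_word_length"] = float(np.mean(bseq.word_lengths)) if bseq.word_spans else 0.0
    aio.write_burst_sequence(seq, outdir / "burst_sequence.txt")
    aio.write_word_table(avalanches, bseq, outdir / "words.tsv")

    null_sizes, null_lengths = [], []
    rng = np.random.default_rng(config.seed)
    for _ in range(config.n_isi_randomizations):
        surr = parsing.isi_randomize(ensemble, rng)
        d_s = parsing.ensemble_bin_size(surr)
        av_s = parsing.detect_avalanches(surr, d_s)
        bs_s = parsing.parse_burst_words(surr, av_s, config.max_isi_s)
        null_sizes.append(av_s.sizes)
        null_lengths.append(bs_s.word_lengths)
    size_test = parsing.tail_test(avalanches.sizes, np.concatenate(null_sizes),
                                  config.quantile)
    len_test = parsing.tail_test(bseq.word_lengths, np.concatenate(null_lengths),
                                 config.quantile)
    summary["size_tail"] = asdict(size_test)
    summary["word_length_tail"] = asdict(len_test)
    t0 = _stage("avalanches+tails", t0)

    # --- VLMC depth selection ----------------------------------------------
    A = ensemble.n_cells + 1
    cv = vlmc.cross_validate(seq, depths=config.depths, folds=config.folds,
                             p_min=config.p_min, gamma=config.gamma, r=config.r,
                             alphabet_size=A)
    summary["selected_depth"] = cv.selected_depth
    summary["avg_log_losses"] = cv.avg_losses.tolist()
    summary["normalized_information"] = cv.normalized_information.tolist()
    np.savetxt(outdir / "cv_losses.tsv", cv.losses, delimiter="\t")
    fitted = vlmc.fit_pst(seq, cv.selected_depth, config.p_min, config.gamma,
                          config.r, alphabet_size=A)
    aio.serialize_model(fitted, outdir / "fitted_model.json")
    t0 = _stage("cross-validation", t0)

    # --- AIM, enrichment, rates --------------------------------------------
    aim = enr.build_aim(seq, alphabet_size=A, gamma=config.gamma)
    aio.serialize_model(aim, outdir / "aim_model.json")
    R = enr.conditional_loglik_matrix(fitted, aim)
    aio.write_loglik_matrix(R, outdir / "loglik_matrix.tsv")
    fo = vlmc.fit_pst(seq, 1, config.p_min, config.gamma, config.r,
                      alphabet_size=A, prune=False)
    R1 = enr.first_order_loglik_matrix(fo, aim)
    net = enr.enriched_network(R1, threshold=0.0, run_sequence=config.run_sequence)
    aio.write_network(net, outdir / "enriched_edges.tsv",
                      outdir / "enriched_network.graphml")
    if len(R.contexts) >= 2:
        clustering = enr.cluster_contexts(R)
        summary["n_context_clusters"] = len(clustering.communities)
    t0 = _stage("aim+matrices", t0)

    if config.run_sequence is not None and len(config.run_sequence) >= 2:
        probes = enr.enumerate_run_order(config.run_sequence)
        fold_models = enr.build_fold_models(seq, cv.selected_depth, cv.fold_spans,
                                            config.p_min, config.gamma, config.r,
                                            alphabet_size=A)
        results = enr.enrichment_analysis(fitted, aim, fold_models, probes,
                                          alpha=config.alpha)
        aio.write_enrichment_table(results, outdir / "run_order_enrichment.tsv")
        full = results[-1]
        summary["run_sequence"] = list(config.run_sequence)
        summary["n_run_order_sequences"] = len(probes)
        summary["n_enriched"] = int(sum(r.enriched for r in results))
        summary["n_significant"] = int(sum(bool(r.significant) for r in results))
        summary["run_L"] = full.likelihood_ratio
        summary["run_z"] = full.z
        summary["run_p"] = full.p_value

        if len(config.run_sequence) <= config.permutation_max_m:
            ratios, run_L, q = enr.permutation_enrichment(
                fitted, aim, config.run_sequence, max_m=config.permutation_max_m)
            summary["permutation_quantile"] = q
            summary["n_permutations"] = int(ratios.size)

        chain, r_max, converged = run_optimal.optimize_run_chain(
            aim.stationary(), aim.P00, config.run_sequence,
            n_restarts=config.optimizer_restarts, seed=config.seed)
        aio.serialize_model(chain, outdir / "run_optimal_chain.json")
        rt = run_optimal.rate_table(aim, fitted, chain, config.run_sequence)
        summary["rates"] = {
            "r_aim": rt.r_aim, "r_fit": rt.r_fit, "r_max": rt.r_max,
            "fit_over_aim": rt.fit_over_aim, "max_over_aim": rt.max_over_aim,
            "optimizer_converged": converged,
        }
        with open(outdir / "rate_table.tsv", "w") as fh:
            fh.write("r_aim\tr_fit\tr_max\tfit_over_aim\tmax_over_aim\n")
            fh.write(f"{rt.r_aim:.6e}\t{rt.r_fit:.6e}\t{rt.r_max:.6e}\t"
                     f"{rt.fit_over_aim:.6e}\t{rt.max_over_aim:.6e}\n")
        t0 = _stage("enrichment+rates", t0)
    else:
        logger.info("no RUN sequence configured; skipping enrichment stages")

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary
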