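"""End-to-end orchestration: simulate or load a matrix, then run
genotype identification, diversity statistics, compatibility analysis
and pairwise differentiation, writing one tidy report bundle.

The bundle is fully reproducible: every output is a function of the
input matrix (or simulation config) and the run seed, and the manifest
JSON records all parameters so a rerun regenerates every file
byte-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import compat, diversity
from .bayes import pairwise_theta, theta_table
from .compat import DeletionTrajectory
from .matrix import (MarkerMatrix, filter_population_loci, identify_genotypes,
                     read_matrix, write_genotype_table, write_matrix)
from .simulate import SimConfig, simulate_population

__all__ = ["RunConfig", "run_pipeline", "classify_reproduction"]

log = logging.getLogger("dompop")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` and ``sim_config`` must be given.
    The MCMC schedule is ``(burn_in, run_length, thin)``.
    """

    out_dir: str | Path
    input_path: str | Path | None = None
    sim_config: SimConfig | None = None
    populations: list[str] | None = None
    missing_code: str = "?"
    n_boot: int = 1000
    mcmc_schedule: tuple[int, int, int] = (50_000, 250_000, 50)
    n_chains: int = 3
    classify_threshold: float = 0.5
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim_config is None):
            raise ValueError("give exactly one of input_path or sim_config")


def classify_reproduction(trajectory: DeletionTrajectory,
                          threshold: float = 0.5) -> str:
    """Label a deletion trajectory by its dominant source of variation.

    When at least *threshold* of the genotypes must be deleted to reach
    full compatibility, most genotypes owe their distinctness to
    recombination ("recombination-dominated"); a small deleted fraction
    means a few recombinants sit on top of an otherwise tree-like,
    mutation-generated genotype pool ("mutation-dominated").
    """
    frac = trajectory.fraction_deleted
    return "recombination-dominated" if frac >= threshold else "mutation-dominated"


def _stage(name: str, t0: float, **params) -> None:
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0,
             " ".join(f"{k}={v}" for k, v in params.items()))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Outputs: the analysed matrix (``matrix.tsv``), per-population
    genotype tables, a diversity summary table plus pairwise
    Mann-Whitney comparisons, per-population deletion trajectories with
    classifications, a pairwise theta^B table (skipped with a logged
    notice when only one population is present) and ``manifest.json``
    tying everything together.  Returns the manifest as a dict.  On any
    stage failure the partially written files are removed.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    ss = np.random.SeedSequence(config.seed)
    seed_sim, seed_boot, seed_theta = ss.spawn(3)

    def save(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    stage = "input"
    try:
        t0 = time.perf_counter()
        # ---- input stage ---------------------------------------------
        if config.input_path is not None:
            m = read_matrix(config.input_path, missing_code=config.missing_code)
            sim_truth = None
        else:
            cfg = config.sim_config
            if cfg.seed is None:
                cfg = SimConfig(**{**asdict(cfg), "seed": int(seed_sim.generate_state(1)[0] % (2 ** 31))})
            m, truth = simulate_population(cfg)
            sim_truth = {"mode": truth.mode, "seed": truth.seed,
                         "labels": truth.labels, "genealogy": truth.genealogy,
                         "params": truth.params}
            with open(save("truth.json"), "w") as fh:
                json.dump(sim_truth, fh, indent=1, sort_keys=True)
        pops = config.populations or m.population_labels
        write_matrix(m, save("matrix.tsv"), missing_code=config.missing_code)
        _stage("input", t0, n_individuals=m.n_individuals, n_loci=m.n_loci,
               n_pops=len(pops))

        # ---- genotypes + compatibility -------------------------------
        stage = "compatibility"
        t0 = time.perf_counter()
        summaries = {}
        for pop in pops:
            sub = filter_population_loci(m, pop)
            table = identify_genotypes(sub)
            write_genotype_table(table, save(f"genotypes_{pop}.tsv"))
            traj = compat.successive_deletion(table)
            pd.DataFrame({
                "step": range(len(traj.mic_after)),
                "deleted_genotype": [""] + traj.deleted_order,
                "mic": traj.mic_after,
            }).to_csv(save(f"trajectory_{pop}.tsv"), sep="\t", index=False)
            summaries[pop] = {
                "n_individuals": sub.n_individuals,
                "n_loci_retained": sub.n_loci,
                "n_genotypes": table.n_genotypes,
                "n_found_once": table.n_found_once,
                "mic_initial": traj.mic_after[0],
                "n_deleted_to_zero": traj.n_deleted_to_zero,
                "fraction_deleted": round(traj.fraction_deleted, 4),
                "tie_steps": traj.tie_steps,
                "classification": classify_reproduction(traj, config.classify_threshold),
            }
        _stage("compatibility", t0)

        # ---- diversity ----------------------------------------------
        stage = "diversity"
        t0 = time.perf_counter()
        mp = m if config.populations is None else _restrict(m, pops)
        div = diversity.diversity_table(mp, n_boot=config.n_boot,
                                        seed=seed_boot)
        div.to_csv(save("diversity.tsv"), sep="\t", index=False)
        diversity.pairwise_mannwhitney(mp).to_csv(
            save("mannwhitney.tsv"), sep="\t", index=False)
        _stage("diversity", t0, n_boot=config.n_boot)

        # ---- differentiation ----------------------------------------
        stage = "theta"
        t0 = time.perf_counter()
        theta_summary = {}
        if len(pops) >= 2:
            burn, run, thin = config.mcmc_schedule
            posts = pairwise_theta(mp, burn, run, thin, seed=seed_theta,
                                   n_chains=config.n_chains)
            theta_table(posts).to_csv(save("theta.tsv"), sep="\t")
            for (a, b), post in posts.items():
                theta_summary[f"{a}|{b}"] = {
                    "point": round(post.point, 4),
                    "ci95": [round(v, 4) for v in post.ci95],
                    "dbar": round(post.dbar, 2),
                    "pd": round(post.pd, 2),
                    "dic": round(post.dic, 2),
                    "split_rhat": round(post.diagnostics["split_rhat"], 4),
                }
        else:
            log.info("stage=theta skipped: only one population present")
        _stage("theta", t0, n_pairs=len(theta_summary))

        # ---- manifest -----------------------------------------------
        stage = "manifest"
        manifest = {
            "config": {
                "input_path": str(config.input_path) if config.input_path else None,
                "sim_config": asdict(config.sim_config) if config.sim_config else None,
                "populations": pops,
                "n_boot": config.n_boot,
                "mcmc_schedule": list(config.mcmc_schedule),
                "n_chains": config.n_chains,
                "classify_threshold": config.classify_threshold,
                "seed": config.seed,
            },
            "populations": summaries,
            "theta": theta_summary,
            "outputs": sorted(p.name for p in written) + ["manifest.json"],
        }
        with open(save("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except Exception as exc:
        log.error("pipeline aborted during stage %s: %s", stage, exc)
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _restrict(m: MarkerMatrix, pops: list[str]) -> MarkerMatrix:
    keep = [i for i, p in enumerate(m.populations) if p in pops]
    return MarkerMatrix(m.bands[keep],
                        [m.individual_ids[i] for i in keep],
                        [m.populations[i] for i in keep],
                        list(m.locus_ids))
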