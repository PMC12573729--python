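"""Assembly-metric summaries and end-to-end pipeline orchestration.

``load_assembly_metrics`` returns the packaged quality-metrics table for
the twelve de novo symbiont genome assemblies (one row per host species);
``summarize_assemblies`` reduces any such table to per-column min / max /
mean.  ``run_pipeline`` executes the simulation-driven pipeline —
simulate, dereplicate, detect, share-test, date, turnover, screen — from a
structured configuration, writing TSV/JSON outputs plus a log of every
seed and threshold so that re-running a config reproduces results
byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from wolbshift import __version__, anikit, divtime, lociscreen, sharestats, simdata, straincall

NUMERIC_COLUMNS = [
    "n_contigs", "span", "n50", "longest", "gc", "busco_complete",
    "busco_missing", "n_cds", "mean_protein_length", "n_rrna", "n_trna",
]


def load_assembly_metrics() -> pd.DataFrame:
    """Quality metrics of the twelve de novo symbiont assemblies."""
    with resources.files("wolbshift.data").joinpath("assembly_metrics.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def summarize_assemblies(metrics: pd.DataFrame) -> pd.DataFrame:
    """Min / max / mean per numeric column.

    Span and CDS means are rounded to integers, GC to three decimals, to
    match conventional reporting precision.
    """
    if metrics.empty:
        raise ValueError("empty metrics table")
    cols = [c for c in NUMERIC_COLUMNS if c in metrics.columns]
    summary = pd.DataFrame(
        {
            "min": metrics[cols].min(),
            "max": metrics[cols].max(),
            "mean": metrics[cols].mean(),
        }
    )
    for col in ("span", "n_cds"):
        if col in summary.index:
            summary.loc[col, "mean"] = round(summary.loc[col, "mean"])
    if "gc" in summary.index:
        summary.loc["gc", "mean"] = round(summary.loc["gc", "mean"], 3)
    return summary


DEFAULT_CONFIG = {
    "seed": 1,
    "simulate": {
        "n_strains": 4,
        "genome_length": 20_000,
        "strain_distance": 0.03,
        "n_pairs": 6,
        "coverage": 25.0,
        "read_length": 150,
        "error_rate": 0.002,
    },
    "derep": {"ani_threshold": 99.0, "maf_threshold": 0.90},
    "detect": {"breadth_infected": 0.90, "het_max_per_kb": 10.0},
    "share_test": {"filter": "both_infected", "n_reps": 2000},
    "date": {},
    "turnover": {},
    "screen": {},
}

_STAGE_INPUTS = {
    "share_test": "simulate",
    "date": "simulate",
    "turnover": "simulate",
    "detect": "simulate",
    "derep": "simulate",
}


def _preflight(config: dict) -> None:
    for stage, needs in _STAGE_INPUTS.items():
        if stage in config and needs not in config:
            raise ValueError(
                f"stage {stage!r} requested but required input stage "
                f"{needs!r} is missing from the config"
            )


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages; return a summary dict.

    Every stage writes its table under ``outdir`` and appends to
    ``run_log.json``.  Missing inputs are reported before any stage runs.
    """
    _preflight(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log: dict = {"version": __version__, "seed": seed, "stages": {}}
    summary: dict = {}

    sim_cfg = config.get("simulate")
    if sim_cfg is None:
        raise ValueError("this pipeline runs from a 'simulate' config block")

    # --- simulate strains and host system -------------------------------
    n_strains = sim_cfg.get("n_strains", 4)
    L = sim_cfg.get("genome_length", 20_000)
    dist = sim_cfg.get("strain_distance", 0.03)
    d = np.full((n_strains, n_strains), dist)
    np.fill_diagonal(d, 0.0)
    strains, realized = simdata.evolve_strains(
        simdata.SimStrainConfig(
            seed=seed, genome_length=L, n_strains=n_strains, target_distances=d
        )
    )
    host = simdata.simulate_host_system(
        simdata.HostSystemConfig(n_pairs=sim_cfg.get("n_pairs", 6), seed=seed + 1)
    )
    from wolbshift.seqio import write_fasta

    write_fasta([(g.id, g.sequence) for g in strains], outdir / "strains.fasta")
    realized.to_csv(outdir / "realized_distances.tsv", sep="\t")
    host.pair_table.to_csv(outdir / "pair_table.tsv", sep="\t", index=False)
    host.occurrence.to_csv(outdir / "occurrence.tsv", sep="\t", index_label="species")
    log["stages"]["simulate"] = {"n_strains": n_strains, "genome_length": L,
                                 "strain_distance": dist, "seed": seed}

    # --- dereplicate -----------------------------------------------------
    if "derep" in config:
        dcfg = anikit.DerepConfig(
            ani_threshold=config["derep"].get("ani_threshold", 99.0),
            maf_threshold=config["derep"].get("maf_threshold", 0.90),
        )
        clusters = anikit.dereplicate(strains, dcfg)
        pd.DataFrame(
            [
                {"representative": rep, "member": m}
                for rep, members in clusters.clusters
                for m in members
            ]
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        log["stages"]["derep"] = {"ani_threshold": dcfg.ani_threshold,
                                  "maf_threshold": dcfg.maf_threshold,
                                  "n_clusters": len(clusters.clusters)}
        summary["n_clusters"] = len(clusters.clusters)
        panel = [g for g in strains if g.id in clusters.representatives]
    else:
        panel = strains

    # --- detect: one single-strain sample per panel strain ---------------
    if "detect" in config:
        det = straincall.DetectionConfig(
            breadth_infected=config["detect"].get("breadth_infected", 0.90),
            het_max_per_kb=config["detect"].get("het_max_per_kb", 10.0),
        )
        rows = []
        for i, g in enumerate(panel):
            reads = simdata.simulate_reads(
                panel,
                simdata.SimReadConfig(
                    mixture=[(g.id, 1.0)],
                    coverage=sim_cfg.get("coverage", 25.0),
                    read_length=sim_cfg.get("read_length", 150),
                    error_rate=sim_cfg.get("error_rate", 0.002),
                    seed=seed + 100 + i,
                ),
            )
            call = straincall.detect(reads, panel, det, sample_id=f"sample_{i:02d}")
            rows.append(
                {
                    "sample": call.sample_id,
                    "true_strain": g.id,
                    "status": call.status,
                    "strains": ",".join(call.strain_ids),
                }
            )
        calls_df = pd.DataFrame(rows)
        calls_df.to_csv(outdir / "infection_calls.tsv", sep="\t", index=False)
        log["stages"]["detect"] = {"breadth_infected": det.breadth_infected,
                                   "het_max_per_kb": det.het_max_per_kb}
        summary["detect_correct"] = int(
            (calls_df["strains"] == calls_df["true_strain"]).sum()
        )

    # --- sharing statistics ----------------------------------------------
    if "share_test" in config:
        matrix = sharestats.OccurrenceMatrix(
            counts=host.occurrence, n_specimens=host.n_specimens
        )
        pairs = [
            sharestats.PairRecord(
                r.species_a, r.species_b, r.split_gen, r.split_my, r.sympatry
            )
            for r in host.pair_table.itertuples(index=False)
        ]
        st_cfg = config["share_test"]
        try:
            res = sharestats.sharing_permutation_test(
                matrix,
                pairs,
                filter=st_cfg.get("filter", "both_infected"),
                statistic="shared_count",
                n_reps=st_cfg.get("n_reps", 2000),
                seed=seed + 7,
            )
            share_out = {
                "observed": res.observed,
                "p_emp": res.p_emp,
                "n_reps": res.n_reps,
                "filter": res.filter,
                "seed": res.seed,
            }
        except ValueError as exc:  # too few / odd filtered species
            share_out = {"error": str(exc)}
        (outdir / "share_test.json").write_text(json.dumps(share_out, indent=2))
        log["stages"]["share_test"] = share_out
        summary["share_test"] = share_out

    # --- dating and turnover ---------------------------------------------
    clock = divtime.ClockConfig()
    if "date" in config:
        rows = []
        for r in host.pair_table.itertuples(index=False):
            if r.species_a not in host.wolb_seqs or r.species_b not in host.wolb_seqs:
                continue
            d_obs = divtime.p_distance(
                host.wolb_seqs[r.species_a], host.wolb_seqs[r.species_b]
            )
            gen_range, _ = divtime.wolb_split_range(divtime.jc_correct(d_obs), clock)
            host_range = divtime.TimeRange(
                0.8 * r.split_gen, 1.2 * r.split_gen, units="generations"
            )
            rows.append(
                {
                    "pair_id": r.pair_id,
                    "scenario": r.scenario,
                    "wolb_lo_gen": gen_range.lo,
                    "wolb_hi_gen": gen_range.hi,
                    "host_split_gen": r.split_gen,
                    "verdict": divtime.classify_congruence(gen_range, host_range),
                }
            )
        dates = pd.DataFrame(rows)
        dates.to_csv(outdir / "split_dates.tsv", sep="\t", index=False)
        log["stages"]["date"] = {"clock": asdict(clock), "n_comparisons": len(dates)}

    if "turnover" in config:
        tin = divtime.TurnoverInput(
            pairs=[
                (
                    host.strain_sets[r.species_a],
                    host.strain_sets[r.species_b],
                    r.split_gen,
                )
                for r in host.pair_table.itertuples(index=False)
            ]
        )
        rate = divtime.turnover_rate(tin, clock)
        turn_out = {"rate_per_million_generations": rate}
        (outdir / "turnover.json").write_text(json.dumps(turn_out, indent=2))
        log["stages"]["turnover"] = turn_out
        summary["turnover_rate"] = rate

    # --- locus screen -----------------------------------------------------
    if "screen" in config:
        plan = simdata.HitTablePlan(
            genome_id="genomeA", n_operons=1, n_wmk=2, decoys=("evalue", "annotation")
        )
        fixture = simdata.simulate_hit_tables(plan, seed=seed + 13)
        call = lociscreen.screen_genome(
            "genomeA",
            fixture.hits,
            fixture.reciprocal,
            fixture.features,
            fixture.family_map,
        )
        table = lociscreen.tabulate([call])
        table.to_csv(outdir / "locus_screen.tsv", sep="\t", index=False)
        log["stages"]["screen"] = table.iloc[0].to_dict()
        summary["locus_screen"] = table.iloc[0].to_dict()

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return summary
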