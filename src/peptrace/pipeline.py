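"""End-to-end pipeline: simulate -> clean -> database -> map -> enrich.

These helpers run whole simulated experiments in memory using the
vectorized read-processing path, which is what the recovery and
error-control studies use.  Each stage is the same code the file-based
CLI drives; only the transport differs (Counters of clean reads instead
of FASTA on disk).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .construct import AmpliconContext
from .database import CloneDatabase, build_database
from .enrichment import (
    ExperimentDesign,
    consensus_category,
    run_experiment,
)
from .mapping import MappingParams, map_all_to_counts
from .reads import AnchorSpec, clean_reads_from_sample
from .simulate import (
    ClonePool,
    PassageConfig,
    SequencingConfig,
    TrajectoryTable,
    simulate_sample_reads,
    simulate_serial_passage,
)


@dataclass
class ExperimentData:
    """Clean reads and bookkeeping of one simulated experiment."""

    experiment: str
    trajectory: TrajectoryTable
    clean_by_sample: dict[tuple[int, int], Counter]
    stats: pd.DataFrame


def simulate_experiment_reads(
    pool: ClonePool,
    passage: PassageConfig,
    seqcfg: SequencingConfig,
    rng: np.random.Generator,
    experiment: str = "exp1",
    context: AmpliconContext | None = None,
    anchors: AnchorSpec | None = None,
    max_diffs: int = 30,
    min_merge_length: int = 100,
) -> ExperimentData:
    """Simulate one experiment and process its reads to clean sequences."""
    context = context or AmpliconContext()
    anchors = anchors or AnchorSpec.from_layout(pool.layout, context)
    trajectory = simulate_serial_passage(pool, passage, rng)
    clean: dict[tuple[int, int], Counter] = {}
    stat_rows = []
    for r in range(trajectory.n_replicates):
        for c in range(trajectory.n_cycles):
            sample = simulate_sample_reads(
                pool, trajectory.freqs[r, c], seqcfg, rng, context
            )
            reads, stats = clean_reads_from_sample(
                sample, anchors, max_diffs, min_merge_length
            )
            clean[(r + 1, c + 1)] = reads
            stat_rows.append(
                {
                    "experiment": experiment,
                    "replicate": r + 1,
                    "cycle": c + 1,
                    "n_input": stats.n_input,
                    "n_merged": stats.n_merged,
                    "n_clean": stats.n_clean,
                }
            )
    return ExperimentData(experiment, trajectory, clean, pd.DataFrame(stat_rows))


@dataclass
class PipelineResult:
    database: CloneDatabase
    count_tables: dict[str, pd.DataFrame]
    mapping_stats: pd.DataFrame
    results: dict[str, pd.DataFrame]
    consensus: pd.DataFrame
    truth_to_db: dict[str, str] = field(default_factory=dict)


def analyze_experiments(
    experiments: list[ExperimentData],
    mapping_params: MappingParams | None = None,
    min_cluster_size: int = 8,
    identity: float = 0.97,
    min_total: int = 5,
    alpha: float = 0.05,
    majority: int | None = None,
    pool: ClonePool | None = None,
) -> PipelineResult:
    """Database construction, mapping, testing, and consensus calling.

    When the generating ``pool`` is supplied, database clone ids are
    linked back to ground-truth clone ids by exact sequence match
    (``truth_to_db``), enabling recovery scoring.
    """
    per_file = [
        reads
        for exp in experiments
        for (_, _), reads in sorted(exp.clean_by_sample.items())
    ]
    database = build_database(per_file, identity, min_cluster_size)

    count_tables: dict[str, pd.DataFrame] = {}
    stats_frames = []
    results: dict[str, pd.DataFrame] = {}
    for exp in experiments:
        table, stats = map_all_to_counts(
            exp.clean_by_sample, database, mapping_params, exp.experiment
        )
        count_tables[exp.experiment] = table
        stats_frames.append(stats)
        design = ExperimentDesign.from_labels(table.columns)
        results[exp.experiment] = run_experiment(table, design, min_total, alpha)

    flags = pd.DataFrame(
        {name: res["flag"] for name, res in results.items()}
    ).reindex(database.ids)
    consensus = consensus_category(flags, majority, n_experiments=len(experiments))

    truth_to_db: dict[str, str] = {}
    if pool is not None:
        layout = pool.layout
        stop = len(layout.stop_codon)
        coding = {c.sequence[:-stop]: c.id for c in pool.clones}
        for db_id, seq in zip(database.ids, database.sequences):
            truth_id = coding.get(seq)
            if truth_id is not None:
                truth_to_db[truth_id] = db_id
    mapping_stats = pd.concat(stats_frames) if stats_frames else pd.DataFrame()
    return PipelineResult(
        database, count_tables, mapping_stats, results, consensus, truth_to_db
    )


def counts_from_trajectory(
    trajectory: TrajectoryTable, depth: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Idealized count table: multinomial reads with perfect mapping.

    Models sequencing at the count level (no per-base errors, no read
    loss); useful for isolating the statistical behavior of the
    enrichment test from read-processing effects.
    """
    cols = {}
    for r in range(trajectory.n_replicates):
        for c in range(trajectory.n_cycles):
            cols[f"rep{r + 1}_cyc{c + 1}"] = rng.multinomial(
                depth, trajectory.freqs[r, c]
            )
    return pd.DataFrame(
        cols, index=pd.Index(trajectory.clone_ids, name="clone_id"), dtype=int
    )
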