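"""Global-alignment mapping of clean reads to the clone database.

Every clean read of every (replicate, cycle) sample is assigned to at
most one database clone: the best-identity hit passing all thresholds
(identity >= 0.97, query coverage >= 0.9, at most 5 gap columns).  Ties
go to the larger cluster, then to the lexicographically smaller clone id.
Hits are tallied into one count table per experiment (rows clones,
columns samples).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .align import KmerIndex, global_align, min_shared_kmers
from .database import CloneDatabase


@dataclass(frozen=True)
class MappingParams:
    min_identity: float = 0.97
    min_query_coverage: float = 0.9
    max_hits: int = 1
    max_gaps: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_query_coverage <= 1:
            raise ValueError("min_query_coverage must be in (0, 1]")
        if self.max_hits != 1:
            raise ValueError("only max_hits=1 is supported")
        if self.max_gaps < 0:
            raise ValueError("max_gaps must be >= 0")


@dataclass(frozen=True)
class Hit:
    read_id: str
    clone_id: str
    identity: float
    coverage: float
    n_gap_columns: int


@dataclass
class MappingStats:
    n_reads: int = 0
    n_mapped: int = 0

    @property
    def mapped_fraction(self) -> float:
        return self.n_mapped / self.n_reads if self.n_reads else 0.0


class ReadMapper:
    """Maps clean-read sequences to a database, caching by sequence.

    Identical sequences recur heavily in amplicon data, so results are
    memoized; an exact-match dictionary short-circuits reads equal to a
    centroid, and a lossless 16-mer prefilter restricts alignment
    candidates for the rest (thresholds >= 0.97 identity guarantee a
    shared 16-mer; below that every clone is scanned).
    """

    def __init__(self, database: CloneDatabase, params: MappingParams | None = None):
        self.database = database
        self.params = params or MappingParams()
        self._by_seq = {}
        for cid, cl in zip(database.ids, database.clusters):
            self._by_seq.setdefault(cl.centroid, cid)
        self._use_prefilter = self.params.min_identity >= 0.97
        self._index = KmerIndex(database.sequences, k=16)
        self._cache: dict[str, str | None] = {}

    def map_sequence(self, seq: str) -> str | None:
        """Clone id of the accepted best hit for ``seq``, or None."""
        hit = self._cache.get(seq, "?")
        if hit != "?":
            return hit
        result = self._map_uncached(seq)
        self._cache[seq] = result
        return result

    def _map_uncached(self, seq: str) -> str | None:
        p = self.params
        exact = self._by_seq.get(seq)
        if exact is not None and p.min_identity <= 1.0 and p.min_query_coverage <= 1.0:
            return exact
        if self._use_prefilter:
            shared = self._index.shared_counts(seq)
            if shared is None:
                cand = range(len(self.database))
            else:
                cand = [
                    ci
                    for ci, n_shared in shared.items()
                    if n_shared
                    >= min_shared_kmers(
                        len(seq),
                        len(self.database.clusters[ci].centroid),
                        p.min_identity,
                        self._index.k,
                    )
                ]
        else:
            cand = range(len(self.database))
        best = None  # (identity, total_size, -ord) selection
        for ci in cand:
            target = self.database.clusters[ci].centroid
            summary = global_align(seq, target)
            if (
                summary.identity >= p.min_identity
                and summary.query_coverage >= p.min_query_coverage
                and summary.n_gap_columns <= p.max_gaps
            ):
                key = (
                    summary.identity,
                    self.database.clusters[ci].total_size,
                )
                if (
                    best is None
                    or key > best[0]
                    or (key == best[0] and self.database.ids[ci] < best[1])
                ):
                    best = (key, self.database.ids[ci], summary)
        return None if best is None else best[1]

    def map_read(self, seq: str, read_id: str = "") -> Hit | None:
        """Full Hit record for one read (uncached identity details)."""
        cid = self.map_sequence(seq)
        if cid is None:
            return None
        target = self.database.clusters[self.database.ids.index(cid)].centroid
        s = global_align(seq, target)
        return Hit(read_id, cid, s.identity, s.query_coverage, s.n_gap_columns)


def map_read(
    seq: str, database: CloneDatabase, params: MappingParams | None = None
) -> Hit | None:
    """One-shot mapping of a single read (see ReadMapper for bulk use)."""
    return ReadMapper(database, params).map_read(seq)


def map_counter_to_counts(
    mapper: ReadMapper, reads: Counter
) -> tuple[Counter, MappingStats]:
    """Map dereplicated reads (sequence -> multiplicity) to clone counts."""
    counts: Counter = Counter()
    stats = MappingStats()
    for seq, k in reads.items():
        stats.n_reads += k
        cid = mapper.map_sequence(seq)
        if cid is not None:
            counts[cid] += k
            stats.n_mapped += k
    return counts, stats


def map_all_to_counts(
    samples: dict[tuple[int, int], Counter],
    database: CloneDatabase,
    params: MappingParams | None = None,
    experiment: str = "exp1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count table for one experiment from per-sample clean reads.

    ``samples`` maps (replicate, cycle) to a Counter of clean-read
    sequences.  Returns (count table, mapping stats); the table has clone
    ids as rows and ``rep{r}_cyc{c}`` sample labels as columns, ordered by
    replicate then cycle.  Duplicate (replicate, cycle) labels are an
    error upstream by construction of the dict.
    """
    mapper = ReadMapper(database, params)
    labels = []
    columns = {}
    stat_rows = []
    for (r, c) in sorted(samples):
        label = f"rep{r}_cyc{c}"
        counts, stats = map_counter_to_counts(mapper, samples[(r, c)])
        labels.append(label)
        columns[label] = counts
        stat_rows.append(
            {
                "experiment": experiment,
                "sample": label,
                "replicate": r,
                "cycle": c,
                "n_reads": stats.n_reads,
                "n_mapped": stats.n_mapped,
                "mapped_fraction": stats.mapped_fraction,
            }
        )
    table = pd.DataFrame(
        {lab: [columns[lab].get(cid, 0) for cid in database.ids] for lab in labels},
        index=pd.Index(database.ids, name="clone_id"),
        dtype=int,
    )
    return table, pd.DataFrame(stat_rows)
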