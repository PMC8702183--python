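"""Clone reference database via three-round dereplication.

Round 1: per-file exact dereplication with size (multiplicity) counts.
Round 2: per-file singleton removal, pooling, exact dereplication again
with sizes summed.  Round 3: greedy centroid clustering at 0.97 identity
(abundance-sorted, as in OTU validation pipelines) followed by a minimum
cluster size filter of 8 reads.  Surviving cluster centroids form the
reference the count tables are built against.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .align import KmerIndex, min_shared_kmers, pairwise_identity


@dataclass(frozen=True)
class UniqueSequence:
    sequence: str
    size: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("size must be >= 1")


@dataclass
class Cluster:
    centroid: str
    total_size: int
    members: list[UniqueSequence] = field(default_factory=list)


@dataclass
class CloneDatabase:
    """Final database: clusters with stable ids, sorted by abundance."""

    clusters: list[Cluster]
    ids: list[str]

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def sequences(self) -> list[str]:
        return [c.centroid for c in self.clusters]

    @property
    def sizes(self) -> list[int]:
        return [c.total_size for c in self.clusters]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"clone_id": self.ids, "sequence": self.sequences, "total_size": self.sizes}
        )

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for cid, cl in zip(self.ids, self.clusters):
                fh.write(f">{cid};size={cl.total_size}\n{cl.centroid}\n")

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def dereplicate_exact(clean_reads) -> list[UniqueSequence]:
    """Collapse identical sequences; one record per distinct string.

    Accepts any iterable of sequence strings, or a Counter / mapping of
    sequence -> multiplicity.  Output is sorted by descending size, ties
    lexicographic, so downstream processing is order-invariant.
    """
    if isinstance(clean_reads, (Counter, dict)):
        counts = Counter(dict(clean_reads))
    else:
        counts = Counter(clean_reads)
    return [
        UniqueSequence(seq, size)
        for seq, size in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def drop_singletons(uniques: list[UniqueSequence]) -> list[UniqueSequence]:
    """Remove size-1 records (likely PCR or sequencing errors)."""
    return [u for u in uniques if u.size > 1]


def greedy_cluster(
    uniques: list[UniqueSequence], threshold: float = 0.97
) -> list[Cluster]:
    """Abundance-sorted greedy centroid clustering.

    Records are processed in decreasing size order (ties: lexicographic by
    sequence).  Each record joins the first existing centroid — in
    centroid creation order — with global-alignment identity >= threshold,
    else founds a new cluster.  Members are compared to centroids only; no
    re-centering.  A lossless k-mer prefilter restricts the identity
    computations (equivalence with the exhaustive scan is tested).
    """
    ordered = sorted(uniques, key=lambda u: (-u.size, u.sequence))
    clusters: list[Cluster] = []
    # The 16-mer prefilter is lossless only when the identity threshold is
    # tight enough that any member shares an exact 16-mer with its centroid
    # (pigeonhole over the edit budget); below 0.97 scan everything.
    use_prefilter = threshold >= 0.97
    index = KmerIndex([], k=16)
    for rec in ordered:
        if not clusters:
            cand = []
        elif use_prefilter:
            shared = index.shared_counts(rec.sequence)
            if shared is None:
                cand = range(len(clusters))
            else:
                cand = sorted(
                    ci
                    for ci, n_shared in shared.items()
                    if n_shared
                    >= min_shared_kmers(
                        len(rec.sequence),
                        len(clusters[ci].centroid),
                        threshold,
                        index.k,
                    )
                )
        else:
            cand = range(len(clusters))
        joined = False
        for ci in cand:
            if pairwise_identity(rec.sequence, clusters[ci].centroid) >= threshold:
                clusters[ci].members.append(rec)
                clusters[ci].total_size += rec.size
                joined = True
                break
        if not joined:
            index.add(len(clusters), rec.sequence)
            clusters.append(Cluster(rec.sequence, rec.size, [rec]))
    return clusters


def filter_min_cluster_size(
    clusters: list[Cluster], min_size: int = 8
) -> CloneDatabase:
    """Drop clusters below ``min_size`` reads; assign stable clone ids.

    Ids follow descending total size, ties broken lexicographically by
    centroid sequence.
    """
    kept = sorted(
        (c for c in clusters if c.total_size >= min_size),
        key=lambda c: (-c.total_size, c.centroid),
    )
    width = max(4, len(str(len(kept))))
    ids = [f"clone{i + 1:0{width}d}" for i in range(len(kept))]
    return CloneDatabase(kept, ids)


def build_database(
    per_file_reads: list,
    threshold: float = 0.97,
    min_cluster_size: int = 8,
) -> CloneDatabase:
    """Three-round dereplication over per-file clean reads.

    ``per_file_reads`` holds one entry per sequencing file: an iterable of
    clean-read sequences or a Counter of sequence -> multiplicity.
    """
    if not per_file_reads:
        raise ValueError("at least one input file required")
    pooled: Counter = Counter()
    for reads in per_file_reads:
        uniques = dereplicate_exact(reads)  # round 1
        for u in drop_singletons(uniques):  # round 2a: per-file singletons out
            pooled[u.sequence] += u.size
    pooled_uniques = dereplicate_exact(pooled)  # round 2b: pooled exact derep
    clusters = greedy_cluster(pooled_uniques, threshold)  # round 3
    return filter_min_cluster_size(clusters, min_cluster_size)
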