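"""From raw read pairs to clean coding sequences.

A *clean read* is a merged amplicon read that contains both constant
anchors — an 18-nt sequence around the start codon and the FLAG-tag coding
sequence plus stop — trimmed to the coding region from the start codon
through the last FLAG codon (stop excluded).  Full-length clones yield
195-nt clean reads; the insert-less vector yields 45 nt.

Two execution paths exist: per-read functions (`quality_trim`,
`merge_pair`, `extract_clean_read`) that define the semantics, and a
vectorized bulk path (`merge_batches`, `clean_reads_from_sample`) for
simulation-scale data, which is exact-equivalent for fixed-length
fully-overlapping pairs (tested).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .construct import AmpliconContext, ConstructLayout
from .simulate import ReadBatch, SampleReads, revcomp


@dataclass
class ReadPair:
    forward: str
    forward_qual: list[int]
    reverse: str
    reverse_qual: list[int]
    id: str = ""

    def __post_init__(self) -> None:
        if len(self.forward) != len(self.forward_qual):
            raise ValueError("forward sequence/quality length mismatch")
        if len(self.reverse) != len(self.reverse_qual):
            raise ValueError("reverse sequence/quality length mismatch")


@dataclass
class MergedRead:
    sequence: str
    quality: list[int]
    n_diffs: int
    id: str = ""


@dataclass(frozen=True)
class CleanRead:
    sequence: str
    source_id: str = ""


def _trim_one(qual: list[int], window: int, min_mean_q: float) -> int:
    """Return the kept length under sliding-window 3' quality trimming.

    Scan 5'->3'; at the first window whose mean quality drops below the
    threshold, keep bases from the window start while their individual
    quality stays at or above the threshold, then cut.
    """
    n = len(qual)
    if n < window:
        return n if n and sum(qual) / n >= min_mean_q else 0
    acc = np.cumsum([0] + list(qual))
    for i in range(n - window + 1):
        if (acc[i + window] - acc[i]) / window < min_mean_q:
            j = i
            while j < n and qual[j] >= min_mean_q:
                j += 1
            return j
    return n


def quality_trim(
    pair: ReadPair, window: int = 4, min_mean_q: float = 15.0
) -> ReadPair | None:
    """Sliding-window 3' quality trimming of both mates.

    Returns the trimmed pair, or None when either mate is trimmed away
    entirely (the pair is dropped).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    kf = _trim_one(pair.forward_qual, window, min_mean_q)
    kr = _trim_one(pair.reverse_qual, window, min_mean_q)
    if kf == 0 or kr == 0:
        return None
    return ReadPair(
        pair.forward[:kf],
        pair.forward_qual[:kf],
        pair.reverse[:kr],
        pair.reverse_qual[:kr],
        pair.id,
    )


def merge_pair(
    pair: ReadPair, max_diffs: int = 30, min_merge_length: int = 100
) -> MergedRead | None:
    """Merge overlapping mates; higher-quality base wins at conflicts.

    The reverse mate is reverse-complemented and slid along the forward
    mate; among offsets with overlap >= ``min_merge_length`` the one with
    the most matching bases wins (ties -> longer overlap).  Conflicting
    overlap positions take the base with the higher quality (tie -> the
    forward mate's base); merged quality is the per-position maximum.
    Rejected (None) when no admissible overlap exists, the best overlap
    has more than ``max_diffs`` mismatches, or the merged length is below
    ``min_merge_length``.
    """
    f = np.frombuffer(pair.forward.encode(), dtype=np.uint8)
    r = np.frombuffer(revcomp(pair.reverse).encode(), dtype=np.uint8)
    rq = np.array(pair.reverse_qual[::-1], dtype=np.int64)
    fq = np.array(pair.forward_qual, dtype=np.int64)
    nf, nr = len(f), len(r)

    best = None  # (matches, overlap, offset)
    for off in range(0, nf - min_merge_length + 1):
        ov = min(nf - off, nr)
        if ov < min_merge_length:
            continue
        matches = int((f[off : off + ov] == r[:ov]).sum())
        key = (matches, ov)
        if best is None or key > best[:2]:
            best = (matches, ov, off)
    if best is None:
        return None
    matches, ov, off = best
    n_diffs = ov - matches
    if n_diffs > max_diffs:
        return None

    cons = f[off : off + ov].copy()
    consq = np.maximum(fq[off : off + ov], rq[:ov])
    conflict = f[off : off + ov] != r[:ov]
    take_r = conflict & (rq[:ov] > fq[off : off + ov])
    cons[take_r] = r[:ov][take_r]

    merged_seq = pair.forward[:off] + cons.tobytes().decode() + (
        r[ov:].tobytes().decode() if nr > ov else ""
    )
    merged_q = (
        list(pair.forward_qual[:off]) + consq.tolist() + rq[ov:].tolist()
    )
    if len(merged_seq) < min_merge_length:
        return None
    return MergedRead(merged_seq, merged_q, n_diffs, pair.id)


@dataclass(frozen=True)
class AnchorSpec:
    """Anchors bounding the coding region within a merged read.

    ``upstream`` must contain the start codon at offset ``start_offset``
    from its left end; the clean read runs from there through
    ``coding_end_offset`` bases after the start of ``downstream`` (the end
    of the FLAG-tag coding sequence, stop excluded).
    """

    upstream: str
    downstream: str
    start_offset: int
    coding_end_offset: int

    @classmethod
    def from_layout(
        cls,
        layout: ConstructLayout | None = None,
        context: AmpliconContext | None = None,
        upstream_length: int = 18,
        flag_nt: int = 24,
    ) -> "AnchorSpec":
        layout = layout or ConstructLayout()
        context = context or AmpliconContext()
        up = context.upstream_anchor(layout, upstream_length)
        down = context.downstream_anchor(layout, flag_nt)
        return cls(up, down, upstream_length - len(layout.flank5), flag_nt)


def _find_unique(haystack: str, needle: str) -> int | None:
    """Position of ``needle`` if it occurs exactly once, else None."""
    first = haystack.find(needle)
    if first < 0:
        return None
    if haystack.find(needle, first + 1) >= 0:
        return None  # ambiguous
    return first


def extract_clean_read(
    merged: MergedRead, anchors: AnchorSpec
) -> CleanRead | None:
    """Trim a merged read to the coding region between the two anchors.

    Both anchors must occur exactly once (exact substring match); reads
    missing either anchor, or containing one twice, are rejected.
    """
    up = _find_unique(merged.sequence, anchors.upstream)
    if up is None:
        return None
    down = _find_unique(merged.sequence, anchors.downstream)
    if down is None:
        return None
    start = up + anchors.start_offset
    end = down + anchors.coding_end_offset
    if end <= start:
        return None
    return CleanRead(merged.sequence[start:end], merged.id)


# ---------------------------------------------------------------------------
# bulk (vectorized) path for simulation-scale samples
# ---------------------------------------------------------------------------


def merge_batches(
    r1: ReadBatch, r2: ReadBatch, max_diffs: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized merge of equal-length fully-overlapping pairs.

    Equivalent to `merge_pair` at offset 0 with full overlap; valid for
    the simulator's read geometry where both mates span the amplicon.
    Returns (merged sequence matrix, accepted-row mask).
    """
    from .simulate import revcomp_bytes

    f, fq = r1.seq, r1.qual.astype(np.int16)
    r = revcomp_bytes(r2.seq)
    rq = r2.qual[:, ::-1].astype(np.int16)
    conflict = f != r
    n_diffs = conflict.sum(axis=1)
    merged = f.copy()
    take_r = conflict & (rq > fq)
    merged[take_r] = r[take_r]
    return merged, n_diffs <= max_diffs


@dataclass
class CleanStats:
    n_input: int = 0
    n_merged: int = 0
    n_clean: int = 0


def clean_reads_from_sample(
    sample: SampleReads,
    anchors: AnchorSpec,
    max_diffs: int = 30,
    min_merge_length: int = 100,
) -> tuple[Counter, CleanStats]:
    """Merge, anchor-filter and trim a whole sample; dereplicated output.

    Returns a Counter of clean-read sequences (sequence -> multiplicity)
    plus per-sample statistics.  Merged reads are deduplicated before the
    anchor search so the exact-substring scan runs once per distinct
    sequence.
    """
    stats = CleanStats()
    out: Counter = Counter()
    for b1, b2 in zip(sample.r1, sample.r2):
        n = b1.seq.shape[0]
        stats.n_input += n
        if n == 0 or b1.seq.shape[1] < min_merge_length:
            continue
        merged, ok = merge_batches(b1, b2, max_diffs)
        stats.n_merged += int(ok.sum())
        kept = merged[ok]
        if kept.shape[0] == 0:
            continue
        buf = kept.tobytes()
        width = kept.shape[1]
        uniq = Counter(buf[i : i + width] for i in range(0, len(buf), width))
        for row, k in uniq.items():
            seq = row.decode()
            clean = extract_clean_read(MergedRead(seq, [], 0), anchors)
            if clean is not None:
                out[clean.sequence] += int(k)
                stats.n_clean += int(k)
    return out, stats


# ---------------------------------------------------------------------------
# FASTQ file path
# ---------------------------------------------------------------------------


def read_fastq_pairs(path1: str, path2: str):
    """Yield ReadPair objects from two Phred+33 FASTQ files (gzip allowed)."""
    from Bio import SeqIO

    def _open(p):
        if p.endswith(".gz"):
            import gzip

            return gzip.open(p, "rt")
        return open(p)

    with _open(path1) as h1, _open(path2) as h2:
        for rec1, rec2 in zip(SeqIO.parse(h1, "fastq"), SeqIO.parse(h2, "fastq")):
            yield ReadPair(
                str(rec1.seq),
                rec1.letter_annotations["phred_quality"],
                str(rec2.seq),
                rec2.letter_annotations["phred_quality"],
                rec1.id,
            )


def clean_fastq_files(
    path1: str,
    path2: str,
    anchors: AnchorSpec,
    max_diffs: int = 30,
    min_merge_length: int = 100,
    trim_window: int | None = None,
    trim_min_mean_q: float = 15.0,
) -> tuple[Counter, CleanStats]:
    """File-based cleaning: trim (optional), merge, anchor-extract.

    Quality trimming is off unless ``trim_window`` is given.
    """
    stats = CleanStats()
    out: Counter = Counter()
    for pair in read_fastq_pairs(path1, path2):
        stats.n_input += 1
        if trim_window is not None:
            trimmed = quality_trim(pair, trim_window, trim_min_mean_q)
            if trimmed is None:
                continue
            pair = trimmed
        merged = merge_pair(pair, max_diffs, min_merge_length)
        if merged is None:
            continue
        stats.n_merged += 1
        clean = extract_clean_read(merged, anchors)
        if clean is not None:
            out[clean.sequence] += 1
            stats.n_clean += 1
    return out, stats
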