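"""Synthetic serial-passage competition data.

Emulates the experimental design the analysis pipeline assumes: a library
of *E. coli* clones, each expressing a random-sequence peptide from an
inducible plasmid, grown in competition through serial passages with 1:10
bottlenecks, and sampled by paired-end amplicon sequencing at each cycle.

The growth model is deterministic exponential competition: over ``g``
generations a clone with selection coefficient ``s`` multiplies its
frequency by ``2**(g*(1+s))`` relative to the shared normalization, so a
clone's expected log2 frequency change has a closed form.  Stochasticity
enters only at bottlenecks (multinomial resampling of the seeding
population) and at sequencing (multinomial read sampling plus per-base
substitution errors).  This separation gives every downstream estimator a
known ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .construct import AmpliconContext, ConstructLayout

NUCS = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_a] = _b


def revcomp_bytes(arr: np.ndarray) -> np.ndarray:
    """Reverse-complement an array of ASCII nucleotide codes (last axis)."""
    return _COMPLEMENT[arr][..., ::-1]


def revcomp(seq: str) -> str:
    return revcomp_bytes(np.frombuffer(seq.encode(), dtype=np.uint8)).tobytes().decode()


class PositionProbMatrix:
    """Per-position nucleotide probabilities for insert synthesis.

    ``probs`` is an ``(insert_length, 4)`` matrix over the alphabet A,C,G,T;
    every row must sum to 1.  The uniform matrix models equimolar chemistry;
    a biased matrix reproduces synthesis artefacts such as the elevated G
    content the real library shows in its 3' half.
    """

    ALPHABET = "ACGT"

    def __init__(self, probs: np.ndarray):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must have shape (length, 4)")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every row must sum to 1 within 1e-9")
        self.probs = probs

    def __len__(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def uniform(cls, length: int) -> "PositionProbMatrix":
        return cls(np.full((length, 4), 0.25))

    @classmethod
    def g_biased(
        cls, length: int, start: int = 36, g_extra: float = 0.08
    ) -> "PositionProbMatrix":
        """Uniform matrix with G elevated (and A depleted) from ``start`` on."""
        probs = np.full((length, 4), 0.25)
        probs[start:, 2] += g_extra
        probs[start:, 0] -= g_extra
        return cls(probs)

    def stop_probability(self) -> float:
        """Mean per-codon probability of an in-frame stop (TAA, TAG, TGA)."""
        idx = {c: i for i, c in enumerate(self.ALPHABET)}
        total = 0.0
        n_codons = len(self) // 3
        for j in range(n_codons):
            p = self.probs[3 * j : 3 * j + 3]
            for codon in ("TAA", "TAG", "TGA"):
                total += p[0, idx[codon[0]]] * p[1, idx[codon[1]]] * p[2, idx[codon[2]]]
        return total / n_codons


def generate_insert(
    length: int, probs: PositionProbMatrix, rng: np.random.Generator
) -> str:
    """Draw one random insert, position ``j`` from row ``j`` of ``probs``."""
    return generate_inserts(1, length, probs, rng)[0]


def generate_inserts(
    n: int, length: int, probs: PositionProbMatrix, rng: np.random.Generator
) -> list[str]:
    """Vectorized draw of ``n`` inserts (each column uses its own row of probs)."""
    if length != len(probs):
        raise ValueError(f"length {length} != probability matrix rows {len(probs)}")
    arr = insert_matrix(n, probs, rng)
    return [row.tobytes().decode() for row in arr]


def insert_matrix(
    n: int, probs: PositionProbMatrix, rng: np.random.Generator
) -> np.ndarray:
    """``(n, length)`` ASCII-code matrix of random inserts."""
    cum = np.cumsum(probs.probs, axis=1)
    u = rng.random((n, len(probs)))
    idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    return NUCS[idx]


@dataclass(frozen=True)
class Clone:
    id: str
    sequence: str  # full construct, flanks + insert + stop
    init_freq: float
    s: float = 0.0  # per-generation selection coefficient


@dataclass
class ClonePool:
    """A set of clones with initial frequencies and true fitness effects."""

    clones: list[Clone]
    layout: ConstructLayout = field(default_factory=ConstructLayout)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("clone ids must be unique")
        total = sum(c.init_freq for c in self.clones)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"initial frequencies sum to {total}, not 1")

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.clones]

    @property
    def sequences(self) -> list[str]:
        return [c.sequence for c in self.clones]

    @property
    def init_freqs(self) -> np.ndarray:
        return np.array([c.init_freq for c in self.clones])

    @property
    def s_values(self) -> np.ndarray:
        return np.array([c.s for c in self.clones])

    def with_fitness(self, s: np.ndarray) -> "ClonePool":
        s = np.asarray(s, dtype=float)
        if s.shape != (len(self),):
            raise ValueError("one selection coefficient per clone required")
        clones = [replace(c, s=float(v)) for c, v in zip(self.clones, s)]
        return ClonePool(clones, self.layout)

    def ground_truth_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "clone_id": self.ids,
                "sequence": self.sequences,
                "init_freq": self.init_freqs,
                "s": self.s_values,
            }
        )


def generate_clone_library(
    n_clones: int,
    layout: ConstructLayout | None = None,
    probs: PositionProbMatrix | None = None,
    include_empty_vector: bool = False,
    empty_vector_freq: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ClonePool:
    """Generate ``n_clones`` distinct random-insert clones.

    Duplicated inserts are regenerated so all sequences are distinct.  When
    ``include_empty_vector`` is set, one extra clone carries the construct
    without insert at initial frequency ``empty_vector_freq``; the random
    clones share the remaining probability mass uniformly.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    layout = layout or ConstructLayout()
    probs = probs or PositionProbMatrix.uniform(layout.insert_length)
    rng = rng if rng is not None else np.random.default_rng()

    seen: dict[str, None] = {}
    while len(seen) < n_clones:
        for ins in generate_inserts(n_clones - len(seen), layout.insert_length, probs, rng):
            if len(seen) >= n_clones:
                break
            seen.setdefault(ins, None)
    inserts = list(seen)

    base = (1.0 - empty_vector_freq) if include_empty_vector else 1.0
    f = base / n_clones
    width = max(4, len(str(n_clones)))
    clones = [
        Clone(f"clone{i + 1:0{width}d}", layout.assemble(ins), f)
        for i, ins in enumerate(inserts)
    ]
    if include_empty_vector:
        clones.append(
            Clone("empty_vector", layout.assemble_empty_vector(), empty_vector_freq)
        )
    return ClonePool(clones, layout)


def assign_fitness_effects(
    pool: ClonePool,
    frac_pos: float,
    frac_neg: float,
    s_pos: float,
    s_neg: float,
    rng: np.random.Generator,
    neutral_ids: tuple[str, ...] = ("empty_vector",),
) -> ClonePool:
    """Assign selection coefficients: exact fractions get s_pos / s_neg.

    Counts are deterministic (``round(frac * n)``); which clones get them is
    randomized.  Clones named in ``neutral_ids`` (the empty vector by
    default) are held neutral and excluded from the draw.  Returns a new
    pool; the original initial frequencies are untouched.
    """
    if frac_pos < 0 or frac_neg < 0:
        raise ValueError("fractions must be non-negative")
    if frac_pos + frac_neg > 1:
        raise ValueError("frac_pos + frac_neg must be <= 1")
    eligible = [i for i, c in enumerate(pool.clones) if c.id not in neutral_ids]
    n = len(eligible)
    n_pos = int(round(frac_pos * n))
    n_neg = int(round(frac_neg * n))
    if n_pos + n_neg > n:
        raise ValueError("requested fractions exceed eligible clones")
    order = rng.permutation(n)
    s = np.zeros(len(pool))
    s[np.array(eligible)[order[:n_pos]]] = s_pos
    s[np.array(eligible)[order[n_pos : n_pos + n_neg]]] = s_neg
    return pool.with_fitness(s)


@dataclass(frozen=True)
class PassageConfig:
    """Serial-passage design: cycles, growth, bottlenecks, replicates."""

    n_cycles: int = 4
    generations_per_cycle: float = 10.0
    dilution_factor: int = 10
    bottleneck_size: int = 10_000_000
    n_replicates: int = 5
    stochastic: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cycles < 2:
            raise ValueError("n_cycles must be >= 2")
        if self.dilution_factor < 2:
            raise ValueError("dilution_factor must be >= 2")
        if self.bottleneck_size < 1:
            raise ValueError("bottleneck_size must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class SequencingConfig:
    """Amplicon sequencing: depth per sample, error rate, quality codes."""

    depth: int = 100_000
    substitution_error_rate: float = 0.001
    quality_high: int = 40
    quality_low: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.substitution_error_rate <= 0.1:
            raise ValueError("substitution_error_rate must be in [0, 0.1]")
        for q in (self.quality_high, self.quality_low):
            if not 2 <= q <= 41:
                raise ValueError("quality values must be Phred 2..41")


@dataclass
class TrajectoryTable:
    """Clone frequencies at each (replicate, cycle) sampling point.

    ``freqs[r, c, i]`` is clone ``i``'s frequency at cycle ``c+1`` of
    replicate ``r+1``.  Every (replicate, cycle) slice sums to 1.
    """

    clone_ids: list[str]
    freqs: np.ndarray  # (n_replicates, n_cycles, n_clones)

    def __post_init__(self) -> None:
        sums = self.freqs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each (replicate, cycle) slice must sum to 1")

    @property
    def n_replicates(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.freqs.shape[1]

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in range(self.n_replicates):
            for c in range(self.n_cycles):
                rows.append(
                    pd.DataFrame(
                        {
                            "replicate": r + 1,
                            "cycle": c + 1,
                            "clone_id": self.clone_ids,
                            "frequency": self.freqs[r, c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def simulate_growth_cycle(
    freqs: np.ndarray, s: np.ndarray, g: float
) -> np.ndarray:
    """One deterministic competitive growth cycle of ``g`` generations.

    ``f_i' = f_i 2^{g(1+s_i)} / sum_j f_j 2^{g(1+s_j)}``.  The shared
    ``2^g`` factor cancels; it is kept explicit for clarity of the model.
    """
    freqs = np.asarray(freqs, dtype=float)
    s = np.asarray(s, dtype=float)
    if not np.isclose(freqs.sum(), 1.0, atol=1e-9):
        raise ValueError("frequencies must sum to 1")
    w = np.exp2(g * (1.0 + s))
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite growth weights; check s and g")
    x = freqs * w
    return x / x.sum()


def simulate_serial_passage(
    pool: ClonePool,
    cfg: PassageConfig,
    rng: np.random.Generator | None = None,
) -> TrajectoryTable:
    """Alternate growth cycles and 1:``dilution_factor`` bottlenecks.

    Each replicate starts from the pool's initial frequencies, grows for
    ``generations_per_cycle`` generations, is sampled (recorded), then
    seeds the next cycle through a bottleneck of ``bottleneck_size`` cells
    (multinomial when stochastic, identity otherwise).  Clones lost at a
    bottleneck stay in the table with frequency 0.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    s = pool.s_values
    g = cfg.generations_per_cycle
    n = len(pool)
    out = np.zeros((cfg.n_replicates, cfg.n_cycles, n))
    for r in range(cfg.n_replicates):
        f = pool.init_freqs.copy()
        for c in range(cfg.n_cycles):
            f = simulate_growth_cycle(f, s, g)
            out[r, c] = f
            if c < cfg.n_cycles - 1 and cfg.stochastic:
                draw = rng.multinomial(cfg.bottleneck_size, f)
                f = draw / cfg.bottleneck_size
    return TrajectoryTable(pool.ids, out)


# ---------------------------------------------------------------------------
# sequencing
# ---------------------------------------------------------------------------


@dataclass
class ReadBatch:
    """Fixed-length reads for one amplicon length class of one sample."""

    seq: np.ndarray  # (n, L) ASCII codes
    qual: np.ndarray  # (n, L) Phred scores
    clone_idx: np.ndarray  # (n,) index into the pool (ground truth)


@dataclass
class SampleReads:
    """Simulated paired reads of one (replicate, cycle) sample.

    R1 reads the amplicon forward, R2 reads its reverse complement; both
    mates span the full amplicon (overlapping paired-end design).  Reads
    are grouped in batches of equal length.
    """

    r1: list[ReadBatch]
    r2: list[ReadBatch]

    @property
    def n_reads(self) -> int:
        return sum(b.seq.shape[0] for b in self.r1)


def _apply_substitutions(
    seq: np.ndarray,
    qual: np.ndarray,
    rate: float,
    q_high: int,
    q_low: int,
    rng: np.random.Generator,
    chunk: int = 50_000,
) -> None:
    """In place: substitute bases at ``rate``; error bases get low quality."""
    n, L = seq.shape
    qual[:] = q_high
    if rate <= 0 or n == 0:
        return
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        mask = rng.random((hi - lo, L), dtype=np.float32) < rate
        r, c = np.nonzero(mask)
        if r.size == 0:
            continue
        # replace with one of the three other bases, uniformly
        cur = seq[lo:hi][r, c]
        shift = rng.integers(1, 4, size=r.size)
        cur_idx = np.searchsorted(NUCS, cur)
        seq[lo:hi][r, c] = NUCS[(cur_idx + shift) % 4]
        qual[lo:hi][r, c] = q_low


def simulate_sample_reads(
    pool: ClonePool,
    freqs: np.ndarray,
    seqcfg: SequencingConfig,
    rng: np.random.Generator,
    context: AmpliconContext | None = None,
) -> SampleReads:
    """Draw ``depth`` read pairs multinomially from clone frequencies.

    Each pair covers the full amplicon (primer context + construct).  Both
    mates carry independent per-base substitution errors at the configured
    rate; error positions receive ``quality_low``, everything else
    ``quality_high``, so conflicting overlap bases are distinguishable by
    quality during merging.
    """
    context = context or AmpliconContext()
    counts = rng.multinomial(seqcfg.depth, np.asarray(freqs, dtype=float))
    amplicons = [context.amplicon(seq) for seq in pool.sequences]

    by_len: dict[int, list[int]] = {}
    for i, a in enumerate(amplicons):
        by_len.setdefault(len(a), []).append(i)

    r1_batches: list[ReadBatch] = []
    r2_batches: list[ReadBatch] = []
    for L in sorted(by_len):
        members = [i for i in by_len[L] if counts[i] > 0]
        if not members:
            continue
        n = int(sum(counts[i] for i in members))
        seq_f = np.empty((n, L), dtype=np.uint8)
        clone_idx = np.empty(n, dtype=np.int64)
        pos = 0
        for i in members:
            k = int(counts[i])
            row = np.frombuffer(amplicons[i].encode(), dtype=np.uint8)
            seq_f[pos : pos + k] = row
            clone_idx[pos : pos + k] = i
            pos += k
        # shuffle within the batch so file order carries no clone signal
        perm = rng.permutation(n)
        seq_f = seq_f[perm]
        clone_idx = clone_idx[perm]
        seq_r = revcomp_bytes(seq_f).copy()

        qual_f = np.empty_like(seq_f)
        qual_r = np.empty_like(seq_r)
        _apply_substitutions(
            seq_f, qual_f, seqcfg.substitution_error_rate,
            seqcfg.quality_high, seqcfg.quality_low, rng,
        )
        _apply_substitutions(
            seq_r, qual_r, seqcfg.substitution_error_rate,
            seqcfg.quality_high, seqcfg.quality_low, rng,
        )
        r1_batches.append(ReadBatch(seq_f, qual_f, clone_idx))
        r2_batches.append(ReadBatch(seq_r, qual_r, clone_idx))
    return SampleReads(r1_batches, r2_batches)


def write_fastq(path: str, batches: list[ReadBatch], prefix: str) -> int:
    """Write read batches as Phred+33 FASTQ; returns the number of reads."""
    n_written = 0
    with open(path, "w") as fh:
        for b, batch in enumerate(batches):
            seqs = batch.seq
            quals = batch.qual + 33
            for i in range(seqs.shape[0]):
                fh.write(
                    f"@{prefix}_b{b}_r{i}\n"
                    f"{seqs[i].tobytes().decode()}\n+\n"
                    f"{quals[i].astype(np.uint8).tobytes().decode()}\n"
                )
                n_written += 1
    return n_written


def simulate_amplicon_reads(
    trajectory: TrajectoryTable,
    pool: ClonePool,
    seqcfg: SequencingConfig,
    out_dir: str,
    experiment: str = "exp1",
    context: AmpliconContext | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int, str, str]]:
    """Write paired FASTQ files per (replicate, cycle) sampling point.

    Files are named ``{experiment}_{replicate}_{cycle}_R1/R2.fastq``.
    Returns (replicate, cycle, r1_path, r2_path) tuples in a fixed order,
    so identical seeds give byte-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(seqcfg.seed)
    os.makedirs(out_dir, exist_ok=True)
    out = []
    for r in range(trajectory.n_replicates):
        for c in range(trajectory.n_cycles):
            sample = simulate_sample_reads(
                pool, trajectory.freqs[r, c], seqcfg, rng, context
            )
            tag = f"{experiment}_{r + 1}_{c + 1}"
            p1 = os.path.join(out_dir, f"{tag}_R1.fastq")
            p2 = os.path.join(out_dir, f"{tag}_R2.fastq")
            write_fastq(p1, sample.r1, tag)
            write_fastq(p2, sample.r2, tag)
            out.append((r + 1, c + 1, p1, p2))
    return out
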