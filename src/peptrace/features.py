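"""Per-clone sequence descriptors and group-level summaries.

Covers ORF prediction and translation, GC content, the geometric model of
peptide lengths implied by random in-frame stop codons, amino-acid
composition contrasts ordered along a disorder-propensity axis
(TOP-IDP), and ingestion of externally computed disorder (IDS) and
aggregation (PEU) scores.

The geometric length model: a random insert of ``n`` codons terminates
translation at its first in-frame stop.  If each codon is a stop with
probability ``p`` (3/64 for equimolar synthesis), the peptide formed by
the 4 vector residues plus ``j-1`` random residues has probability
``(1-p)**(j-1) * p`` (stop at random codon ``j``), and the full-length
65-residue peptide — read-through into the constant 3' flank — carries
the survival mass ``(1-p)**n``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .construct import STOP_CODONS, ConstructLayout

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# ORFs and peptides
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrfRecord:
    clone_id: str
    sequence: str  # start codon through last codon before stop (or seq end)
    start: int  # 0-based, half-open coordinates on the input sequence
    end: int


def find_first_orf(
    sequence: str, min_orf_nt: int = 12, clone_id: str = ""
) -> OrfRecord | None:
    """Leftmost ATG-initiated ORF of at least ``min_orf_nt`` nucleotides.

    The ORF runs from the ATG to the first in-frame stop (stop excluded)
    or, absent a stop, to the last complete codon.  Forward strand only.
    ATGs whose ORF falls below the minimum length are skipped in favor of
    later starts, mirroring start-to-stop ORF finders with a minimum size.
    """
    seq = sequence.upper()
    pos = seq.find("ATG")
    while pos >= 0:
        end = pos
        for i in range(pos, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                break
            end = i + 3
        length = end - pos
        if length >= min_orf_nt:
            return OrfRecord(clone_id, seq[pos:end], pos, end)
        pos = seq.find("ATG", pos + 1)
    return None


def translate(orf: str) -> str:
    """Standard-genetic-code translation of an ORF (no internal stop)."""
    if len(orf) % 3 != 0:
        raise ValueError("ORF length must be a multiple of 3")
    pep = str(Seq(orf).translate(table=1))
    if "*" in pep:
        raise ValueError("internal stop codon: not a valid ORF")
    return pep


def gc_content(sequence: str) -> float:
    """Percent G+C of a sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def extract_random_part(
    clean_read: str, flank5_nt: int = 12, flank3_nt: int = 33
) -> str:
    """The random insert of a clean read (vector flanks trimmed)."""
    if len(clean_read) < flank5_nt + flank3_nt + 1:
        raise ValueError(
            f"clean read of {len(clean_read)} nt has no random part "
            f"(needs > {flank5_nt + flank3_nt})"
        )
    return clean_read[flank5_nt : len(clean_read) - flank3_nt]


def random_peptide_part(peptide: str, n_term: int = 4, c_term: int = 11) -> str:
    """Vector-coded residues removed: N-terminal MKLS and, for full-length
    peptides only, the C-terminal linker+FLAG block."""
    body = peptide[n_term:]
    if len(peptide) == 65 and len(body) >= c_term:
        body = body[:-c_term]
    return body


# ---------------------------------------------------------------------------
# geometric length model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometricLengthModel:
    """Expected peptide-length distribution of a random-insert library."""

    p: float  # per-codon stop probability
    n_sequences: int = 1
    n_random_codons: int = 50
    min_peptide: int = 4  # vector-coded residues preceding the insert
    full_length: int = 65

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must lie in (0, 1)")

    @property
    def support(self) -> list[int]:
        return list(
            range(self.min_peptide, self.min_peptide + self.n_random_codons)
        ) + [self.full_length]

    def pmf(self) -> pd.Series:
        """P(peptide length); sums to exactly 1 over the support."""
        j = np.arange(1, self.n_random_codons + 1)
        probs = (1.0 - self.p) ** (j - 1) * self.p
        survival = (1.0 - self.p) ** self.n_random_codons
        values = np.append(probs, survival)
        return pd.Series(values, index=pd.Index(self.support, name="peptide_length"))


def stop_probability_equimolar() -> float:
    """Per-codon stop probability under equimolar synthesis: 3/64."""
    return 3.0 / 64.0


def expected_length_distribution(model: GeometricLengthModel) -> pd.DataFrame:
    """Expected count of peptides of each length for ``n_sequences`` clones."""
    pmf = model.pmf()
    return pd.DataFrame(
        {"probability": pmf, "expected_count": pmf * model.n_sequences}
    )


def enumerate_short_peptides(
    layout: ConstructLayout | None = None, random_codons: int = 0
) -> tuple[int, set[str]]:
    """Distinct peptides over all insert prefixes of ``random_codons`` sense
    codons followed by a stop codon, by brute-force enumeration of all
    64**(random_codons+1) codon choices (the final position must be a stop).

    Returns (count, set of peptides).  For 0 random codons the single
    peptide is the vector-coded one (MKLS with the default layout).
    """
    if random_codons not in (0, 1, 2):
        raise ValueError("random_codons must be 0, 1, or 2")
    layout = layout or ConstructLayout()
    prefix_pep = translate(layout.flank5)
    codons = ["".join(c) for c in product("ACGT", repeat=3)]
    peptides: set[str] = set()
    for combo in product(codons, repeat=random_codons + 1):
        *sense, last = combo
        if last not in STOP_CODONS:
            continue
        if any(c in STOP_CODONS for c in sense):
            continue
        peptides.add(prefix_pep + translate("".join(sense)) if sense else prefix_pep)
    return len(peptides), peptides


# ---------------------------------------------------------------------------
# composition and disorder propensity
# ---------------------------------------------------------------------------


def _count_residues(peptides) -> pd.Series:
    counts = pd.Series(0, index=list(AMINO_ACIDS), dtype=float)
    for pep in peptides:
        bad = set(pep) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residues {sorted(bad)} in {pep!r}")
        for aa in pep:
            counts[aa] += 1
    return counts


def aa_frequencies(peptides, per_sequence: bool = False):
    """Amino-acid frequencies in percent.

    Pooled (default): all peptides concatenated and normalized once.
    ``per_sequence``: one distribution per peptide (length-corrected),
    returned as a DataFrame with one row per peptide.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("empty peptide set")
    if per_sequence:
        rows = [_count_residues([p]) / len(p) * 100.0 for p in peptides]
        return pd.DataFrame(rows).reset_index(drop=True)
    counts = _count_residues(peptides)
    return counts / counts.sum() * 100.0


class DisorderScale:
    """Amino-acid disorder propensities (order-promoting < 0 < disorder)."""

    def __init__(self, values: dict[str, float]):
        if set(values) != set(AMINO_ACIDS):
            raise ValueError("scale must cover exactly the 20 standard residues")
        self.values = dict(values)

    @classmethod
    def top_idp(cls) -> "DisorderScale":
        path = importlib.resources.files("peptrace.data").joinpath("top_idp.tsv")
        with path.open() as fh:
            frame = pd.read_csv(fh, sep="\t", comment="#")
        return cls(dict(zip(frame["amino_acid"], frame["propensity"])))

    @property
    def ordering(self) -> list[str]:
        """Residues from order-promoting to disorder-promoting."""
        return sorted(self.values, key=self.values.get)

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]


def mean_disorder_propensity(peptide: str, scale: DisorderScale | None = None) -> float:
    """Arithmetic mean of per-residue disorder propensities."""
    if not peptide:
        raise ValueError("empty peptide")
    scale = scale or DisorderScale.top_idp()
    return float(np.mean([scale[aa] for aa in peptide]))


def group_aa_difference(
    group_peptides, database_peptides, scale: DisorderScale | None = None
) -> pd.Series:
    """Signed pooled-frequency differences (group% - database%) per amino
    acid, ordered along the disorder-propensity axis."""
    scale = scale or DisorderScale.top_idp()
    diff = aa_frequencies(group_peptides) - aa_frequencies(database_peptides)
    return diff.reindex(scale.ordering)


# ---------------------------------------------------------------------------
# external scores and feature/group tables
# ---------------------------------------------------------------------------


def ingest_external_scores(scores: pd.DataFrame, clone_ids) -> pd.DataFrame:
    """Validate and join externally computed per-clone scores.

    ``scores`` must carry a ``clone_id`` column plus ``ids`` (average
    intrinsic disorder score in [0, 1]) and/or ``peu`` (best aggregation
    pairing energy).  Adds boolean flags: ``aggregation_prone`` when
    peu <= -5 and ``high_disorder`` when ids >= 0.5.
    """
    known = set(clone_ids)
    unknown = sorted(set(scores["clone_id"]) - known)
    if unknown:
        raise ValueError(f"unknown clone ids in score table: {unknown}")
    out = scores.set_index("clone_id").copy()
    if "ids" in out:
        bad = out["ids"].dropna()
        bad = bad[(bad < 0) | (bad > 1)]
        if not bad.empty:
            raise ValueError(
                f"IDS values outside [0, 1] for clones: {sorted(bad.index)}"
            )
        out["high_disorder"] = out["ids"] >= 0.5
    if "peu" in out:
        out["aggregation_prone"] = out["peu"] <= -5.0
    return out


DEFAULT_LENGTH_BINS = ((4, 9), (10, 17), (18, 29), (30, 47), (48, 65))


def length_class(length: int, bins=DEFAULT_LENGTH_BINS) -> str:
    for lo, hi in bins:
        if lo <= length <= hi:
            return f"{lo}-{hi}"
    return "other"


def build_feature_table(
    database_frame: pd.DataFrame,
    min_orf_nt: int = 12,
    scale: DisorderScale | None = None,
    flank5_nt: int = 12,
    flank3_nt: int = 33,
) -> pd.DataFrame:
    """Per-clone features from a database frame (clone_id, sequence).

    Columns: ORF coordinates, peptide, peptide length, GC of the read /
    random part / ORF, and mean disorder propensity of the random peptide
    part (vector residues excluded; NaN when none remain).
    """
    scale = scale or DisorderScale.top_idp()
    rows = []
    for _, rec in database_frame.iterrows():
        seq = rec["sequence"]
        orf = find_first_orf(seq, min_orf_nt, rec["clone_id"])
        pep = translate(orf.sequence) if orf else None
        has_random = len(seq) > flank5_nt + flank3_nt
        rand_nt = extract_random_part(seq, flank5_nt, flank3_nt) if has_random else ""
        rand_pep = random_peptide_part(pep) if pep else ""
        rows.append(
            {
                "clone_id": rec["clone_id"],
                "orf_start": orf.start if orf else None,
                "orf_end": orf.end if orf else None,
                "peptide": pep,
                "pep_len": len(pep) if pep else 0,
                "gc_read": gc_content(seq),
                "gc_random": gc_content(rand_nt) if rand_nt else np.nan,
                "gc_orf": gc_content(orf.sequence) if orf else np.nan,
                "mean_propensity": (
                    mean_disorder_propensity(rand_pep, scale) if rand_pep else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).set_index("clone_id")


def summarize_groups(
    features: pd.DataFrame,
    consensus: pd.Series,
    length_bins=DEFAULT_LENGTH_BINS,
    scores: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Group-level summaries per consensus category (POS/NEG/NS).

    Returns tidy frames: ``lengths`` (per-group length histogram),
    ``gc`` (per-clone GC values with group labels, histogram raw data),
    ``aa_difference`` (pooled random-part composition minus the whole
    database, disorder-propensity ordered), and — when external scores
    are supplied — ``scores_by_length`` (IDS/PEU per group and length
    class).  Empty groups simply contribute no rows.
    """
    joined = features.join(consensus.rename("consensus"), how="left")
    joined["consensus"] = joined["consensus"].fillna("UNASSIGNED")
    groups = [g for g in ("POS", "NEG", "NS") if (joined["consensus"] == g).any()]

    lengths = (
        joined[joined["consensus"].isin(groups)]
        .groupby(["consensus", "pep_len"])
        .size()
        .rename("n_clones")
        .reset_index()
    )

    gc = joined.loc[
        joined["consensus"].isin(groups), ["consensus", "gc_read", "gc_orf"]
    ].reset_index()

    db_peps = [random_peptide_part(p) for p in joined["peptide"].dropna()]
    db_peps = [p for p in db_peps if p]
    scale = DisorderScale.top_idp()
    diffs = {}
    for g in groups:
        peps = [
            random_peptide_part(p)
            for p in joined.loc[joined["consensus"] == g, "peptide"].dropna()
        ]
        peps = [p for p in peps if p]
        if peps and db_peps:
            diffs[g] = group_aa_difference(peps, db_peps, scale)
    aa_difference = pd.DataFrame(diffs)
    aa_difference.index.name = "amino_acid"

    out = {"lengths": lengths, "gc": gc, "aa_difference": aa_difference}

    if scores is not None:
        sc = joined.join(scores, how="left")
        sc["length_class"] = [length_class(n, length_bins) for n in sc["pep_len"]]
        cols = [c for c in ("ids", "peu") if c in sc.columns]
        if cols:
            out["scores_by_length"] = (
                sc[sc["consensus"].isin(groups)]
                .groupby(["consensus", "length_class"])[cols]
                .agg(["mean", "median", "count"])
                .reset_index()
            )
    return out
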