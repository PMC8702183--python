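"""Expression-construct layout for the random-peptide library.

Each clone carries a random insert cloned between constant vector flanks:
a short 5' coding flank that contributes the first residues of every
peptide (M-K-L-S), and a 3' coding flank of three linker codons plus the
eight FLAG-tag codons, followed by a stop codon.  A full-length construct
is therefore ``flank5 + insert + flank3_coding + stop`` and, with the
default 150-nt insert, codes for a 65-residue peptide on a 195-nt coding
region.
"""

from __future__ import annotations

from dataclasses import dataclass

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: 5' vector flank: ATG AAG CTT AGC -> M K L S (HindIII-derived K/L codons).
DEFAULT_FLANK5 = "ATGAAGCTTAGC"
#: 3' vector flank coding part: 3 linker codons (L E G) + FLAG tag DYKDDDDK.
DEFAULT_FLANK3_CODING = "CTCGAGGGT" + "GATTACAAGGATGACGATGACAAG"
DEFAULT_STOP = "TAA"

#: Fixed primer context flanking the construct in the sequenced amplicon.
#: Long enough that even the insert-less vector amplicon exceeds the
#: minimum merge length of the read-processing defaults.
DEFAULT_PRIMER5 = "GAGCTGTTGACAATTAATCATCGGCTCGTATAATGTGGATAACAATTTCACACAGG"
DEFAULT_PRIMER3 = "CATCATAACGGTTCTGGCAAATATTCTGAAATGAGCTGTTGACAATTAATCATCGG"


def _has_inframe_stop(seq: str) -> bool:
    return any(seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq) - 2, 3))


@dataclass(frozen=True)
class ConstructLayout:
    """Geometry of the cloning construct.

    Parameters
    ----------
    flank5 : constant 5' coding flank, starting with the ATG start codon.
    insert_length : length of the random insert in nucleotides.
    flank3_coding : constant 3' coding flank (linker + FLAG tag), no stop.
    stop_codon : the stop codon terminating full-length constructs.
    """

    flank5: str = DEFAULT_FLANK5
    insert_length: int = 150
    flank3_coding: str = DEFAULT_FLANK3_CODING
    stop_codon: str = DEFAULT_STOP

    def __post_init__(self) -> None:
        for name in ("flank5", "flank3_coding", "stop_codon"):
            seq = getattr(self, name)
            if set(seq) - set("ACGT"):
                raise ValueError(f"{name} contains non-ACGT characters: {seq!r}")
        if len(self.flank5) % 3 != 0:
            raise ValueError("flank5 length must be a multiple of 3")
        if len(self.flank3_coding) % 3 != 0:
            raise ValueError("flank3_coding length must be a multiple of 3")
        if self.insert_length % 3 != 0:
            raise ValueError("insert_length must be a multiple of 3")
        if self.insert_length < 0:
            raise ValueError("insert_length must be non-negative")
        if not self.flank5.startswith("ATG"):
            raise ValueError("flank5 must start with the ATG start codon")
        if self.stop_codon not in STOP_CODONS:
            raise ValueError(f"stop_codon must be one of {sorted(STOP_CODONS)}")
        if _has_inframe_stop(self.flank3_coding):
            raise ValueError("flank3_coding must not contain an in-frame stop")
        if _has_inframe_stop(self.flank5):
            raise ValueError("flank5 must not contain an in-frame stop")

    @property
    def coding_length(self) -> int:
        """Length of the coding region (start codon through last FLAG codon)."""
        return len(self.flank5) + self.insert_length + len(self.flank3_coding)

    @property
    def full_length(self) -> int:
        """Construct length including the stop codon."""
        return self.coding_length + len(self.stop_codon)

    @property
    def n_insert_codons(self) -> int:
        return self.insert_length // 3

    @property
    def full_peptide_length(self) -> int:
        """Residues of a full-length peptide (no stop within the insert)."""
        return self.coding_length // 3

    @property
    def min_peptide_length(self) -> int:
        """Residues when the first insert codon is a stop (vector peptide)."""
        return len(self.flank5) // 3

    def assemble(self, insert: str) -> str:
        """Return the full construct carrying ``insert``."""
        if len(insert) != self.insert_length:
            raise ValueError(
                f"insert length {len(insert)} != layout insert_length "
                f"{self.insert_length}"
            )
        return self.flank5 + insert + self.flank3_coding + self.stop_codon

    def assemble_empty_vector(self) -> str:
        """The construct with no insert (the 'empty vector' clone)."""
        return self.flank5 + self.flank3_coding + self.stop_codon


@dataclass(frozen=True)
class AmpliconContext:
    """Constant primer-derived sequence surrounding the construct in reads."""

    primer5: str = DEFAULT_PRIMER5
    primer3: str = DEFAULT_PRIMER3

    def amplicon(self, construct: str) -> str:
        return self.primer5 + construct + self.primer3

    def upstream_anchor(self, layout: ConstructLayout, length: int = 18) -> str:
        """Anchor around the start codon: primer tail + 5' flank (18 nt)."""
        n_primer = length - len(layout.flank5)
        if n_primer < 0:
            raise ValueError("anchor shorter than flank5")
        if n_primer > len(self.primer5):
            raise ValueError("anchor longer than available primer context")
        return (self.primer5[len(self.primer5) - n_primer :] + layout.flank5)[:length]

    def downstream_anchor(self, layout: ConstructLayout, flag_nt: int = 24) -> str:
        """Anchor at the 3' end: FLAG-tag codons plus the stop codon."""
        return layout.flank3_coding[-flag_nt:] + layout.stop_codon
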