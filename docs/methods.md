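# Methods

## Competition model

The simulator treats the library as a closed population of clones
competing during regrowth after each dilution.  Growth is deterministic
exponential: over a cycle of `g` generations, clone *i* with selection
coefficient `s_i` (per-generation relative growth advantage, `s = 0`
neutral, `|s| < 1`) changes frequency as

    f_i' = f_i · 2^{g(1+s_i)} / Σ_j f_j · 2^{g(1+s_j)}.

Stochasticity enters only at two places: the bottleneck between cycles
(a multinomial draw of `bottleneck_size` cells from the current
frequencies, modelling the 1:10 seeding), and sequencing (a multinomial
draw of `depth` read pairs per sample plus independent per-base
substitution errors).  This separation is deliberate: the expected log2
frequency change of any clone has a closed form (the product of
per-cycle weights), which gives the enrichment estimator an analytic
oracle, while the bottleneck and sequencing layers contribute realistic
counting noise.  Samples are taken after each growth phase; with 4
cycles the reported contrast (cycle 4 vs cycle 1) spans exactly three
growth updates.

Key defaults and why:

- `generations_per_cycle = 10`: a 3-h rich-medium *E. coli* cycle
  supports roughly 6–10 doublings; the value is configurable and the
  studies below state the value they use.
- `bottleneck_size = 10⁷` cells: large enough that bottleneck drift is
  negligible relative to sequencing noise at desk-scale depths; culture
  population sizes are otherwise unconstrained by the experimental
  description, so this is a free parameter.
- `dilution_factor = 10`, `n_cycles = 4`, 5 replicates: the serial
  passage design being emulated.
- Empty vector at initial frequency 0.05: the real library contains an
  extreme-outlier cluster for the insert-less vector; the exact
  proportion is data-dependent, so a single representative value is
  fixed here.
- Fitness assignment uses exact deterministic counts
  (`round(frac · n)`) with randomized placement, so recovery studies
  have integer ground-truth group sizes.
- Sequencing errors are substitutions only; error bases receive the low
  quality value (default Q10) and correct bases the high one (Q40), so
  quality-directed merge resolution is exercised by construction.  PCR
  amplification bias is not modelled; PCR errors are treated as part of
  the substitution rate.

## Construct geometry

A clone's construct is `flank5 (12 nt, coding MKLS) + insert (150 nt) +
flank3 (33 nt coding: 3 linker codons + 8 FLAG codons) + stop`.  The
coding region from start codon through the last FLAG codon is 195 nt
(65 residues); the insert-less vector yields 45 nt.  Amplicons embed
the construct in fixed primer context long enough that even the empty
vector exceeds the minimum merge length.  The anchors used for clean-
read extraction are the 18 nt ending at the last base of `flank5`
(primer tail + flank, containing the start codon) and the 27-nt
FLAG+stop block; both must occur exactly once.

## Read processing

Merging slides the reverse-complemented mate along the forward mate and
takes the offset maximizing matching bases among those with overlap ≥
`min_merge_length` (default 100; ties → longer overlap).  Conflicting
overlap positions take the base with the higher quality, ties keeping
the forward base; pairs with more than `max_diffs = 30` conflicts are
rejected.  Quality trimming (sliding window, mean-quality threshold) is
available but off by default — the simulator's quality model makes it
redundant, and the upstream trimming protocol of the emulated
experiments left its parameters unstated.  Anchor matching is exact
substring search: a read whose anchors carry errors is better discarded
than rescued, and ambiguity (an anchor twice) rejects the read.

For simulation-scale samples a vectorized path (`merge_batches`,
`clean_reads_from_sample`) performs the same merge at the known
full-overlap geometry on whole arrays and deduplicates merged reads
before anchor search; its equivalence to the per-read functions is
tested.

## Database construction

Three dereplication rounds: (1) per-file exact dereplication with size
annotations; (2) removal of per-file singletons — the most likely PCR or
sequencing artefacts — followed by pooling and a second exact
dereplication summing sizes; (3) abundance-sorted greedy centroid
clustering at 0.97 identity, then a minimum cluster size of 8.

Identity is defined as matching columns divided by alignment columns of
a global (Needleman–Wunsch) alignment with match +1, mismatch −1, gap
−2, counting every gap column as a mismatch.  This definition makes the
mismatch budget of the threshold exact: a 195-nt read tolerates at most
5 substitutions (190/195 = 0.9744 ≥ 0.97; 189/195 = 0.9692 < 0.97).
Gapped alignments are allowed but gaps count against identity.  Ties in
the abundance sort are broken lexicographically by sequence, making
clustering deterministic and input-order invariant; members are
compared to centroids only (no re-centering).

Two exact-equivalent accelerations are used and tested against
brute-force references: a hamming fast path for equal-length pairs
within distance 2 (where the diagonal alignment is provably optimal
under the scoring above), and a 16-mer candidate screen — identity ≥
0.97 bounds the edit count, each edit destroys at most 16 of the
query's 16-mers, so true matches must share a computable minimum number
of 16-mer positions.  Below 0.97 the screen is disabled and every
candidate is scanned.

## Mapping and count tables

Each clean read maps to at most one database clone: the best-identity
centroid passing identity ≥ 0.97, query coverage ≥ 0.9 (non-gap query
columns / query length), and ≤ 5 gap columns; ties prefer the larger
cluster, then the lexicographically smaller clone id.  Thresholds are
inclusive (≥).  Reads are orientation-fixed by the primers, so only the
forward strand is aligned.  Results are memoized per distinct sequence
and tallied into clone × (replicate, cycle) count tables.

## Enrichment test

Counts are normalized by median-of-ratios size factors (median over
clones nonzero in every sample of count / geometric mean across
samples, rescaled to geometric mean 1; column-sum fallback when no
clone qualifies).  Per clone, cycle is a categorical factor; the
per-cycle means of normalized counts `q_c` summarize the fit, and the
reported effect is `β = log2 q_last − log2 q_first`.  Under a
negative-binomial model with dispersion α, `Var(K/f) = q/f + α q²`;
dispersions are estimated per clone by method of moments on the
within-cycle residuals (floored at 1e-8), a mean–dispersion trend
`α(μ) = a₀ + a₁/μ` is fitted across clones, and the final dispersion is
the 50/50 log-space combination of the two.  The Wald statistic uses
the delta-method standard error of β; p-values come from the normal
approximation, adjusted by Benjamini–Hochberg across clones within the
single last-vs-first contrast per experiment.  Flags: POS if `β > 0`
and `p_adj < α` (default 0.05), NEG if `β < 0` and `p_adj < α`, else
NS.  A cycle with all-zero counts enters the contrast with a
pseudo-mean of 0.5 normalized counts.

This is a transparent simplification of the standard RNA-seq count
frameworks: no empirical-Bayes dispersion shrinkage, no outlier
refitting, no independent filtering, no fold-change shrinkage.  The
intended use — detecting the large, replicated frequency changes that
serial-passage competition produces — is validated by its statistical
properties on simulated data (type-I error ≤ 7% adjusted rejections on
an all-neutral library; ≥ 80% consensus recovery of ±0.05 selection
coefficients at 3 experiments × 5 replicates × 10⁵ reads) rather than
by numerical agreement with any particular implementation.

Consensus across experiments: a clone's consensus category is the flag
reached by at least a strict majority (`floor(n/2)+1`) of the
*configured* number of experiments; experiments where the clone was
filtered out still count toward the denominator.  If the threshold is
lowered so that two flags qualify, the more frequent one wins and exact
ties stay UNASSIGNED.  The empty vector is traced across experiments as
an internal reference clone.

## Sequence features

- **ORFs**: leftmost ATG-initiated frame to the first in-frame stop
  (excluded) or the last complete codon, forward strand, minimum 12 nt
  including the start codon; ATGs whose ORF falls short are skipped in
  favor of later starts.  Translation uses the standard genetic code.
- **Geometric length model**: with per-codon stop probability `p`
  (3/64 for equimolar synthesis; computed from the positional
  probability matrix, averaged over codons, when one is supplied),
  `P(length 4+j−1) = (1−p)^{j−1} p` for stop at insert codon `j`, and
  `P(65) = (1−p)^{50}` for read-through into the constant flank.  The
  PMF sums to 1 exactly for any `p`.
- **Short-peptide enumeration**: brute force over all codon choices
  shows clones whose insert starts with a stop encode exactly 1 peptide
  (MKLS), one free sense codon gives 20, two give 400 (the standard
  code has 20 amino acids over 61 sense codons).  Counts of 21 and 441
  would follow only from a 21-letter alphabet; this package reports the
  brute-force values.
- **GC content** is reported separately for the clean read, the random
  insert, and the predicted ORF, so either inclusion convention for the
  vector-coded codons is available.
- **Composition**: pooled amino-acid frequencies (concatenated counts,
  normalized once) and per-sequence (length-corrected) distributions;
  group-vs-database differences are reported signed and ordered along
  the TOP-IDP disorder-propensity axis (shipped as a versioned data
  file; constants of the method, not fitted).  The mean TOP-IDP
  propensity of the random peptide part serves as an internal
  disorder-propensity proxy.
- **External scores**: per-residue disorder predictors and aggregation
  energy predictors are external to this package; their per-clone
  outputs (average IDS in [0,1]; best pairing energy in PEU) are
  ingested from TSV, validated against the database, and flagged at the
  conventional cutoffs (IDS ≥ 0.5 high disorder; PEU ≤ −5
  aggregation-prone).
- **Length classes** for grouped summaries default to 4–9, 10–17,
  18–29, 30–47, 48–65 residues; the bins are configurable and echoed in
  output headers, since figure conventions for such classes vary.

## What the simulations do and do not show

The generator reproduces the statistical structure the pipeline relies
on: multinomial sampling at bottleneck and sequencer, substitution
errors with informative qualities, a geometric peptide-length spectrum,
optional positional nucleotide bias, and an empty-vector reference
clone.  It does not model PCR amplification bias or chimeras, indels
(beyond an exercised gap-handling path in mapping), mutation during
passaging, plasmid copy-number variation, or chemostat/logistic growth.
Passing recovery tests therefore demonstrate correctness of the
algorithms under the stated noise model, not robustness to every
artefact of real amplicon data.  Real libraries also show overdispersion
between biological replicates beyond multinomial noise; the
moment-based dispersion estimator absorbs this in principle, but its
calibration here is only tested under the simulated noise model.

## Numerical choices

Frequency vectors are validated to sum to 1 within 1e-9; growth updates
renormalize exactly.  Dispersion floor 1e-8; Wald standard errors
floored at 1e-12; BH adjustment enforces monotonicity and caps at 1.
Clustering and mapping tie-breaks are fully specified (size, then
lexicographic), making every pipeline output deterministic for a fixed
seed — verified byte-for-byte in the test suite.  Problem sizes used by
the heavy studies: 2000 clones × 5 replicates × 4 cycles × 10⁵ reads
(error control) and 500 clones × 3 experiments × 5 replicates × 4
cycles × 10⁵ reads at substitution rate 0.001 (recovery); both run in a
few minutes on one CPU via the vectorized bulk path.
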