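# Methods

## Fold coordinate system

The globin fold is modeled as an ordered sequence of named segments —
helices `A`–`H`, internal loops `AB`…`GH`, and the terminal regions `NT`
and `CT` — declared as 1-based inclusive residue ranges on a single
reference sequence (`ReferenceFold`). Positions are 1-based within a
segment, rendered `B12`, `CD1`, `E10`. Segments need not tile the
reference: residues between declared segments are assigned to the
enclosing inter-segment region (the loop named by the flanking helices, or
`NT`/`CT` at the ends) with their own running indices.

Projection of queries works column-by-column through an MSA containing the
reference. A query residue aligned to a reference residue inherits that
residue's coordinate. Query residues in columns where the reference is
gapped are insertions: inside a segment they continue that segment's index
past the last one seen for that query (so labels like `E16` remain
well-defined even when the reference helix is shorter); between segments
they take the enclosing loop or terminus. One consequence, accepted by
design: an insertion index may coincide with a later reference index in
the same segment (e.g. an inserted `CD4` followed by the reference's own
`CD4`). Labels stay well-defined per query and segment order stays
monotone, which is what the downstream intron and residue surveys require.

The shipped default fold is a synthetic consensus globin: 155 residues,
helices A (16 aa) through H (21 aa) with short loops, carrying the
canonical Phe-CD1/His-E7/His-F8 triad. Its boundaries are an internal
convention, chosen so every helix comfortably contains the classical
landmark positions (B12, E7, E10, E16, F8, G7); users analyzing real data
should supply their own annotation TSV. Because published helix-boundary
conventions differ, results that depend on the boundary choice (e.g.
whether a central intron falls in `E` or `DE`) should be read relative to
the annotation used.

## Intron labeling

Intron positions are counted on the strand-ordered concatenated CDS.
For an intron after coding nucleotide `c` (1-based count):

- phase = `c mod 3`;
- phase 1/2: the intron interrupts codon `⌊(c−1)/3⌋+1` after its first or
  second base;
- phase 0: the intron precedes codon `c/3+1`.

The label concatenates the fold coordinate of that residue with the phase
(`B12.2`, `G7.0`). Valid offsets are `1 … 3N−1`; offset `3N` would fall
after the last codon and is rejected as outside the CDS, and a phase-0
"intron" before the first codon (offset 0) is likewise not an intron.
Only CDS-interrupting introns are labeled; UTR introns are ignored because
the notation is codon-anchored.

Conservation classes: `B12.2` and `G7.0` are ancestral for every globin
class; `E10.2` is additionally ancestral for GbX; all other labels are
variant. Variant sites are counted **by distinct label across the
dataset**, not by gene, since the question of interest is positional
novelty. "In or between helices E and F" is operationalized as segments
{E, EF, F}; a flag widens the rule to {DE, E, EF, F, FG} because the
phrase is genuinely ambiguous, and reports record which rule was used.

## Key residues and acylation

The survey reads the alignment columns of CD1, E7 and F8 (located via the
reference annotation). Verdicts: the canonical Phe/His/His are
`canonical`; Gln at E7 is `conservative` (a replacement repeatedly
observed in functional hemoglobins); a gap is `absent`; anything else
`deviant`. The dataset aggregate counts sequences whose three verdicts are
all `canonical` — strictly F/H/H by default. Because one could also read
"all three residues present" as admitting the conservative Gln, a
`count_conservative` switch implements that alternative; the default is
the strict reading.

Myristoylation is detected by the deterministic six-position consensus
applied after initiator-Met removal: `G` at position 2, position 3 not in
{E,D,R,K,H,P,F,Y,W}, positions 4–5 free, position 6 in {S,T,A,G,C,N},
position 7 not `P`. Learned predictors (neural or taxon-calibrated) are
*not* re-implemented; their calls can be imported as extra votes and
combined into a consensus tier (number of agreeing predictors, positive at
a configurable threshold, default 2 when multiple predictors are
registered). Palmitoylation is a window rule — any Cys at positions
2–`window` (default 10) — standing in for trained site predictors, since
the biological signal tracked here is dual acylation near the N-terminus.
Sequences that do not begin with Met or are shorter than the pattern are
reported `uncertain` and excluded from counts.

## Conservation statistics

Pairwise metrics run over the "globin core": alignment columns from the
first helix-A reference column through the last helix-H column. Columns
where either row is gapped are excluded from the denominator
(pairwise-deletion — the only convention under which sequences identical
modulo gaps score 100%). Identity is exact residue match; similarity is
BLOSUM62 score > 0 *or* identity (the disjunction matters only for
ambiguous `X`–`X` pairs, whose BLOSUM62 diagonal entry is negative, and it
preserves the invariant similarity ≥ identity). Class summaries average
over all unordered within-class pairs; averaging against a consensus would
be the main alternative and would give systematically higher numbers for
diverse classes. Classes with fewer than two labeled members are omitted
with a warning.

## Expression statistics

The standard curve is an ordinary least-squares fit of Ct on
log₁₀(copies) over a dilution series (≥ 3 distinct concentrations);
efficiency is `10^(−1/slope) − 1`, and unknowns are quantified by
inversion, averaging technical-replicate Cts before inversion. Relative
expression scales each tissue's mean to the reference tissue (= 100%) and
tests each tissue against the reference with a two-tailed, equal-variance
Student's t-test (Welch behind a flag). No multiple-testing correction is
applied. RPKM is definitional. The Rj statistic uses the natural
logarithm; another base would only rescale it. Zero counts contribute
zero; an all-zero gene is undefined and reported missing.

## Synthetic data

`synthdata` generates the study conditions, not arbitrary fixtures:

- **Families.** Members of a class derive independently from a class
  ancestor (itself a diverged copy of the reference with the canonical
  triad restored). Each site mutates with probability `q` to a
  BLOSUM62-softmax-weighted alternative; `q` is solved by root-finding so
  the expected pairwise identity between members equals the configured
  target, with an exact correction for the three key sites that are pinned
  canonical. No phylogeny is simulated — divergence is star-shaped — so
  the data test metric definitions and recovery, not tree-aware behavior.
  N-terminal extensions are random sequence (with pattern-conformant or
  pattern-breaking heads according to the motif plan) left-padded with
  gaps in the alignment, so they fall in reference-gap columns and map to
  `NT`.
- **Default dataset.** 187 sequences: HbL n=120 at 25% target identity
  (total length 171 aa), GbX n=30 at 68% (228 aa), GbXL n=37 at 67%
  (199 aa), N-terminal extension lengths chosen as total − 155-aa core.
  Fourteen key-residue deviants are planted in HbL (five Gln-E7, four
  other E7 replacements, four F8 replacements, one triple mutant
  Met-CD1/Val-E7/Val-F8), so the all-canonical aggregate is exactly 173.
  Similarity is emergent, not targeted: at a given identity the
  BLOSUM62-weighted substitution process yields similarity a few points
  below what natural purifying selection produces, which is why the
  generated GbXL similarity (~77%) sits below values reported for real
  conserved globin classes; tests therefore assert identity recovery and
  the similarity ≥ identity invariant, not a similarity target.
- **Gene models.** Proteins are back-translated with one fixed codon per
  amino acid (introns only care about codon boundaries), split at the CDS
  offsets implied by the planted fold labels, and interleaved with short
  `GT…AG` introns. Minus-strand genes are emitted as the reverse
  complement with mirrored exon coordinates, so label recovery is
  exercised on both strands.
- **qPCR.** Ct = intercept + slope·log₁₀(copies) + N(0, σ); defaults
  slope −3.45 (efficiency ≈ 0.95), intercept 38, σ = 0.2 cycles, 10-fold
  dilutions 10⁷…10¹ copies, triplicate technical replicates, and
  brain-dominant tissue means (brain 10× the weakest tissue), matching
  the design of a brain-expressed globin quantification.
- **Counts.** x_ij ~ Poisson(N_i·f_j·fc_ij) with log-normal baseline
  abundances around 10⁻⁴ and a planted fold change (default scenarios use
  fc = 8 in one library for 10 of 200 genes). Truth tables name the
  planted genes.

All generators take a seed and are byte-identical under it.

## Problem sizes and numerical notes

The shipped analyses run at deliberately modest sizes — 187-sequence
families, 155-residue core, 200-gene count matrices, 100-replicate
simulation sweeps, and exhaustive checks of 3.2 × 10⁶ N-termini and ~930
planted introns — chosen so the full test suite and the reproduction
script each complete in seconds to minutes on a single core while still
covering every code path exhaustively where enumeration is possible.

Tie-breaks and degenerate inputs: alignment-column filtering keeps scores
exactly at the threshold (columns "lower than" the cutoff are removed);
zero comparable columns yield missing identity/similarity rather than 0;
an all-zero gene yields missing Rj; a standard curve needs three distinct
concentrations; slope 0 cannot be inverted. Floating-point report fields
are printed at 4 decimals for reproducible diffs.

## Known limitations

- The fold mapping is alignment-derived; a poor MSA propagates into every
  downstream label. No structural validation is attempted.
- Insertion labeling can duplicate within-segment indices (see above).
- The myristoylation scan is the deterministic consensus pattern only;
  agreement counts with learned predictors require importing their calls.
- The per-site substitution generator has no rate heterogeneity, indels
  (beyond N-terminal extensions) or phylogenetic structure; passing
  recovery tests demonstrates correctness of the statistics, not
  robustness to real alignment error.
- Palmitoylation is a window heuristic; it does not model acyl-transferase
  specificity.
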