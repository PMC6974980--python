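# Methods

## Problem and model

`hdrquant` quantifies the outcome of a CRISPR/Cas9 knock-in experiment from
targeted amplicon sequencing. A knock-in attempt at a locus produces a
mixture of molecules: unedited wild type, correctly repaired alleles
(homology-directed repair, HDR, from a single-stranded donor), HDR alleles
carrying secondary damage, and NHEJ indels at the cut site. Deep sequencing
of a short (~250 bp) amplicon over the cut site samples this mixture; the
pipeline's job is to turn read pairs into per-category fractions.

The categorisation model is deliberately simple and auditable. Two exact
strings are derived from the locus and the edit: the wild-type sequence of
the guide-covered window (`wt_pattern`) and the same window with every
intended substitution applied (`hdr_pattern`). Each merged read is assigned
by an ordered cascade:

1. `wt_pattern` occurs as an exact substring → **WT**.
2. else `hdr_pattern` occurs as an exact substring → align the read
   end-to-end to the reference, reconstruct the covered CDS window,
   translate it, and compare against the wild-type protein with the
   expected residue change(s) applied. Equal → **Correct_HDR**; different →
   **Incorrect_HDR**. Extra *synonymous* nucleotide changes therefore never
   disqualify a correct edit, while any extra protein-changing event
   (substitution or frameshift) demotes the read.
3. else → **Others** (indels over the guide window, unmapped reads, PCR
   artifacts). Reads whose best global identity falls below a floor are
   tagged `unmapped` within this bucket.

"Match exactly" means substring occurrence, not whole-read equality: reads
extend well beyond the guide window and accumulate sequencing errors there;
only the assayed window is held to exactness. Both read orientations are
tried (forward first, then reverse complement) and the chosen orientation is
recorded.

Percentages are reported over assembled (merged) reads only; unmerged pairs
are counted separately and never enter denominators.

## Read merging

Pairs are merged by an alignment-free overlap scan: R2 is
reverse-complemented and slid along R1; the shift maximising overlap length
among shifts with mismatch density ≤ `max_mismatch_density` (default 0.25)
and overlap ≥ `min_overlap` (default 10 nt) wins. Within the overlap each
base is taken from the mate with the higher Phred quality; ties go to R1.
The contract (not the bit-level output) matches the widely used FLASH
merger; re-implementing it keeps the pipeline free of external binaries.
"Outie" overlaps (R2 extending left of R1) are not modelled — amplicon pairs
are "innie" by construction.

## Global alignment

Merged reads are aligned end-to-end to the reference amplicon with a
Needleman–Wunsch alignment under affine gap penalties (match +5, mismatch
−4, a gap of length L costs 10 + 0.5·L — EMBOSS-needle DNA defaults; end
gaps are penalised). The aligner is Biopython's `PairwiseAligner`; reported
indels are post-processed into leftmost placement (shifting gap runs through
equal bases, which preserves the score) so diff lists are reproducible. `N`
bases align with the mismatch score and never count toward identity.
Alignment scores are verified in the test suite against an independent
exhaustive oracle on a complete small-sequence grid.

The protein check translates only the CDS codons fully covered by the
read's alignment. If an expected residue change falls outside the covered
window the check is `not_applicable` and the read is reported under
`Others` with an explicit reason: correctness cannot be asserted without
observing the expected change, and incorrectness should not be asserted on
missing evidence. For full-length amplicon reads this path never triggers.

## Donor design

Donors are assembled as left arm + edited core + right arm, where the core
defaults to the classifier pattern window (guaranteeing the donor carries
every assayed substitution). `build_lssdna_donor` makes symmetric-arm long
ssDNA (e.g. 137 nt arms around a 25 nt core → 299 nt); `build_ssodn` makes
short donors of a fixed total length, symmetric (arms differ by ≤1 nt) or
asymmetric with an explicit split (default suggestion 36/68 for a 129-mer).
Antisense donors are the exact reverse complement of the sense design.

PAM/seed silencing (`silence_pam`) prevents re-cutting of the repaired
allele. In coding context it searches single-base synonymous substitutions
that destroy a G of the NGG PAM, with a total preference order — fewest
changes, wobble position, lexicographically smallest resulting codon — so
output is reproducible; if the PAM codon admits no synonymous change (e.g.
Trp TGG) it falls back to a synonymous substitution in the 12 nt
PAM-proximal seed, and raises when none exists. Outside coding sequence the
first G of the GG dinucleotide becomes A (arbitrary but fixed). Synonymy is
judged on the post-edit sequence so silencing can never revert the
knock-in.

Coding-bar design (`design_coding_bar`) enumerates all combinations of at
most `max_changes` synonymous codon replacements in a codon-aligned window
and keeps those that create a recognition site (IUPAC-aware, both strands)
for a listed enzyme where the wild-type context has none — a de-novo
restriction site usable for cheap RFLP genotyping without touching the
protein. Codons already carrying an intended substitution are left alone;
with `max_changes = 0` only sites completed by the intended edit itself
qualify. Candidates are ordered by nucleotide-change count, site position,
enzyme name. `verify_donor` closes the loop: arm identity, substitution
presence, absence of the intact protospacer+PAM on either strand, and
protein-level agreement.

## Restriction screen

`find_sites` scans IUPAC-degenerate recognitions with overlapping matches
on both strands (palindromes reported once); `digest` places cuts at the
top-strand offset from a bundled REBASE-style table (22 common enzymes,
cross-checked against Biopython's Restriction data in the tests) and falls
back to a blunt mid-site cut when the offset is unknown — fragment sizes
then shift by at most the site length, which never flips a
positive/negative call. `genotype_pool` models the pooled-embryo screen:
the enzyme must cut the edited amplicon and not the wild type (otherwise
the assay is uninformative), pools of mosaic embryos are summarised by the
mean edited fraction of their members, and a pool is called positive when
that fraction reaches `detection_threshold` (default 0.05, a nominal
agarose band-detection floor; the true floor of a gel assay is not
quantified anywhere, so it is a free parameter).

## Synthetic data

`simulate_locus` draws a random amplicon (default 250 nt) with a 45 nt CDS
window (15 codons, frame 0, sense strand) around its midpoint, a 20 nt
codon-aligned protospacer with NGG PAM inside the CDS, and an edit
consisting of one non-synonymous substitution at a seed-region codon middle
base (the knock-in, which also silences re-cutting) plus synonymous
Coding-bar substitutions creating a de-novo site for a bundled enzyme that
cuts the edited amplicon and not the wild type anywhere. Rejection sampling
with a bounded attempt count keeps the construction fully seeded.

`simulate_reads` draws molecules from a configurable class mixture
(defaults: WT 0.70, Correct_HDR 0.12, Incorrect_HDR_indel 0.04,
Incorrect_HDR_substitution 0.02, NHEJ_indel 0.12 — desk-scale conditions
loosely anchored to the published per-condition outcome fractions and
clearly illustrative). Class construction:

- *Correct_HDR*: all intended substitutions applied.
- *Incorrect_HDR_substitution*: HDR plus one protein-changing change at a
  codon middle base in the CDS outside the pattern window.
- *Incorrect_HDR_indel*: HDR plus a 1–2 nt (frameshifting) deletion in the
  CDS just downstream of the pattern window. Placing the secondary indel
  outside the guide window keeps the HDR pattern intact, which is the only
  way this class is expressible as `Incorrect_HDR` under the cascade; an
  indel inside the guide window would be (correctly) classified `Others`.
- *NHEJ_indel*: deletion (80%) or insertion (20%) centred at the cut site
  (3 bp 5′ of the PAM), lengths from {1: .3, 2: .2, 3: .15, 5: .1, 7: .1,
  10: .1, 25: .05} — no empirical indel spectrum is published for these
  loci; the 25 echoes the 25 bp founder deletion.

Molecules are fragmented into an R1 over the 5′ end and a
reverse-complemented R2 over the 3′ end (150 nt each over a 250 nt
amplicon → 50 nt true overlap); uniform, strand-independent substitution
errors are injected at `per_base_error` (default 1e-3). Quality strings are
constant (`quality_mean`, default Phred 35) and intentionally independent
of the injected errors. A truth record accompanies every pair.

What the generator does *not* emulate: position-dependent and
substitution-biased Illumina error profiles, quality decay, PCR chimeras
and jackpots, donor concatemer integrations, adapter read-through, and
per-embryo pooling structure (pools appear only as mixture fractions).
Passing closed-loop tests therefore demonstrates correctness of the
*pipeline logic* under idealised noise, not robustness to every artifact of
real libraries.

## Expected category fractions under sequencing error

With uniform per-base error *e* and pattern length *L*, a molecule's
pattern window survives sequencing with probability (1−e)^L; hit reads leak
to `Others`. For correct-HDR molecules an additional factor
Π(1 − e·f_i) accounts for protein-changing errors at CDS positions outside
the pattern window, where f_i is the exact fraction of the three possible
substitutions at site i that change the protein (enumerated from the edited
sequence). `expected_category_probabilities` implements this closed form;
recovery tests compare observed category fractions against it within three
binomial standard errors, and a separate test checks the WT→Others leakage
against 1−(1−e)^L within 20% relative. The closed form ignores multi-error
interactions and error-induced merge failures, both of order (e·L)² —
negligible at the error rates simulated.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere internally.
- Pattern extent: protospacer + PAM plus a configurable symmetric flank
  (default 0). The estimator's `flank="auto"` picks the smallest flank
  containing every substitution of the edit, so Coding-bar changes near but
  outside the protospacer are covered without manual bookkeeping.
- Genetic code: the standard nuclear table only.
- Identity floor for the `unmapped` tag: 60% (no published threshold;
  affects only the reason string inside `Others`, never counts).
- No read-quality filtering is applied by default; an optional mean-Phred
  floor exists on the merger.
- Determinism: identical input and configuration yield byte-identical
  reports; all randomness flows through a single seeded NumPy generator.
- Desk-scale problem sizes: closed-loop checks run 20,000 read pairs per
  seed (seeds 1–10, plus 11–20 for the error statistics), chosen so that
  three binomial standard errors resolve sub-percentage-point deviations
  while a full sweep stays in the minutes range on one core.

## Known limitations

- The merger considers only un-gapped overlaps; indels *between* the mates
  (which cannot occur in this amplicon design) would defeat it.
- Alignment tie-breaking among co-optimal alignments follows the underlying
  aligner's canonical traceback; only indel placement is normalised
  (leftmost). Scores are unaffected.
- The closed-form error model is first-order in e.
- Bottom-strand cut offsets for non-palindromic enzymes are approximated by
  reflecting the top-strand offset; fragment sizes may shift by up to the
  site length for such enzymes (calls are unaffected).
- The rule cascade inherits the published definition's blind spots: an HDR
  read whose secondary indel lies inside the guide window is counted under
  `Others`, and perfectly synonymous NHEJ events within the window are
  indistinguishable from other `Others` reads.
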