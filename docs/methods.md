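# Methods

## The mining model

lassomine treats lasso-peptide discovery as a deterministic pipeline over
four pieces of biology:

1. **Anchor homology.** The maturation enzymes (leader peptidase, lasso
   cyclase, ABC transporter) are long and conserved enough to find by
   alignment. The screen is exact Smith–Waterman with affine gaps
   (BLOSUM62; gap open 11, extend 1, a gap of length k costing
   `open + (k-1)·extend`) over all six reading frames of the target,
   translated with the bacterial/archaeal genetic code (table 11).
   Heuristic seeding is deliberately absent: targets are single genomes,
   and exactness buys determinism and a clean oracle test (the optimized
   aligner is checked against an independent Gotoh DP in the suite).
   Hits require ≥30 % identity (identical columns over alignment columns,
   internal gaps included) and Karlin–Altschul expect value
   `E = K·m·n·e^(−λS) < 1e−5` with the commonly published gapped-BLOSUM62
   constants K = 0.041, λ = 0.267 (configurable; E-values from a
   rigorous local aligner are an approximation, but only the threshold
   behaviour matters here). Known-core matching uses *global* identity
   with a strict >70 % rule, so a conserved fragment cannot mask a
   divergent tail on peptides this short.

2. **Genomic context.** Precursor genes are short and hypervariable, so
   they are sought near the anchors, not by homology. The window spans
   the anchor span plus a flank of **8 500 bp** per side (configurable
   2–20 kb; examined context regions in this setting run roughly 5–17 kb,
   and 2×8.5 kb sits inside that envelope). ORFs are enumerated
   stop-to-stop in all six frames; an ORF runs from the first ATG/GTG/TTG
   after an in-frame stop to the next in-frame stop, alternative starts
   translate as Met, codons containing N translate as X (flagged), and
   peptides outside 15–80 aa are dropped. When a segment's primary ORF
   exceeds 80 aa, in-bounds internal-start ORFs are reported instead —
   precursors are short, and this avoids both blind spots and
   combinatorial blowup. ORFs overlapping an anchor hit are excluded:
   precursors flank the maturation genes rather than nesting inside them,
   and the exclusion makes planted-truth evaluation exact.

3. **The precursor grammar.** A candidate split of a peptide into
   leader + core requires, with defaults:
   - ring donor **G at core position 1** (Cys donors and Glu acceptors,
     allowed by the broader lasso definition, are off by default because
     the rumen precursors all use G/D; both are switchable);
   - ring acceptor **D at core position 8 or 9** — when both hold a D the
     smaller ring is taken (deterministic, convention-preferred);
   - a leader **Thr at offset −4, −3 or −2** from the core start. The
     window is wider than the canonical −3 because curated splits in this
     family place the Thr at −4 and −2 as well; −3 is rewarded in the
     score (+2, vs +1 for −4/−2) rather than gated. When several window
     positions hold a Thr the canonical −3 is recorded, then the nearest
     to the cleavage site;
   - leader length 10–40 aa, core length 15–50 aa. The core bound is
     wider than the 21–42 aa the curated set describes because recomputed
     curated cores actually span 22–44 aa;
   - a Ser in the core's last 6 residues adds +1 (observed C-terminal
     serine conservation), and a valid acceptor adds +1, so every
     candidate scores ≥2.

   `best_split` maximizes the score with ties broken by longest leader
   (curated splits favour late donors), then smallest acceptor position.
   On the packaged 35-entry curated table this grammar reproduces every
   printed leader/core boundary.

4. **Cluster completeness.** A genome's cluster is *complete* when the
   union of the two mining tools' calls covers lasA, lasB and lasC;
   *incomplete* when at least one but not all is present; the transporter
   lasD never affects the call. Genus summaries key on the first
   whitespace token of the label (so "Lachnospiraceae bacterium" groups
   as "Lachnospiraceae" — deterministic, and adequate for summaries).

## Conservation profiles

Instead of a multiple aligner, precursor sets are stacked on the shared
donor glycine: leaders right-justified before the donor column, cores
left-justified after, gaps elsewhere. The landmark makes this meaningful
for this family, and it is fully deterministic; a hook accepts an external
aligned-FASTA for parity experiments. Per column the profile reports
residue frequencies over non-gap rows, occupancy, and information content
`IC = (log₂20 − H)·occupancy` bits, without small-sample correction by
default (sets here are n ≤ 35 and the logos are descriptive, not
inferential). Consensus letters require a ≥0.5 majority; argmax ties break
alphabetically.

## Expression

RPKM is `C·10⁹/(L·N)` with N the total primary mapped alignments of the
whole dataset (not just the genes of interest), matching the
"per million mapped reads" definition; a per-gene-total variant is a
caller-side choice by passing a different N. SAM parsing (header
required) counts primary, mapped, non-supplementary alignments.
Dereplication collapses genes with global (end-to-end) pairwise identity
strictly above 50 %, greedily from the longest record — global because the
intent is whole-gene redundancy, not shared domains. The built-in
`naive_map` assigns a read to a gene sharing an exact ≥31-nt substring on
either strand, longest-match wins, ties discarded; it is a deterministic
stand-in used to close the simulation loop, not a general aligner.

## The synthetic generator

`synthetic.make_genome` emulates the structure of a mined genome: i.i.d.
background DNA at GC 0.42 (rumen-Firmicutes-like), anchor genes
reverse-translated with uniform codon choice, a precursor ORF and
grammar-violating decoy ORFs planted in the intergenic gaps (decoys are
sampled from an alphabet without the donor residue and Thr, so their
negative labels are exact). Two details guarantee exact truth labels:

- a **guard stop codon** is written immediately upstream, in frame, of
  every planted precursor/decoy ORF, so the planted start is the first
  start of its stop-to-stop segment;
- a **repair pass** rescans the assembled contig and mutates an early
  codon of any chance background ORF that would pass the grammar (never
  touching planted intervals), iterating until none remains. Without it,
  random background occasionally yields grammar-passing ORFs and
  planted-truth precision would not be a meaningful 1.0 target.

`sample_precursor` draws leader/core lengths uniformly within the grammar
bounds, jointly capped at 80 aa so every sampled precursor fits the ORF
scanner's default envelope, places donor/acceptor/Thr per the rules, and
fills the rest i.i.d. from a rumen-like residue composition; closure
(every sample passes its own grammar) is asserted at construction.
Simulated reads are uniform within each gene with optional per-base
substitution errors. What the generator does **not** emulate: real codon
usage and GC skew, operon structure beyond co-linear order, indel or
quality-score error models, and community complexity — so passing tests
demonstrate correctness of the pipeline's logic on realistic-shaped
inputs, not performance on real draft genomes, where BLAST-parity of the
exact hit lists is explicitly not promised.

## Packaged fixtures

The 34-genome presence matrix and the 35-entry precursor table are
transcribed digitizations shipped inside the package with a SHA-256
manifest (loading verifies integrity). The precursor table keeps the
printed core-length column verbatim alongside a recomputed length column:
they disagree for three entries (a 30-residue core printed as 29, a
27-residue core printed as 18, and a 44-residue core outside the stated
21–42 range), and the package reports recomputed lengths without
reconciling the misprints. One table row lists a single sequence shared
by two predicted precursors; it is stored once with a multiplicity-2
note, and genus subsets expand multiplicities (giving 19 Butyrivibrio and
7 Lachnospira precursors). The anchor protein panel and the 68-entry
known-core panel are **synthetic stand-ins** (named `*_syn`, files
`synthetic_*.faa`): the real reference proteins are external database
records not redistributable here, and no test or result depends on their
true sequences — screens are validated against planted copies and decoys.

## Problem sizes and numerical choices

Default test and acceptance runs use 12–18 kb contigs, one planted
cluster per genome, 20 seeded genomes for end-to-end recovery, 1 000
sampled precursors for grammar closure, 200 random pairs for the
alignment oracle, and 10⁵ simulated reads for RPKM recovery — sizes
chosen so each property is statistically meaningful while the whole suite
stays desk-scale. All randomness flows through seeded NumPy generators;
equal-score alignments resolve to the earliest subject start then query
start; profile frequencies are exact rationals of counts, compared at
1e−9.

## Known limitations

- E-values use fixed Karlin–Altschul constants rather than per-search
  estimation; absolute values are approximate, thresholds are the contract.
- The ORF rule reports one primary ORF per stop-to-stop segment; a true
  precursor nested behind an in-frame upstream start in real data could
  be reported with a longer leader and then rejected by the leader bound.
- The anchor-based alignment underlying profiles does not model indels
  within leaders or cores; columns away from the donor landmark mix
  non-homologous positions more than a real MSA would.
- Genus parsing by first label token conflates family-level names with
  genera.
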