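# Methods

## Overview

`dupprofiler` profiles gene duplication in an annotated genome. The chain is:

1. **Gene catalog** — one gene model per gene (longest coding form), genes on
   unplaced/random/mitochondrial sequences removed, overlapping spans resolved
   to the longest CDS.
2. **Similarity** — all-vs-all Smith–Waterman protein alignment (BLOSUM62,
   affine gaps 11/1) after windowed-entropy low-complexity masking; scores are
   converted to expectation values with the Karlin–Altschul formula
   `E = k·m·N·exp(−λS)` (λ = 0.267, k = 0.041, N = total catalog residues);
   self matches and duplicate orientations are removed; edges kept at
   E ≤ 1e−5.
3. **Markov clustering** — edges weighted `min(200, −0.4343·ln E)` (a capped
   −log10 E); MCL with expansion 2, inflation 2.0, self-loops at the maximum
   incident weight, pruning below 1e−5, convergence tolerance 1e−6; clusters
   of ≥ 2 genes become duplication sets.
4. **Arrangement types** — every member pair is tandem (same chromosome,
   intergenic gap < 10 kb, strict), intra-chromosomal (same chromosome,
   ≥ 10 kb) or inter-chromosomal; set labels are the non-exclusive union and
   a set with more than one label is *mixed*.
5. **Ks** — per pair: Needleman–Wunsch protein alignment (BLOSUM62, gap open
   12 / extend 1), codon back-translation, Nei–Gojobori counting with
   equal-weight pathway averaging and Jukes–Cantor correction
   `d = −(3/4)·ln(1 − (4/3)p)`; `ps ≥ 0.75` is reported as *saturated*,
   fewer than 30 compared codons as *too_short*.
6. **Profiles** — summary table, set-size distribution (fraction of
   duplicated genes per size, tail pooled above 20), Ks histogram (bin 0.25
   on [0, 6], pairwise comparisons as the unit, saturated pairs tallied
   separately), low-Ks fraction, mean Ks by size and by size × type.
7. **GO enrichment** — annotations propagated to all is_a ancestors; study
   set = genes in ≥ 1 pair with Ks ≤ 1.0, population = all clustered genes;
   two-sided Fisher exact test (hypergeometric point-probability summation);
   Bonferroni, Šidák and Benjamini–Hochberg corrections over the number of
   terms with ≥ 1 population annotation.
8. **Assembly collapse** — error-free 500 bp reads at 10× coverage from a
   reference, greedy longest-overlap assembly (exact suffix–prefix overlaps
   ≥ 50 bp), contigs mapped back by edlib infix alignment at ≥ 98% identity;
   identical repeat copies longer than the read length co-assemble and are
   counted as collapse events.

## NG86 details and conventions

Site counts: each codon position contributes the fraction of its non-stop
single-nucleotide neighbours that are synonymous, so `s + n = 3` exactly per
codon; S and N are averaged over the two sequences. Differences: for codons
differing at *d* positions, the *d*! orderings of single-nucleotide steps are
averaged with equal weight; orderings that pass through a stop codon are
discarded, and a column whose orderings are all blocked is skipped entirely.
Columns with gaps or ambiguous bases are dropped pairwise. These stop-codon
conventions are the main source of small discrepancies against other NG86
implementations.

A consequence of pathway averaging worth knowing: two synonymous codons can
be connected only through non-synonymous intermediates (serine's two codon
islands, e.g. TCA↔AGT), so Ka is slightly positive even for protein-identical
sequences. Saturation is a *status*, not a number: the Jukes–Cantor map is
undefined at `p ≥ 3/4` and estimates just below it are unstable.

## Protein alignment gap penalties

The Ks stage aligns proteins globally with BLOSUM62 and gap open 12 /
extend 1. With looser penalties (e.g. 10/0.5) chance runs of mismatches in
highly diverged, indel-free paralogs (Ks ≈ 2, ~65% identity) occasionally buy
compensating gap pairs that frame-shift the codon correspondence and inflate
dS by up to +0.75; at 12/1 the true gapless alignment is recovered across the
estimator's usable range while genuinely indelled homologs still align. The
similarity stage keeps BLAST-like 11/1 penalties; its scores only rank edges.

## Synthetic genomes: what they emulate, and what not

The generator stands in for an Ensembl-style gene build: multiple
chromosomes, single-exon protein-coding genes (length ~ N(200, 50) codons,
min 60) laid out without overlaps, intergenic gaps 12–40 kb. Planted
duplication sets control size (2–6), arrangement (tandem arrays spaced 2 kb;
dispersed same-chromosome copies ≥ 50 kb apart; cross-chromosome copies on
distinct chromosomes; whole-genome events duplicating a batch of genes onto
partner chromosomes; mixed sets combining a tandem pair with cross-chromosome
copies) and divergence. The default study configuration uses six chromosomes,
300 background genes and 40 planted sets in two age cohorts (target Ks 0.3
and 2.0). Six chromosomes are the minimum that lets cross-chromosome sets of
up to six copies place every copy on its own chromosome.

Divergence is generated by an accept/reject walk on one copy (the ancestor is
kept): single-nucleotide proposals, synonymous changes accepted with
probability 1, non-synonymous with probability ω (default 0.2), stop-creating
changes rejected; the walk stops when the NG86 estimate against the ancestor
first reaches the target. Targeting the estimator itself makes the planted
truth directly comparable to the pipeline's output without rate calibration;
the cost is that "target" means *estimated* divergence: the first crossing of
a target below saturation necessarily has `ps < 0.75`, so even high targets
(3–4) mostly return an estimate rather than saturated status, and while the
estimate dawdles below the target the protein keeps decaying, so short genes
in the old cohort occasionally drop below the E-value detection cutoff — the
same detectability decay that affects old duplicates in real genomes.

Ground-truth pair labels are computed from the realized planted coordinates
(the 10 kb rule applied to known positions): within a tandem array of ≥ 4
members the outermost pairs can exceed 10 kb, making the set genuinely mixed,
and the truth records that.

Not modelled: indels, introns/alternative transcripts, gene loss and
fractionation, codon-usage bias, transposable elements, sequencing error.
Passing the recovery tests therefore shows the statistical machinery is
correct, not that real-genome complications (fragmented assemblies, tandem
mis-annotation, alignment over introns) are handled.

The GO generator emits a small synthetic DAG (root, three mid-level terms,
filler leaves at 10% annotation probability) and plants enriched terms on the
low-Ks cohort at a chosen study frequency versus population frequency.

## Numerical choices

- MCL operates per connected component (walks cannot cross components) with
  dense column-stochastic matrices; attractors are read off the diagonal and
  overlapping attractor systems merged, which guarantees a strict partition.
- Weights from E-values are computed in log space, so astronomically small
  E-values (float underflow to 0) still map to the 200 cap deterministically.
- Fisher's two-sided p sums hypergeometric point probabilities ≤ the observed
  one with a 1e−7 relative tie tolerance (the R/scipy convention).
- The greedy assembler breaks overlap-length ties lexicographically on the
  sorted, deduplicated read sequences; all stages are deterministic given the
  seed, and a single pipeline seed is fanned out to the per-stage generators.
- Tandem status uses the intergenic gap (not midpoints) with a strict
  `< 10 kb` rule, so a gap of exactly 10,000 bp is intra-chromosomal; tandem
  pairs are not required to be adjacent.
- Set-level mean Ks is the arithmetic mean over pairs with `ok` status;
  saturated pairs are reported in their own category, never silently dropped.

## Problem sizes

The reference configuration (≈ 450 genes, ≈ 100k all-vs-all alignments,
≈ 240 Ks pairs) runs end-to-end in under a minute on one core; the estimator
recovery experiment uses 50 replicate 300-codon pairs per target, and the
assembly simulation a 50 kb reference at 10×. These sizes give stable
recovery statistics while keeping a full run interactive.

## Known limitations

- NG86 with equal pathway weights and Jukes–Cantor correction ignores
  transition/transversion bias and codon frequencies; against ML estimators
  (GY94/YN00) expect modest systematic differences, growing with divergence.
- The Karlin–Altschul E-value uses fixed gapped-BLOSUM62 parameters rather
  than per-query fitting, so absolute E-values differ from BLAST's; only
  their ranking and log-magnitude enter the clustering.
- The greedy assembler is single-strand and error-free by design; it answers
  the paralog-collapse question, not assembly quality in general.
- Inter-chromosomal set percentages depend on the planted mixture; they are
  not calibrated to any particular species.
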