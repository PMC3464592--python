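# dupprofiler

Gene-duplication profiling for annotated genomes, built for studying how
continuous small-scale duplication (especially tandem arrays) and old
large-scale events together shape genome architecture — the kind of question
asked of teleost fish genomes, where recent tandem duplicates of immune and
sensory genes sit alongside remnants of whole-genome duplication.

Given a genome as GFF3 + CDS/protein FASTA, the pipeline

- detects **duplicated gene sets** by Markov clustering (MCL) of an
  all-vs-all protein similarity graph, with edges weighted
  `min(200, −log10 E)` from Karlin–Altschul E-values;
- classifies each set by chromosomal arrangement: **tandem** (pairwise
  intergenic gap < 10 kb), **intra-chromosomal** (same chromosome, ≥ 10 kb)
  and **inter-chromosomal**, with non-exclusive labels and *mixed* sets;
- estimates pairwise **Ks** (synonymous substitutions per synonymous site)
  by protein-guided codon alignment and the Nei–Gojobori (1986) method with
  Jukes–Cantor correction, `dS = −(3/4)·ln(1 − (4/3)·pS)`;
- profiles set sizes and Ks distributions (duplication-age cohorts appear as
  histogram modes);
- tests **GO-term enrichment** among recent duplicates (pairs with Ks ≤ 1)
  against all duplicated genes, via two-sided Fisher exact tests on a
  propagated ontology DAG with Bonferroni/Šidák/BH corrections;
- simulates **shotgun-assembly collapse**: fragments a reference into 500 bp
  reads at 10×, reassembles greedily, and checks whether identical paralogs
  co-assemble into one contig.

Because real Ensembl gene builds are not shipped, a first-class
**synthetic-genome generator** plants duplication sets of controlled size,
arrangement and target Ks (via an accept/reject codon mutation walk with
selectable Ka/Ks ratio ω) and emits the ground truth, so every stage is
scored against planted truth. See `docs/methods.md` for the model details.

## Worked example

The numbered drivers under `analysis/` run the study end to end on the
default synthetic genome (six chromosomes, 300 background genes, 40 planted
sets in age cohorts at Ks 0.3 and 2.0):

```bash
python analysis/01_simulate_genome.py --seed 1
python analysis/02_detect_duplication_sets.py
python analysis/03_classify_types.py
python analysis/04_estimate_ks.py
python analysis/05_profile_duplications.py --plot
python analysis/06_go_enrichment.py
python analysis/07_assembly_collapse.py --seed 1
```

which prints (seed 1):

```
wrote 447 genes on 6 chromosomes to results/genome
  40 planted duplication sets (147 genes), 300 background genes
447 genes after filtering
215 significant non-redundant pairs (E <= 1e-05)
40 duplication sets covering 147 genes; mean set size 3.67
40 sets: inter 18 (45.0%), intra 13 (32.5%), tandem 16 (40.0%)
6 mixed sets carry more than one arrangement label
236 pairs: 204 estimable, 32 saturated, 0 too short
median Ks 0.621; 62.3% of estimable pairs at Ks <= 1.0
mean Ks by arrangement: inter 1.91, intra 1.10, tandem 0.47
  GO:9100001 (planted enriched GO:9100001): over, study 61/79 vs population
  70/147, p 2.38e-15, BH-FDR 7.15e-14
repeat-free 50 kb reference: 1 contigs, 100.0% mapped, 99.8% of bases covered
two identical 2 kb paralogs planted: 1 collapse event(s), 2 contigs
```

Reading the output: all 40 planted sets are recovered exactly (the truth
comparison in the pipeline manifest reports adjusted Rand index 1.0 and 100%
type-label agreement), no background gene is recruited, the Ks histogram is
bimodal at the planted cohorts, tandem pairs are the youngest arrangement
(mean Ks 0.47 < intra 1.10 < inter 1.91), the planted GO term is recovered
far below FDR 0.05, and the two identical planted paralogs collapse into a
single contig while the repeat-free reference maps back completely —
saturated pairs (the old cohort's copy-vs-copy comparisons, beyond the
Jukes–Cantor domain) are reported as a category, not silently dropped.

The same chain is available as one command (`dupprofiler run --synthetic
--outdir results/run --seed 1`), which also writes a run manifest with the
config hash, seed and per-stage record counts; reruns are byte-identical.

## Layout

```
src/dupprofiler/    library: catalog, similarity, mcl, classify, ks,
                    profiles, enrichment, assembly, simulate, evaluate,
                    pipeline, cli
analysis/           numbered study drivers (thin wrappers over the library)
tests/              pytest suite incl. brute-force oracles and acceptance
                    properties
scripts/            acceptance.py
docs/methods.md     model, conventions, parameter rationale, limitations
```
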