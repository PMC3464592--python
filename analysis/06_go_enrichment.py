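#!/usr/bin/env python
"""Test GO-term over/under-representation among recent duplicates: genes in
pairs with Ks <= 1.0 (study) against all duplicated genes (population),
Fisher exact test with Bonferroni / Sidak / BH-FDR corrections.
"""

import argparse
from pathlib import Path

from dupprofiler.enrichment import enrich, parse_obo, read_annotations
from dupprofiler.ks import STATUS_OK, read_ks_table
from dupprofiler.mcl import read_sets


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--genome", default="results/genome")
    ap.add_argument("--sets", default="results/dupsets/sets.tsv")
    ap.add_argument("--ks", default="results/dupsets/pairwise_ks.tsv")
    ap.add_argument("--out", default="results/profiles/enrichment.tsv")
    ap.add_argument("--ks-threshold", type=float, default=1.0)
    args = ap.parse_args()
    genome = Path(args.genome)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)

    dag = parse_obo(genome / "ontology.obo")
    annotations = read_annotations(genome / "annotations.tsv", dag)
    results = read_ks_table(args.ks)
    population = sorted({g for s in read_sets(args.sets) for g in s.members})
    study = sorted({g for r in results
                    if r.status == STATUS_OK and r.ks <= args.ks_threshold
                    for g in r.pair})
    table = enrich(study, population, annotations, dag)
    table.to_csv(args.out, sep="\t", index=False)

    print(f"study {len(study)} genes (pairs with Ks <= {args.ks_threshold}), "
          f"population {len(population)} duplicated genes, "
          f"{len(table)} terms tested")
    hits = table[table["p_fdr_bh"] < 0.05]
    if hits.empty:
        print("no term passes BH-FDR 0.05")
    else:
        for _, row in hits.iterrows():
            print(f"  {row['term_id']} ({row['name']}): {row['direction']}, "
                  f"study {row['study_count']}/{row['study_n']} vs population "
                  f"{row['pop_count']}/{row['pop_n']}, "
                  f"p {row['p']:.2e}, BH-FDR {row['p_fdr_bh']:.2e}")


if __name__ == "__main__":
    main()
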