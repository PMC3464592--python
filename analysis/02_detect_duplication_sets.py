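#!/usr/bin/env python
"""Detect duplicated gene sets: load and filter the gene catalog, run the
all-vs-all protein similarity search, and cluster the weighted pair graph
with MCL.  Writes the BLAST-style pair list and the set table.
"""

import argparse
from pathlib import Path

from dupprofiler.catalog import filter_catalog, load_catalog
from dupprofiler.mcl import clusters_to_sets, mcl, write_sets
from dupprofiler.similarity import build_pair_list, write_pair_list


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--genome", default="results/genome")
    ap.add_argument("--outdir", default="results/dupsets")
    ap.add_argument("--evalue-cutoff", type=float, default=1e-5)
    ap.add_argument("--inflation", type=float, default=2.0)
    args = ap.parse_args()
    genome = Path(args.genome)
    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    catalog = filter_catalog(load_catalog(
        genome / "genome.gff3", genome / "cds.fa", genome / "protein.fa"))
    print(f"{len(catalog)} genes after filtering")

    edges = build_pair_list(catalog, evalue_cutoff=args.evalue_cutoff)
    write_pair_list(edges, out / "pairs.blast6.tsv")
    print(f"{len(edges)} significant non-redundant pairs "
          f"(E <= {args.evalue_cutoff:g})")

    sets = clusters_to_sets(mcl(edges, inflation=args.inflation))
    write_sets(sets, out / "sets.tsv")
    genes_in_sets = sum(s.size for s in sets)
    print(f"{len(sets)} duplication sets covering {genes_in_sets} genes; "
          f"mean set size {genes_in_sets / len(sets):.2f}" if sets
          else "no duplication sets found")


if __name__ == "__main__":
    main()
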