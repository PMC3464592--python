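#!/usr/bin/env python
"""Classify every duplication set by chromosomal arrangement: tandem
(pairwise gap < 10 kb), intra-chromosomal (same chromosome, >= 10 kb) and
inter-chromosomal, with non-exclusive set labels and a mixed flag.
"""

import argparse
from collections import Counter
from pathlib import Path

from dupprofiler.catalog import filter_catalog, load_catalog
from dupprofiler.classify import classify_sets, write_pair_labels, write_set_labels
from dupprofiler.mcl import read_sets


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--genome", default="results/genome")
    ap.add_argument("--sets", default="results/dupsets/sets.tsv")
    ap.add_argument("--outdir", default="results/dupsets")
    ap.add_argument("--tandem-threshold", type=int, default=10_000)
    args = ap.parse_args()
    genome = Path(args.genome)
    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    catalog = filter_catalog(load_catalog(
        genome / "genome.gff3", genome / "cds.fa", genome / "protein.fa"))
    sets = classify_sets(read_sets(args.sets), catalog,
                         tandem_threshold=args.tandem_threshold)
    write_set_labels(sets, out / "set_labels.tsv")
    write_pair_labels(sets, catalog, out / "pair_labels.tsv")

    counts = Counter(label for s in sets for label in s.set_labels)
    mixed = sum(1 for s in sets if s.mixed)
    print(f"{len(sets)} sets: " + ", ".join(
        f"{label} {counts[label]} ({100 * counts[label] / len(sets):.1f}%)"
        for label in ("inter", "intra", "tandem")))
    print(f"{mixed} mixed sets carry more than one arrangement label")


if __name__ == "__main__":
    main()
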