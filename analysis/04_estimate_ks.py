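#!/usr/bin/env python
"""Estimate pairwise synonymous divergence (Ks) for every member pair of
every duplication set by protein-guided codon alignment and the
Nei-Gojobori method with Jukes-Cantor correction.
"""

import argparse
from pathlib import Path

from dupprofiler.catalog import filter_catalog, load_catalog
from dupprofiler.ks import STATUS_OK, set_pairwise_ks
from dupprofiler.mcl import read_sets
from dupprofiler.pipeline import _write_ks


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--genome", default="results/genome")
    ap.add_argument("--sets", default="results/dupsets/sets.tsv")
    ap.add_argument("--out", default="results/dupsets/pairwise_ks.tsv")
    ap.add_argument("--min-codons", type=int, default=30)
    args = ap.parse_args()
    genome = Path(args.genome)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)

    catalog = filter_catalog(load_catalog(
        genome / "genome.gff3", genome / "cds.fa", genome / "protein.fa"))
    results = []
    for s in read_sets(args.sets):
        pair_results, _ = set_pairwise_ks(s.members, catalog, set_id=s.set_id,
                                          min_codons=args.min_codons)
        results.extend(pair_results)
    _write_ks(results, args.out)

    ok = [r for r in results if r.status == STATUS_OK]
    saturated = sum(1 for r in results if r.status == "saturated")
    print(f"{len(results)} pairs: {len(ok)} estimable, {saturated} saturated, "
          f"{len(results) - len(ok) - saturated} too short")
    if ok:
        low = sum(1 for r in ok if r.ks <= 1.0)
        print(f"median Ks {sorted(r.ks for r in ok)[len(ok) // 2]:.3f}; "
              f"{100 * low / len(ok):.1f}% of estimable pairs at Ks <= 1.0")


if __name__ == "__main__":
    main()
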