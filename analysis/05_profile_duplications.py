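#!/usr/bin/env python
"""Profile the duplication landscape: per-genome summary table, set-size
distribution as fraction of duplicated genes, Ks histogram, low-Ks
fraction, and mean Ks grouped by set size and by arrangement type.
Optionally renders the figure analogs as PNG.
"""

import argparse
from pathlib import Path

from dupprofiler.catalog import filter_catalog, load_catalog
from dupprofiler.classify import classify_sets
from dupprofiler.ks import read_ks_table
from dupprofiler.mcl import read_sets
from dupprofiler.pipeline import _write_histogram
from dupprofiler.profiles import (fraction_ks_below, ks_histogram,
                                  mean_ks_by_size, mean_ks_by_size_and_type,
                                  set_size_distribution, summarize)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--genome", default="results/genome")
    ap.add_argument("--sets", default="results/dupsets/sets.tsv")
    ap.add_argument("--ks", default="results/dupsets/pairwise_ks.tsv")
    ap.add_argument("--outdir", default="results/profiles")
    ap.add_argument("--plot", action="store_true",
                    help="also write PNG figure analogs")
    args = ap.parse_args()
    genome = Path(args.genome)
    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    catalog = filter_catalog(load_catalog(
        genome / "genome.gff3", genome / "cds.fa", genome / "protein.fa"))
    sets = classify_sets(read_sets(args.sets), catalog)
    results = read_ks_table(args.ks)
    ks_by_pair = {tuple(sorted(r.pair)): r for r in results}

    summary = summarize(sets, catalog)
    summary.to_frame().to_csv(out / "summary.tsv", sep="\t", index=False)
    set_size_distribution(sets).to_csv(out / "set_size_distribution.tsv",
                                       sep="\t", index=False)
    hist = ks_histogram(results)
    _write_histogram(hist, out / "ks_histogram.tsv")
    by_size = mean_ks_by_size(sets, ks_by_pair)
    by_size.to_csv(out / "mean_ks_by_size.tsv", sep="\t", index=False)
    by_type = mean_ks_by_size_and_type(sets, ks_by_pair)
    by_type.to_csv(out / "mean_ks_by_size_and_type.tsv", sep="\t", index=False)

    frac = fraction_ks_below(results, 1.0)
    print(f"{summary.n_sets} sets, mean size {summary.mean_set_size:.2f}; "
          f"inter {summary.pct_inter:.1f}%, intra {summary.pct_intra:.1f}%, "
          f"tandem {summary.pct_tandem:.1f}%, mixed {summary.n_mixed}")
    if frac is not None:
        print(f"{100 * frac:.1f}% of estimable pairs have Ks <= 1.0; "
              f"{hist.n_saturated} pairs saturated")
    pooled = by_type.groupby("label").apply(
        lambda g: (g["mean_ks"] * g["n_pairs"]).sum() / g["n_pairs"].sum(),
        include_groups=False)
    print("mean Ks by arrangement: " +
          ", ".join(f"{k} {v:.2f}" for k, v in pooled.items()))

    if args.plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 3, figsize=(13, 3.5))
        dist = set_size_distribution(sets)
        axes[0].bar(dist["size"], 100 * dist["fraction_of_duplicated_genes"])
        axes[0].set(xlabel="duplication set size",
                    ylabel="% of duplicated genes")
        centers = [(a + b) / 2 for a, b in zip(hist.bin_edges, hist.bin_edges[1:])]
        axes[1].bar(centers, hist.counts, width=0.22)
        axes[1].set(xlabel="Ks", ylabel="pairwise comparisons")
        for label, group in by_type.groupby("label"):
            axes[2].plot(group["set_size"], group["mean_ks"], marker="o",
                         label=label)
        axes[2].set(xlabel="set size", ylabel="mean Ks")
        axes[2].legend()
        fig.tight_layout()
        fig.savefig(out / "profiles.png", dpi=120)
        print(f"figure written to {out / 'profiles.png'}")


if __name__ == "__main__":
    main()
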