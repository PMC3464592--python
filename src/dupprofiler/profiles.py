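"""Summary profiles of duplication sets: counts, size and Ks distributions.

The summary mirrors a per-species duplication table (gene count, set
count, mean set size, per-type set counts with percentages, mixed sets);
the distribution helpers profile set sizes as fractions of duplicated
genes and pairwise Ks values as histograms and grouped means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import INTER, INTRA, TANDEM
from .ks import STATUS_OK, KsResult
from .mcl import DuplicationSet


@dataclass
class DuplicationSummary:
    n_genes: int
    n_sets: int
    n_duplicated_genes: int
    mean_set_size: float | None
    n_inter: int
    n_intra: int
    n_tandem: int
    pct_inter: float | None
    pct_intra: float | None
    pct_tandem: float | None
    n_mixed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


@dataclass
class Histogram:
    bin_edges: list[float]
    counts: list[int]
    fractions: list[float]
    n_saturated: int = 0
    n_too_short: int = 0


def summarize(sets: list[DuplicationSet], catalog) -> DuplicationSummary:
    n_sets = len(sets)
    sizes = [s.size for s in sets]
    count = lambda label: sum(1 for s in sets if label in s.set_labels)
    n_inter, n_intra, n_tandem = count(INTER), count(INTRA), count(TANDEM)
    pct = lambda c: 100.0 * c / n_sets if n_sets else None
    return DuplicationSummary(
        n_genes=len(catalog.genes),
        n_sets=n_sets,
        n_duplicated_genes=sum(sizes),
        mean_set_size=sum(sizes) / n_sets if n_sets else None,
        n_inter=n_inter, n_intra=n_intra, n_tandem=n_tandem,
        pct_inter=pct(n_inter), pct_intra=pct(n_intra), pct_tandem=pct(n_tandem),
        n_mixed=sum(1 for s in sets if s.mixed),
    )


def set_size_distribution(sets: list[DuplicationSet],
                          max_size_bin: int = 20) -> pd.DataFrame:
    """Per set size: number of sets and fraction of all duplicated genes.

    Sizes above ``max_size_bin`` are pooled into one tail bin labelled
    ``>{max_size_bin}``.
    """
    total_genes = sum(s.size for s in sets)
    rows = []
    by_size: dict[int, list[DuplicationSet]] = {}
    for s in sets:
        key = s.size if s.size <= max_size_bin else max_size_bin + 1
        by_size.setdefault(key, []).append(s)
    for key in sorted(by_size):
        members = by_size[key]
        genes = sum(s.size for s in members)
        rows.append({
            "size": f">{max_size_bin}" if key > max_size_bin else str(key),
            "n_sets": len(members),
            "n_genes": genes,
            "fraction_of_duplicated_genes": genes / total_genes if total_genes else 0.0,
        })
    return pd.DataFrame(rows, columns=["size", "n_sets", "n_genes",
                                       "fraction_of_duplicated_genes"])


def ks_histogram(results: list[KsResult], bin_width: float = 0.25,
                 max_ks: float = 6.0) -> Histogram:
    """Histogram of pairwise Ks over status-ok pairs.

    Saturated and too-short pairs are tallied separately, never silently
    dropped; ok values above ``max_ks`` land in the last bin.
    """
    ok = [r.ks for r in results if r.status == STATUS_OK]
    n_sat = sum(1 for r in results if r.status == "saturated")
    n_short = sum(1 for r in results if r.status == "too_short")
    edges = np.arange(0.0, max_ks + bin_width / 2, bin_width)
    if not ok:
        return Histogram(bin_edges=list(edges), counts=[0] * (len(edges) - 1),
                         fractions=[0.0] * (len(edges) - 1),
                         n_saturated=n_sat, n_too_short=n_short)
    clipped = np.clip(ok, 0.0, max_ks - 1e-12)
    counts, _ = np.histogram(clipped, bins=edges)
    return Histogram(bin_edges=list(edges), counts=[int(c) for c in counts],
                     fractions=list(counts / counts.sum()),
                     n_saturated=n_sat, n_too_short=n_short)


def fraction_ks_below(results: list[KsResult], threshold: float = 1.0) -> float | None:
    """Fraction of ok pairs with ks <= threshold; None with no ok pairs."""
    ok = [r.ks for r in results if r.status == STATUS_OK]
    if not ok:
        return None
    return sum(1 for v in ok if v <= threshold) / len(ok)


def _pair_table(sets: list[DuplicationSet],
                ks_by_pair: dict[tuple[str, str], KsResult]) -> pd.DataFrame:
    rows = []
    for s in sets:
        for pair, label in s.pair_labels.items():
            r = ks_by_pair.get(pair)
            if r is None or r.status != STATUS_OK:
                continue
            rows.append({"set_size": s.size, "label": label, "ks": r.ks})
    return pd.DataFrame(rows, columns=["set_size", "label", "ks"])


def mean_ks_by_size(sets: list[DuplicationSet],
                    ks_by_pair: dict[tuple[str, str], KsResult]) -> pd.DataFrame:
    """Mean pairwise Ks grouped by duplication-set size (ok pairs only)."""
    table = _pair_table(sets, ks_by_pair)
    if table.empty:
        return pd.DataFrame(columns=["set_size", "mean_ks", "n_pairs"])
    grouped = table.groupby("set_size")["ks"].agg(["mean", "count"]).reset_index()
    return grouped.rename(columns={"mean": "mean_ks", "count": "n_pairs"})


def mean_ks_by_size_and_type(sets: list[DuplicationSet],
                             ks_by_pair: dict[tuple[str, str], KsResult]) -> pd.DataFrame:
    """Mean pairwise Ks grouped by set size and pair duplication type."""
    table = _pair_table(sets, ks_by_pair)
    if table.empty:
        return pd.DataFrame(columns=["set_size", "label", "mean_ks", "n_pairs"])
    grouped = (table.groupby(["set_size", "label"])["ks"]
               .agg(["mean", "count"]).reset_index())
    return grouped.rename(columns={"mean": "mean_ks", "count": "n_pairs"})
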