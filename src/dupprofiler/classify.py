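"""Three-way, non-exclusive duplication-type classification.

Every unordered pair in a duplication set is labelled tandem (same
chromosome, intergenic gap under 10 kb), intra-chromosomal (same
chromosome, gap of 10 kb or more), or inter-chromosomal (different
chromosomes).  A set's labels are the union over its pairs; a set with
more than one label is mixed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .catalog import GeneCatalog, GeneModel
from .mcl import DuplicationSet

TANDEM = "tandem"
INTRA = "intra"
INTER = "inter"
TANDEM_THRESHOLD = 10_000  # bp, exclusive for tandem


@dataclass(frozen=True)
class PairClassification:
    pair: tuple[str, str]
    same_chromosome: bool
    distance: int | None
    label: str


def gene_distance(a: GeneModel, b: GeneModel) -> int | None:
    """Intergenic gap in bp between two genes; None across chromosomes.

    The gap is the number of bases strictly between the two gene spans;
    overlapping or abutting spans give 0.  Strand-blind.
    """
    if a.chromosome != b.chromosome:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end) - 1)


def classify_pair(a: GeneModel, b: GeneModel,
                  tandem_threshold: int = TANDEM_THRESHOLD) -> PairClassification:
    """Label one gene pair; the tandem boundary is strict (gap == threshold is intra)."""
    pair = tuple(sorted((a.gene_id, b.gene_id)))
    distance = gene_distance(a, b)
    if distance is None:
        return PairClassification(pair, False, None, INTER)
    label = TANDEM if distance < tandem_threshold else INTRA
    return PairClassification(pair, True, distance, label)


def classify_set(dup_set: DuplicationSet, catalog: GeneCatalog,
                 tandem_threshold: int = TANDEM_THRESHOLD) -> DuplicationSet:
    """Fill pair_labels, set_labels and the mixed flag of one set in place."""
    for gid in dup_set.members:
        if gid not in catalog.genes:
            raise KeyError(f"set {dup_set.set_id}: member {gid} missing from catalog")
    dup_set.pair_labels = {}
    for ga, gb in itertools.combinations(sorted(dup_set.members), 2):
        pc = classify_pair(catalog.genes[ga], catalog.genes[gb], tandem_threshold)
        dup_set.pair_labels[pc.pair] = pc.label
    dup_set.set_labels = set(dup_set.pair_labels.values())
    dup_set.mixed = len(dup_set.set_labels) > 1
    return dup_set


def classify_sets(sets: list[DuplicationSet], catalog: GeneCatalog,
                  tandem_threshold: int = TANDEM_THRESHOLD) -> list[DuplicationSet]:
    return [classify_set(s, catalog, tandem_threshold) for s in sets]


def write_set_labels(sets: list[DuplicationSet], path) -> None:
    with open(path, "w") as fh:
        fh.write("set_id\tsize\tlabels\tmixed\n")
        for s in sets:
            fh.write(f"{s.set_id}\t{s.size}\t{';'.join(sorted(s.set_labels))}"
                     f"\t{str(s.mixed).lower()}\n")


def write_pair_labels(sets: list[DuplicationSet], catalog: GeneCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tset_id\tsame_chromosome\tdistance\tlabel\n")
        for s in sets:
            for (ga, gb), label in sorted(s.pair_labels.items()):
                d = gene_distance(catalog.genes[ga], catalog.genes[gb])
                fh.write(f"{ga}\t{gb}\t{s.set_id}\t{str(d is not None).lower()}"
                         f"\t{'' if d is None else d}\t{label}\n")
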