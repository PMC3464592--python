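"""Synthetic genomes with planted duplication histories.

The generator lays independent random coding genes on multiple
chromosomes and plants duplication sets of controlled size, arrangement
(tandem array, dispersed same-chromosome, cross-chromosome, whole-genome
event, or mixed), and codon-level divergence.  Divergence is produced by
an accept/reject mutation walk on one copy: synonymous single-nucleotide
changes are always accepted, nonsynonymous changes with probability omega,
stop-creating changes never, and the walk stops when the Nei-Gojobori
estimate of Ks against the ancestor first reaches the target.  The
planted truth (memberships, realized pair labels, per-pair target Ks, and
any enriched GO terms) is emitted alongside the genome so every pipeline
stage can be scored against ground truth.

What this emulates: a multi-chromosome Ensembl-style gene build with gene
families of known age.  What it does not: indels, gene loss, codon-usage
bias, or transposable elements.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .catalog import GeneCatalog, GeneModel
from .ks import (SENSE_CODONS, STOP_CODONS, jukes_cantor, ng86_codon_differences,
                 ng86_codon_sites)

NUCLEOTIDES = "ACGT"
SATURATION_TARGET_BOUND = 5.0  # Ks; JC correction is unusable this close to ps=0.75

TANDEM_TYPE = "tandem"
INTRA_TYPE = "intra"
INTER_TYPE = "inter"
WGD_TYPE = "wgd"
MIXED_TYPE = "mixed"


@dataclass
class PlantedSet:
    size: int
    set_type: str  # tandem | intra | inter | wgd | mixed
    target_ks: float
    omega: float = 0.2


@dataclass
class SimConfig:
    n_chromosomes: int = 6
    n_background_genes: int = 300
    gene_length_mean: int = 200   # codons
    gene_length_min: int = 60     # codons
    intergenic_gap_min: int = 12_000  # bp; keeps unrelated neighbours non-tandem
    intergenic_gap_max: int = 40_000
    tandem_spacing: int = 2_000   # bp, < 10 kb
    intra_spacing: int = 50_000   # bp, > 10 kb
    planted_sets: list[PlantedSet] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not self.tandem_spacing < 10_000 <= self.intra_spacing:
            raise ValueError("need tandem_spacing < 10000 <= intra_spacing")
        for p in self.planted_sets:
            if p.size < 2:
                raise ValueError("planted sets need >= 2 members")
            if p.target_ks < 0:
                raise ValueError("target_ks must be >= 0")


@dataclass
class TruthSet:
    set_id: str
    members: list[str]
    planted_type: str
    target_ks: float
    omega: float
    pair_labels: dict[tuple[str, str], str] = field(default_factory=dict)
    set_labels: set[str] = field(default_factory=set)
    pair_target_ks: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class SyntheticTruth:
    sets: list[TruthSet] = field(default_factory=list)
    background_genes: list[str] = field(default_factory=list)
    enriched_terms: list[tuple[str, float, float]] = field(default_factory=list)
    study_genes: list[str] = field(default_factory=list)

    @property
    def duplicated_genes(self) -> list[str]:
        return sorted(g for s in self.sets for g in s.members)

    def membership(self) -> dict[str, int]:
        return {g: i for i, s in enumerate(self.sets) for g in s.members}

    def to_json(self, path) -> None:
        payload = {
            "sets": [{
                "set_id": s.set_id, "members": s.members,
                "planted_type": s.planted_type, "target_ks": s.target_ks,
                "omega": s.omega,
                "pair_labels": {f"{a}|{b}": l for (a, b), l in s.pair_labels.items()},
                "set_labels": sorted(s.set_labels),
                "pair_target_ks": {f"{a}|{b}": v
                                   for (a, b), v in s.pair_target_ks.items()},
            } for s in self.sets],
            "background_genes": self.background_genes,
            "enriched_terms": [list(t) for t in self.enriched_terms],
            "study_genes": self.study_genes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def random_cds(length: int, rng: random.Random | int) -> str:
    """Uniform random sense codons, starting with ATG; no stop codons."""
    if isinstance(rng, int):
        rng = random.Random(rng)
    internal = [c for c in SENSE_CODONS if c != "ATG"] + ["ATG"]
    codons = ["ATG"] + [rng.choice(SENSE_CODONS) for _ in range(length - 1)]
    return "".join(codons)


def evolve_paralog(cds: str, target_ks: float, omega: float,
                   rng: random.Random | int) -> str:
    """Mutate a copy of ``cds`` until its NG86 Ks versus the original reaches
    ``target_ks``.

    Single-nucleotide proposals at uniform random positions; synonymous
    changes accepted with probability 1, nonsynonymous with probability
    omega, stop-creating changes rejected.  Proposals that would leave the
    (original, mutant) codon pair connected only through stop codons are
    also rejected so every column stays countable.
    """
    if isinstance(rng, int):
        rng = random.Random(rng)
    if target_ks < 0 or omega < 0:
        raise ValueError("target_ks and omega must be non-negative")
    if target_ks >= SATURATION_TARGET_BOUND:
        raise ValueError(
            f"target_ks {target_ks} is at or beyond the Jukes-Cantor saturation "
            f"bound; choose a target below {SATURATION_TARGET_BOUND}")
    if target_ks == 0:
        return cds
    n_codons = len(cds) // 3
    orig = [cds[3 * i:3 * i + 3] for i in range(n_codons)]
    mut = list(orig)
    # running NG86 sums, updated incrementally per accepted change
    s_orig = n_orig = s_mut = n_mut = 0.0
    sd = nd = 0.0
    per_codon = []
    for c in orig:
        s, n = ng86_codon_sites(c)
        s_orig += s
        n_orig += n
        per_codon.append((s, n, 0.0, 0.0))  # (s_mut, n_mut, sd, nd) per column
    s_mut, n_mut = s_orig, n_orig
    per_codon = [list(t) for t in per_codon]

    def current_ks() -> float | None:
        S = (s_orig + s_mut) / 2
        if S == 0:
            return None
        return jukes_cantor(sd / S)

    max_proposals = 2000 * n_codons + 10_000
    for _ in range(max_proposals):
        ks_now = current_ks()
        if ks_now is None or ks_now >= target_ks:
            break
        i = rng.randrange(n_codons)
        pos = rng.randrange(3)
        old_codon = mut[i]
        nt = rng.choice(NUCLEOTIDES)
        if nt == old_codon[pos]:
            continue
        new_codon = old_codon[:pos] + nt + old_codon[pos + 1:]
        if new_codon in STOP_CODONS:
            continue
        synonymous = (str(Seq(old_codon).translate()) == str(Seq(new_codon).translate()))
        if not synonymous and rng.random() >= omega:
            continue
        diffs = ng86_codon_differences(orig[i], new_codon)
        if diffs is None:
            continue  # would leave the column uncountable
        new_s, new_n = ng86_codon_sites(new_codon)
        col = per_codon[i]
        s_mut += new_s - col[0]
        n_mut += new_n - col[1]
        sd += diffs[0] - col[2]
        nd += diffs[1] - col[3]
        per_codon[i] = [new_s, new_n, diffs[0], diffs[1]]
        mut[i] = new_codon
    else:
        raise RuntimeError(f"evolve_paralog did not reach Ks {target_ks} "
                           f"within {max_proposals} proposals")
    return "".join(mut)


def _translate(cds: str) -> str:
    return str(Seq(cds).translate())


def _pair_label(a: GeneModel, b: GeneModel) -> str:
    if a.chromosome != b.chromosome:
        return INTER_TYPE
    gap = max(0, max(a.start, b.start) - min(a.end, b.end) - 1)
    return TANDEM_TYPE if gap < 10_000 else INTRA_TYPE


def simulate_genome(config: SimConfig) -> tuple[GeneCatalog, SyntheticTruth]:
    """Generate the annotated genome and its planted truth.

    Background genes are mutually non-homologous random sequences; planted
    sets honour the per-type spacing rules.  Genes are laid out in
    coordinate order with no overlaps, so catalog pre-filtering is a no-op
    on clean synthetic output.  Bit-identical across runs with one seed.
    """
    rng = random.Random(config.seed)
    chromosomes = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    # queued[chrom] -> list of (gene_id, cds, forced_gap_before or None)
    queued: dict[str, list[tuple[str, str, int | None]]] = {c: [] for c in chromosomes}
    truth = SyntheticTruth()

    def gene_length() -> int:
        return max(config.gene_length_min,
                   int(rng.gauss(config.gene_length_mean, config.gene_length_mean / 4)))

    tandem_blocks: dict[str, list[list[tuple[str, str, int | None]]]] = \
        {c: [] for c in chromosomes}

    set_index = 0
    for planted in config.planted_sets:
        if planted.set_type == WGD_TYPE:
            # one WGD event: `size` genes each duplicated once onto a partner
            # chromosome at the shared target Ks -> `size` two-member sets
            for _ in range(planted.size):
                set_index += 1
                sid = f"p{set_index:03d}"
                ancestor = random_cds(gene_length(), rng)
                copy = evolve_paralog(ancestor, planted.target_ks, planted.omega, rng)
                c1 = rng.randrange(config.n_chromosomes)
                c2 = (c1 + config.n_chromosomes // 2) % config.n_chromosomes
                ga, gb = f"{sid}a", f"{sid}b"
                queued[chromosomes[c1]].append((ga, ancestor, None))
                queued[chromosomes[c2]].append((gb, copy, None))
                truth.sets.append(TruthSet(
                    set_id=sid, members=[ga, gb], planted_type=WGD_TYPE,
                    target_ks=planted.target_ks, omega=planted.omega,
                    pair_target_ks={(ga, gb): planted.target_ks}))
            continue
        set_index += 1
        sid = f"p{set_index:03d}"
        ancestor = random_cds(gene_length(), rng)
        copies = [ancestor] + [
            evolve_paralog(ancestor, planted.target_ks, planted.omega, rng)
            for _ in range(planted.size - 1)]
        ids = [f"{sid}{chr(ord('a') + i)}" for i in range(planted.size)]
        tset = TruthSet(set_id=sid, members=list(ids),
                        planted_type=planted.set_type,
                        target_ks=planted.target_ks, omega=planted.omega)
        for i in range(1, planted.size):
            tset.pair_target_ks[(ids[0], ids[i])] = planted.target_ks
        if planted.set_type == TANDEM_TYPE:
            chrom = rng.choice(chromosomes)
            block = [(ids[0], copies[0], None)]
            block += [(gid, c, config.tandem_spacing)
                      for gid, c in zip(ids[1:], copies[1:])]
            tandem_blocks[chrom].append(block)
        elif planted.set_type == INTRA_TYPE:
            chrom = rng.choice(chromosomes)
            for gid, c in zip(ids, copies):
                queued[chrom].append((gid, c, config.intra_spacing))
        elif planted.set_type == INTER_TYPE:
            if planted.size > config.n_chromosomes:
                raise ValueError("inter set larger than the chromosome count")
            chroms = rng.sample(chromosomes, planted.size)
            for gid, c, chrom in zip(ids, copies, chroms):
                queued[chrom].append((gid, c, None))
        elif planted.set_type == MIXED_TYPE:
            if planted.size < 3:
                raise ValueError("mixed sets need >= 3 members")
            chrom = rng.choice(chromosomes)
            tandem_blocks[chrom].append([
                (ids[0], copies[0], None), (ids[1], copies[1], config.tandem_spacing)])
            others = [c for c in chromosomes if c != chrom]
            for gid, c in zip(ids[2:], copies[2:]):
                queued[rng.choice(others)].append((gid, c, None))
        else:
            raise ValueError(f"unknown planted set type {planted.set_type!r}")
        truth.sets.append(tset)

    for i in range(config.n_background_genes):
        gid = f"b{i + 1:04d}"
        queued[rng.choice(chromosomes)].append((gid, random_cds(gene_length(), rng), None))
        truth.background_genes.append(gid)

    catalog = GeneCatalog()
    for chrom in chromosomes:
        items = list(queued[chrom])
        rng.shuffle(items)
        # splice tandem blocks in as contiguous runs
        for block in tandem_blocks[chrom]:
            at = rng.randrange(len(items) + 1)
            items[at:at] = block
        pos = 0
        prev_set: str | None = None
        for gid, cds, forced_gap in items:
            this_set = gid[:4] if gid.startswith("p") else None
            gap = rng.randint(config.intergenic_gap_min, config.intergenic_gap_max)
            if forced_gap is not None and prev_set == this_set:
                gap = forced_gap  # tandem-internal spacing
            elif forced_gap is not None:
                gap = max(gap, forced_gap)  # keep intra members far apart
            start = pos + gap + 1
            end = start + len(cds) - 1
            pos = end
            catalog.genes[gid] = GeneModel(
                gene_id=gid, chromosome=chrom, start=start, end=end,
                strand=rng.choice("+-"), cds=cds, protein=_translate(cds))
            prev_set = this_set
        catalog.chromosome_lengths[chrom] = pos + rng.randint(
            config.intergenic_gap_min, config.intergenic_gap_max)
    catalog.genes = dict(sorted(catalog.genes.items()))

    # realized ground-truth labels from the planted coordinates
    for tset in truth.sets:
        for i, ga in enumerate(tset.members):
            for gb in tset.members[i + 1:]:
                key = tuple(sorted((ga, gb)))
                tset.pair_labels[key] = _pair_label(catalog.genes[ga],
                                                    catalog.genes[gb])
        tset.set_labels = set(tset.pair_labels.values())
    return catalog, truth


def default_config(seed: int = 0) -> SimConfig:
    """The package's reference study conditions.

    Six chromosomes, 300 background genes, and 40 planted sets spanning all
    arrangement types with two age cohorts (target Ks 0.3 and 2.0): tandem
    arrays at 0.3, inter-chromosomal sets at 2.0, dispersed
    same-chromosome sets split between the cohorts, a handful of mixed
    sets, and one whole-genome-event batch of four gene pairs at 2.0.
    """
    sizes = [2, 3, 4, 5, 6]
    planted: list[PlantedSet] = []
    for i in range(12):
        planted.append(PlantedSet(size=sizes[i % 5], set_type=TANDEM_TYPE,
                                  target_ks=0.3))
    for i in range(10):
        planted.append(PlantedSet(size=sizes[i % 5], set_type=INTRA_TYPE,
                                  target_ks=0.3 if i % 2 == 0 else 2.0))
    for i in range(10):
        planted.append(PlantedSet(size=sizes[i % 5], set_type=INTER_TYPE,
                                  target_ks=2.0))
    for i in range(4):
        planted.append(PlantedSet(size=3 + i % 2, set_type=MIXED_TYPE,
                                  target_ks=0.3))
    planted.append(PlantedSet(size=4, set_type=WGD_TYPE, target_ks=2.0))
    return SimConfig(planted_sets=planted, seed=seed)


def make_go_annotations(truth: SyntheticTruth, dag_size: int = 30,
                        enriched_terms: list[tuple[str, float, float]] | None = None,
                        seed: int = 0,
                        low_ks_threshold: float = 1.0):
    """Synthetic ontology plus gene annotations with planted enrichment.

    The study set is every gene of a planted set whose target Ks is at or
    below ``low_ks_threshold``; the population is every planted duplicated
    gene.  Each enriched term (term_id, study_freq, pop_freq) annotates
    study genes with probability study_freq and the rest of the population
    with probability pop_freq.  Filler terms annotate uniformly at 10%.
    Returns (obo_text, annotations dict); also records the study set and
    enriched terms on the truth object.
    """
    rng = random.Random(seed)
    if enriched_terms is None:
        enriched_terms = [("GO:9100001", 0.8, 0.1)]
    pop = truth.duplicated_genes
    study = sorted({g for s in truth.sets if s.target_ks <= low_ks_threshold
                    for g in s.members})
    truth.study_genes = study
    truth.enriched_terms = list(enriched_terms)
    study_set = set(study)

    root = "GO:9000000"
    mids = [f"GO:90000{i + 1:02d}" for i in range(3)]
    n_fill = max(0, dag_size - 1 - len(mids) - len(enriched_terms))
    fillers = [f"GO:91000{i + 50:02d}" for i in range(n_fill)]
    lines = ["format-version: 1.2", "ontology: synthetic", ""]

    def stanza(tid, name, parent=None):
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {name}")
        lines.append("namespace: synthetic_process")
        if parent:
            lines.append(f"is_a: {parent} ! parent")
        lines.append("")

    stanza(root, "synthetic root")
    for m in mids:
        stanza(m, f"mid {m}", root)
    for i, (tid, _, _) in enumerate(enriched_terms):
        stanza(tid, f"planted enriched {tid}", mids[i % len(mids)])
    for i, tid in enumerate(fillers):
        stanza(tid, f"filler {tid}", mids[i % len(mids)])
    obo_text = "\n".join(lines)

    annotations: dict[str, set[str]] = {}

    def annotate(gene, term):
        annotations.setdefault(gene, set()).add(term)

    for tid, study_freq, pop_freq in enriched_terms:
        for gene in pop:
            freq = study_freq if gene in study_set else pop_freq
            if rng.random() < freq:
                annotate(gene, tid)
    for tid in fillers:
        for gene in pop:
            if rng.random() < 0.1:
                annotate(gene, tid)
    # every population gene carries at least the root so pop_n is stable
    for gene in pop:
        annotate(gene, root)
    return obo_text, annotations


def write_annotations(annotations: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
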