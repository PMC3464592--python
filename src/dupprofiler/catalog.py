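"""Gene catalogs: loading, validation, and pre-filtering of gene models.

A catalog holds one protein-coding gene model per gene (the longest coding
form when several transcripts are annotated), with 1-based inclusive
chromosomal coordinates.  Pre-filtering removes genes on unplaced, random,
or mitochondrial sequences and resolves overlapping gene spans by keeping
the gene with the longest CDS.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DEFAULT_DROP_PATTERNS = ("Un", "random", "MT", "mito")


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    start: int  # 1-based, inclusive
    end: int    # 1-based, inclusive
    strand: str
    cds: str
    protein: str

    def validate(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        translated = str(Seq(self.cds).translate())
        if translated.endswith("*"):
            translated = translated[:-1]
        if "*" in translated:
            raise ValueError(f"{self.gene_id}: internal stop codon in CDS")
        if translated != self.protein:
            raise ValueError(f"{self.gene_id}: CDS translation does not match protein")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneCatalog:
    genes: dict[str, GeneModel] = field(default_factory=dict)
    chromosome_lengths: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def validate(self) -> None:
        for gene in self.genes.values():
            gene.validate()
            if gene.chromosome not in self.chromosome_lengths:
                raise ValueError(f"{gene.gene_id}: unknown chromosome {gene.chromosome}")
            if gene.end > self.chromosome_lengths[gene.chromosome]:
                raise ValueError(f"{gene.gene_id}: end beyond chromosome length")

    def by_chromosome(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for gene in self.genes.values():
            out.setdefault(gene.chromosome, []).append(gene)
        for genes in out.values():
            genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        return out


def load_catalog(gff_path, cds_fasta, protein_fasta) -> GeneCatalog:
    """Build a catalog from GFF3 gene/mRNA features plus CDS/protein FASTA.

    CDS and protein FASTA records are keyed by transcript ID.  When a gene
    has several transcripts the longest coding form is kept (ties broken by
    transcript ID).  A gene whose transcript has no sequence is a hard
    error; a gene whose CDS length is not divisible by 3 is rejected with a
    warning.
    """
    cds_seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta), "fasta")}
    protein_seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(protein_fasta), "fasta")}
    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    catalog = GeneCatalog()
    for directive in db.directives:
        m = re.match(r"sequence-region\s+(\S+)\s+(\d+)\s+(\d+)", directive)
        if m:
            catalog.chromosome_lengths[m.group(1)] = int(m.group(3))
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = list(db.children(gene, featuretype="mRNA"))
        if not transcripts:
            transcripts = [gene]
        best = None
        for tx in sorted(transcripts, key=lambda t: t.id):
            if tx.id not in cds_seqs:
                raise KeyError(f"no CDS sequence for transcript {tx.id} of gene {gene.id}")
            if best is None or len(cds_seqs[tx.id]) > len(cds_seqs[best.id]):
                best = tx
        cds = cds_seqs[best.id]
        if len(cds) % 3 != 0:
            logger.warning("gene %s rejected: CDS length %d not divisible by 3",
                           gene.id, len(cds))
            continue
        if best.id not in protein_seqs:
            raise KeyError(f"no protein sequence for transcript {best.id} of gene {gene.id}")
        model = GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            start=gene.start,
            end=gene.end,
            strand=gene.strand if gene.strand in "+-" else "+",
            cds=cds,
            protein=protein_seqs[best.id],
        )
        model.validate()
        catalog.genes[model.gene_id] = model
    for gene in catalog.genes.values():
        catalog.chromosome_lengths.setdefault(gene.chromosome, 0)
        catalog.chromosome_lengths[gene.chromosome] = max(
            catalog.chromosome_lengths[gene.chromosome], gene.end)
    return catalog


def filter_catalog(catalog: GeneCatalog,
                   drop_patterns: tuple[str, ...] = DEFAULT_DROP_PATTERNS) -> GeneCatalog:
    """Remove unplaced/mitochondrial genes and resolve overlapping spans.

    Chromosomes whose name contains any drop pattern (case-insensitive) are
    removed wholesale.  Among genes whose [start, end] spans overlap on the
    same chromosome, only the gene with the longest CDS survives (ties:
    lexicographically smallest gene_id); the comparison is strand-blind.
    Idempotent: filtering a filtered catalog is a no-op.
    """
    patterns = [p.lower() for p in drop_patterns]
    kept = [g for g in catalog.genes.values()
            if not any(p in g.chromosome.lower() for p in patterns)]
    # longest-CDS-first greedy sweep: keep a gene unless it overlaps a kept one
    kept.sort(key=lambda g: (-len(g.cds), g.gene_id))
    accepted: dict[str, list[GeneModel]] = {}
    result = GeneCatalog(chromosome_lengths={
        c: l for c, l in catalog.chromosome_lengths.items()
        if not any(p in c.lower() for p in patterns)})
    for gene in kept:
        overlapping = any(g.start <= gene.end and gene.start <= g.end
                          for g in accepted.get(gene.chromosome, ()))
        if not overlapping:
            accepted.setdefault(gene.chromosome, []).append(gene)
            result.genes[gene.gene_id] = gene
    result.genes = dict(sorted(result.genes.items()))
    return result


def write_catalog(catalog: GeneCatalog, gff_path, cds_fasta, protein_fasta,
                  source: str = "dupprofiler") -> None:
    """Emit GFF3 (gene/mRNA/CDS) and CDS/protein FASTA for a catalog.

    Transcript IDs are ``<gene_id>.t1``; the writer round-trips through
    :func:`load_catalog` without loss.
    """
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for chrom in sorted(catalog.chromosome_lengths):
            gff.write(f"##sequence-region {chrom} 1 {catalog.chromosome_lengths[chrom]}\n")
        for chrom, genes in sorted(catalog.by_chromosome().items()):
            for g in genes:
                tx = f"{g.gene_id}.t1"
                base = f"{chrom}\t{source}"
                coords = f"{g.start}\t{g.end}\t.\t{g.strand}"
                gff.write(f"{base}\tgene\t{coords}\t.\tID={g.gene_id}\n")
                gff.write(f"{base}\tmRNA\t{coords}\t.\tID={tx};Parent={g.gene_id}\n")
                gff.write(f"{base}\tCDS\t{coords}\t0\tID={tx}.cds;Parent={tx}\n")
    ordered = sorted(catalog.genes.values(), key=lambda g: g.gene_id)
    with open(cds_fasta, "w") as fh:
        for g in ordered:
            fh.write(f">{g.gene_id}.t1\n{g.cds}\n")
    with open(protein_fasta, "w") as fh:
        for g in ordered:
            fh.write(f">{g.gene_id}.t1\n{g.protein}\n")
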