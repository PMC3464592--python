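from __future__ import annotations

import pytest

from dupprofiler.catalog import GeneCatalog, GeneModel
from dupprofiler.pipeline import PipelineConfig, run


def make_gene(gene_id: str, chromosome: str = "chr1", start: int = 1000,
              cds: str = "ATGGCTGCT", strand: str = "+") -> GeneModel:
    from Bio.Seq import Seq
    return GeneModel(gene_id=gene_id, chromosome=chromosome, start=start,
                     end=start + len(cds) - 1, strand=strand, cds=cds,
                     protein=str(Seq(cds).translate()))


def make_catalog(genes: list[GeneModel]) -> GeneCatalog:
    catalog = GeneCatalog(genes={g.gene_id: g for g in genes})
    for g in genes:
        catalog.chromosome_lengths[g.chromosome] = max(
            catalog.chromosome_lengths.get(g.chromosome, 0), g.end + 100_000)
    return catalog


@pytest.fixture(scope="session")
def synthetic_run(tmp_path_factory):
    """One full pipeline run on the default planted genome (seed 1).

    Session-scoped: the end-to-end recovery, classification identity, and
    profile-shape checks all read from this single run.
    """
    outdir = tmp_path_factory.mktemp("synthetic_run")
    config = PipelineConfig(outdir=str(outdir), seed=1, synthetic=True)
    return run(config)
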