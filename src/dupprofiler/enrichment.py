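"""GO-term over/under-representation with annotation propagation.

Annotations are propagated from each term to all of its is_a ancestors in
the ontology DAG, then every term annotated to at least one population
gene is tested with a two-sided Fisher exact test of the study set against
the population (the study is a subset of the population).  Raw p-values
are corrected by Bonferroni, Sidak, and Benjamini-Hochberg FDR over the
number of tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

OVER = "over"
UNDER = "under"


@dataclass
class GoDag:
    """Ontology terms with is_a parents; backed by a child->parent digraph."""

    graph: nx.MultiDiGraph
    alt_ids: dict[str, str]

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def resolve(self, term_id: str) -> str | None:
        if term_id in self.graph:
            return term_id
        return self.alt_ids.get(term_id)

    def ancestors(self, term_id: str) -> set[str]:
        # edges point child -> parent, so graph-descendants are ontology ancestors
        return nx.descendants(self.graph, term_id)

    def name(self, term_id: str) -> str:
        return self.graph.nodes[term_id].get("name", "")

    def namespace(self, term_id: str) -> str:
        return self.graph.nodes[term_id].get("namespace", "")


@dataclass
class EnrichmentRow:
    term_id: str
    name: str
    study_count: int
    study_n: int
    pop_count: int
    pop_n: int
    direction: str
    p: float
    p_bonferroni: float = 1.0
    p_sidak: float = 1.0
    p_fdr_bh: float = 1.0


def parse_obo(path) -> GoDag:
    """Read an OBO 1.2 ontology; obsolete terms dropped, alt_ids aliased.

    A cyclic is_a graph is a hard error listing one offending cycle.
    """
    graph = obonet.read_obo(str(path))  # skips obsolete stanzas
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"ontology is_a graph contains a cycle: {cycle}")
    alt = {}
    for node, data in graph.nodes(data=True):
        for alt_id in data.get("alt_id", []):
            alt[alt_id] = node
    return GoDag(graph=graph, alt_ids=alt)


def read_annotations(path, dag: GoDag | None = None) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id) -> gene -> term set.

    With a DAG given, alt_ids are mapped to primary IDs and annotations to
    unknown (e.g. obsolete) terms are dropped.
    """
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            if dag is not None:
                resolved = dag.resolve(term)
                if resolved is None:
                    continue
                term = resolved
            annotations.setdefault(gene, set()).add(term)
    return annotations


def propagate(annotations: dict[str, set[str]], dag: GoDag) -> dict[str, set[str]]:
    """Union each gene's terms with all their is_a ancestors."""
    closed = {}
    for gene, terms in annotations.items():
        full = set()
        for term in terms:
            resolved = dag.resolve(term)
            if resolved is None:
                continue
            full.add(resolved)
            full |= dag.ancestors(resolved)
        closed[gene] = full
    return closed


def fisher_exact(study_count: int, study_n: int, pop_count: int,
                 pop_n: int, alternative: str = "two-sided") -> tuple[float, str]:
    """Fisher exact p for a study subset drawn from a population.

    The 2x2 table contrasts the study genes against the non-study remainder
    of the population, so the null is hypergeometric sampling of the study
    from the population.  Two-sided p sums all tables whose point
    probability does not exceed the observed one.
    """
    if not (0 <= study_count <= study_n <= pop_n and study_count <= pop_count <= pop_n
            and pop_count - study_count <= pop_n - study_n):
        raise ValueError("inconsistent study/population counts")
    k_min = max(0, study_n + pop_count - pop_n)
    k_max = min(study_n, pop_count)
    support = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(support, pop_n, pop_count, study_n)
    p_obs = pmf[study_count - k_min]
    if alternative == "two-sided":
        # point-probability rule with a relative tie tolerance for symmetric tables
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    elif alternative == "greater":
        p = float(pmf[support >= study_count].sum())
    elif alternative == "less":
        p = float(pmf[support <= study_count].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    study_freq = study_count / study_n if study_n else 0.0
    pop_freq = pop_count / pop_n if pop_n else 0.0
    return min(p, 1.0), OVER if study_freq > pop_freq else UNDER


def enrich(study_genes, pop_genes, annotations: dict[str, set[str]], dag: GoDag,
           alternative: str = "two-sided") -> pd.DataFrame:
    """Test every term annotated to the population; rows sorted by raw p."""
    study = set(study_genes)
    pop = set(pop_genes)
    if not study <= pop:
        raise ValueError("study genes must be a subset of the population")
    closed = propagate(annotations, dag)
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in pop:
        for term in closed.get(gene, ()):
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1
    rows = []
    for term in sorted(term_pop):
        p, direction = fisher_exact(term_study.get(term, 0), len(study),
                                    term_pop[term], len(pop), alternative)
        rows.append(EnrichmentRow(
            term_id=term, name=dag.name(term),
            study_count=term_study.get(term, 0), study_n=len(study),
            pop_count=term_pop[term], pop_n=len(pop),
            direction=direction, p=p))
    if rows:
        raw = [r.p for r in rows]
        import numpy as np
        with np.errstate(divide="ignore"):  # sidak takes log1p(-1) at p == 1
            bonf = multipletests(raw, method="bonferroni")[1]
            sidak = multipletests(raw, method="sidak")[1]
            bh = multipletests(raw, method="fdr_bh")[1]
        for r, pb, psk, pbh in zip(rows, bonf, sidak, bh):
            r.p_bonferroni = float(pb)
            r.p_sidak = float(psk)
            r.p_fdr_bh = float(pbh)
    frame = pd.DataFrame([vars(r) for r in rows],
                         columns=["term_id", "name", "study_count", "study_n",
                                  "pop_count", "pop_n", "direction", "p",
                                  "p_bonferroni", "p_sidak", "p_fdr_bh"])
    return frame.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
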