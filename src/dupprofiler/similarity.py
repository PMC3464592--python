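"""All-vs-all protein similarity: the edge list fed to Markov clustering.

Proteins are masked for low compositional complexity with a windowed
Shannon-entropy filter, aligned pairwise by Smith-Waterman with BLOSUM62
and affine gaps, and each alignment score is converted to an expectation
value with the Karlin-Altschul formula E = k m n exp(-lambda S) using
fixed gapped-BLOSUM62 parameters.  Redundant pairs (self matches,
duplicate orientations) are removed and each surviving unordered pair
carries one edge with an MCL weight derived from its E-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

# gapped BLOSUM62 conventions (BLAST defaults for gap open 11 / extend 1)
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041
DEFAULT_EVALUE_CUTOFF = 1e-5
MASK_WINDOW = 12
MASK_ENTROPY = 2.2  # bits


@dataclass(frozen=True)
class SimilarityEdge:
    gene_a: str
    gene_b: str
    score: float
    evalue: float
    weight: float

    def __post_init__(self):
        if self.gene_a >= self.gene_b:
            raise ValueError("edges are stored with gene_a < gene_b")


def shannon_entropy(window: str) -> float:
    """Shannon entropy in bits over the residues of one window."""
    if not window:
        return 0.0
    _, counts = np.unique(list(window), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mask_low_complexity(protein: str, window: int = MASK_WINDOW,
                        entropy_threshold: float = MASK_ENTROPY) -> str:
    """Replace residues inside low-entropy windows with X.

    Every length-``window`` sliding window whose Shannon entropy (log2 over
    the 20-letter alphabet) falls below ``entropy_threshold`` has all of its
    residues masked.  Sequences shorter than the window are returned
    unchanged.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    n = len(protein)
    if n < window:
        return protein
    masked = np.zeros(n, dtype=bool)
    for i in range(n - window + 1):
        if shannon_entropy(protein[i:i + window]) < entropy_threshold:
            masked[i:i + window] = True
    if not masked.any():
        return protein
    chars = list(protein)
    for i in np.flatnonzero(masked):
        chars[i] = "X"
    return "".join(chars)


def _masked_matrix(matrix_name: str = "BLOSUM62"):
    """Substitution matrix in which X scores 0 against everything."""
    m = substitution_matrices.load(matrix_name).copy()
    xi = m.alphabet.index("X")
    m[xi, :] = 0.0
    m[:, xi] = 0.0
    return m


def make_aligner(mode: str = "local", matrix: str = "BLOSUM62",
                 gap_open: float = 11.0, gap_extend: float = 1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _masked_matrix(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(a: str, b: str, matrix: str = "BLOSUM62",
               gap_open: float = 11.0, gap_extend: float = 1.0):
    """Smith-Waterman local alignment; returns (score, alignment or None).

    The alignment is None when every local score is non-positive (the
    local-alignment floor); the score is then 0.
    """
    aligner = make_aligner("local", matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, None
    return score, aligner.align(a, b)[0]


def estimate_evalue(score: float, len_a: int, len_b: int, db_residues: int,
                    lam: float = DEFAULT_LAMBDA, k: float = DEFAULT_K) -> float:
    """Karlin-Altschul expectation E = k * m * N * exp(-lambda * S).

    ``len_b`` is unused beyond its contribution to ``db_residues`` (the
    search-space size); it is accepted for signature symmetry.
    """
    if score < 0:
        raise ValueError("score must be non-negative")
    return math.exp(log_evalue(score, len_a, db_residues, lam, k))


def log_evalue(score: float, len_a: int, db_residues: int,
               lam: float = DEFAULT_LAMBDA, k: float = DEFAULT_K) -> float:
    """Natural log of the Karlin-Altschul E-value (underflow-safe)."""
    return math.log(k) + math.log(len_a) + math.log(db_residues) - lam * score


def edge_weight_from_log_evalue(ln_evalue: float, mul: float = 0.4343,
                                ceil: float = 200.0) -> float:
    return min(ceil, max(0.0, -mul * ln_evalue))


def build_pair_list(catalog, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
                    mask: bool = True, matrix: str = "BLOSUM62",
                    gap_open: float = 11.0, gap_extend: float = 1.0,
                    lam: float = DEFAULT_LAMBDA, k: float = DEFAULT_K,
                    mul: float = 0.4343, ceil: float = 200.0) -> list[SimilarityEdge]:
    """All-vs-all alignment of the catalog; one edge per significant pair.

    Self matches are removed, both orientations of a pair collapse to a
    single edge keyed (gene_a < gene_b), and edges are emitted sorted by
    that key.  ``db_residues`` is the total residue count of the catalog's
    proteins, mirroring a self-BLAST search space.
    """
    gene_ids = sorted(catalog.genes)
    seqs = {}
    for gid in gene_ids:
        p = catalog.genes[gid].protein
        seqs[gid] = mask_low_complexity(p) if mask else p
    db_residues = sum(len(p) for p in seqs.values())
    aligner = make_aligner("local", matrix, gap_open, gap_extend)
    edges = []
    for ga, gb in itertools.combinations(gene_ids, 2):
        a, b = seqs[ga], seqs[gb]
        if not a or not b:
            continue
        score = aligner.score(a, b)
        if score <= 0:
            continue
        ln_e = log_evalue(score, len(a), db_residues, lam, k)
        if ln_e > math.log(evalue_cutoff):
            continue
        evalue = math.exp(ln_e) if ln_e > -700 else 0.0
        edges.append(SimilarityEdge(
            gene_a=ga, gene_b=gb, score=float(score), evalue=evalue,
            weight=edge_weight_from_log_evalue(ln_e, mul, ceil)))
    return edges


BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                  "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def write_pair_list(edges: list[SimilarityEdge], path) -> None:
    """Write edges in a 12-column BLAST outfmt-6 layout.

    Alignment-detail columns not tracked by the edge list (pident, length,
    mismatch, gapopen, coordinates) are emitted as zeros; qseqid/sseqid,
    evalue and bitscore are faithful.
    """
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t0\t0\t0\t0\t0\t0\t0\t0"
                     f"\t{e.evalue:.3e}\t{e.score:.1f}\n")


def read_pair_list(path, mul: float = 0.4343, ceil: float = 200.0,
                   evalue_cutoff: float | None = None) -> list[SimilarityEdge]:
    """Read a BLAST outfmt-6 tab file into a non-redundant edge list.

    Accepts real BLAST output: self matches are dropped, reciprocal and
    duplicate HSPs collapse to the best-scoring record per unordered pair.
    """
    best: dict[tuple[str, str], tuple[float, float]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qa, qb = f[0], f[1]
            if qa == qb:
                continue
            evalue, score = float(f[10]), float(f[11])
            if evalue_cutoff is not None and evalue > evalue_cutoff:
                continue
            key = (min(qa, qb), max(qa, qb))
            if key not in best or score > best[key][1]:
                best[key] = (evalue, score)
    edges = []
    for (ga, gb), (evalue, score) in sorted(best.items()):
        ln_e = math.log(evalue) if evalue > 0 else -math.inf
        edges.append(SimilarityEdge(gene_a=ga, gene_b=gb, score=score, evalue=evalue,
                                    weight=ceil if evalue == 0
                                    else edge_weight_from_log_evalue(ln_e, mul, ceil)))
    return edges
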