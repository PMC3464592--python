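"""Pairwise Ka/Ks estimation by the Nei-Gojobori (1986) counting method.

For each homologous gene pair the protein sequences are globally aligned,
the alignment is back-translated onto the coding sequences codon by codon,
and synonymous/nonsynonymous sites and differences are counted under the
standard genetic code with equal-weight averaging over minimal mutational
pathways.  Observed proportions are corrected for multiple hits with the
Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p), which saturates at
p >= 3/4; saturated pairs carry a status flag instead of a number.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(
    sorted(a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
           if a + b + c not in STOP_CODONS)
)

STATUS_OK = "ok"
STATUS_SATURATED = "saturated"
STATUS_TOO_SHORT = "too_short"


@dataclass
class CodonAlignment:
    """Codon-level pairwise alignment derived from a protein alignment."""

    pair: tuple[str, str]
    codon_columns: list[tuple[str | None, str | None]]
    n_compared: int


@dataclass
class KsResult:
    """NG86 site/difference counts and Jukes-Cantor corrected rates."""

    pair: tuple[str, str]
    n_compared: int = 0
    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0
    ps: float | None = None
    pn: float | None = None
    ks: float | None = None
    ka: float | None = None
    status: str = STATUS_OK
    set_id: str | None = field(default=None)


def jukes_cantor(p: float) -> float | None:
    """Multiple-hit correction; None when p is at or beyond saturation."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@functools.lru_cache(maxsize=None)
def ng86_codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for one sense codon.

    Each position contributes the fraction of its non-stop single-nucleotide
    neighbours that preserve the encoded amino acid; mutational paths into
    stop codons are excluded from the denominator, so s + n = 3 exactly.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    if codon not in CODON_TABLE:
        raise ValueError(f"not a valid codon: {codon!r}")
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            neighbour = codon[:pos] + nt + codon[pos + 1:]
            if neighbour in STOP_CODONS:
                continue
            valid += 1
            if CODON_TABLE[neighbour] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@functools.lru_cache(maxsize=None)
def ng86_codon_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Synonymous/nonsynonymous difference counts between two sense codons.

    Counts are averaged with equal weight over every minimal mutational
    pathway between the codons; pathways that pass through a stop codon are
    discarded.  Returns None when no stop-free pathway exists (the column is
    then skipped entirely).
    """
    if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
        raise ValueError("stop codons are not comparable")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    total_sd = total_nd = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_positions):
        current = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TABLE[current] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            total_sd += sd
            total_nd += nd
            n_paths += 1
    if n_paths == 0:
        return None
    return total_sd / n_paths, total_nd / n_paths


def _protein_aligner(matrix: str = "BLOSUM62",
                     gap_open: float = 12.0,
                     gap_extend: float = 1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align_protein(a: str, b: str, matrix: str = "BLOSUM62",
                         gap_open: float = 12.0,
                         gap_extend: float = 1.0) -> tuple[str, str, float]:
    """Needleman-Wunsch global alignment with affine gaps.

    Returns the two gapped strings (equal length, '-' gaps) and the score.
    """
    if not a or not b:
        raise ValueError("cannot align empty protein sequences")
    aligner = _protein_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1]), aln.score


def back_translate(aligned_a: str, aligned_b: str, cds_a: str, cds_b: str,
                   pair: tuple[str, str] = ("a", "b")) -> CodonAlignment:
    """Map a gapped protein alignment onto its coding sequences.

    Residue i of each protein corresponds to codon i of its CDS (a trailing
    stop codon, if present, is stripped first).  Gap columns and columns in
    which either codon contains a non-ACGT character are excluded from the
    compared-codon count.
    """
    cds_a = _strip_stop(cds_a.upper())
    cds_b = _strip_stop(cds_b.upper())
    for name, aligned, cds in ((pair[0], aligned_a, cds_a), (pair[1], aligned_b, cds_b)):
        n_res = len(aligned.replace("-", ""))
        if len(cds) != 3 * n_res:
            raise ValueError(
                f"CDS of {name} has {len(cds)} nt but protein alignment "
                f"implies {3 * n_res} nt"
            )
    columns: list[tuple[str | None, str | None]] = []
    n_compared = 0
    ia = ib = 0
    for ra, rb in zip(aligned_a, aligned_b):
        ca = cb = None
        if ra != "-":
            ca = cds_a[3 * ia:3 * ia + 3]
            ia += 1
        if rb != "-":
            cb = cds_b[3 * ib:3 * ib + 3]
            ib += 1
        columns.append((ca, cb))
        if ca is not None and cb is not None and _is_unambiguous(ca) and _is_unambiguous(cb):
            n_compared += 1
    return CodonAlignment(pair=pair, codon_columns=columns, n_compared=n_compared)


def _strip_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def _is_unambiguous(codon: str) -> bool:
    return len(codon) == 3 and all(c in NUCLEOTIDES for c in codon)


def ng86_pair(aln: CodonAlignment, min_codons: int = 30) -> KsResult:
    """NG86 estimate for one codon alignment.

    Site counts S and N are averaged over the two sequences; differences are
    summed column-wise with pathway averaging.  Columns whose codons are
    gapped, ambiguous, stop, or connected only through stop codons are
    dropped pairwise (complete-case).
    """
    result = KsResult(pair=aln.pair)
    S_a = S_b = N_a = N_b = Sd = Nd = 0.0
    n_used = 0
    for ca, cb in aln.codon_columns:
        if ca is None or cb is None:
            continue
        if not (_is_unambiguous(ca) and _is_unambiguous(cb)):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        diffs = ng86_codon_differences(ca, cb)
        if diffs is None:
            continue
        sa, na = ng86_codon_sites(ca)
        sb, nb = ng86_codon_sites(cb)
        S_a += sa
        N_a += na
        S_b += sb
        N_b += nb
        Sd += diffs[0]
        Nd += diffs[1]
        n_used += 1
    result.n_compared = n_used
    result.S = (S_a + S_b) / 2.0
    result.N = (N_a + N_b) / 2.0
    result.Sd = Sd
    result.Nd = Nd
    if n_used < min_codons or result.S == 0.0 or result.N == 0.0:
        result.status = STATUS_TOO_SHORT
        return result
    result.ps = Sd / result.S
    result.pn = Nd / result.N
    result.ks = jukes_cantor(result.ps)
    result.ka = jukes_cantor(result.pn)
    result.status = STATUS_OK if result.ks is not None else STATUS_SATURATED
    return result


def pair_ks(protein_a: str, protein_b: str, cds_a: str, cds_b: str,
            pair: tuple[str, str] = ("a", "b"), min_codons: int = 30,
            gap_open: float = 12.0, gap_extend: float = 1.0) -> KsResult:
    """Convenience chain: protein alignment -> codon alignment -> NG86."""
    ga, gb, _ = global_align_protein(protein_a, protein_b,
                                     gap_open=gap_open, gap_extend=gap_extend)
    aln = back_translate(ga, gb, cds_a, cds_b, pair=pair)
    return ng86_pair(aln, min_codons=min_codons)


def read_ks_table(path) -> list[KsResult]:
    """Read the pairwise TSV written by the pipeline back into KsResults."""
    results = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            opt = lambda key: float(row[key]) if row[key] else None
            results.append(KsResult(
                pair=(row["gene_a"], row["gene_b"]),
                set_id=row["set_id"] or None,
                n_compared=int(row["n_compared"]),
                S=float(row["S"]), N=float(row["N"]),
                Sd=float(row["Sd"]), Nd=float(row["Nd"]),
                ps=opt("ps"), pn=opt("pn"), ka=opt("ka"), ks=opt("ks"),
                status=row["status"]))
    return results


def set_pairwise_ks(members: list[str], catalog, set_id: str | None = None,
                    min_codons: int = 30) -> tuple[list[KsResult], float | None]:
    """All unordered member pairs of one duplication set, plus the set mean.

    The set mean is the arithmetic mean of ks over pairs with status ok;
    None when no pair yields a defined estimate.
    """
    results = []
    for ga, gb in itertools.combinations(sorted(members), 2):
        a = catalog.genes[ga]
        b = catalog.genes[gb]
        res = pair_ks(a.protein, b.protein, a.cds, b.cds, pair=(ga, gb),
                      min_codons=min_codons)
        res.set_id = set_id
        results.append(res)
    ok = [r.ks for r in results if r.status == STATUS_OK]
    mean = sum(ok) / len(ok) if ok else None
    return results, mean
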