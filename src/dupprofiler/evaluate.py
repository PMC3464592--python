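"""Scoring pipeline output against a planted synthetic truth."""

from __future__ import annotations

from sklearn.metrics import adjusted_rand_score

from .ks import STATUS_OK, KsResult
from .mcl import DuplicationSet
from .simulate import SyntheticTruth


def membership_ari(truth: SyntheticTruth, sets: list[DuplicationSet]) -> float:
    """Adjusted Rand index between planted and recovered memberships.

    Evaluated over the union of planted and recovered genes; a gene absent
    from one side counts as its own singleton there, so both spurious
    background recruitment and missed members depress the score.
    """
    truth_label = truth.membership()
    found_label = {g: i for i, s in enumerate(sets) for g in s.members}
    genes = sorted(set(truth_label) | set(found_label))
    next_t = len(truth.sets)
    next_f = len(sets)
    t_labels, f_labels = [], []
    for g in genes:
        if g in truth_label:
            t_labels.append(truth_label[g])
        else:
            t_labels.append(next_t)
            next_t += 1
        if g in found_label:
            f_labels.append(found_label[g])
        else:
            f_labels.append(next_f)
            next_f += 1
    return float(adjusted_rand_score(t_labels, f_labels))


def type_agreement(truth: SyntheticTruth, sets: list[DuplicationSet]) -> float:
    """Fraction of planted sets whose recovered set carries identical labels.

    A planted set is matched to the recovered set containing its first
    member; a missing match or any difference in the label union counts as
    disagreement.
    """
    by_gene = {g: s for s in sets for g in s.members}
    agree = 0
    for tset in truth.sets:
        found = by_gene.get(tset.members[0])
        if found is None:
            continue
        if sorted(found.members) == sorted(tset.members) \
                and found.set_labels == tset.set_labels:
            agree += 1
    return agree / len(truth.sets) if truth.sets else 1.0


def ks_recovery_errors(truth: SyntheticTruth,
                       results: list[KsResult]) -> list[tuple[float, float]]:
    """(target, estimate) for every planted-target pair with an ok estimate."""
    by_pair = {tuple(sorted(r.pair)): r for r in results}
    out = []
    for tset in truth.sets:
        for pair, target in tset.pair_target_ks.items():
            r = by_pair.get(tuple(sorted(pair)))
            if r is not None and r.status == STATUS_OK:
                out.append((target, r.ks))
    return out


def background_false_positive_rate(truth: SyntheticTruth,
                                   sets: list[DuplicationSet]) -> float:
    """Fraction of background genes recruited into any duplication set."""
    clustered = {g for s in sets for g in s.members}
    bg = truth.background_genes
    if not bg:
        return 0.0
    return sum(1 for g in bg if g in clustered) / len(bg)
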