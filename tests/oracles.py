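"""Independent oracles used by the test suite.

These deliberately avoid the package's own dynamic-programming and
annotation code paths: alignment optima come from exhaustive enumeration of
every alignment, and consequence calls from translating the whole CDS before
and after a variant.
"""

from __future__ import annotations

from Bio.Seq import Seq


def exhaustive_global_score(a: str, b: str, submat, gap_open: float,
                            gap_extend: float) -> float:
    """Optimal global alignment score by enumerating every alignment.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``. Feasible only
    for short sequences (the number of alignments grows like the Delannoy
    numbers).
    """
    best = [-float("inf")]

    def rec(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + submat[a[i], b[j]], "M")
        if i < len(a):
            cost = gap_extend if last == "U" else gap_open
            rec(i + 1, j, score + cost, "U")
        if j < len(b):
            cost = gap_extend if last == "L" else gap_open
            rec(i, j + 1, score + cost, "L")

    rec(0, 0, 0.0, "M")
    return best[0]


def oracle_consequence(pos: int, ref: str, alt: str, tx, genome: str) -> str:
    """Consequence of a SNV by whole-CDS translation before/after.

    Returns one of 'nonsense', 'missense', 'synonymous', 'splice_donor',
    'other' (frameshift is indel-only and out of scope here).
    """
    assert genome[pos - 1] == ref
    if tx.genomic_to_cds(pos) is None:
        if pos in tx.splice_donor_positions():
            return "splice_donor"
        return "other"
    mutated = genome[: pos - 1] + alt + genome[pos:]
    cds_before = tx.cds_sequence(genome)
    cds_after = tx.cds_sequence(mutated)
    prot_before = str(Seq(cds_before).translate())
    prot_after = str(Seq(cds_after).translate())
    if prot_before == prot_after:
        return "synonymous"
    diffs = [(i, x, y) for i, (x, y) in enumerate(zip(prot_before, prot_after))
             if x != y]
    i, x, y = diffs[0]
    if y == "*" and x != "*":
        return "nonsense"
    return "missense"


def oracle_protein_change(pos: int, ref: str, alt: str, tx,
                          genome: str) -> tuple[int, str, str] | None:
    """(protein position, ref aa, alt aa) of the first changed residue."""
    mutated = genome[: pos - 1] + alt + genome[pos:]
    prot_before = str(Seq(tx.cds_sequence(genome)).translate())
    prot_after = str(Seq(tx.cds_sequence(mutated)).translate())
    for i, (x, y) in enumerate(zip(prot_before, prot_after), start=1):
        if x != y:
            return i, x, y
    return None
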