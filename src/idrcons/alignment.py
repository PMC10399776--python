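"""Pairwise global alignment and percent-identity conventions.

The aligner is a Needleman-Wunsch / Gotoh dynamic program with affine gap
costs over BLOSUM62 (defaults: gap open -11, gap extend -1; a gap of length L
costs ``open + (L-1)*extend``). It is deterministic: traceback ties prefer the
diagonal move, then a gap in the second sequence ("up"), then a gap in the
first ("left").

Percent identity is offered under the two denominator conventions used when
comparing Canoe/Afadin regions: over all alignment columns, or over gap-free
columns only ("ignoring indels"). Columns containing an unknown residue X are
never counted identical.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import substitution_matrices

from .seq_regions import ProteinRecord

GAP = "-"
_NEG = -1e12


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for global alignment."""

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")

    def matrix(self):
        return substitution_matrices.load(self.substitution_matrix)


@dataclass
class PairwiseAlignment:
    """Two gapped rows over a shared column space."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows differ in length")
        for ca, cb in zip(self.row_a, self.row_b):
            if ca == GAP and cb == GAP:
                raise ValueError("gap/gap column in alignment")

    @property
    def ncol(self) -> int:
        return len(self.row_a)

    def ungapped(self, which: str = "a") -> str:
        row = self.row_a if which == "a" else self.row_b
        return row.replace(GAP, "")


@dataclass
class MultiAlignment:
    """An ordered map id -> gapped row, all rows the same length."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("a multiple alignment needs >= 2 rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            bad = next(i for i, r in self.rows.items()
                       if len(r) != len(next(iter(self.rows.values()))))
            raise ValueError(f"ragged alignment row for {bad!r}")

    @property
    def ncol(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.rows)


class IdentityMode(str, enum.Enum):
    ALL_COLUMNS = "all_columns"
    UNGAPPED_COLUMNS = "ungapped_columns"


def _score_lookup(params: AlignParams) -> tuple[np.ndarray, dict[str, int]]:
    mat = params.matrix()
    alpha = str(mat.alphabet)
    idx = {ch: i for i, ch in enumerate(alpha)}
    return np.asarray(mat, dtype=np.float64), idx


def global_align(a: ProteinRecord, b: ProteinRecord,
                 params: AlignParams | None = None) -> PairwiseAlignment:
    """Optimal global alignment of two proteins (Gotoh, affine gaps).

    Three-state DP: M (residue/residue), Ix (gap in b, consuming a),
    Iy (gap in a, consuming b). Row recurrences are vectorized with numpy;
    the within-row Iy dependency is resolved with a running prefix maximum,
    so runtime is O(n*m) with O(n+m)-length vector ops per row.
    """
    params = params or AlignParams()
    s_mat, idx = _score_lookup(params)
    sa = np.array([idx[c] for c in a.sequence], dtype=np.intp)
    sb = np.array([idx[c] for c in b.sequence], dtype=np.intp)
    n, m = len(sa), len(sb)
    go, ge = params.gap_open, params.gap_extend
    S = s_mat[np.ix_(sa, sb)]  # (n, m) residue-pair scores

    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    Ix[1:, 0] = go + np.arange(n) * ge
    Iy[0, 1:] = go + np.arange(m) * ge
    jj = np.arange(1, m + 1, dtype=np.float64)

    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = S[i - 1] + best_prev[:-1]
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] + go, Iy[i - 1, 1:] + go),
            Ix[i - 1, 1:] + ge,
        )
        # Iy[i, j] = max over k < j of (max(M[i,k], Ix[i,k]) + go + (j-k-1)*ge)
        opener = np.maximum(M[i], Ix[i])
        run = np.maximum.accumulate(opener - np.arange(m + 1) * ge)
        Iy[i, 1:] = go + (jj - 1.0) * ge + run[:-1]

    # traceback; ties prefer diagonal (M), then up (Ix), then left (Iy)
    def pick(vals: tuple[float, float, float]) -> int:
        best = max(vals)
        for k in range(3):
            if vals[k] == best:
                return k
        raise AssertionError  # pragma: no cover

    state = pick((M[n, m], Ix[n, m], Iy[n, m]))
    score = (M[n, m], Ix[n, m], Iy[n, m])[state]
    i, j = n, m
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M
            ra.append(a.sequence[i - 1])
            rb.append(b.sequence[j - 1])
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            state = pick((
                M[i, j] if M[i, j] == target else _NEG * 2,
                Ix[i, j] if Ix[i, j] == target else _NEG * 2,
                Iy[i, j] if Iy[i, j] == target else _NEG * 2,
            )) if (i, j) != (0, 0) else 0
        elif state == 1:  # Ix: consume a, gap in b
            ra.append(a.sequence[i - 1])
            rb.append(GAP)
            val = Ix[i, j]
            i -= 1
            if val == M[i, j] + go:
                state = 0
            elif val == Ix[i, j] + ge:
                state = 1
            else:
                state = 2
        else:  # Iy: consume b, gap in a
            ra.append(GAP)
            rb.append(b.sequence[j - 1])
            val = Iy[i, j]
            j -= 1
            if val == M[i, j] + go:
                state = 0
            elif val == Iy[i, j] + ge:
                state = 2
            else:
                state = 1
    return PairwiseAlignment(
        id_a=a.id, id_b=b.id,
        row_a="".join(reversed(ra)), row_b="".join(reversed(rb)),
        score=float(score),
    )


def _identical_column(ca: str, cb: str) -> bool:
    return ca == cb and ca != GAP and ca != "X"


def percent_identity(aln: PairwiseAlignment,
                     mode: IdentityMode | str = IdentityMode.ALL_COLUMNS) -> float:
    """Percent identity of a pairwise alignment under a denominator convention.

    ``all_columns``: identical columns / total columns.
    ``ungapped_columns``: identical columns / gap-free columns (the
    "ignoring indels" convention). Raises if there are no gap-free columns.
    """
    mode = IdentityMode(mode)
    ident = 0
    ungapped = 0
    for ca, cb in zip(aln.row_a, aln.row_b):
        gapfree = ca != GAP and cb != GAP
        ungapped += gapfree
        ident += gapfree and _identical_column(ca, cb)
    if mode is IdentityMode.ALL_COLUMNS:
        return 100.0 * ident / aln.ncol
    if ungapped == 0:
        raise ZeroDivisionError(
            "ungapped_columns identity undefined: no gap-free columns")
    return 100.0 * ident / ungapped


def read_alignment(path: str | Path, format: str = "clustal") -> MultiAlignment:
    """Read a Clustal ``.aln`` or aligned-FASTA file.

    Blocks are reassembled and any consensus line is ignored. Ragged rows
    raise with the offending sequence named.
    """
    fmt = {"clustal": "clustal", "aligned_fasta": "fasta", "fasta": "fasta"}[format]
    if fmt == "fasta":
        # AlignIO would pad/reject inconsistently; read records and validate.
        from Bio import SeqIO
        rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return MultiAlignment(rows=rows)
    msa = AlignIO.read(str(path), fmt)
    return MultiAlignment(rows={rec.id: str(rec.seq).upper() for rec in msa})


def write_alignment(msa: MultiAlignment, path: str | Path,
                    format: str = "clustal") -> None:
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    fmt = {"clustal": "clustal", "aligned_fasta": "fasta", "fasta": "fasta"}[format]
    biomsa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=name, description="") for name, row in msa.rows.items()]
    )
    AlignIO.write(biomsa, str(path), fmt)


# Canonical Clustal conservation groups (strong -> ':', weak -> '.').
STRONG_GROUPS = [frozenset(g) for g in
                 ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF",
                  "HY", "FYW")]
WEAK_GROUPS = [frozenset(g) for g in
               ("CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK",
                "NDEQHK", "NEQHRK", "FVLIM", "HFY")]


def consensus_symbols(msa: MultiAlignment) -> str:
    """Clustal-style consensus line: '*' identity, ':' strong, '.' weak.

    A column with any gap, or any X, never scores above ' '.
    """
    rows = list(msa.rows.values())
    out = []
    for col in zip(*rows):
        residues = set(col)
        if GAP in residues or "X" in residues:
            out.append(" ")
        elif len(residues) == 1:
            out.append("*")
        elif any(residues <= g for g in STRONG_GROUPS):
            out.append(":")
        elif any(residues <= g for g in WEAK_GROUPS):
            out.append(".")
        else:
            out.append(" ")
    return "".join(out)
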