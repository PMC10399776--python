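"""Conserved-motif scanning of aligned IDRs.

Short linear motifs (SLiMs/MoRFs) inside a fast-evolving disordered region
show up as islands of identity in an alignment. The scanner formalizes the
"highlight conserved stretches" procedure as maximal-scoring-segment
extraction: each alignment column between the reference row and a designated
comparator row scores ``1 - t`` if the residues are identical (no gap, no X)
and ``-t`` otherwise, with ``t = min_identity / 100``. A segment then has
percent identity >= min_identity iff its score is >= 0, and the disjoint
maximal segments (Ruzzo & Tompa's all-maximal-scoring-subsequences) are
exactly the stretches that cannot be extended or trimmed without lowering
their score. Segment boundaries always fall on identical columns. Segments
shorter than ``min_len`` columns are discarded; segments separated by at most
``merge_gap`` columns are merged when the merged stretch still meets the
identity threshold.

Defaults follow the insect-IDR criteria (>= 14 columns, >= 48% identity);
``ScanConfig.vertebrate()`` gives the vertebrate preset (>= 15, >= 63%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .alignment import GAP, MultiAlignment


@dataclass(frozen=True)
class ScanConfig:
    """Motif-scan criteria.

    ``comparator_id`` selects the row whose identity with the reference
    defines each motif (typically the most diverged taxon); None means the
    last non-reference row of the alignment.
    """

    min_len: int = 14
    min_identity: float = 48.0
    comparator_id: str | None = None
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError("min_identity must be in [0, 100]")

    @classmethod
    def vertebrate(cls, **kw) -> "ScanConfig":
        return cls(min_len=15, min_identity=63.0, **kw)


@dataclass
class Motif:
    """A conserved alignment segment, in alignment and reference coordinates.

    All coordinates are 1-based inclusive; ``ref_start``/``ref_end`` index
    residues of the ungapped reference row.
    """

    aln_start: int
    aln_end: int
    ref_start: int
    ref_end: int
    identity: float
    helical: bool = False

    @property
    def n_columns(self) -> int:
        return self.aln_end - self.aln_start + 1

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start + 1


@dataclass(frozen=True)
class AnnotationInterval:
    """A labelled residue interval on a named protein (e.g. a predicted
    helix or a mapped binding site)."""

    label: str
    start: int
    end: int
    klass: str = "annotation"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"annotation {self.label!r}: start > end")


@dataclass(frozen=True)
class StructureConfidence:
    """pTM/ipTM accuracy estimates of a predicted complex, both in [0, 1]."""

    ptm: float
    iptm: float

    def __post_init__(self) -> None:
        for name, v in (("ptm", self.ptm), ("iptm", self.iptm)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def model_confidence(c: StructureConfidence) -> float:
    """Weighted model confidence of a predicted heterodimer: 0.8*ipTM + 0.2*pTM."""
    return 0.8 * c.iptm + 0.2 * c.ptm


def _match_vector(ref_row: str, cmp_row: str) -> list[bool]:
    return [
        a == b and a != GAP and a != "X"
        for a, b in zip(ref_row, cmp_row)
    ]


def _maximal_scoring_segments(scores: list[float]) -> list[tuple[int, int]]:
    """Ruzzo-Tompa all maximal scoring subsequences (0-based [start, end])."""
    # stack of candidate segments: (start, end_exclusive, L, R) where L/R are
    # cumulative scores just before the segment and at its end
    stack: list[list] = []
    total = 0.0
    out: list[tuple[int, int]] = []
    for i, x in enumerate(scores):
        prev_total = total
        total += x
        if x <= 0:
            continue
        cur = [i, i + 1, prev_total, total]
        while True:
            # find rightmost j with L_j < L_cur
            j = len(stack) - 1
            while j >= 0 and stack[j][2] >= cur[2]:
                j -= 1
            if j < 0 or stack[j][3] >= cur[3]:
                stack.append(cur)
                break
            # absorb stack[j] .. end into the current candidate and retry
            cur = [stack[j][0], cur[1], stack[j][2], cur[3]]
            del stack[j:]
    out = [(s, e - 1) for s, e, _l, _r in stack]
    return out


def find_conserved_motifs(msa: MultiAlignment, ref_id: str,
                          cfg: ScanConfig | None = None) -> list[Motif]:
    """Scan an alignment for conserved motifs between reference and comparator.

    Returns non-overlapping motifs sorted by alignment start, each with its
    percent identity (all-columns convention within the segment) against the
    comparator row.
    """
    cfg = cfg or ScanConfig()
    if ref_id not in msa.rows:
        raise KeyError(f"reference {ref_id!r} not in alignment")
    cmp_id = cfg.comparator_id
    if cmp_id is None:
        non_ref = [i for i in msa.ids if i != ref_id]
        cmp_id = non_ref[-1]
    if cmp_id not in msa.rows:
        raise KeyError(f"comparator {cmp_id!r} not in alignment")

    ref_row = msa.rows[ref_id]
    match = _match_vector(ref_row, msa.rows[cmp_id])
    t = cfg.min_identity / 100.0
    scores = [(1.0 - t) if m else -t for m in match]
    segments = _maximal_scoring_segments(scores)

    # merge segments separated by <= merge_gap columns when the merged
    # stretch still meets the identity threshold
    merged: list[tuple[int, int]] = []
    for seg in segments:
        if merged and seg[0] - merged[-1][1] - 1 <= cfg.merge_gap:
            s, e = merged[-1][0], seg[1]
            n_match = sum(match[s:e + 1])
            if 100.0 * n_match / (e - s + 1) >= cfg.min_identity:
                merged[-1] = (s, e)
                continue
        merged.append(seg)

    # reference-coordinate map: residues of the ungapped reference row
    ref_index = []  # per column: residue index (1-based) at or before column
    respos = 0
    for ch in ref_row:
        if ch != GAP:
            respos += 1
        ref_index.append(respos)

    motifs = []
    for s, e in merged:
        if e - s + 1 < cfg.min_len:
            continue
        n_match = sum(match[s:e + 1])
        motifs.append(Motif(
            aln_start=s + 1,
            aln_end=e + 1,
            ref_start=max(1, ref_index[s]),
            ref_end=ref_index[e],
            identity=100.0 * n_match / (e - s + 1),
        ))
    return motifs


@dataclass
class OverlapRecord:
    motif: Motif
    annotation: AnnotationInterval
    overlap_length: int
    jaccard: float


def interval_overlap(motifs: list[Motif],
                     annotations: list[AnnotationInterval],
                     helix_jaccard: float = 0.5,
                     helix_class: str = "helix") -> list[OverlapRecord]:
    """Overlap motifs (reference frame) with annotation intervals.

    ``overlap_length`` counts residues of the inclusive intersection;
    ``jaccard`` = intersection / union. A motif's ``helical`` flag is set
    when its jaccard with any helix-class annotation reaches
    ``helix_jaccard``.
    """
    out = []
    for m in motifs:
        for a in annotations:
            lo = max(m.ref_start, a.start)
            hi = min(m.ref_end, a.end)
            inter = max(0, hi - lo + 1)
            union = m.ref_length + (a.end - a.start + 1) - inter
            jac = inter / union if union else 0.0
            if a.klass == helix_class and jac >= helix_jaccard:
                m.helical = True
            out.append(OverlapRecord(motif=m, annotation=a,
                                     overlap_length=inter, jaccard=jac))
    return out


ANNOTATION_COLUMNS = ["protein_id", "label", "start", "end", "class"]


def load_annotation_table(path: str | Path) -> dict[str, list[AnnotationInterval]]:
    """Read a TSV of structure/binding-site annotations keyed by protein id.

    Header: ``protein_id  label  start  end  class``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing column(s) {missing}")
    out: dict[str, list[AnnotationInterval]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["protein_id"], []).append(AnnotationInterval(
            label=row["label"], start=int(row["start"]), end=int(row["end"]),
            klass=row["class"]))
    return out


def motif_report(motifs: list[Motif], path: str | Path) -> pd.DataFrame:
    """Write (and return) the motif report table."""
    df = pd.DataFrame([
        {"aln_start": m.aln_start, "aln_end": m.aln_end,
         "ref_start": m.ref_start, "ref_end": m.ref_end,
         "identity": round(m.identity, 2), "helical": int(m.helical)}
        for m in motifs
    ], columns=["aln_start", "aln_end", "ref_start", "ref_end",
                "identity", "helical"])
    df.to_csv(path, sep="\t", index=False)
    return df
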