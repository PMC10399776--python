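"""Region-by-region conservation matrix for a protein family.

Builds the kind of summary used to compare Canoe/Afadin orthologs: for each
ortholog and each annotated region (folded domains, IDR, FAB), the percent
identity to a reference protein, binned into color bands, with notes for
sizeable indels and for region pairs with no detectable similarity.

Identity bands: green 85-100%, blue 70-84%, yellow 55-69%, red <55%.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import (GAP, AlignParams, IdentityMode, MultiAlignment,
                        PairwiseAlignment, global_align, percent_identity)
from .seq_regions import ProteinRecord, RegionSet, extract_region


class Band(str, enum.Enum):
    GREEN = "green"
    BLUE = "blue"
    YELLOW = "yellow"
    RED = "red"


#: Rank for "greener than" comparisons; lower is better conserved.
BAND_RANK = {Band.GREEN: 0, Band.BLUE: 1, Band.YELLOW: 2, Band.RED: 3}

#: Bands partition [0, 100]: (band, lower, upper) with lower-inclusive bins.
BAND_EDGES = [
    (Band.GREEN, 85.0, 100.0),
    (Band.BLUE, 70.0, 85.0),
    (Band.YELLOW, 55.0, 70.0),
    (Band.RED, 0.0, 55.0),
]


def bin_identity(pct: float) -> Band:
    """Map a percent identity to its color band."""
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percent identity {pct} outside [0, 100]")
    for band, lo, _hi in BAND_EDGES:
        if pct >= lo:
            return band
    return Band.RED  # pragma: no cover


@dataclass
class Cell:
    """One (ortholog, region) entry of the conservation matrix."""

    identity: float | None
    band: Band | None
    indel_note: bool = False
    no_similarity: bool = False
    absent: bool = False

    def __post_init__(self) -> None:
        if not self.absent and (self.identity is None) == (not self.no_similarity):
            raise ValueError("cell must carry identity xor no_similarity")


@dataclass
class ConservationMatrix:
    reference_id: str
    row_ids: list[str]
    region_names: list[str]
    cells: dict[tuple[str, str], Cell] = field(default_factory=dict)

    def cell(self, row_id: str, region: str) -> Cell:
        return self.cells[(row_id, region)]

    def to_frame(self) -> pd.DataFrame:
        """Identity values as a DataFrame (NaN for absent/no-similarity)."""
        data = {
            reg: [
                self.cells[(rid, reg)].identity
                if self.cells[(rid, reg)].identity is not None else np.nan
                for rid in self.row_ids
            ]
            for reg in self.region_names
        }
        return pd.DataFrame(data, index=self.row_ids)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for rid in self.row_ids:
            for reg in self.region_names:
                c = self.cells[(rid, reg)]
                rows.append({
                    "protein_id": rid,
                    "region": reg,
                    "identity": "" if c.identity is None else f"{c.identity:.1f}",
                    "band": c.band.value if c.band else "",
                    "indel_note": int(c.indel_note),
                    "no_similarity": int(c.no_similarity),
                    "absent": int(c.absent),
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def to_text(self) -> str:
        """Plain-text report mirroring the banded-matrix layout."""
        width = max(12, max((len(r) for r in self.region_names), default=12) + 2)
        head = "".ljust(18) + "".join(r.ljust(width) for r in self.region_names)
        lines = [head]
        for rid in self.row_ids:
            parts = [rid.ljust(18)]
            for reg in self.region_names:
                c = self.cells[(rid, reg)]
                if c.absent:
                    txt = "absent"
                elif c.no_similarity:
                    txt = "no sim."
                else:
                    txt = f"{c.identity:5.1f}% {c.band.value}"
                    if c.indel_note:
                        txt += " (indel)"
                parts.append(txt.ljust(width))
            lines.append("".join(parts))
        return "\n".join(lines)


def max_gap_run(aln: PairwiseAlignment) -> int:
    """Longest run of gap columns (either row) in a pairwise alignment."""
    best = run = 0
    for ca, cb in zip(aln.row_a, aln.row_b):
        if ca == GAP or cb == GAP:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def no_similarity_check(a: ProteinRecord, b: ProteinRecord,
                        n_shuffles: int = 99, alpha: float = 0.05,
                        seed: int = 0) -> bool:
    """Shuffle-null local-alignment significance test.

    Computes the Smith-Waterman local score of (a, b) and compares it with the
    scores of ``a`` against residue-shuffles of ``b``. Returns True ("no
    significant similarity") iff the empirical p-value >= alpha. Deterministic
    given ``seed``.
    """
    if n_shuffles < 19:
        raise ValueError("n_shuffles must be >= 19 for a meaningful null")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = AlignParams().matrix()
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    obs = aligner.score(a.sequence, b.sequence)
    rng = np.random.default_rng(seed)
    letters = np.array(list(b.sequence))
    exceed = 0
    for _ in range(n_shuffles):
        null_seq = "".join(rng.permutation(letters))
        if aligner.score(a.sequence, null_seq) >= obs:
            exceed += 1
    pval = (1 + exceed) / (n_shuffles + 1)
    return pval >= alpha


def _msa_slice_identity(msa: MultiAlignment, ref_id: str, other_id: str,
                        ref_start: int, ref_end: int,
                        mode: IdentityMode) -> tuple[float, int]:
    """Identity between two MSA rows over the columns spanned by a reference
    region (1-based inclusive residue interval on the ungapped reference)."""
    ref_row = msa.rows[ref_id]
    other_row = msa.rows[other_id]
    cols = []
    respos = 0
    for c, ch in enumerate(ref_row):
        if ch != GAP:
            respos += 1
            if ref_start <= respos <= ref_end:
                cols.append(c)
        elif respos >= ref_start and respos < ref_end:
            cols.append(c)  # interior gap column of the region span
    sub = PairwiseAlignment(
        id_a=ref_id, id_b=other_id,
        row_a="".join(ref_row[c] for c in cols),
        row_b="".join(other_row[c] for c in cols),
    )
    return percent_identity(sub, mode), max_gap_run(sub)


def region_identity_matrix(
    ref: ProteinRecord,
    ref_regions: RegionSet,
    others: list[tuple[ProteinRecord, RegionSet]],
    params: AlignParams | None = None,
    route: str = "pairwise_regions",
    msa: MultiAlignment | None = None,
    mode: IdentityMode | str = IdentityMode.ALL_COLUMNS,
    indel_run_threshold: int = 3,
    similarity_test: bool = False,
    n_shuffles: int = 99,
    alpha: float = 0.05,
    seed: int = 0,
) -> ConservationMatrix:
    """Build the per-region identity matrix of orthologs against a reference.

    ``route="pairwise_regions"`` (default) extracts each region from both
    proteins (the ortholog's own annotation) and aligns the two subsequences
    globally. ``route="slice_msa"`` instead slices a supplied MSA over the
    columns spanned by the reference region.

    The indel note is set when the region alignment contains a gap run of at
    least ``indel_run_threshold`` columns. With ``similarity_test=True``,
    regions whose shuffle-null test finds no significant local similarity are
    reported as "no similarity" instead of an identity (opt-in: it costs
    ``n_shuffles`` local alignments per cell and deliberately blanks cells
    that have drifted to random-level identity).
    """
    params = params or AlignParams()
    mode = IdentityMode(mode)
    if route not in ("pairwise_regions", "slice_msa"):
        raise ValueError(f"unknown route {route!r}")
    if route == "slice_msa":
        if msa is None:
            raise ValueError("route 'slice_msa' requires an msa")
        need = [ref.id] + [o.id for o, _ in others]
        missing = [i for i in need if i not in msa.rows]
        if missing:
            raise ValueError(f"msa missing rows {missing}")

    region_names = [r.name for r in ref_regions]
    matrix = ConservationMatrix(
        reference_id=ref.id,
        row_ids=[o.id for o, _ in others],
        region_names=region_names,
    )
    for other, other_regions in others:
        for region in ref_regions:
            key = (other.id, region.name)
            if route == "pairwise_regions":
                other_region = other_regions.get(region.name)
                if other_region is None:
                    matrix.cells[key] = Cell(identity=None, band=None, absent=True,
                                             no_similarity=False)
                    continue
                sub_ref = extract_region(ref, region)
                sub_other = extract_region(other, other_region)
                if similarity_test and no_similarity_check(
                        sub_ref, sub_other, n_shuffles=n_shuffles,
                        alpha=alpha, seed=seed):
                    matrix.cells[key] = Cell(identity=None, band=None,
                                             no_similarity=True)
                    continue
                aln = global_align(sub_ref, sub_other, params)
                ident = percent_identity(aln, mode)
                gap_run = max_gap_run(aln)
            else:
                ident, gap_run = _msa_slice_identity(
                    msa, ref.id, other.id, region.start, region.end, mode)
            matrix.cells[key] = Cell(
                identity=ident,
                band=bin_identity(ident),
                indel_note=gap_run >= indel_run_threshold,
            )
    return matrix
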