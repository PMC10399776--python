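"""Amino-acid composition and charge comparison of IDRs.

Disordered regions that have lost sequence identity sometimes still share
bulk properties — residue enrichment or net charge. These helpers quantify
that: per-residue frequencies, the top-3 enriched residues, and the charged
fraction (D, E, K, R; histidine is only partially charged at neutral pH and
is excluded by default, but can be added via ``charged_set``).

Unknown residues (X) are excluded from all denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq_regions import AMINO_ACIDS, ProteinRecord

CHARGED_RESIDUES = frozenset("DEKR")


@dataclass
class CompositionReport:
    protein_id: str
    region: str
    length: int
    freqs: dict[str, float]
    top3: list[str]
    charged_fraction: float


def aa_composition(seq: ProteinRecord, region: str = "") -> CompositionReport:
    """Residue frequencies and top-3 enriched residues of a sequence.

    Frequencies are count/length over non-X residues; ties in the top-3
    ranking break alphabetically.
    """
    counted = [c for c in seq.sequence if c != "X"]
    if not counted:
        raise ValueError(f"{seq.id!r} contains no countable residues")
    n = len(counted)
    freqs = {aa: counted.count(aa) / n for aa in AMINO_ACIDS if aa in counted}
    ranked = sorted(freqs, key=lambda aa: (-freqs[aa], aa))
    return CompositionReport(
        protein_id=seq.id,
        region=region,
        length=len(seq.sequence),
        freqs=freqs,
        top3=ranked[:3],
        charged_fraction=charged_fraction(seq),
    )


def charged_fraction(seq: ProteinRecord,
                     charged_set: frozenset[str] = CHARGED_RESIDUES) -> float:
    """Percentage of charged residues (default set D/E/K/R, X excluded)."""
    counted = [c for c in seq.sequence if c != "X"]
    if not counted:
        raise ValueError(f"{seq.id!r} contains no countable residues")
    return 100.0 * sum(c in charged_set for c in counted) / len(counted)


@dataclass
class PropertyComparison:
    """Side-by-side comparison of two region composition reports."""

    id_a: str
    id_b: str
    length_a: int
    length_b: int
    length_difference: int
    top3_a: list[str]
    top3_b: list[str]
    charged_a: float
    charged_b: float
    charged_difference: float


def idr_property_report(a: CompositionReport,
                        b: CompositionReport) -> PropertyComparison:
    """Tabulate length, enrichment and charge differences between two IDRs."""
    return PropertyComparison(
        id_a=a.protein_id,
        id_b=b.protein_id,
        length_a=a.length,
        length_b=b.length,
        length_difference=a.length - b.length,
        top3_a=list(a.top3),
        top3_b=list(b.top3),
        charged_a=a.charged_fraction,
        charged_b=b.charged_fraction,
        charged_difference=a.charged_fraction - b.charged_fraction,
    )
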