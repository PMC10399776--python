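"""Lesion identification from per-line VCFs of balanced mutant stocks.

A chemically mutagenized lethal allele kept over a balancer chromosome
carries, besides its causal lesion, the balancer's private variants (shared
by every balanced line in the collection) and background noise. The triage
pipeline reproduces that logic:

1. quality filter — drop calls with QUAL < 199 or DP < 2;
2. balancer subtraction — variants present (non hom-ref) in *all* lines are
   attributed to the shared balancer and discarded;
3. consequence annotation against a transcript model and genome — nonsense,
   missense, synonymous, splice-donor, frameshift;
4. prioritization — truncating lesions (nonsense = splice donor = frameshift)
   outrank missense, which outrank synonymous/other — and, for truncating
   calls, a map of which annotated protein regions are retained, truncated
   or lost.

Coordinates are 1-based VCF conventions; codon extraction is strand-aware.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .seq_regions import RegionSet


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    depth: int
    genotype: Genotype
    line_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def read_vcf(path: str | Path, line_id: str | None = None) -> list[VariantRecord]:
    """Read a VCF (v4.x) into one record per ALT allele.

    Multi-allelic sites are split. Genotype comes from the first sample's GT
    (required); depth from FORMAT/DP, falling back to INFO/DP.
    """
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if line_id is None:
            line_id = samples[0] if samples else Path(path).stem
        for rec in vf:
            if not samples:
                raise ValueError(f"{path}: no sample column, GT unavailable")
            sample = rec.samples[samples[0]]
            gt = sample.get("GT")
            if gt is None or all(a is None for a in gt):
                raise ValueError(f"{path}: missing GT at {rec.chrom}:{rec.pos}")
            depth = sample.get("DP")
            if depth is None:
                depth = rec.info.get("DP", 0)
            for ai, alt in enumerate(rec.alts or (), start=1):
                n_alt = sum(1 for a in gt if a == ai)
                if n_alt == 0:
                    genotype = Genotype.HOM_REF
                elif n_alt == len([a for a in gt if a is not None]):
                    genotype = Genotype.HOM_ALT
                else:
                    genotype = Genotype.HET
                records.append(VariantRecord(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    qual=float(rec.qual if rec.qual is not None else 0.0),
                    depth=int(depth), genotype=genotype, line_id=line_id,
                ))
    return records


QUAL_THRESHOLD = 199.0
DEPTH_THRESHOLD = 2


def site_filter(v: VariantRecord) -> str:
    """GATK-style hard filter: 'filtered' iff QUAL < 199 or DP < 2."""
    if v.qual < QUAL_THRESHOLD or v.depth < DEPTH_THRESHOLD:
        return "filtered"
    return "pass"


def balancer_subtract(
        cohort: dict[str, list[VariantRecord]]) -> dict[str, list[VariantRecord]]:
    """Remove variants shared (non hom-ref) by every line in the cohort.

    Variants are keyed by (chrom, pos, ref, alt); anything present in all
    lines is attributed to the common balancer chromosome. Output lists are
    per-line subsets of the input.
    """
    if len(cohort) < 2:
        raise ValueError("balancer subtraction needs >= 2 lines")
    key_sets = [
        {v.key for v in variants if v.genotype is not Genotype.HOM_REF}
        for variants in cohort.values()
    ]
    shared = set.intersection(*key_sets)
    return {
        line: [v for v in variants if v.key not in shared]
        for line, variants in cohort.items()
    }


def union_callsets(a: list[VariantRecord],
                   b: list[VariantRecord]) -> list[VariantRecord]:
    """Union of two callers' records on the (chrom, pos, ref, alt) key.

    The first callset wins on key collisions (genotype reconciliation across
    callers is out of scope); output is sorted by position.
    """
    merged = {v.key: v for v in b}
    merged.update({v.key: v for v in a})
    return sorted(merged.values(), key=lambda v: (v.chrom, v.pos, v.ref, v.alt))


@dataclass
class TranscriptModel:
    """Minimal transcript: exons plus a genomic CDS interval."""

    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"exon {s}-{e} inverted")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")
        if len(self.cds_positions()) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases in transcription order."""
        pos = [
            p
            for s, e in self.exons
            for p in range(max(s, self.cds_start), min(e, self.cds_end) + 1)
        ]
        return pos[::-1] if self.strand == "-" else pos

    def cds_sequence(self, genome: str) -> str:
        bases = "".join(
            genome[p - 1]
            for s, e in self.exons
            for p in range(max(s, self.cds_start), min(e, self.cds_end) + 1)
        )
        if self.strand == "-":
            return str(Seq(bases).reverse_complement())
        return bases

    def genomic_to_cds(self, pos: int) -> int | None:
        """1-based CDS index of a genomic position, or None outside the CDS."""
        positions = self.cds_positions()
        try:
            return positions.index(pos) + 1
        except ValueError:
            return None

    def splice_donor_positions(self) -> dict[int, int]:
        """Map genomic position -> intron index (1-based, transcription
        order) for the two donor (GT) bases of each intron."""
        out: dict[int, int] = {}
        introns = [
            (e1 + 1, s2 - 1)
            for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:])
        ]
        if self.strand == "+":
            for k, (istart, iend) in enumerate(introns, start=1):
                out[istart] = k
                if istart + 1 <= iend:
                    out[istart + 1] = k
        else:
            for k, (istart, iend) in enumerate(reversed(introns), start=1):
                out[iend] = k
                if iend - 1 >= istart:
                    out[iend - 1] = k
        return out

    @property
    def protein_length(self) -> int:
        return len(self.cds_positions()) // 3


class Consequence(str, enum.Enum):
    NONSENSE = "nonsense"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    SPLICE_DONOR = "splice_donor"
    FRAMESHIFT = "frameshift"
    OTHER = "other"


#: Rank for prioritization; lower ranks first. Truncating lesions tie.
CONSEQUENCE_RANK = {
    Consequence.NONSENSE: 0,
    Consequence.SPLICE_DONOR: 0,
    Consequence.FRAMESHIFT: 0,
    Consequence.MISSENSE: 1,
    Consequence.SYNONYMOUS: 2,
    Consequence.OTHER: 2,
}

TRUNCATING = {Consequence.NONSENSE, Consequence.SPLICE_DONOR,
              Consequence.FRAMESHIFT}


@dataclass
class ConsequenceCall:
    category: Consequence
    protein_pos: int | None = None
    notation: str = ""
    intron_index: int | None = None
    variant: VariantRecord | None = None

    def __post_init__(self) -> None:
        if self.category in (Consequence.NONSENSE, Consequence.MISSENSE) \
                and self.protein_pos is None:
            raise ValueError(f"{self.category.value} call needs protein_pos")
        if self.category is Consequence.SPLICE_DONOR and self.intron_index is None:
            raise ValueError("splice_donor call needs intron_index")


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def annotate_consequence(v: VariantRecord, tx: TranscriptModel,
                         genome: str) -> ConsequenceCall:
    """Codon-level consequence of one variant against a transcript model.

    Uses the standard genetic code. SNVs inside the CDS become
    nonsense/missense/synonymous with a protein position and a notation such
    as ``Q1310STOP`` or ``D2048G``; SNVs hitting the two donor bases of an
    intron are splice_donor; CDS indels with a length shift not divisible by
    3 are frameshift; everything else is other. Raises if the REF allele
    disagrees with the genome.
    """
    if v.chrom != tx.chrom:
        raise ValueError(f"variant on {v.chrom}, transcript on {tx.chrom}")
    gref = genome[v.pos - 1: v.pos - 1 + len(v.ref)]
    if gref.upper() != v.ref.upper():
        raise ValueError(
            f"REF {v.ref!r} at {v.chrom}:{v.pos} disagrees with genome {gref!r}")

    if v.is_snv:
        cds_idx = tx.genomic_to_cds(v.pos)
        if cds_idx is not None:
            cds = tx.cds_sequence(genome)
            codon_num = (cds_idx - 1) // 3 + 1
            offset = (cds_idx - 1) % 3
            codon = cds[3 * (codon_num - 1): 3 * codon_num]
            alt_base = v.alt.upper()
            if tx.strand == "-":
                alt_base = alt_base.translate(_COMPLEMENT)
            alt_codon = codon[:offset] + alt_base + codon[offset + 1:]
            aa_ref = str(Seq(codon).translate())
            aa_alt = str(Seq(alt_codon).translate())
            if aa_alt == "*" and aa_ref != "*":
                return ConsequenceCall(
                    Consequence.NONSENSE, protein_pos=codon_num,
                    notation=f"{aa_ref}{codon_num}STOP", variant=v)
            if aa_alt == aa_ref:
                return ConsequenceCall(
                    Consequence.SYNONYMOUS, protein_pos=codon_num,
                    notation=f"{aa_ref}{codon_num}{aa_alt}", variant=v)
            return ConsequenceCall(
                Consequence.MISSENSE, protein_pos=codon_num,
                notation=f"{aa_ref}{codon_num}{aa_alt}", variant=v)
        donors = tx.splice_donor_positions()
        if v.pos in donors:
            k = donors[v.pos]
            return ConsequenceCall(
                Consequence.SPLICE_DONOR, intron_index=k,
                notation=f"splice_donor_intron{k}", variant=v)
        return ConsequenceCall(Consequence.OTHER, variant=v)

    # indel: changed bases are those after the shared anchor base
    shift = len(v.alt) - len(v.ref)
    if len(v.ref) > 1:  # deletion (or complex): bases pos+1 .. pos+len(ref)-1
        affected = range(v.pos + 1, v.pos + len(v.ref))
    else:  # pure insertion after pos
        affected = range(v.pos, v.pos + 1)
    in_cds = any(tx.genomic_to_cds(p) is not None for p in affected)
    if in_cds and shift % 3 != 0:
        first = next(p for p in affected if tx.genomic_to_cds(p) is not None)
        cds_idx = tx.genomic_to_cds(first)
        codon_num = (cds_idx - 1) // 3 + 1
        return ConsequenceCall(
            Consequence.FRAMESHIFT, protein_pos=codon_num,
            notation=f"{codon_num}fs", variant=v)
    return ConsequenceCall(Consequence.OTHER, variant=v)


@dataclass
class TriageEntry:
    line_id: str
    call: ConsequenceCall
    rank: int
    truncation_map: dict[str, str] = field(default_factory=dict)


def truncation_map(protein_pos: int, regions: RegionSet) -> dict[str, str]:
    """Fate of each annotated region given a stop at ``protein_pos``."""
    out = {}
    for r in regions:
        if r.end < protein_pos:
            out[r.name] = "retained"
        elif r.start >= protein_pos:
            out[r.name] = "lost"
        else:
            out[r.name] = "truncated"
    return out


def prioritize_and_map(calls: list[ConsequenceCall],
                       regions: RegionSet | None = None) -> list[TriageEntry]:
    """Rank consequence calls and map protein truncations onto regions.

    Truncating lesions (nonsense, splice donor, frameshift) rank first,
    then missense, then synonymous/other; ties break by genomic position.
    """
    def sort_key(c: ConsequenceCall):
        pos = c.variant.pos if c.variant else 0
        return (CONSEQUENCE_RANK[c.category], pos)

    entries = []
    for call in sorted(calls, key=sort_key):
        tmap = {}
        if regions is not None and call.category in TRUNCATING \
                and call.protein_pos is not None:
            tmap = truncation_map(call.protein_pos, regions)
        entries.append(TriageEntry(
            line_id=call.variant.line_id if call.variant else "",
            call=call, rank=CONSEQUENCE_RANK[call.category],
            truncation_map=tmap))
    return entries


CODING_CATEGORIES = {Consequence.NONSENSE, Consequence.MISSENSE,
                     Consequence.SYNONYMOUS, Consequence.SPLICE_DONOR,
                     Consequence.FRAMESHIFT}


def triage_cohort(cohort: dict[str, list[VariantRecord]],
                  tx: TranscriptModel, genome: str,
                  regions: RegionSet | None = None) -> dict[str, TriageEntry]:
    """Full triage: filter, balancer-subtract, annotate, prioritize.

    Returns the top candidate lesion per line (lines with no coding candidate
    after filtering are omitted).
    """
    passing = {
        line: [v for v in vs if site_filter(v) == "pass"]
        for line, vs in cohort.items()
    }
    private = balancer_subtract(passing)
    out: dict[str, TriageEntry] = {}
    for line, variants in private.items():
        calls = [
            annotate_consequence(v, tx, genome)
            for v in variants if v.chrom == tx.chrom
        ]
        calls = [c for c in calls if c.category in CODING_CATEGORIES]
        if not calls:
            continue
        out[line] = prioritize_and_map(calls, regions)[0]
    return out


def triage_report(entries: dict[str, TriageEntry], path: str | Path) -> pd.DataFrame:
    """Write (and return) the per-line lesion report."""
    rows = []
    for line in sorted(entries):
        e = entries[line]
        v = e.call.variant
        rows.append({
            "line_id": line,
            "chrom": v.chrom if v else "",
            "pos": v.pos if v else "",
            "ref": v.ref if v else "",
            "alt": v.alt if v else "",
            "category": e.call.category.value,
            "notation": e.call.notation,
            "protein_pos": e.call.protein_pos if e.call.protein_pos else "",
            "truncation_map": ";".join(
                f"{k}={v_}" for k, v_ in e.truncation_map.items()),
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


TRANSCRIPT_COLUMNS = ["chrom", "strand", "exon_start", "exon_end",
                      "cds_start", "cds_end"]


def write_transcript_table(tx: TranscriptModel, path: str | Path) -> None:
    rows = [
        {"chrom": tx.chrom, "strand": tx.strand, "exon_start": s,
         "exon_end": e, "cds_start": tx.cds_start, "cds_end": tx.cds_end}
        for s, e in tx.exons
    ]
    pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_transcript_table(path: str | Path) -> TranscriptModel:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRANSCRIPT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transcript table missing column(s) {missing}")
    return TranscriptModel(
        chrom=str(df["chrom"].iloc[0]),
        strand=str(df["strand"].iloc[0]),
        exons=list(zip(df["exon_start"].astype(int), df["exon_end"].astype(int))),
        cds_start=int(df["cds_start"].iloc[0]),
        cds_end=int(df["cds_end"].iloc[0]),
    )
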