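"""Synthetic data with known ground truth for every analysis in the package.

Three generators:

* :func:`simulate_family` — a protein family evolved on a star phylogeny
  under a 20-state symmetric substitution model with region-specific rates:
  slow folded domains, a fast IDR containing slower "planted" motifs, and
  geometric-length indels confined to the IDR outside the motifs. Because
  substitutions are uniform over the 19 alternative residues, the expected
  pairwise identity to the root has the closed form

      E[identity] = 100 * (1/20 + (19/20) * exp(-(20/19) * d_eff)),

  with ``d_eff = distance * rate multiplier``, which the tests use as an
  oracle. The true root/taxon alignment, per-taxon region coordinates and
  planted-motif locations are all returned.

* :func:`simulate_phenotypes` — multinomial cuticle-category counts per
  genotype and two-group junctional-intensity images with a known true
  mean ratio.

* :func:`simulate_vcf_cohort` — a cohort of balanced mutant lines sharing
  one set of balancer variants (het in every line), each with a unique
  planted coding lesion, plus passing and sub-threshold noise variants,
  written as standard VCF text.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import GAP, PairwiseAlignment
from .pheno import CuticleTable, IntensityGroup, IntensitySample
from .seq_regions import (AMINO_ACIDS, ProteinRecord, RegionAnnotation,
                          RegionClass, RegionSet)
from .variants import Genotype, TranscriptModel, VariantRecord

# ---------------------------------------------------------------------------
# protein family simulation
# ---------------------------------------------------------------------------

REFERENCE_ID = "ref"


@dataclass(frozen=True)
class PlantedMotif:
    """A slow-evolving island inside a (fast) region: coordinates are
    1-based inclusive, relative to the region start."""

    region: str
    start: int
    length: int
    multiplier: float = 0.1


@dataclass
class FamilySimConfig:
    """Study conditions for the protein-family generator.

    Defaults emulate a deep-insect comparison: folded domains still clearly
    alignable (expected identity ~82% at distance 2.0), an IDR diverged to
    near the random floor (~17%), and planted motifs retaining ~82% identity.
    """

    regions: list[tuple[str, int, RegionClass]] = field(default_factory=lambda: [
        ("RA", 100, RegionClass.DOMAIN),
        ("PDZ", 90, RegionClass.DOMAIN),
        ("IDR", 300, RegionClass.IDR),
        ("FAB", 80, RegionClass.FAB),
    ])
    n_taxa: int = 6
    distances: list[float] | None = None  # default: 2.0 per taxon
    rate_multipliers: dict[RegionClass, float] = field(default_factory=lambda: {
        RegionClass.DOMAIN: 0.1,
        RegionClass.IDR: 1.0,
        RegionClass.FAB: 0.3,
    })
    planted_motifs: list[PlantedMotif] = field(default_factory=lambda: [
        PlantedMotif("IDR", 41, 20),
        PlantedMotif("IDR", 141, 20),
        PlantedMotif("IDR", 241, 20),
    ])
    indel_rate: float = 0.02  # events per eligible IDR site
    indel_mean_len: float = 3.0

    def __post_init__(self) -> None:
        if self.distances is None:
            self.distances = [2.0] * self.n_taxa
        if len(self.distances) != self.n_taxa:
            raise ValueError("need one distance per taxon")
        if any(m < 0 for m in self.rate_multipliers.values()):
            raise ValueError("rate multipliers must be >= 0")
        bounds = {name: length for name, length, _k in self.regions}
        for m in self.planted_motifs:
            if m.region not in bounds:
                raise ValueError(f"motif region {m.region!r} unknown")
            if m.start < 1 or m.start + m.length - 1 > bounds[m.region]:
                raise ValueError(f"motif outside region {m.region!r}")

    @property
    def root_length(self) -> int:
        return sum(length for _n, length, _k in self.regions)


@dataclass
class SimTruth:
    """Ground truth of one simulated family."""

    records: list[ProteinRecord]  # reference first, then taxa
    region_sets: dict[str, RegionSet]
    true_motifs: list[tuple[int, int]]  # absolute 1-based intervals on ref
    expected_identity: dict[tuple[str, str], float]  # (taxon, region) -> pct
    alignments: dict[str, PairwiseAlignment]  # taxon -> true ref/taxon rows

    @property
    def reference(self) -> ProteinRecord:
        return self.records[0]

    @property
    def taxa(self) -> list[ProteinRecord]:
        return self.records[1:]

    def true_motif_alignment_spans(self, taxon: str) -> list[tuple[int, int]]:
        """Planted-motif intervals as 1-based column spans of the true
        pairwise alignment of ``taxon`` against the reference."""
        row = self.alignments[taxon].row_a
        respos = 0
        col_of_res = {}
        for col, ch in enumerate(row, start=1):
            if ch != GAP:
                respos += 1
                col_of_res[respos] = col
        return [(col_of_res[s], col_of_res[e]) for s, e in self.true_motifs]


def _expected_identity_pct(d_eff: float) -> float:
    return 100.0 * (1.0 / 20.0 + (19.0 / 20.0) * np.exp(-(20.0 / 19.0) * d_eff))


def simulate_family(cfg: FamilySimConfig | None = None,
                    seed: int = 0) -> SimTruth:
    """Evolve a family from a uniform-random root on a star phylogeny."""
    cfg = cfg or FamilySimConfig()
    rng = np.random.default_rng(seed)
    L = cfg.root_length
    aa = np.array(list(AMINO_ACIDS))
    root_idx = rng.integers(0, 20, size=L)

    # per-site rate multipliers and region/motif bookkeeping (0-based sites)
    mult = np.empty(L)
    region_bounds: dict[str, tuple[int, int]] = {}  # 1-based inclusive on root
    region_class: dict[str, RegionClass] = {}
    offset = 0
    for name, length, klass in cfg.regions:
        mult[offset:offset + length] = cfg.rate_multipliers[klass]
        region_bounds[name] = (offset + 1, offset + length)
        region_class[name] = klass
        offset += length
    motif_sites = np.zeros(L, dtype=bool)
    true_motifs = []
    for m in cfg.planted_motifs:
        rstart = region_bounds[m.region][0]
        a = rstart + m.start - 1
        b = a + m.length - 1
        mult[a - 1: b] = m.multiplier
        motif_sites[a - 1: b] = True
        true_motifs.append((a, b))

    idr_sites = np.zeros(L, dtype=bool)
    for name, (a, b) in region_bounds.items():
        if region_class[name] is RegionClass.IDR:
            idr_sites[a - 1: b] = True
    eligible = idr_sites & ~motif_sites  # indel-eligible root sites

    ref_seq = "".join(aa[root_idx])
    ref_regions = RegionSet(
        protein_id=REFERENCE_ID,
        regions=[RegionAnnotation(name, *region_bounds[name],
                                  klass=region_class[name])
                 for name, _len, _k in cfg.regions],
    )

    records = [ProteinRecord(id=REFERENCE_ID, sequence=ref_seq)]
    region_sets = {REFERENCE_ID: ref_regions}
    expected = {}
    alignments = {}

    for t, dist in enumerate(cfg.distances):
        taxon = f"taxon{t + 1}"
        # substitutions: per-site Poisson jump counts under the symmetric model
        k = rng.poisson(dist * mult)
        p_same = 1.0 / 20.0 + (19.0 / 20.0) * (-1.0 / 19.0) ** k
        stay = rng.random(L) < p_same
        shift = rng.integers(1, 20, size=L)  # uniform over the 19 alternatives
        tax_idx = np.where(stay, root_idx, (root_idx + shift) % 20)

        # alignment columns: (root_char, taxon_char, root_site or None)
        cols: list[list] = [[aa[root_idx[i]], aa[tax_idx[i]], i]
                            for i in range(L)]

        # indels in eligible IDR sites only
        n_eligible = int(eligible.sum())
        if cfg.indel_rate > 0 and n_eligible > 0:
            n_events = rng.poisson(cfg.indel_rate * n_eligible)
            p_geom = 1.0 / cfg.indel_mean_len
            for _ in range(n_events):
                length = int(rng.geometric(p_geom))
                site = int(rng.choice(np.flatnonzero(eligible)))
                if rng.random() < 0.5:
                    # deletion: gap the taxon row over eligible sites from
                    # `site`, stopping at any non-eligible site
                    run = 0
                    for i in range(site, L):
                        if run >= length or not eligible[i]:
                            break
                        run += 1
                    for col in cols:
                        if col[2] is not None and site <= col[2] < site + run:
                            col[1] = GAP
                else:
                    # insertion: new residues in the taxon row after `site`
                    ins = [[GAP, aa[rng.integers(0, 20)], None]
                           for _ in range(length)]
                    at = next(ci for ci, col in enumerate(cols)
                              if col[2] == site)
                    cols[at + 1: at + 1] = ins

        row_ref = "".join(c[0] for c in cols)
        row_tax = "".join(c[1] for c in cols)
        # drop all-gap columns (a fully deleted insertion cannot occur, but a
        # deletion may gap a column whose root char is present, never both)
        tax_seq = row_tax.replace(GAP, "")

        # per-taxon region coordinates: taxon residues aligned within the
        # column span of each root region (inserted residues between the
        # first and last such column are included implicitly)
        regions = []
        for name, (a, b) in region_bounds.items():
            start_res = end_res = None
            respos = 0
            for col in cols:
                if col[1] != GAP:
                    respos += 1
                if col[2] is None or col[1] == GAP:
                    continue
                if a - 1 <= col[2] <= b - 1:
                    if start_res is None:
                        start_res = respos
                    end_res = respos
            if start_res is not None:
                regions.append(RegionAnnotation(
                    name, start_res, end_res, klass=region_class[name]))
        region_sets[taxon] = RegionSet(protein_id=taxon, regions=regions)

        records.append(ProteinRecord(id=taxon, sequence=tax_seq))
        alignments[taxon] = PairwiseAlignment(
            id_a=REFERENCE_ID, id_b=taxon, row_a=row_ref, row_b=row_tax)
        for name, (a, b) in region_bounds.items():
            d_eff_sites = dist * mult[a - 1: b]
            expected[(taxon, name)] = float(np.mean(
                [_expected_identity_pct(d) for d in d_eff_sites]))

    return SimTruth(records=records, region_sets=region_sets,
                    true_motifs=true_motifs, expected_identity=expected,
                    alignments=alignments)


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------


@dataclass
class PhenoSimConfig:
    """Study conditions for the phenotype generator.

    Intensity defaults mirror the imaging protocol: 10 images per group,
    20 line (junction) and 12 circle (background) measurements per image,
    with the mutant group's junctional signal scaled by ``true_ratio``.
    """

    cuticle_probs: dict[str, list[float]] = field(default_factory=lambda: {
        "null_allele": [0.35, 0.25, 0.32, 0.04, 0.03, 0.01],
        "strong_allele": [0.05, 0.07, 0.36, 0.22, 0.20, 0.10],
    })
    n_embryos: int = 200
    true_ratio: float = 0.5
    mu: float = 100.0  # control-group junctional signal, arbitrary units
    background: float = 20.0
    noise_sd: float = 10.0
    n_per_group: int = 10  # close-up images per group
    n_lines: int = 20
    n_circles: int = 12

    def __post_init__(self) -> None:
        for g, p in self.cuticle_probs.items():
            if len(p) != 6 or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"cuticle probs for {g!r} must be 6 values "
                                 "summing to 1")


@dataclass
class PhenoTruth:
    cuticle_tables: dict[str, CuticleTable]
    samples: list[IntensitySample]
    x_values: list[float]  # per-image junctional intensity, mutant group
    y_values: list[float]  # per-image junctional intensity, control group
    true_ratio: float
    true_mean_scores: dict[str, float]


def simulate_phenotypes(cfg: PhenoSimConfig | None = None,
                        seed: int = 0) -> PhenoTruth:
    """Multinomial cuticle counts and two-group intensity images."""
    cfg = cfg or PhenoSimConfig()
    rng = np.random.default_rng(seed)

    tables = {}
    true_means = {}
    for genotype, probs in cfg.cuticle_probs.items():
        counts = rng.multinomial(cfg.n_embryos, probs)
        tables[genotype] = CuticleTable(
            genotype=genotype, counts={k: int(c) for k, c in enumerate(counts)})
        true_means[genotype] = float(sum(k * p for k, p in enumerate(probs)))

    samples = []
    x_values, y_values = [], []
    groups = [(IntensityGroup.GFP_NEGATIVE, cfg.true_ratio * cfg.mu, x_values),
              (IntensityGroup.GFP_POSITIVE, cfg.mu, y_values)]
    for group, signal, sink in groups:
        for i in range(cfg.n_per_group):
            lines = np.clip(rng.normal(cfg.background + signal, cfg.noise_sd,
                                       size=cfg.n_lines), 0.0, None)
            circles = np.clip(rng.normal(cfg.background, cfg.noise_sd,
                                         size=cfg.n_circles), 0.0, None)
            sample = IntensitySample(
                embryo_id=f"{group.value}_{i + 1}", group=group,
                line_values=list(lines), circle_values=list(circles))
            samples.append(sample)
            sink.append(float(lines.mean() - circles.mean()))
    return PhenoTruth(cuticle_tables=tables, samples=samples,
                      x_values=x_values, y_values=y_values,
                      true_ratio=cfg.true_ratio, true_mean_scores=true_means)


# ---------------------------------------------------------------------------
# VCF cohort simulation
# ---------------------------------------------------------------------------

#: Codon planted at lesion sites; C->T at its first base yields a TAG stop.
_LESION_CODON = "CAG"  # glutamine
#: Codon planted at synonymous-noise sites; T->C at base 3 keeps leucine.
_SYN_CODON = "CTT"


@dataclass
class CohortSimConfig:
    """Study conditions for the balanced-cohort generator: one unique
    nonsense lesion per line over a shared set of balancer variants."""

    n_lines: int = 18
    genome_length: int = 9000
    n_balancer_variants: int = 50
    n_noise: int = 6  # intergenic noise variants per line
    noise_fail_fraction: float = 0.5  # fraction of noise below QUAL/DP cutoffs
    n_syn_noise: int = 1  # passing synonymous coding variants per line
    qual_pass: tuple[float, float] = (250.0, 3000.0)
    qual_fail: tuple[float, float] = (20.0, 150.0)
    dp_pass: tuple[int, int] = (10, 60)
    chrom: str = "chr3R"


@dataclass
class CohortTruth:
    cohort: dict[str, list[VariantRecord]]
    transcript: TranscriptModel
    genome: str
    lesions: dict[str, dict]  # line -> {pos, ref, alt, notation, protein_pos}


def _toy_transcript(chrom: str, genome_length: int) -> TranscriptModel:
    # four exons on the + strand; CDS spans exon interiors, length % 3 == 0
    exons = [(1001, 1600), (2001, 2600), (3001, 3600), (4001, 4702)]
    cds_start, cds_end = 1101, 4502  # 2202 coding bases, 734 codons
    tx = TranscriptModel(chrom=chrom, strand="+", exons=exons,
                         cds_start=cds_start, cds_end=cds_end)
    if genome_length < exons[-1][1] + 200:
        raise ValueError("genome_length too short for the toy transcript")
    return tx


def simulate_vcf_cohort(cfg: CohortSimConfig | None = None,
                        seed: int = 0) -> CohortTruth:
    """Simulate per-line variant sets over a toy genome and transcript.

    Every line carries the same ``n_balancer_variants`` heterozygous
    balancer variants, one unique heterozygous nonsense lesion in the CDS,
    ``n_syn_noise`` passing synonymous CDS variants, and ``n_noise``
    intergenic noise variants of which a known fraction fails the
    QUAL/DP filter.
    """
    cfg = cfg or CohortSimConfig()
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    genome = list("".join(bases[rng.integers(0, 4, size=cfg.genome_length)]))
    tx = _toy_transcript(cfg.chrom, cfg.genome_length)

    cds_positions = tx.cds_positions()
    n_codons = len(cds_positions) // 3
    # reserve distinct codons: one lesion + n_syn_noise per line; skip the
    # first and last codon (start/stop context kept untouched)
    need = cfg.n_lines * (1 + cfg.n_syn_noise)
    codon_pool = rng.choice(np.arange(2, n_codons), size=need, replace=False)
    lesion_codons = codon_pool[:cfg.n_lines]
    syn_codons = codon_pool[cfg.n_lines:]

    def plant_codon(codon_num: int, codon_seq: str) -> list[int]:
        pos3 = cds_positions[3 * (codon_num - 1): 3 * codon_num]
        for p, b in zip(pos3, codon_seq):
            genome[p - 1] = b
        return pos3

    lesion_info = {}
    syn_info: dict[tuple[str, int], tuple[int, str, str]] = {}
    for i in range(cfg.n_lines):
        line = f"line{i + 1:02d}"
        codon_num = int(lesion_codons[i])
        pos3 = plant_codon(codon_num, _LESION_CODON)
        lesion_info[line] = {
            "pos": pos3[0], "ref": "C", "alt": "T",
            "notation": f"Q{codon_num}STOP", "protein_pos": codon_num,
        }
        for j in range(cfg.n_syn_noise):
            codon_num_s = int(syn_codons[i * cfg.n_syn_noise + j])
            pos3s = plant_codon(codon_num_s, _SYN_CODON)
            syn_info[(line, j)] = (pos3s[2], "T", "C")

    genome_str = "".join(genome)

    # positions outside the transcript span, for balancer + noise variants
    tx_span = set(range(tx.exons[0][0] - 10, tx.exons[-1][1] + 11))
    intergenic = np.array([p for p in range(1, cfg.genome_length + 1)
                           if p not in tx_span])
    n_needed = cfg.n_balancer_variants + cfg.n_lines * cfg.n_noise
    noise_pool = rng.choice(intergenic, size=n_needed, replace=False)
    balancer_pos = noise_pool[:cfg.n_balancer_variants]
    line_noise_pos = noise_pool[cfg.n_balancer_variants:]

    def snv_alt(pos: int) -> str:
        ref = genome_str[pos - 1]
        alts = [b for b in "ACGT" if b != ref]
        return alts[int(rng.integers(0, 3))]

    def qual_dp(passing: bool) -> tuple[float, int]:
        # whole-number QUALs survive the float32 round-trip through VCF
        if passing:
            q = float(round(rng.uniform(*cfg.qual_pass)))
            dp = int(rng.integers(cfg.dp_pass[0], cfg.dp_pass[1] + 1))
        elif rng.random() < 0.5:  # fail on QUAL
            q = float(round(rng.uniform(*cfg.qual_fail)))
            dp = int(rng.integers(cfg.dp_pass[0], cfg.dp_pass[1] + 1))
        else:  # fail on depth
            q = float(round(rng.uniform(*cfg.qual_pass)))
            dp = int(rng.integers(0, 2))
        return q, dp

    balancer = []
    for pos in sorted(int(p) for p in balancer_pos):
        q, dp = qual_dp(passing=True)
        balancer.append((pos, genome_str[pos - 1], snv_alt(pos), q, dp))

    cohort: dict[str, list[VariantRecord]] = {}
    for i in range(cfg.n_lines):
        line = f"line{i + 1:02d}"
        recs = [
            VariantRecord(chrom=cfg.chrom, pos=pos, ref=ref, alt=alt,
                          qual=q, depth=dp, genotype=Genotype.HET,
                          line_id=line)
            for pos, ref, alt, q, dp in balancer
        ]
        info = lesion_info[line]
        q, dp = qual_dp(passing=True)
        recs.append(VariantRecord(
            chrom=cfg.chrom, pos=info["pos"], ref=info["ref"], alt=info["alt"],
            qual=q, depth=dp, genotype=Genotype.HET, line_id=line))
        for j in range(cfg.n_syn_noise):
            pos, ref, alt = syn_info[(line, j)]
            q, dp = qual_dp(passing=True)
            recs.append(VariantRecord(
                chrom=cfg.chrom, pos=pos, ref=ref, alt=alt, qual=q, depth=dp,
                genotype=Genotype.HET, line_id=line))
        my_noise = line_noise_pos[i * cfg.n_noise:(i + 1) * cfg.n_noise]
        for k, pos in enumerate(sorted(int(p) for p in my_noise)):
            passing = k >= round(cfg.n_noise * cfg.noise_fail_fraction)
            q, dp = qual_dp(passing=passing)
            recs.append(VariantRecord(
                chrom=cfg.chrom, pos=pos, ref=genome_str[pos - 1],
                alt=snv_alt(pos), qual=q, depth=dp, genotype=Genotype.HET,
                line_id=line))
        cohort[line] = sorted(recs, key=lambda v: v.pos)

    return CohortTruth(cohort=cohort, transcript=tx, genome=genome_str,
                       lesions=lesion_info)


def write_vcf(variants: list[VariantRecord], path: str | Path,
              chrom_length: int, sample: str) -> None:
    """Write records as a minimal, pysam-readable VCF v4.2 text file."""
    chroms = {v.chrom for v in variants}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(chroms):
            fh.write(f"##contig=<ID={chrom},length={chrom_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        gt_of = {Genotype.HOM_REF: "0/0", Genotype.HET: "0/1",
                 Genotype.HOM_ALT: "1/1"}
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t"
                     f"{v.qual:.1f}\t.\t.\tGT:DP\t"
                     f"{gt_of[v.genotype]}:{v.depth}\n")


def write_cohort(truth: CohortTruth, outdir: str | Path) -> dict[str, Path]:
    """Write per-line VCFs, the genome FASTA, the transcript table and the
    truth JSON; returns the per-line VCF paths."""
    from .variants import write_transcript_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for line, variants in truth.cohort.items():
        p = outdir / f"{line}.vcf"
        write_vcf(variants, p, chrom_length=len(truth.genome), sample=line)
        paths[line] = p
    with open(outdir / "genome.fasta", "w") as fh:
        fh.write(f">{truth.transcript.chrom}\n")
        for i in range(0, len(truth.genome), 60):
            fh.write(truth.genome[i:i + 60] + "\n")
    write_transcript_table(truth.transcript, outdir / "transcript.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.lesions, fh, indent=2)
    return paths
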