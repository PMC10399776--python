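# Methods

This note documents the models and procedures implemented in `idrcons`, the
assumptions behind them, the parameter defaults and why they were chosen,
and what the synthetic-data generators do and do not emulate.

## Pairwise global alignment

`alignment.global_align` is a three-state Needleman–Wunsch/Gotoh dynamic
program (states: residue/residue, gap-in-second, gap-in-first) with affine
gap costs: a gap of length L costs `gap_open + (L-1)*gap_extend`, defaults
BLOSUM62 with open −11 and extend −1, the most common protein-alignment
convention. All state transitions are allowed, including adjacent
opposite-direction gaps (each run re-pays the open cost), so the DP optimum
coincides with the optimum over *every* possible alignment — the test suite
verifies this against exhaustive enumeration on short sequences and against
Biopython's independent implementation on longer ones.

Determinism: traceback ties prefer the diagonal move, then a gap in the
second sequence, then a gap in the first. The row recurrences are
numpy-vectorized; the within-row dependency of the gap-in-first state is
closed out with a running prefix maximum, giving O(nm) time with O(n+m)
vector operations per row.

Percent identity is defined over two denominators, both used when comparing
Canoe/Afadin regions: all alignment columns, or gap-free columns only
("ignoring indels"). A column counts as identical only if both residues are
equal, non-gap, and not X; the ungapped-columns value therefore can never be
smaller than the all-columns value. When an alignment has no gap-free column
the ungapped convention is undefined and raised explicitly.

## Conservation matrix

`conservation.region_identity_matrix` reproduces the region-by-region
ortholog comparison: for each (ortholog, region) cell, extract the region
from both proteins using each protein's *own* annotation, globally align the
two subsequences, and report identity, its color band (green 85–100, blue
70–84, yellow 55–69, red < 55, lower bounds inclusive), and an indel note
when the alignment contains a gap run of ≥ 3 columns (one threshold
separating "1 aa indel" from larger events; configurable). A region missing
from an ortholog's annotation yields an `absent` cell, not an error.

The default route is pairwise region alignment because it is reproducible
without a trusted multiple alignment; a `slice_msa` route computes the same
quantity over the columns of a supplied MSA spanned by the reference region,
for workflows that start from an external Clustal alignment. The identity
denominator is exposed (`mode`) because published per-region identities
rarely state their gap handling.

"No significant similarity" is an opt-in shuffle-null test
(`no_similarity_check`): the observed Smith–Waterman local score (BLOSUM62,
−11/−1, via Biopython's PairwiseAligner) is compared with the scores of the
first sequence against `n_shuffles` residue-shuffles of the second, and the
add-one empirical p-value `(1+#null≥obs)/(n_shuffles+1)` is compared with
alpha — "no similarity" iff p ≥ alpha. The floor of the estimator is
1/(n_shuffles+1), so alpha must exceed that floor for significance to be
attainable; 99 shuffles support alpha = 0.05. The test is off by default in
the matrix builder: on strongly diverged IDRs its entire job is to blank
cells whose identity is at the random-comparison floor, which is the right
behavior on real data but discards the identity values the simulation
studies compare.

## Conserved-motif scanning

The motif criteria are a minimum segment length (default 14 alignment
columns) and a minimum identity between the reference row and one designated
comparator row (default 48 %; vertebrate preset 15/63). Identity against a
single comparator, not an average over taxa, matches how per-motif
percentages are quoted for ortholog pairs. The captions' upper identity
bounds (88 %/83 %) describe the motifs that were found and are not a filter:
a perfectly conserved motif is reported.

"Conserved stretch" is formalized as maximal-scoring-segment extraction:
each column scores `1−t` on a match and `−t` otherwise (t = identity
threshold as a fraction; gap and X columns never match), and all maximal
scoring segments are extracted with the Ruzzo–Tompa algorithm. This has
three properties that a literal "longest window with average ≥ t" rule
lacks: a segment's identity is ≥ t exactly when its score is ≥ 0; no segment
can be extended *or trimmed* without lowering its score, so boundaries are
not dragged outward by distant chance matches in fast-evolving background;
and boundaries always land on identical columns, which is how a human
highlights a motif. An identical block flanked by pure mismatch is returned
exactly, because any extension strictly lowers the score. Segments shorter
than `min_len` are discarded; segments separated by ≤ `merge_gap` columns
(default 0) are merged when the merged stretch still meets the threshold.

Motif coordinates are reported in both frames: alignment columns and
residues of the ungapped reference row (1-based inclusive throughout; since
boundaries are match columns, both ends map to real residues). Overlap with
helix or binding-site annotations uses inclusive-interval intersection and
Jaccard; a motif is flagged helical when its Jaccard with any helix-class
annotation reaches 0.5 (configurable). Helix intervals are inputs, not
predictions — structure prediction is out of scope; only the printed
confidence combination 0.8·ipTM + 0.2·pTM is implemented.

## Composition and charge

Residue frequencies are counts over non-X residues; the top-3 ranking breaks
ties alphabetically so reports are deterministic. The charged set is
{D, E, K, R}: histidine is only partially protonated at neutral pH and is
excluded by default, but can be added through `charged_set`.

## Phenotype statistics

Cuticle scoring uses the fixed ordinal scheme 0–5 (wildtype → fragmented
cuticle); the per-genotype mean is Σ k·count_k / n and the category
distribution is suitable for 100 %-cumulative-bar rendering. Categories are
not reweighted.

`expected_lethality` enumerates Mendelian classes with per-class viability:

- het × het (zygotic): death = 0.25·(1−v_hom) + 0.5·(1−v_het); a fully
  lethal recessive gives exactly 25 %.
- germline clone × het: every embryo lacks maternal product; half receive a
  paternal wildtype allele (viability = zygotic rescue), half are
  maternal/zygotic mutants (viability = v_hom); full rescue of the rescued
  half gives exactly 50 %. Observed lethality bands of 48–65 % in such
  crosses correspond to partial rescue.

Relative viability from balancer counts defaults to
`100·non_balancer/(non_balancer+balancer)`; because published tables rarely
state the denominator, `denominator="balancer"` provides the alternative
convention.

Junctional intensity per image is mean(line values) − mean(circle values)
(background subtraction; negative values are reported, not clamped). The
ratio of the two group means carries a first-order Taylor (delta-method)
variance, Var[X/Y] ≈ Var[X]/μ²_Y + μ²_X·Var[Y]/μ⁴_Y − 2·μ_X·Cov[X,Y]/μ³_Y,
with sample moments at ddof = 1 and Cov set to 0 for unpaired groups —
GFP-negative and GFP-positive embryos are distinct animals; the `paired`
switch keeps the full formula. The Monte-Carlo check applies the formula to
replicates of sample means, where it tracks the empirical variance of the
ratio to well within 10 % at the coefficients of variation typical of such
measurements.

## Variant triage

The pipeline starts from called VCFs (calling itself is out of scope).
Records are split per ALT allele and keyed by (chrom, pos, ref, alt); the
hard filter removes QUAL < 199 or DP < 2 (strict inequalities). Balancer
subtraction removes every key that is non-hom-ref in *all* lines of the
cohort — the defining signature of a shared balancer chromosome — and never
removes a variant absent from at least one line. A `union_callsets` helper
merges two callers' records on the same key (first caller wins on
collisions; genotype reconciliation across callers is not modeled).

Consequence annotation is codon-level against a minimal transcript model
(sorted non-overlapping exons, genomic CDS interval, CDS length divisible
by 3, strand-aware extraction): CDS SNVs become nonsense
(`Q1310STOP`-style notation), missense (`D2048G`) or synonymous; SNVs at
the first two bases of an intron in transcription order are splice-donor
calls (acceptors are deliberately not modeled); CDS indels with a length
shift not divisible by 3 are frameshifts; everything else is `other`. The
REF allele is checked against the genome and a disagreement is an error, not
a silent skip. Prioritization ranks truncating lesions (nonsense = splice
donor = frameshift) above missense above synonymous/other, ties broken by
position, and maps each truncating call onto annotated regions: a region is
retained if it ends before the stop, lost if it starts at or after it,
truncated otherwise.

## Synthetic data

`simulate_family` evolves a root protein (drawn uniformly over the 20
residues) independently to each taxon on a star phylogeny — matching a
reference-versus-each-ortholog comparison design. Substitution counts per
site are Poisson(distance × multiplier) and each jump is uniform over the 19
alternatives, so expected identity to the root has the closed form
100·(1/20 + (19/20)·exp(−(20/19)·d_eff)), used throughout the tests as an
oracle (computed per site and averaged per region; it describes
substitution-only divergence, i.e. gap-free columns). Indels (geometric
lengths, mean 3) occur only in the IDR outside planted motifs, so motif
ground-truth coordinates stay well defined; deletions stop at the boundary
of non-eligible sites. The generator returns the true root/taxon alignment,
per-taxon region coordinates and planted-motif spans.

Default conditions: 6 taxa at distance 2.0 expected substitutions per site;
rate multipliers 0.1 (domains), 1.0 (IDR), 0.3 (FAB); three 20-residue
planted motifs at 0.1. This emulates the deep-insect comparison regime in
which folded domains remain clearly alignable (expected identity ≈ 82 %)
while the IDR outside its motifs approaches the 5 % random floor (≈ 17 %)
— the regime where region-aware profiling earns its keep. The shallower
Diptera-like regime (IDR ≈ 37 %) is reachable by setting `distances` ≈ 1.0.
Realism deliberately sacrificed for testability: no empirical substitution
matrix (LG/WAG), no rate variation beyond the region classes, no
insertion/deletion outside the IDR, and a star rather than a general tree —
so passing tests demonstrate correctness of the analyses under a known
model, not performance on real ortholog sets.

`simulate_phenotypes` draws multinomial cuticle counts (n = 200 per
genotype) and per-image intensity values following the imaging protocol:
10 close-up images per group, 20 line and 12 circle measurements per image,
Gaussian noise (σ = 10 around a background of 20 and a control signal of
100, truncated at zero), with the mutant group's signal scaled by the true
ratio (default 0.5). It does not model optical artifacts, embryo-to-embryo
variance components, or correlated measurements within an embryo.

`simulate_vcf_cohort` builds a toy genome (9 kb) and a four-exon plus-strand
transcript (734 codons), plants one unique heterozygous nonsense lesion per
line (a CAG codon whose C→T transition creates TAG), 50 balancer variants
heterozygous in every line, one passing synonymous CDS variant per line
(exercising prioritization), and intergenic noise of which half fails the
QUAL/DP filter. Lesion, balancer and noise positions are disjoint by
construction. Everything round-trips through written VCF text (whole-number
QUALs survive the float32 round-trip through VCF parsers).

All generators are bit-reproducible given (config, seed).

## Numerical and degenerate-input choices

- Scores are sums of integers held in float64, so traceback equality
  comparisons are exact.
- 1-based inclusive coordinates everywhere (residues, alignment columns,
  VCF positions); region tables are validated for overlap and range.
- X is a first-class residue: allowed in sequences, never identical in any
  identity computation, excluded from composition denominators.
- Empty inputs raise: empty FASTA, empty cuticle table, empty intensity
  lists, zero denominator mean, no gap-free columns in ungapped identity.
- Band edges partition [0, 100] with lower-inclusive bins, so banding a
  computed identity always succeeds and is consistent with `bin_identity`.

## Known limitations

- The profiler's per-region identities depend on the supplied region
  coordinates; no attempt is made to infer domain boundaries.
- The motif scanner compares exactly two rows; conservation across many taxa
  must be assessed by scanning against different comparators.
- The splice model covers donors only, and the transcript model carries a
  single CDS interval (no alternative isoforms).
- The delta-method variance is first-order; it understates the variance of
  a ratio when the denominator's coefficient of variation is large.
- Test problem sizes (570-residue families, 9 kb cohort genomes, 10⁵
  Monte-Carlo replicates) were chosen as the smallest sizes at which the
  statistical checks have useful power.
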