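# Methods

## Genotyping model

Each pileup site is summarised by its depth *d*, base calls *o₁…o_d* and
Phred qualities *q₁…q_d* (error probabilities εᵢ = 10^(−qᵢ/10)).  For the
most frequent non-reference base (ties broken lexicographically; N calls
never count as reference or alternate support), four genotype states are
compared.  A read drawn from a cell population with alternate fraction *f*
contributes likelihood

    L_i(f) = (1 − f)·P(oᵢ | ref, qᵢ) + f·P(oᵢ | alt, qᵢ),
    P(o | a, q) = 1 − ε  if o = a,  else ε/3,

so the three germline states are the fixed points f = 0, ½, 1 and the
mosaic state is the marginal ∫₀¹ ∏ᵢ L_i(f) · π(f) df.  All products are
accumulated in log space; observations are collapsed to counts per unique
quality so the cost per site is independent of depth.

Priors are Hardy–Weinberg in the population alternate frequency p_alt,
rescaled by (1 − p_m), with p_m the prior mass of the mosaic state:
π(hom_ref) = (1−p_alt)²(1−p_m), π(het) = 2p_alt(1−p_alt)(1−p_m),
π(hom_alt) = p_alt²(1−p_m), π(mosaic) = p_m.  Defaults p_m = 10⁻⁷ and
default_p_alt = 10⁻⁴ encode that a random genomic site is very unlikely to
be either polymorphic (absent a database record) or mosaic; both are
config-exposed.  p_alt is looked up allele-aware in a dbSNP-style VCF (AF
INFO tag) when one is supplied.

A site is nominated as a candidate when posterior(het) + posterior(mosaic)
≥ 0.05 and at least one read supports the alternate.  Both germline-het
and mosaic mass count because allele-specific expression and copy-number
change distort RNA allele fractions; germline status is resolved later by
the matched-DNA/population/VAF filters rather than by the genotyper.

### Quadrature

The mosaic marginal uses 512-point Gauss–Legendre quadrature on (0, 1)
under a Beta(1,1) (uniform) fraction prior, evaluated by log-sum-exp.
Gauss–Legendre was chosen over equal-weight rules because the error-free
likelihood is a polynomial in *f* of degree ≤ *d*: the rule is then exact
(the 1/2 and 1/6 closed-form cases hold to machine precision), and on
random sites with depth ≤ 30 it agrees with a 10⁵-point trapezoid
reference to better than 10⁻⁸ relative.  A non-uniform Beta prior is
supported by folding its log-density into the quadrature weights.

## Filters

Filters are pure predicates over (candidate, site, config); each records a
pass/fail verdict and the final call set is the intersection, so ordering
is bookkeeping only.  Boundary semantics are strict-less-than throughout
(5% VAF, 5 alternate reads, 50% high-quality support all pass exactly at
the boundary; RNA VAF exactly 0.5 passes the germline cap).

- **Strand bias** uses a two-sided Fisher exact test on the allele ×
  orientation table.  The p-value is computed by direct hypergeometric
  enumeration, vectorised over the table family with fixed margins, with
  the standard relative tie tolerance of 10⁻⁷ (the convention of R's
  fisher.test); it matches `scipy.stats.fisher_exact` to ~10⁻¹⁶ while
  allowing an exhaustive scan of all ~6.4·10⁵ tables with total ≤ 60 in
  seconds.  Mapping-quality and within-read-position bias use the Wilcoxon
  rank-sum test (`scipy.stats.mannwhitneyu`, exact for small tie-free
  samples, otherwise normal approximation with tie correction);
  within-read position is operationalised as distance to the nearer
  aligned read end.  α = 0.01 per test, no cross-candidate correction:
  these are per-site artifact heuristics, not inference.
- **Linkage**: two candidates within 1 kb co-covered by ≥2 read pairs fail
  when the co-covering pairs carrying the alternate at one site are
  exactly those carrying it at the other (non-empty) — the signature of a
  misaligned read population.  One shared read cannot establish complete
  linkage, hence the minimum of two.
- **Realignment verification** replaces an external second aligner with a
  pluggable contract: a read is confirmed iff an affine-gap local
  alignment (match 1, mismatch −2, gap open −4, extend −1; Biopython
  PairwiseAligner) of the read against its claimed spliced reference beats
  the best alternative placement in the surrounding window (claimed blocks
  masked to N, window = locus ± 2 read lengths) by ≥5 score units and
  reaches at least half the perfect score.  Tandem duplications therefore
  compete as alternative placements and defeat confirmation.
- **High-quality support**: high-quality = realignment-confirmed AND ≥6 bp
  from both aligned read ends AND ≥5 bp from any splice junction.  The
  paper-free constants 6/5 bp are config-exposed defaults; "near" has no
  canonical value in the field.
- **Editing strand rule** in genome coordinates: a + strand gene
  transcribes A>I editing as A>G; a − strand gene as T>C.  Candidates
  overlapping any gene that triggers a rule fail (conservative for
  opposite-strand gene overlaps); intergenic candidates are exempt.  The
  optional oxidation rule set (G>T on +, C>A on −) follows the same
  mechanics and is off by default.  Every editing filter can flag instead
  of drop (`flag_only`), emitting non-PASS VCF records.
- **Germline**: with matched DNA, het/hom-alt genotypes are germline,
  hom-ref sites with DNA VAF ≤ 0.02 are somatic, anything else is
  unresolved (kept, flagged).  Without matched DNA, allele-aware population
  database membership and an RNA VAF cap of 0.5 stand in.  Cohort
  recurrence removes variants carried by more than `max_individuals`
  distinct individuals (default 1; disease-cohort analyses typically use
  2); tissues of one donor never trigger it.

## Pileup construction

Reads must be coordinate-sorted SAM/BAM, QC-passed: primary, not
duplicate-flagged, properly paired (unless single-end mode), MAPQ ≥ 20 —
the ambiguity gate passes STAR's 255 for unique mappers.  Aligned blocks
are split at N CIGAR operations; spliced-out positions contribute no
evidence.  Overlapping mates contribute their higher-quality base once per
pair (one molecule, one vote).  N base calls are excluded from depth by
default.  Sites require post-QC depth ≥ 10; the same gate defines the
powered territory used as the burden and sensitivity denominator.  The
depth gate is applied after QC because QC-failed reads carry no calling
evidence.

## Synthetic data

The generator emulates a stranded (dUTP-convention: read 2 matches the
gene strand) paired-end mRNA-seq experiment: a random genome (default
1 Mb, GC 0.5) with 40 multi-exon genes on alternating strands (introns
≥ 60 bp), uniform fragment sampling over each transcript interior,
junction-spanning alignments, per-gene depth drawn from 50–200×, and
constant base qualities q = −10·log₁₀(base_error) with base_error = 10⁻³,
so the genotyper's error model matches the simulation exactly.  A 200 bp
segment of one gene is duplicated into intergenic space to defeat unique
realignment there; nothing is planted in that gene.  Planted classes:
mosaics (VAF 0.10–0.40), germline heterozygotes (VAF 0.5, also emitted as
a population VCF with AF 0.25), editing events on the strand-rule
signatures (VAF 0.15–0.60; half are catalogued in the emitted editing
database, the strand rule must catch the rest), 8-oxo-G and generic
strand-biased artifacts whose alternate allele appears only on
forward-orientation reads (VAF 0.25–0.40), and misalignment clusters of
three completely linked substitutions.  Carrier status is drawn once per
fragment (shared across a cluster), so empirical VAFs are binomial around
the planted values.

What the simulation does **not** model: expression heterogeneity between
genes beyond the uniform depth draw, PCR duplicates beyond flagged decoys,
indels and structural variation, position-dependent machine error
profiles, allele-specific expression, and real misalignment (clusters are
planted as linked substitutions rather than as displaced reads).  Passing
tests therefore demonstrate the correctness of the genotyper and the
discriminating logic of each filter under matched model assumptions — not
calling performance on real tissue, where error processes are richer.

Mosaic plants avoid the editing/oxidation signature substitutions of their
host gene strand so that a perfectly specific editing filter costs no
planted sensitivity; a real A>G mosaic inside a + strand gene would be
removed, which is the documented precision-first trade-off of the strand
rule.  Plants sit ≥15 bp apart, ≥8 bp from exon boundaries, outside
homopolymer runs, and within transcript interiors where simulated coverage
is uniform.

The benchmark configuration used by the acceptance layer enables the
oxidation rule set because the dataset plants 8-oxo-G artifacts — the
recommended pairing for oxidation-affected samples.  Read-orientation
evidence alone cannot flag a low-depth oxidative artifact at α = 0.01
(about seven forward-only alternate reads are needed), which is why the
signature-based rule exists.

A cell-line-mixture design is supported for benchmarking against germline
surrogates: expected VAF = Σ_lines proportion × copies / 2, matching the
mixing arithmetic of pooled-line experiments.

## Evaluation

Sensitivity = recovered / powered truth; precision = true calls / all
calls.  The denominators are deliberately asymmetric: coverage limits what
is recoverable, but every emitted call is accountable.  Empty denominators
report NaN, never zero.  Burden = calls per powered megabase.  Spectra use
the 96 pyrimidine-centric trinucleotide channels with purine-reference
calls collapsed by reverse complement; optional per-channel opportunity
weights (trinucleotide counts of the powered territory) divide before
renormalisation.  A two-sample Z-test of proportions with odds ratio is
provided for group burden comparisons.

## Problem sizes and determinism

The default test and acceptance datasets use a 1 Mb genome with ~40 kb of
powered exonic territory (~21 000 read pairs), which exercises every
filter with hundreds of candidates while a full run completes in well
under a minute; smaller 120 kb datasets back the fast unit-level tests.
All randomness flows through seeded `numpy` generators: identical seeds
give byte-identical FASTA/GTF/SAM outputs and byte-identical VCF/TSV call
files (no timestamps are written).  Per-chromosome runs are supported and
their union equals the whole-genome run; cohort recurrence, which crosses
samples, is applied after any such union.

## Known limitations

- Indels and multi-nucleotide variants are out of scope; multi-allelic
  sites analyse the top alternate and fail when the second alternate
  exceeds 2% VAF.
- The realignment verifier is a local-alignment stand-in for an external
  second aligner; an adapter satisfying the same contract can substitute.
- p-values from the bias tests are heuristics at per-site level; no
  multiplicity control is attempted or intended.
- The germline VAF cap (0.5) passes balanced heterozygotes whose sampled
  RNA VAF falls at or below 0.5 when no database or matched DNA covers
  them.
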