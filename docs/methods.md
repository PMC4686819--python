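# Methods

`brcaness` re-implements, as a tested library, the analysis chain used to
argue that osteosarcoma genomes carry "BRCAness" — the genomic scars of
homologous-recombination deficiency (HRD) familiar from *BRCA1/2*-mutated
breast and ovarian cancer — from tumor/normal exome variant calls and
allele-specific SNP-array copy-number profiles. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Somatic variant filtering

Calls are cleaned with pure per-call exclusion predicates: segmental
duplication regions; mapability < 0.5; any variant-supporting read in the
matched normal; normal depth < 10; tumor depth < 8; fewer than 3 variant
reads in the tumor; VAF < 0.05; population allele frequency > 2%; call
quality not above a phred floor of 20. Pass conditions are inclusive at
each stated boundary (a VAF of exactly 0.05 passes), the literal reading
of exclusions phrased as strict inequalities. Because every filter is a
pure predicate, the chain is idempotent, order-independent, and monotone
in each threshold — all three are asserted as property tests. A call
failing several filters is tallied under each. The "fewer than 3 variants
in the tumour" clause is interpreted as a minimum of 3 variant-supporting
reads. Summaries report SNV/indel burden, Dn:Ds over exonic SNVs
(non-synonymous = missense + truncating) and Ts:Tv (transitions C↔T,
A↔G); ratios with a zero denominator are reported as missing.

## Mutation spectra and signatures

SNVs are binned into the 96 pyrimidine-normalized trinucleotide channels;
purine-reference calls are reverse-complemented (a hypothesis property
test asserts strand invariance). Spectra can be normalized by the
reference exome's 3-mer frequencies (channel count / context frequency,
rescaled to sum to 1). The packaged 3-mer table is synthetic — shaped
like a capture design (CpG-depleted, GC-enriched flanks) but not derived
from a real bait set; users supply their own for real data.

Deviation of a tumor's 6-class spectrum from the cohort background
(pooled counts, tested tumor included by default) uses a Pearson
chi-square test with df = 5. Tumors with fewer than six SNVs are flagged
underpowered but still tested.

Signature decomposition is non-negative matrix factorization under the
generalized Kullback–Leibler divergence with multiplicative updates —
the convention for count data — with a Frobenius objective available by
flag. Convergence: relative objective change < 1e-6 or 2,000 iterations.
Ten random restarts are run and the lowest-error restart kept; fitted
signatures are column-normalized with exposures rescaled compensatorily.
Initial exposures are identical across samples, which makes the fit
exactly equivariant under sample permutation (asserted in tests); the
objective trajectory is stored so its monotonicity can be asserted per
iteration. The number of signatures is swept over {2, 3, 4} and chosen
from the differentiation report (maximum pairwise cosine between fitted
signatures; lower is better). Recovery tests match fitted to true
signatures by greedy maximum-cosine assignment, since NMF column order is
arbitrary.

## Copy-number scars

Segment tables are 0-based half-open with total and minor-allele copy
number. Non-diploid segments must be larger than 50 kb with at least 21
probes; diploid-heterozygous segments are always retained as background.

* **HRD-LOH**: adjacent LOH segments (minor CN 0, total CN ≥ 1; homozygous
  deletions excluded, since array LOH reflects allelic imbalance of
  retained DNA) are merged, and runs longer than 15 Mb that cover less
  than 90% of their chromosome ("subchromosomal", tolerating unsegmented
  telomeric gaps; configurable) are counted.
* **LST**: after smoothing out segments shorter than 3 Mb and merging
  equal-state neighbours, breakpoints whose two flanking segments are both
  ≥ 10 Mb are counted per chromosome arm (whole chromosome when no arm
  model is supplied — toy karyotypes lack centromeres). LST is computed on
  the **total** copy-number profile: copy-neutral LOH is not an LST state
  change here. This keeps the two scars orthogonal — LOH events move only
  HRD-LOH, amplitude changes only LST — and lets the simulator realize
  requested counts of each exactly.

Both scores are checked for exact agreement against independent
brute-force enumerators on 1,000 random profiles, and for invariance
under splitting segments into identical-state pieces. Tumors are flagged
BRCA-like at HRD-LOH ≥ 15; the LST threshold is a required configuration
value with a documented default of 15, since no validated cutoff exists
for this scoring variant. Percent genome altered counts territory with
total CN ≠ 2 or minor CN 0.

SCNA events are classed as amplification (total CN > 4), gain (= 3) or
deletion (< 2); segments at total CN 4 or in copy-neutral LOH fall in no
class and yield no event. Focal events (< 1 Mb) recurring in more than
15% of the cohort are reported after interval union across samples.

## Windowed SCNA significance

A GISTIC-style question — which loci are hit more often than chance? —
answered by resampling: per chromosome and event class (gains and
amplifications fold into one gain-like class; deletions are loss-like),
every observed event is re-placed uniformly at random with its length and
sample identity preserved, events placed independently. Coverage is the
number of distinct samples overlapping each 1-kb window. The empirical
p-value uses a +1 pseudo-count, `p = (1 + #{null ≥ obs}) / (1 + N)`, so it
is a valid finite-sample p-value; N defaults to 10,000 iterations, which
resolves p ≈ 1e-4. Benjamini–Hochberg adjustment runs across all windows
of the genome within each class (cross-checked against a textbook BH
implementation), and contiguous windows with q < 0.01 are merged into
regions annotated with their minimum-q peak.

Because coverage is integer-valued, the +1-corrected p is conservatively
discrete; calibration is therefore assessed as the mean per-chromosome
rejection rate at level α against α within Monte-Carlo error computed
across replicate chromosomes, where correlation between nearby windows
dominates the variance. No G-score amplitude weighting, arm-level
analysis or peel-off is implemented.

## Clonality

The cancer cell fraction of a point mutation is inverted from its VAF:

    CCF = VAF · (ρ·CN_t + 2·(1 − ρ)) / (ρ · m)

with purity ρ, local total copy number CN_t and multiplicity m chosen as
the integer in [1, CN_t] whose expected clonal VAF is nearest the
observation; the estimate is capped at 1 (read-sampling noise otherwise
pushes clonal mutations to nominal CCFs slightly above 1, and
re-assigning them a larger multiplicity instead fabricates intermediate
subclones). With known multiplicity the inversion is exact.

Clones are counted by 1-D single-linkage clustering: sorted CCFs split
wherever the neighbour gap exceeds 0.1; clusters smaller than max(2, 5%
of variants) are absorbed into the nearest center. This is a deliberately
simple substitute for a Dirichlet-process mixture: it cannot resolve
subclones carrying fewer than ~5% of mutations, and overlapping clones
closer than the read-noise scale merge. Mutations (and SCNA events) are
labeled clonal at cellular fraction ≥ 0.9 — a documented convention, not
a fitted threshold. SCNA cellular fractions come from simulation truth in
tests; for array-style input a single-event mixture fit (grid search of
the fraction against the expected log-ratio) is provided.

Gene-level analysis over a 69-gene BRCA-network panel (BRCA1/2 plus 67
interactors; real symbols, synthetic placeholder coordinates on the toy
karyotype) computes each gene's clonal and subclonal SCNA frequency
across the cohort and their product, clusters genes by average-linkage
Euclidean distance on the frequency pair, and ranks outliers by distance
from the cohort centroid.

## Driver prioritization and reporting

Variants are retained when protein-truncating or splice-site, or missense
with SIFT ≤ 0.05 and both PolyPhen2 and MutationTaster > 0.8 (the
conventional damaging directions; indels are retained by effect class
only, as the missense predictors do not score them), at VAF ≥ 0.05.
Recurrent genes require retained mutations in ≥ 2 distinct tumors —
somatic only by default. The germline screen applies the same predicate
to a susceptibility panel and annotates overlap with tumor LOH segments.
The cohort report aggregates per-tumor burden, scar profiles and a
gene-by-tumor matrix; the packaged 32-tumor reference table reproduces
its printed cohort statistics (SNV median 66.5, range 7–3,153; indel
median 33.5, range 17–529).

## The synthetic-data generator

The generator emulates the study design — an exome-sequenced tumor/normal
cohort at mean depth 150 with SNP-array copy-number profiles — with full
ground truth. SNV contexts are drawn from per-tumor mixtures of three
built-in generator signatures occupying disjoint substitution-class
blocks (CpG-focused C>T, C>A, T>C; well-separated so recovery is
identifiable). Read support follows
VAF = ρ·CCF·m / (ρ·CN_t + 2(1 − ρ)) with Poisson depths (floor 1) and
binomial alt counts. Segment profiles tile each chromosome exactly;
requested counts of >15-Mb subchromosomal LOH segments and ≥10-Mb-flank
breakpoints are realized exactly on disjoint chromosomes, recurrent focal
loci are embedded per tumor at a configured penetrance, and uniform
background events (0.5–2.9 Mb, below the LST smoothing scale) are
overlaid on diploid territory only. Ground truth — signature of origin,
true CCF, intended filter fate, per-tumor HRD-LOH/LST/percent-altered,
locus carrier status — lives in sidecar tables, never in the VCF/SEG
records the pipeline reads.

What the generator does **not** emulate: alignment artifacts, FFPE
damage, kataegis or chromothripsis breakpoint geometry, array intensity
noise or segmentation error, germline contamination of somatic calls,
correlated read depth along the genome. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to real-data artifacts.

Default problem sizes used by the test suite and the acceptance script —
a 5-chromosome toy karyotype (50–250 Mb; a GRCh37-like 24-chromosome
model is available), cohorts of 30–50 tumors, 10,000 resampling
iterations on a reduced 3×10-Mb karyotype for the windowed test, 1,000
random profiles for the oracle checks — are desk-scale choices that keep
every quantity identifiable at the stated tolerances.

## Known limitations

* The LST variant counted here (total-CN states, default threshold 15) is
  one member of a family of large-scale-instability scores; absolute
  values are not interchangeable with other implementations.
* Clone counting is heuristic; it reports a lower bound on clonal
  complexity under read noise.
* The resampling null places events independently; joint per-sample
  multiplicities are not preserved.
* CN = 4 segments belong to no event class by the reporting convention
  adopted; they still contribute to percent genome altered and LST.
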