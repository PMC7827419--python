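# Methods

## Scope and data model

The pipeline starts from variant tables, not reads: a minimal VCF 4.2
dialect (CHROM, POS, REF, ALT and per-sample DP/AD), BED3 mapped-region
intervals, GFF3 gene models and a TSV sample manifest (roles `parentA`,
`parentB`, `f1`, `control`, `mutant`, `progeny`). Only DP and AD are
interpreted; multi-allelic sites are split into biallelic records on read
and merged on write, and screening operates on biallelic records. An absent
sample cell means "uncovered", never "zero depth". Upstream trimming,
alignment and primary variant calling are out of scope, as are structural
variants and InDels longer than 2 bp, which a short-fragment
reduced-representation assay cannot screen.

## Mutation screen

**Control consensus.** A site is assessable when every control sample has
depth ≥ `min_depth` (default 5) and a clearly homozygous major allele
(major-allele fraction ≥ 0.75), and all controls agree on that allele.
Requiring the controls' own depth floor is a deliberate reading of
"common to the controls": without it, a shallowly covered control could
rubber-stamp a site it cannot actually vouch for. Both thresholds are
parameters.

**Calling.** At an assessable site a mutant line is called mutated when its
depth is ≥ `min_depth` and the non-consensus allele reaches fraction
≥ `min_af` (default 0.25). Induced mutations in these designs are
heterozygous, so an allele fraction near 0.5 is the expectation and the
0.25 floor separates real heterozygous variants from read noise; fractions
up to 1.0 are accepted so that a homozygous-looking novel allele (possible
after segregation) still counts as one mutation. InDels are kept only when
|len(alt) − len(ref)| ∈ {1, 2}; equal-length multi-base blocks and longer
InDels are dropped.

**Summaries.** Substitutions are strand-collapsed into six categories; the
two transition categories are A/T>G/C and G/C>A/T. Densities are
n / L × 10⁷ per 10 Mb. Every line currently shares the mapped-region BED
total as its denominator L because the minimal variant tables carry no
per-base coverage; `mutation_density` accepts an explicit per-line length
for pipelines that track per-line assessable footprints, where denominators
genuinely differ. The generation back-correction divides an observed
density by (1 − h·q); the default heterozygous-carrier fraction h = 2/3 is
the Mendelian carrier composition one selfing after a heterozygous
induction event (1/3 of carriers are homozygous, 2/3 heterozygous) and
q = 1/4 is the fraction of heterozygous mutations lost at the next selfing.
Both are exposed as parameters since the carrier-composition assumption,
while standard, is a modelling choice.

## Recombination screen

**Marker cascade.** Pooled parental read depths must reach `min_depth_pool`
(default 10) with *every* read in a pool supporting one allele (a single
discordant read disqualifies the site — pooled inbred parents should be
fixed), the two parents must be fixed for different alleles, and the F1
pool's donor-allele fraction must lie in the closed interval [0.25, 0.75].

**Zygosity.** BC1 genotypes are recurrent-homozygous or heterozygous, never
donor-homozygous, so calls are driven by the recurrent-parent allele
fraction: exactly 1.0 → HOM, within the closed band [0.25, 0.75] → HET,
anything else → MISSING. The literal 1.0 requirement means a single
discordant read voids a HOM call; with per-marker depths of order 5–50 this
is the faithful reading of "100% allele frequency", and the band bounds are
closed at both ends.

**Counting.** MISSING calls are dropped before adjacency is formed:
informative markers flanking a gap become adjacent, which uses every marker
without inventing events at gaps. The singleton rule then removes every
interior call whose two informative neighbours both disagree with it —
flags are computed on the unmodified vector and removals applied
simultaneously, terminal calls are never removed, and exactly one pass is
applied (iterating the rule could erode genuine short double-crossover
tracts). Events are adjacent unequal pairs, counted per chromosome and
summed; no event spans a chromosome boundary. Chromosomes with fewer than
three informative markers pass through the filter unchanged.

Counts are downward biased even at zero genotyping error: double crossovers
inside one marker interval cancel, crossovers beyond the outermost markers
are invisible, and the singleton filter removes genuine double crossovers
that isolate a single marker. The recovery tests therefore compare counted
events against a truth-side expectation that applies the same restriction
of crossovers to marker intervals, computed independently by run-length
decomposition of the true zygosity sequence.

## Group statistics

Student's pooled-variance two-sided t-test is the default (Welch available
behind a flag); identical zero-variance groups return t = 0, p = 1, and
zero-variance groups with unequal means are flagged degenerate rather than
silently returning infinities. Chi-square tests are Pearson tests on
group × category count tables (never percentages) with df = (G−1)(C−1), a
flag when any expected count is below 5, and exclusion of zero-total groups
with a warning. Because published spectrum comparisons are sometimes
per-category, a category-vs-rest construction is provided alongside the
full-table test; neither is asserted to be the canonical one. No
multiple-testing correction is applied by default; Bonferroni is available
behind a flag.

## Synthetic data generator

The generator emulates the study conditions end to end. Defaults describe a
12-chromosome, ~3.1 Gb genome assayed at 79,402 mapped regions of mean
length 144 bp (~11.4 Mb, 0.37% of the genome), mean site depth 35 with
negative-binomial dispersion k = 20 (variance m + m²/k ≈ 96 at m = 35 —
GBS depth is overdispersed, and this dispersion keeps the probability of a
site dropping below the 5× floor near 10⁻⁵ at 30× mean), read-level allele
flips at rate 0.002, parental divergence 3 × 10⁻⁴ per mapped bp, 1.5
crossovers per chromosome per meiosis placed uniformly without interference
(starting phase a fair coin), induced-mutation density 20 per 10 Mb with
12% 1–2 bp InDels, and a pistil-irradiation-like substitution spectrum
(0.31, 0.38, 0.11, 0.05, 0.11, 0.04) over the six categories, whose two
transition categories carry 69% of substitutions. Four controls and three
mutant lines per condition mirror the usual panel layout.

Design choices worth noting:

* **Mutations are injected only inside mapped regions** — unmappable
  mutations are invisible to the assay and would silently distort density
  denominators.
* **Genotyping error is modelled at the read level** (per-read allele
  flips), not the genotype level, so allele-fraction filters are actually
  exercised.
* **Gene models are placed around the assayed footprint**: each mapped
  region is genic with probability 0.6 and its gene extent (mean ~4 kb,
  four exons covering 60% of the gene) is padded around the region and
  clipped against neighbours. This reflects the genic enrichment of a
  methylation-sensitive restriction assay and gives exon fractions of
  screened mutations in a realistic 30–45% range; gene placement far from
  any assayed region is irrelevant to every downstream computation and is
  not simulated.
* **One global seed** drives a single `numpy` generator threaded through
  every stage; a fixed seed reproduces the VCF byte for byte.
* **Induced mutations are heterozygous** (dosage 0.5) in their line and
  absent from all other lines; no two mutations share a position, and
  mutation positions avoid marker positions, which keeps sites biallelic.
* Region lengths are Poisson around the mean with a 30 bp floor (roughly
  the shortest alignable fragment); gaps follow uniform order statistics
  over the unoccupied sequence.

What the generator does **not** emulate: restriction-site sequence biology
(regions are placed uniformly, not at enzyme sites), linked depth
covariation between neighbouring sites or samples (library effects),
mapping artefacts and multi-mapping noise, crossover interference (a
Poisson model; hooks exist in the meiosis routine but interference is off
because no interference information was available), residual heterozygosity
in the "inbred" parents, and dose–response biology (mutation density is a
dial, not a function of dose). Passing recovery tests therefore demonstrate
that the screening logic is correct under the stated statistical model, not
that the thresholds are optimal for any particular real dataset.

## Test and verification sizes

Unit tests run on footprints of tens to hundreds of kilobases. The
end-to-end recovery checks use: a mutation panel of 12 × 2 Mb chromosomes
with 15,000 regions (~2.16 Mb mapped), 3 controls + 3 mutants at 20
mutations/10 Mb, depth 30×, error 0 — the screened set must equal the
injected truth exactly; and a BC1 panel of 200 progeny with ~100 markers on
each of 12 chromosomes at 1.5 crossovers/chromosome — the mean counted
events must lie within three standard errors of the truth-derived
expectation. Counting primitives are checked exhaustively against
independent run-length oracles over all binary zygosity vectors up to
length 12 (counting) and length 8 (singleton rule), plus randomised vectors
via hypothesis. Chi-square calibration uses 1,000 replicate 3 × 6 tables of
420 draws each from one multinomial, requiring a 5%-level rejection rate in
[0.035, 0.065]. These sizes were chosen so the whole suite completes in
seconds while leaving Monte-Carlo standard errors well inside the asserted
tolerances.

## Known limitations

* The control-consensus purity threshold (0.75) and the heterozygous
  calling band are coupled to the assumed error model; heavily contaminated
  controls would need a stricter purity.
* Per-line density denominators require external per-line coverage
  information; the bundled driver uses the common BED total.
* The exact-1.0 HOM rule discards high-but-imperfect recurrent fractions as
  MISSING rather than calling them HOM; at very high depth with nonzero
  error this deflates marker usage (by design — it is the conservative
  reading).
* The CLI's `report` t-tests require at least two lines per group and two
  groups; degenerate layouts produce summary tables only.
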